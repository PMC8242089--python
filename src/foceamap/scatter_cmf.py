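"""Cortical magnification, receptive-field scatter, and aggregate pRFs.

Cortical magnification (CMF, mm/deg) is estimated by fitting an exponential
relationship between cortical position and visual-field position,
x = exp(log(v / a) / b) (equivalently v = a * x^b), by robust least-absolute
residual regression, then differencing the fitted curve on a 5-deg grid.
RF scatter is the residual deviation of observed RF positions from that fit,
summarized as the interquartile range (IQR) in decile bins with a
permutation null for the IQR-vs-eccentricity slope. Aggregate pRFs pool the
FWHM discs of all units within a cortical window and measure the convex hull
of the disc union; its equivalent diameter is 2*sqrt(area/pi).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.ops import unary_union

from .geometry import FocealFrame, r_eccentricity

IQR_PER_SIGMA = 1.3489795003921634  # IQR of a Gaussian in units of sigma

EVAL_RANGES = {
    "azimuth": (-60.0, 20.0),
    "elevation": (-30.0, 30.0),
    "eccentricity": (0.0, 60.0),
}


# ------------------------------------------------------------- localization

def locate_focea_cortex(
    records: pd.DataFrame,
    frame: FocealFrame | None = None,
    window_radius_mm: float = 0.1,
    lattice_mm: float = 0.025,
    min_cells: int = 3,
):
    """Cortical point whose local RFs are closest to the focea.

    Windows of ``window_radius_mm`` slide on a ``lattice_mm`` lattice over the
    cell positions; the window minimizing the mean r-eccentricity of its cells
    wins (lexicographically smallest lattice point on ties). Returns (x, y) mm.
    """
    frame = frame or FocealFrame()
    x = records["cortical_x_mm"].to_numpy(dtype=float)
    y = records["cortical_y_mm"].to_numpy(dtype=float)
    ecc = r_eccentricity(records["azi"].to_numpy(), records["ele"].to_numpy(), frame)
    gx = np.arange(x.min(), x.max() + lattice_mm / 2, lattice_mm)
    gy = np.arange(y.min(), y.max() + lattice_mm / 2, lattice_mm)
    tree = cKDTree(np.stack([x, y], axis=1))
    best = None
    for xi in gx:
        for yi in gy:
            idx = tree.query_ball_point([xi, yi], window_radius_mm)
            if len(idx) < min_cells:
                continue
            m = float(np.mean(ecc[idx]))
            key = (m, round(xi, 9), round(yi, 9))
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("no window contains enough cells")
    return best[1], best[2]


def rotate_cortical_axes(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Rotate cortical coordinates so azimuth varies principally along x.

    The azimuth gradient direction is estimated from a plane fit of azimuth on
    (x, y); coordinates are rotated by minus its angle (an isometry), after
    which the elevation gradient lies principally along y for an orthogonal
    retinotopy. Returns (rotated records, rotation angle deg).
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    x = records["cortical_x_mm"].to_numpy(dtype=float)
    y = records["cortical_y_mm"].to_numpy(dtype=float)
    X = np.stack([np.ones_like(x), x, y], axis=1)
    coef, *_ = np.linalg.lstsq(X, records["azi"].to_numpy(dtype=float), rcond=None)
    gx, gy = coef[1], coef[2]
    if np.hypot(gx, gy) < 1e-12:
        raise ValueError("degenerate azimuth gradient")
    ang = np.arctan2(gy, gx)
    c, s = np.cos(-ang), np.sin(-ang)
    out = records.copy()
    out["cortical_x_mm"] = c * x - s * y
    out["cortical_y_mm"] = s * x + c * y
    return out, float(np.rad2deg(ang))


# ------------------------------------------------------------------ CMF fit

@dataclass
class CMFFit:
    """Exponential cortical-position model v = a * x^b with CMF evaluation.

    ``shift`` is added to the visual variable before fitting when it spans
    non-positive values (the log otherwise being undefined) and removed for
    evaluation. eval_v are midpoints of the 5-deg evaluation steps; cmf the
    forward-difference magnification (mm/deg) at those midpoints.
    """

    a: float
    b: float
    shift: float
    axis: str
    eval_v: np.ndarray
    cmf: np.ndarray
    v_obs: np.ndarray = field(repr=False, default=None)
    x_obs: np.ndarray = field(repr=False, default=None)
    residuals_deg: np.ndarray = field(repr=False, default=None)

    def predict_cortical(self, v):
        vv = np.asarray(v, dtype=float) + self.shift
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.exp(np.log(vv / self.a) / self.b)

    def predict_visual(self, x):
        return self.a * np.asarray(x, dtype=float) ** self.b - self.shift


def fit_cmf(
    records: pd.DataFrame,
    axis: str = "azimuth",
    frame: FocealFrame | None = None,
    origin_mm=(0.0, 0.0),
    eval_range=None,
    eval_step: float = 5.0,
) -> CMFFit:
    """Fit v = a*x^b by least-absolute residuals and evaluate CMF.

    axis selects the cortical/visual coordinate pair: "azimuth" pairs the
    cortical x with RF azimuth, "elevation" pairs y with elevation, and
    "eccentricity" pairs the distance from ``origin_mm`` (the cortical foceal
    point) with the RF's r-eccentricity. CMF is the forward difference of the
    fitted cortical position over ``eval_step``-deg steps divided by the step.
    """
    frame = frame or FocealFrame()
    if axis not in EVAL_RANGES:
        raise ValueError(f"unknown axis {axis!r}")
    if axis == "azimuth":
        x = records["cortical_x_mm"].to_numpy(dtype=float)
        v = records["azi"].to_numpy(dtype=float)
    elif axis == "elevation":
        x = records["cortical_y_mm"].to_numpy(dtype=float)
        v = records["ele"].to_numpy(dtype=float)
    else:
        x = np.hypot(
            records["cortical_x_mm"].to_numpy(dtype=float) - origin_mm[0],
            records["cortical_y_mm"].to_numpy(dtype=float) - origin_mm[1],
        )
        azi = records["azi"].to_numpy(dtype=float)
        ele = records["ele"].to_numpy(dtype=float)
        # RFs displaced >= 90 deg from the focea on either axis lie outside
        # the r-eccentricity domain (behind the animal); drop them.
        ok = (np.abs(azi - frame.focea.azimuth) < 90.0) & (
            np.abs(ele - frame.focea.elevation) < 90.0
        )
        if not ok.all():
            warnings.warn(f"{int((~ok).sum())} records outside the visual field dropped")
            x, azi, ele = x[ok], azi[ok], ele[ok]
        v = r_eccentricity(azi, ele, frame)
    fin = np.isfinite(x) & np.isfinite(v)
    x, v = x[fin], v[fin]
    if len(x) < 10 or np.ptp(v) < 20.0:
        raise ValueError("need >=10 records spanning >=20 deg on the axis")

    # The model maps a non-negative cortical coordinate increasing with the
    # visual coordinate. The eccentricity axis is already a distance from the
    # cortical foceal point; the signed azimuth/elevation axes are oriented
    # accordingly and re-referenced to start at the smallest position (an
    # isometry: CMF is a derivative).
    if axis != "eccentricity":
        if np.corrcoef(x, v)[0, 1] < 0:
            x = -x
        x = x - x.min()

    shift = 0.0
    if v.min() <= 0:
        shift = -float(v.min()) + 1.0
    vs = v + shift

    # log-log least-squares initialization (positive x only)
    posm = x > 1e-9
    if posm.sum() >= 2:
        slope, inter = np.polyfit(np.log(vs[posm]), np.log(x[posm]), 1)
        b0 = 1.0 / slope if abs(slope) > 1e-9 else 1.0
        loga0 = -inter * b0
    else:
        b0, loga0 = 1.0, np.log(max(vs.mean(), 1e-3))

    def obj(p):
        loga, b = p
        if abs(b) < 1e-6:
            return 1e12
        with np.errstate(over="ignore", invalid="ignore"):
            pred = np.exp((np.log(vs) - loga) / b)
        if not np.all(np.isfinite(pred)):
            return 1e12
        return float(np.sum(np.abs(x - pred)))

    best = None
    for p0 in ([loga0, b0], [np.log(np.median(vs) / max(np.median(x), 1e-6)), 1.0]):
        res = minimize(obj, p0, method="Nelder-Mead",
                       options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ValueError(f"CMF fit did not converge (objective {best.fun})")
    a = float(np.exp(best.x[0]))
    b = float(best.x[1])

    lo, hi = eval_range if eval_range is not None else EVAL_RANGES[axis]
    pts = np.arange(lo, hi + eval_step / 2, eval_step)
    vv = pts + shift
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = np.where(
            vv > 0, np.exp(np.log(np.where(vv > 0, vv, 1.0)) / b - best.x[0] / b),
            np.nan,
        )
    cmf = np.abs(np.diff(xs)) / eval_step
    mids = (pts[:-1] + pts[1:]) / 2.0

    v_pred = a * np.power(x, b) - shift
    residuals = v - v_pred
    return CMFFit(a, b, shift, axis, mids, cmf, v_obs=v, x_obs=x,
                  residuals_deg=residuals)


def cmf_at_focea(fit: CMFFit, frame: FocealFrame | None = None) -> float:
    """Fitted CMF value at the evaluation midpoint nearest the focea."""
    frame = frame or FocealFrame()
    target = {"azimuth": frame.focea.azimuth,
              "elevation": frame.focea.elevation,
              "eccentricity": 0.0}[fit.axis]
    ok = np.isfinite(fit.cmf)
    if not ok.any():
        raise ValueError("no finite CMF values on the evaluation grid")
    i = np.argmin(np.abs(fit.eval_v[ok] - target))
    return float(fit.cmf[ok][i])


# ------------------------------------------------------------ scatter tests

@dataclass
class ScatterProfile:
    """Residual-IQR profile over decile bins with a permutation-null p-value."""

    bin_centers: np.ndarray
    iqr: np.ndarray
    slope: float
    intercept: float
    p: float
    n_null: int

    @property
    def sigma_coefficient(self) -> float:
        """IQR slope converted to a Gaussian-SD proportionality coefficient."""
        return self.slope / IQR_PER_SIGMA


def _binned_iqr_slope(order_vals, residuals, n_bins=10, center_vals=None):
    if center_vals is None:
        center_vals = order_vals
    order = np.argsort(order_vals, kind="stable")
    splits = np.array_split(order, n_bins)
    centers = np.array([center_vals[s].mean() for s in splits])
    iqr = np.array([np.subtract(*np.percentile(residuals[s], [75, 25])) for s in splits])
    xc = centers - centers.mean()
    slope = float(np.sum(xc * iqr) / np.sum(xc * xc))
    intercept = float(iqr.mean() - slope * centers.mean())
    return centers, iqr, slope, intercept, splits


def scatter_profile(
    cmf_fit: CMFFit,
    n_null: int = 1000,
    seed: int | None = 0,
    n_bins: int = 10,
) -> ScatterProfile:
    """Residual scatter vs position with a shuffle null for the slope.

    Residuals (observed minus fitted visual position, deg) are split into
    ``n_bins`` equal-count bins. Cells are *ordered* by the fitted axis value
    (a function of the noise-free cortical coordinate, so ranking is not
    contaminated by the very scatter being measured), while the regression
    abscissa is each bin's mean observed value (an unbiased position for the
    bin). The bin IQRs are regressed on those centers; the one-tailed p-value
    is the fraction of residual-shuffled slopes greater than or equal to the
    observed slope (ties count as exceeding).
    """
    v = cmf_fit.v_obs
    res = cmf_fit.residuals_deg
    if v is None or len(v) < 50:
        raise ValueError("need at least 50 records")
    v_fit = v - res
    centers, iqr, slope, intercept, splits = _binned_iqr_slope(
        v_fit, res, n_bins, center_vals=v
    )

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(res, (n_null, 1)), axis=1)
    xc = centers - centers.mean()
    denom = float(np.sum(xc * xc))
    null_iqr = np.stack(
        [np.subtract(*np.percentile(perm[:, s], [75, 25], axis=1)) for s in splits],
        axis=1,
    )  # (n_null, n_bins)
    null_slopes = (null_iqr * xc).sum(axis=1) / denom
    p = float(np.mean(null_slopes >= slope))
    return ScatterProfile(centers, iqr, slope, intercept, p, n_null)


def binocular_scatter_test(
    azimuths,
    residuals,
    azi_cut: float = 15.0,
    n_null: int = 1000,
    seed: int | None = 0,
):
    """Monocular-vs-binocular residual-SD difference with a shuffle null.

    delta_sd = SD(monocular residuals) - SD(binocular residuals); positive when
    binocular scatter is lower. p is the fraction of label-shuffled differences
    >= the observed one.
    """
    azi = np.asarray(azimuths, dtype=float)
    res = np.asarray(residuals, dtype=float)
    bino = np.abs(azi) < azi_cut
    mono = np.abs(azi) > azi_cut
    if bino.sum() < 20 or mono.sum() < 20:
        raise ValueError("need at least 20 records per group")
    obs = float(np.std(res[mono]) - np.std(res[bino]))
    rng = np.random.default_rng(seed)
    both = np.concatenate([res[mono], res[bino]])
    nm = mono.sum()
    null = np.empty(n_null)
    for i in range(n_null):
        perm = rng.permutation(both)
        null[i] = np.std(perm[:nm]) - np.std(perm[nm:])
    p = float(np.mean(null >= obs))
    return obs, p


# ------------------------------------------------------------ aggregate pRF

@dataclass
class AggregatePRF:
    """Convex-hull pRF of the units inside one cortical window."""

    center_mm: tuple[float, float]
    radius_mm: float
    n_units: int
    area_deg2: float
    diameter_deg: float
    members: np.ndarray = field(repr=False, default=None)


def disc_union_hull_area(azi, ele, fwhm, quad_segs: int = 16) -> float:
    """Area (deg^2) of the convex hull of the union of FWHM-diameter discs."""
    discs = [
        Point(a, e).buffer(f / 2.0, quad_segs=quad_segs)
        for a, e, f in zip(azi, ele, fwhm)
    ]
    return float(unary_union(discs).convex_hull.area)


def aggregate_prf(
    units: pd.DataFrame,
    window_center_mm,
    radius_mm: float,
    quad_segs: int = 16,
) -> AggregatePRF:
    """Aggregate pRF from units within ``radius_mm`` of a cortical point.

    Each unit contributes a disc of diameter FWHM at its RF center; the pRF
    area is the convex hull of the disc union and the diameter follows
    2*sqrt(area/pi). Discs are polygonized at 4*quad_segs vertices.
    """
    dx = units["cortical_x_mm"].to_numpy(dtype=float) - window_center_mm[0]
    dy = units["cortical_y_mm"].to_numpy(dtype=float) - window_center_mm[1]
    inside = np.hypot(dx, dy) <= radius_mm
    if not inside.any():
        raise ValueError("no units inside the window")
    sub = units.loc[inside]
    area = disc_union_hull_area(
        sub["azi"].to_numpy(), sub["ele"].to_numpy(), sub["fwhm"].to_numpy(),
        quad_segs,
    )
    diam = 2.0 * np.sqrt(area / np.pi)
    return AggregatePRF(
        (float(window_center_mm[0]), float(window_center_mm[1])),
        float(radius_mm),
        int(inside.sum()),
        area,
        float(diam),
        members=np.nonzero(inside)[0],
    )


def aggregate_prf_table(
    units: pd.DataFrame,
    radius_mm: float,
    frame: FocealFrame | None = None,
    centers=None,
    quad_segs: int = 16,
) -> pd.DataFrame:
    """Aggregate pRFs centered on every unit (or explicit centers).

    Returns one row per window: center, n, sqrt(n), area, diameter, and the
    r-eccentricity of the window's mean RF position.
    """
    frame = frame or FocealFrame()
    if centers is None:
        centers = list(
            zip(units["cortical_x_mm"].to_numpy(), units["cortical_y_mm"].to_numpy())
        )
    rows = []
    for c in centers:
        try:
            ag = aggregate_prf(units, c, radius_mm, quad_segs)
        except ValueError:
            continue
        sub = units.iloc[ag.members]
        ecc = float(
            r_eccentricity(sub["azi"].mean(), sub["ele"].mean(), frame)
        )
        rows.append(
            dict(
                center_x_mm=c[0],
                center_y_mm=c[1],
                radius_mm=radius_mm,
                n=ag.n_units,
                sqrt_n=np.sqrt(ag.n_units),
                area_deg2=ag.area_deg2,
                diameter_deg=ag.diameter_deg,
                ecc=ecc,
            )
        )
    return pd.DataFrame(rows)


def regress_prf_on_ecc(
    aggregates: pd.DataFrame,
    covariates=("n", "sqrt_n"),
):
    """Multiple OLS of aggregate-pRF diameter on r-eccentricity + covariates.

    Collinear covariates are dropped with a warning. Returns a dict with the
    eccentricity slope, its SE and two-tailed p, plus the intercept.
    """
    if len(aggregates) < 10:
        raise ValueError("need at least 10 aggregates")
    cols = ["ecc"]
    X = aggregates[["ecc"]].to_numpy(dtype=float)
    for c in covariates:
        cand = np.column_stack([X, aggregates[c].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(cand)), cand])) < cand.shape[1] + 1:
            warnings.warn(f"covariate {c!r} dropped (collinear)")
            continue
        X = cand
        cols.append(c)
    fit = sm.OLS(
        aggregates["diameter_deg"].to_numpy(dtype=float), sm.add_constant(X)
    ).fit()
    return dict(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        intercept=float(fit.params[0]),
        covariates=cols[1:],
        n=int(len(aggregates)),
    )


# ------------------------------------------------------- raw-pixel variant

def stitch_tiles(tiles, canvas_shape):
    """Average overlapping tile maps into a global canvas; interpolate gaps.

    ``tiles`` is a list of dicts with keys azimuth/elevation/fwhm (2D arrays)
    and origin (row, col) into the canvas. Pixels covered by no tile but lying
    inside the covered region are filled by linear interpolation; the returned
    ``observed`` mask marks pixels backed by real tile data. Raises if the
    tile coverage is disconnected.
    """
    from scipy.interpolate import griddata
    from skimage.measure import label as cc_label

    sums = {k: np.zeros(canvas_shape) for k in ("azimuth", "elevation", "fwhm")}
    counts = np.zeros(canvas_shape)
    for t in tiles:
        r0, c0 = t["origin"]
        h, w = t["azimuth"].shape
        ok = np.isfinite(t["azimuth"])
        for k in sums:
            sums[k][r0:r0 + h, c0:c0 + w] += np.where(ok, t[k], 0.0)
        counts[r0:r0 + h, c0:c0 + w] += ok
    observed = counts > 0
    if cc_label(observed, connectivity=2).max() > 1:
        raise ValueError("tiles are disconnected")
    out = {}
    for k in sums:
        arr = np.full(canvas_shape, np.nan)
        arr[observed] = sums[k][observed] / counts[observed]
        out[k] = arr

    # fill interior gaps by linear interpolation from observed pixels
    rr, cc = np.nonzero(observed)
    hull_missing = ~observed
    if hull_missing.any() and observed.sum() >= 4:
        mr, mc = np.nonzero(hull_missing)
        for k in out:
            vals = griddata(
                np.stack([rr, cc], axis=1),
                out[k][observed],
                np.stack([mr, mc], axis=1),
                method="linear",
            )
            out[k][mr, mc] = vals
    out["observed"] = observed
    return out


def stitch_and_pixel_prf(
    tiles,
    canvas_shape,
    pixel_mm: float,
    window_radii_mm=(0.05, 0.1, 0.2, 0.4),
    min_data_fraction: float = 0.75,
    smooth_px: int = 0,
    downsample: int = 1,
    frame: FocealFrame | None = None,
    stride_px: int = 4,
    quad_segs: int = 8,
) -> pd.DataFrame:
    """Aggregate pRFs from stitched raw-pixel RF maps.

    Tiles are optionally mean-smoothed (``smooth_px``) and downsampled, then
    stitched; sliding windows keep only positions where at least
    ``min_data_fraction`` of in-window pixels carry observed (non-interpolated)
    data. Every retained window's pixels act as units in the convex-hull pRF.
    """
    from .fieldsign import _nan_mean_filter

    frame = frame or FocealFrame()
    proc = []
    for t in tiles:
        tt = dict(origin=t["origin"])
        for k in ("azimuth", "elevation", "fwhm"):
            arr = t[k].astype(float)
            if smooth_px > 1:
                arr = _nan_mean_filter(arr, smooth_px)
            if downsample > 1:
                arr = arr[::downsample, ::downsample]
            tt[k] = arr
        if downsample > 1:
            tt["origin"] = (t["origin"][0] // downsample, t["origin"][1] // downsample)
        proc.append(tt)
    if downsample > 1:
        canvas_shape = (
            int(np.ceil(canvas_shape[0] / downsample)),
            int(np.ceil(canvas_shape[1] / downsample)),
        )
        pixel_mm = pixel_mm * downsample
    stitched = stitch_tiles(proc, canvas_shape)

    h, w = canvas_shape
    rows = []
    for radius_mm in np.atleast_1d(window_radii_mm):
        r_px = radius_mm / pixel_mm
        yy, xx = np.mgrid[-int(np.ceil(r_px)):int(np.ceil(r_px)) + 1,
                          -int(np.ceil(r_px)):int(np.ceil(r_px)) + 1]
        in_disc = np.hypot(yy, xx) <= r_px
        for rc in range(0, h, stride_px):
            for cc_ in range(0, w, stride_px):
                r0, r1 = rc + yy.min(), rc + yy.max() + 1
                c0, c1 = cc_ + xx.min(), cc_ + xx.max() + 1
                if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                    continue
                disc_obs = stitched["observed"][r0:r1, c0:c1][in_disc]
                frac = disc_obs.mean()
                if frac < min_data_fraction:
                    continue
                azi = stitched["azimuth"][r0:r1, c0:c1][in_disc]
                ele = stitched["elevation"][r0:r1, c0:c1][in_disc]
                fwhm = stitched["fwhm"][r0:r1, c0:c1][in_disc]
                ok = np.isfinite(azi) & np.isfinite(ele) & np.isfinite(fwhm)
                if ok.sum() == 0:
                    continue
                area = disc_union_hull_area(azi[ok], ele[ok], fwhm[ok], quad_segs)
                rows.append(
                    dict(
                        center_x_mm=cc_ * pixel_mm,
                        center_y_mm=rc * pixel_mm,
                        radius_mm=float(radius_mm),
                        n=int(ok.sum()),
                        sqrt_n=float(np.sqrt(ok.sum())),
                        data_fraction=float(frac),
                        area_deg2=area,
                        diameter_deg=2.0 * np.sqrt(area / np.pi),
                        ecc=float(
                            r_eccentricity(
                                np.mean(azi[ok]), np.mean(ele[ok]), frame
                            )
                        ),
                    )
                )
    return pd.DataFrame(rows)
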