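"""Single-cell / single-site receptive fields from sparse-noise trials.

Evoked responses per check position are averaged (optionally with a running
nuisance regressor partialled out), fit with a 2D Gaussian, and screened with
two quality metrics: the r-squared of the fit and a bootstrapped variability
index (BVI) — the SD of bootstrap-resampled RF-center estimates divided by the
fitted Gaussian's SD. Units pass the standard filter when r2 > 0.33, BVI < 1
and the fitted amplitude is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares

from .geometry import FocealFrame, fwhm_from_sigma, r_eccentricity

R2_CUTOFF = 0.33
BVI_CUTOFF = 1.0


@dataclass
class RFMap:
    """Mean evoked response per check position on the stimulus grid."""

    values: np.ndarray  # (n_ele, n_azi), NaN where unsampled
    azi_centers: np.ndarray
    ele_centers: np.ndarray
    n_trials: np.ndarray | None = None


@dataclass
class RFFit:
    """Fitted 2D Gaussian receptive field."""

    center: tuple[float, float]  # (azimuth, elevation) deg
    fwhm: float
    amplitude: float
    baseline: float
    sigma: float  # circular sigma or geometric-mean sigma if elliptical
    r2: float
    valid: bool
    shape: str = "circular"
    bvi: float = np.nan

    def passes_filters(self) -> bool:
        return (
            self.valid
            and self.r2 > R2_CUTOFF
            and self.amplitude > 0
            and (np.isnan(self.bvi) or self.bvi < BVI_CUTOFF)
        )


def rf_map_from_trials(trials: pd.DataFrame, nuisance: str | None = None) -> RFMap:
    """Per-position mean evoked response from a trial table.

    ``trials`` columns: check_azi, check_ele, response (one row per trial).
    With ``nuisance`` naming a column (e.g. running speed), the per-position
    effects are the position coefficients of a linear model that also includes
    the nuisance regressor and its interaction with the stimulus position.
    """
    azi_c = np.unique(trials["check_azi"].to_numpy())
    ele_c = np.unique(trials["check_ele"].to_numpy())
    n_a, n_e = len(azi_c), len(ele_c)
    ai = np.searchsorted(azi_c, trials["check_azi"].to_numpy())
    ei = np.searchsorted(ele_c, trials["check_ele"].to_numpy())
    pos = ei * n_a + ai
    n_pos = n_a * n_e
    counts = np.bincount(pos, minlength=n_pos)
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0]
        coords = [(float(azi_c[m % n_a]), float(ele_c[m // n_a])) for m in missing]
        raise ValueError(f"unsampled check positions: {coords}")
    y = trials["response"].to_numpy(dtype=float)
    if nuisance is None:
        sums = np.bincount(pos, weights=y, minlength=n_pos)
        vals = sums / counts
    else:
        run = trials[nuisance].to_numpy(dtype=float)
        n = len(y)
        X = np.zeros((n, 2 * n_pos))
        X[np.arange(n), pos] = 1.0
        X[np.arange(n), n_pos + pos] = run
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        vals = coef[:n_pos]
    values = vals.reshape(n_e, n_a)
    return RFMap(values, azi_c, ele_c, counts.reshape(n_e, n_a))


def _gauss_model(params, A, E, shape):
    if shape == "circular":
        b, amp, a0, e0, sig = params
        q = ((A - a0) ** 2 + (E - e0) ** 2) / (2.0 * sig * sig)
    else:
        b, amp, a0, e0, sx, sy, th = params
        ca, sa = np.cos(th), np.sin(th)
        xr = (A - a0) * ca + (E - e0) * sa
        yr = -(A - a0) * sa + (E - e0) * ca
        q = xr * xr / (2.0 * sx * sx) + yr * yr / (2.0 * sy * sy)
    return b + amp * np.exp(-q)


def fit_gaussian_rf(rf_map: RFMap, shape: str = "circular") -> RFFit:
    """Nonlinear least-squares Gaussian fit with multi-start initialization.

    Starts from the peak pixel, the response-weighted centroid and the four
    grid corners; the best converged SSE wins. r2 is computed for the full
    model including the baseline offset. Flat maps yield an invalid fit.
    """
    if shape not in ("circular", "elliptical"):
        raise ValueError(f"unknown shape {shape!r}")
    A, E = np.meshgrid(rf_map.azi_centers, rf_map.ele_centers)
    ok = np.isfinite(rf_map.values)
    n_min = 6 if shape == "circular" else 7
    if ok.sum() < n_min:
        raise ValueError(f"need at least {n_min} sampled positions")
    a, e, z = A[ok], E[ok], rf_map.values[ok]
    span = max(a.max() - a.min(), e.max() - e.min())
    zrange = z.max() - z.min()
    if zrange <= 0:
        return RFFit((np.nan, np.nan), np.nan, 0.0, float(z.mean()), np.nan,
                     0.0, False, shape)

    peak = np.argmax(z)
    wpos = np.clip(z - z.min(), 0, None)
    cent_a = float(np.sum(wpos * a) / max(np.sum(wpos), 1e-12))
    cent_e = float(np.sum(wpos * e) / max(np.sum(wpos), 1e-12))
    starts = [(a[peak], e[peak]), (cent_a, cent_e),
              (a.min(), e.min()), (a.min(), e.max()),
              (a.max(), e.min()), (a.max(), e.max())]
    sig0 = span / 6.0

    def residual(p):
        return _gauss_model(p, a, e, shape) - z

    best = None
    for (a0, e0) in starts:
        if shape == "circular":
            p0 = [float(z.min()), float(zrange), a0, e0, sig0]
            lb = [-np.inf, -np.inf, a.min() - span, e.min() - span, 1e-3]
            ub = [np.inf, np.inf, a.max() + span, e.max() + span, 4 * span]
        else:
            p0 = [float(z.min()), float(zrange), a0, e0, sig0, sig0, 0.0]
            lb = [-np.inf, -np.inf, a.min() - span, e.min() - span, 1e-3, 1e-3, -np.pi]
            ub = [np.inf, np.inf, a.max() + span, e.max() + span, 4 * span, 4 * span, np.pi]
        try:
            sol = least_squares(residual, p0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    if best is None:
        return RFFit((np.nan, np.nan), np.nan, np.nan, np.nan, np.nan, np.nan,
                     False, shape)
    sse, p = best
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
    if shape == "circular":
        b, amp, a0, e0, sig = p
    else:
        b, amp, a0, e0, sx, sy, _ = p
        sig = float(np.sqrt(sx * sy))
    valid = np.isfinite(p).all() and r2 > 0
    return RFFit(
        (float(a0), float(e0)),
        float(fwhm_from_sigma(sig)),
        float(amp),
        float(b),
        float(sig),
        float(r2),
        bool(valid),
        shape,
    )


def bootstrap_bvi(
    trials: pd.DataFrame,
    n_boot: int = 100,
    shape: str = "circular",
    seed: int | None = 0,
    nuisance: str | None = None,
) -> float:
    """Bootstrapped variability index of the RF-center estimate.

    Trials are resampled with replacement (same total count), the map rebuilt
    and the Gaussian refit; BVI = pooled SD of the bootstrap centers
    (sqrt((SD_a^2 + SD_e^2)/2), so that BVI = 1 when the per-axis center SD
    equals sigma) divided by the original fit's sigma. If more than half the
    bootstrap fits fail, BVI is infinite and the unit fails the filter.
    """
    rng = np.random.default_rng(seed)
    base_map = rf_map_from_trials(trials, nuisance)
    base_fit = fit_gaussian_rf(base_map, shape)
    if not base_fit.valid or base_fit.sigma <= 0:
        return float("inf")
    n = len(trials)
    centers = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = trials.iloc[idx]
        try:
            m = rf_map_from_trials(boot, nuisance)
            f = fit_gaussian_rf(m, shape)
        except ValueError:
            failed += 1
            continue
        if f.valid:
            centers.append(f.center)
        else:
            failed += 1
    if failed > n_boot / 2 or len(centers) < 2:
        return float("inf")
    centers = np.asarray(centers)
    sd = np.std(centers, axis=0, ddof=0)
    pooled = float(np.sqrt(np.mean(sd * sd)))
    return pooled / base_fit.sigma


def filter_records(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the standard quality filter: r2 > 0.33, BVI < 1, amplitude > 0.

    The predicate is pure: filtering an already-filtered table is a no-op.
    """
    m = (
        (records["r2"] > R2_CUTOFF)
        & (records["bvi"] < BVI_CUTOFF)
        & (records["amplitude"] > 0)
    )
    return records.loc[m].reset_index(drop=True)


def regress_size_on_ecc(records: pd.DataFrame, frame: FocealFrame | None = None):
    """Ordinary least squares of RF size (FWHM, deg) on r-eccentricity.

    ``records`` needs columns azi, ele, fwhm. Returns a dict with slope,
    intercept, r2 and the two-tailed p-value for H0: slope = 0.
    """
    frame = frame or FocealFrame()
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    ecc = r_eccentricity(records["azi"].to_numpy(), records["ele"].to_numpy(), frame)
    if np.ptp(ecc) <= 0:
        raise ValueError("eccentricity is constant across records")
    X = sm.add_constant(ecc)
    fit = sm.OLS(records["fwhm"].to_numpy(dtype=float), X).fit()
    return dict(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        n=int(len(records)),
    )
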