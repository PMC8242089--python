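"""Synthetic data with known ground truth for every pipeline stage.

The conceptual V1 models place cells on a regular cortical grid and assign
receptive-field positions from the cortical radius z:

    ecc(n) = (1 / foceal_cmf) * z(n)^a                     (magnification)
    azi(n) = ecc(n) * cos(atan2(y, x));  ele likewise sin  (polar decomposition)
    ecc(n) <- ecc(n) + N(0, k * ecc(n))                    (radial scatter)

Model A uses a > 1 with k = 0 (a magnification gradient); Model B uses a = 1
with k > 0 (a scatter gradient). Both reduce to the same linear map at a = 1,
k = 0. On top of the cortex model the module generates wide-field evoked
responses (forward Gaussian-times-aperture sums plus noise), sparse-noise
trial tables, Bernoulli go/no-go behavior, gaze traces with compensatory eye
movements, and direct retinotopy/size maps — each with its generator
parameters returned so downstream fits can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gaze as gaze_mod
from .geometry import FocealFrame, ecc_offsets_from_polar, sigma_from_fwhm
from .prf_widefield import EvokedResponses, RetinotopyMaps
from .scatter_cmf import disc_union_hull_area


# ----------------------------------------------------------- cortex models

@dataclass
class CortexModelParams:
    """Parameters of the conceptual V1 models.

    exponent_a > 1 with scatter_k = 0 gives the magnification-gradient model;
    exponent_a = 1 with scatter_k > 0 the scatter-gradient model.
    decomposition "planar" applies the polar decomposition to azimuth and
    elevation directly; "spherical" uses the tangent-corrected inverse so the
    ground-truth eccentricity round-trips exactly through r_eccentricity.
    """

    n_grid: int = 20
    span_mm: float = 2.4
    foceal_cmf: float = 0.02  # mm/deg
    exponent_a: float = 1.5
    scatter_k: float = 0.0
    rf_fwhm: float = 15.0
    seed: int | None = 0
    decomposition: str = "planar"

    def __post_init__(self):
        if self.foceal_cmf <= 0:
            raise ValueError("foceal_cmf must be positive")
        if self.scatter_k < 0:
            raise ValueError("scatter_k must be non-negative")
        if self.exponent_a <= 0:
            raise ValueError("exponent_a must be positive")
        if self.decomposition not in ("planar", "spherical"):
            raise ValueError(f"unknown decomposition {self.decomposition!r}")


def simulate_cortex(
    params: CortexModelParams, frame: FocealFrame | None = None
) -> pd.DataFrame:
    """Cell table from the conceptual V1 model (see module docstring).

    The cortical origin (z = 0, representing the focea) is the grid center.
    Radial scatter can push an eccentricity negative; the sign is folded back
    (reflection through the focea). Columns: cortical_x_mm, cortical_y_mm,
    z_mm, true_ecc (post-noise), azi, ele, fwhm.
    """
    frame = frame or FocealFrame()
    rng = np.random.default_rng(params.seed)
    half = params.span_mm / 2.0
    g = np.linspace(-half, half, params.n_grid)
    xx, yy = np.meshgrid(g, g)
    x = xx.ravel()
    y = yy.ravel()
    z = np.hypot(x, y)
    ecc = (1.0 / params.foceal_cmf) * z ** params.exponent_a
    if params.scatter_k > 0:
        ecc = ecc + rng.normal(0.0, params.scatter_k * ecc)
        ecc = np.abs(ecc)
    phi = np.arctan2(y, x)
    if params.decomposition == "planar":
        da = ecc * np.cos(phi)
        de = ecc * np.sin(phi)
    else:
        da, de = ecc_offsets_from_polar(ecc, np.rad2deg(phi))
        # the tangent-corrected inverse wraps beyond 90 deg; such cells have
        # no visual-field direction and get NaN coordinates
        out = ecc >= 90.0
        da = np.where(out, np.nan, da)
        de = np.where(out, np.nan, de)
    return pd.DataFrame(
        dict(
            cortical_x_mm=x,
            cortical_y_mm=y,
            z_mm=z,
            true_ecc=ecc,
            azi=frame.focea.azimuth + da,
            ele=frame.focea.elevation + de,
            fwhm=np.full_like(x, params.rf_fwhm),
        )
    )


# ------------------------------------------------------------- noise model

@dataclass
class ResponseNoiseModel:
    """Additive-Gaussian trial noise and response gain."""

    noise_sd: float = 0.0
    gain: float = 1.0
    pool_radius_mm: float = 0.15
    pool: str = "disc"  # or "gaussian" (radius acts as the kernel SD)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ------------------------------------------------------------- wide-field

def simulate_widefield(
    cells: pd.DataFrame,
    stimuli,
    grid,
    pixel_shape=(20, 20),
    noise: ResponseNoiseModel | None = None,
    seed: int | None = 0,
):
    """Forward wide-field responses from pooled cells.

    Each imaging pixel pools the cells within ``pool_radius_mm`` of its
    cortical position (hard disc by default, Gaussian weights optionally); the
    response to a stimulus is gain times the pooled sum of aperture-times-
    Gaussian grid sums, plus additive noise. Returns (EvokedResponses,
    ground_truth) where ground_truth holds per-pixel pooled RF centroids and
    the convex-hull aggregate size, plus the cortical pixel size in mm.
    """
    if len(cells) == 0:
        raise ValueError("empty cell list")
    noise = noise or ResponseNoiseModel()
    rng = np.random.default_rng(seed)

    A, E = grid.mesh()
    pts_a, pts_e = A.ravel(), E.ravel()
    S = np.stack([b.aperture.ravel().astype(float) for b in stimuli])

    ca = cells["azi"].to_numpy(dtype=float)
    ce = cells["ele"].to_numpy(dtype=float)
    sig = sigma_from_fwhm(cells["fwhm"].to_numpy(dtype=float))
    # per-cell responses to every stimulus
    cell_R = np.empty((len(cells), len(stimuli)))
    for c in range(len(cells)):
        g = np.exp(-((pts_a - ca[c]) ** 2 + (pts_e - ce[c]) ** 2) / (2 * sig[c] ** 2))
        cell_R[c] = S @ g

    cx = cells["cortical_x_mm"].to_numpy(dtype=float)
    cy = cells["cortical_y_mm"].to_numpy(dtype=float)
    h, w = pixel_shape
    px_x = np.linspace(cx.min(), cx.max(), w)
    px_y = np.linspace(cy.min(), cy.max(), h)
    pixel_mm = (px_x[1] - px_x[0]) if w > 1 else 1.0

    responses = np.zeros((h, w, len(stimuli)))
    valid = np.zeros((h, w), dtype=bool)
    gt_azi = np.full((h, w), np.nan)
    gt_ele = np.full((h, w), np.nan)
    gt_size = np.full((h, w), np.nan)
    for i in range(h):
        for j in range(w):
            d = np.hypot(cx - px_x[j], cy - px_y[i])
            if noise.pool == "disc":
                wgt = (d <= noise.pool_radius_mm).astype(float)
            else:
                wgt = np.exp(-d * d / (2 * noise.pool_radius_mm ** 2))
                wgt[wgt < 1e-3] = 0.0
            members = wgt > 0
            if not members.any():
                continue
            valid[i, j] = True
            responses[i, j] = noise.gain * (wgt @ cell_R)
            gt_azi[i, j] = np.average(ca[members], weights=wgt[members])
            gt_ele[i, j] = np.average(ce[members], weights=wgt[members])
            gt_size[i, j] = 2.0 * np.sqrt(
                disc_union_hull_area(
                    ca[members], ce[members],
                    cells["fwhm"].to_numpy()[members], quad_segs=8,
                ) / np.pi
            )
    if noise.noise_sd > 0:
        responses = responses + rng.normal(0.0, noise.noise_sd, responses.shape)
    ground_truth = dict(
        azimuth=gt_azi, elevation=gt_ele, aggregate_diameter=gt_size,
        pixel_mm=float(pixel_mm),
    )
    return EvokedResponses(responses, valid, n_trials=1), ground_truth


# ------------------------------------------------------------ sparse noise

def simulate_sparse_noise_trials(
    center,
    fwhm: float,
    azi_centers,
    ele_centers,
    n_reps: int = 20,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Trial table for one unit: Gaussian RF sampled at check centers + noise.

    Every (azimuth, elevation) check position appears ``n_reps`` times; the
    mean over reps converges to the noiseless map as n_reps grows. Columns:
    check_azi, check_ele, response.
    """
    rng = np.random.default_rng(seed)
    sig = sigma_from_fwhm(fwhm)
    A, E = np.meshgrid(np.asarray(azi_centers, float), np.asarray(ele_centers, float))
    resp0 = gain * np.exp(
        -((A - center[0]) ** 2 + (E - center[1]) ** 2) / (2 * sig * sig)
    )
    a = np.tile(A.ravel(), n_reps)
    e = np.tile(E.ravel(), n_reps)
    r = np.tile(resp0.ravel(), n_reps)
    if noise_sd > 0:
        r = r + rng.normal(0.0, noise_sd, r.shape)
    order = rng.permutation(len(a))
    return pd.DataFrame(
        dict(check_azi=a[order], check_ele=e[order], response=r[order])
    )


def simulate_rf_size_population(
    slope: float,
    intercept: float,
    n: int,
    ecc_range=(0.0, 60.0),
    target_r2: float | None = None,
    noise_sd: float | None = None,
    seed: int | None = 0,
    frame: FocealFrame | None = None,
) -> pd.DataFrame:
    """Population of RF sizes linear in r-eccentricity with calibrated noise.

    Eccentricities are uniform on ``ecc_range`` with uniform polar direction;
    (azimuth, elevation) use the tangent-corrected inverse so r_eccentricity
    recovers the generating eccentricity exactly. When ``target_r2`` is given,
    the noise SD is set from var(noise) = slope^2 var(ecc) (1 - r2)/r2 so the
    eccentricity term explains about that fraction of size variance.
    """
    frame = frame or FocealFrame()
    rng = np.random.default_rng(seed)
    ecc = rng.uniform(ecc_range[0], ecc_range[1], n)
    phi = rng.uniform(0.0, 360.0, n)
    if target_r2 is not None:
        var_sig = slope * slope * np.var(ecc)
        noise_sd = float(np.sqrt(var_sig * (1.0 - target_r2) / target_r2))
    elif noise_sd is None:
        noise_sd = 0.0
    da, de = ecc_offsets_from_polar(ecc, phi)
    fwhm = intercept + slope * ecc + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(
        dict(
            azi=frame.focea.azimuth + da,
            ele=frame.focea.elevation + de,
            true_ecc=ecc,
            fwhm=fwhm,
        )
    )


# ----------------------------------------------------------- direct maps

def simulate_prf_maps(
    slope: float,
    intercept: float,
    shape=(40, 40),
    azi_range=(-50.0, 30.0),
    ele_range=(-20.0, 50.0),
    noise_frac: float = 0.1,
    seed: int | None = 0,
    pixel_mm: float = 0.05,
    frame: FocealFrame | None = None,
) -> RetinotopyMaps:
    """Retinotopy + size maps whose FWHM is linear in r-eccentricity.

    Azimuth varies linearly across columns and elevation across rows; the size
    map is (slope * r_ecc + intercept) * (1 + noise_frac * N(0, 1)). All
    pixels are valid with r = 1.
    """
    frame = frame or FocealFrame()
    rng = np.random.default_rng(seed)
    h, w = shape
    azi = np.broadcast_to(np.linspace(*azi_range, w), (h, w)).copy()
    ele = np.broadcast_to(np.linspace(*ele_range, h)[:, None], (h, w)).copy()
    from .geometry import r_eccentricity

    ecc = r_eccentricity(azi, ele, frame)
    fwhm = (slope * ecc + intercept) * (1.0 + noise_frac * rng.normal(size=(h, w)))
    return RetinotopyMaps(
        azimuth=azi,
        elevation=ele,
        fwhm=fwhm,
        r=np.ones((h, w)),
        valid=np.ones((h, w), dtype=bool),
        pixel_mm=pixel_mm,
    )


# --------------------------------------------------------------- behavior

@dataclass
class BehaviorSimParams:
    """Generator for go/no-go sessions under the logistic response model."""

    sf_levels: tuple = (0.25, 0.35, 0.45, 0.55, 0.65, 0.75)
    alpha: dict = field(default_factory=lambda: {"focea": 0.5})
    slope: float = 15.0
    lapse: float = 0.05
    guess: float = 0.1
    n_go_per_level: int = 100
    n_nogo: int = 600
    seed: int | None = 0

    def __post_init__(self):
        if not (0.0 <= self.lapse <= 1.0 and 0.0 <= self.guess <= 1.0):
            raise ValueError("lapse and guess must lie in [0, 1]")
        lo, hi = min(self.sf_levels), max(self.sf_levels)
        for loc, a in self.alpha.items():
            if not (lo <= a <= hi):
                raise ValueError(f"alpha for {loc!r} outside the SF range")


def simulate_behavior(params: BehaviorSimParams):
    """Bernoulli go/no-go counts from the logistic psychometric model.

    Returns (table, n_nogo, n_false_alarms): table rows per (location, sf)
    with n_go and binomial n_hits at P(hit) = guess + (1 - guess - lapse) /
    (1 + exp(slope * (sf - alpha_loc))); false alarms are binomial at the
    guess rate.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for loc, a in params.alpha.items():
        for sf in params.sf_levels:
            p = params.guess + (1.0 - params.guess - params.lapse) / (
                1.0 + np.exp(params.slope * (sf - a))
            )
            rows.append(
                dict(
                    location=loc,
                    sf=float(sf),
                    n_go=params.n_go_per_level,
                    n_hits=int(rng.binomial(params.n_go_per_level, p)),
                )
            )
    n_fa = int(rng.binomial(params.n_nogo, params.guess))
    return pd.DataFrame(rows), params.n_nogo, n_fa


# -------------------------------------------------------------------- gaze

@dataclass
class GazeSimParams:
    """Sinusoidal head trajectory with parametric eye compensation."""

    duration_s: float = 10.0
    rate_hz: float = 60.0
    pitch_amp: float = 30.0
    pitch_freq_hz: float = 0.5
    roll_amp: float = 10.0
    roll_freq_hz: float = 0.3
    compensation_gain: float = 1.0
    torsion_gain: float = gaze_mod.DEFAULT_TORSION_GAIN
    seed: int | None = 0

    def __post_init__(self):
        if not (0.0 <= self.compensation_gain <= 1.0):
            raise ValueError("compensation_gain must lie in [0, 1]")


def simulate_gaze(
    params: GazeSimParams, geom: gaze_mod.EyeGeometry | None = None
) -> pd.DataFrame:
    """Gaze samples under sinusoidal head motion.

    At compensation gain 1 the eyes counter-rotate so the foceal projection is
    pinned at the focea; at gain 0 they stay at the head-fixed reference and
    the projection rides the head. Intermediate gains interpolate the eye
    angular positions linearly. Columns: t, pitch, roll, torsion,
    eyeL_h, eyeL_v, eyeR_h, eyeR_v.
    """
    geom = geom or gaze_mod.EyeGeometry()
    n = int(round(params.duration_s * params.rate_hz))
    t = np.arange(n) / params.rate_hz
    pitch = params.pitch_amp * np.sin(2 * np.pi * params.pitch_freq_hz * t)
    roll = params.roll_amp * np.sin(2 * np.pi * params.roll_freq_hz * t)
    out = dict(
        t=t, pitch=pitch, roll=roll,
        torsion=gaze_mod.torsion_from_pitch(pitch, params.torsion_gain),
    )
    for eye, tag in (("left", "L"), ("right", "R")):
        h0, v0 = geom.reference[eye]
        if params.compensation_gain > 0:
            hc, vc = gaze_mod.compensatory_eye_positions(
                pitch, roll, geom, eye, params.torsion_gain
            )
        else:
            hc, vc = np.full(n, h0), np.full(n, v0)
        g = params.compensation_gain
        out[f"eye{tag}_h"] = h0 + g * (hc - h0)
        out[f"eye{tag}_v"] = v0 + g * (vc - v0)
    return pd.DataFrame(out)
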