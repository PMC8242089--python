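"""Wide-field population receptive-field (pRF) model fitting.

The pRF of an imaging pixel is modeled as an unnormalized 2D Gaussian in
visual space. Predicted responses to each bar stimulus are the grid sums of
stimulus aperture times Gaussian; a per-entry gain is fit by least squares and
the dictionary entry minimizing the summed squared error wins. Maps of pRF
azimuth, elevation and size are thresholded by the Pearson correlation between
model and data, and the size-vs-eccentricity surface is summarized by a linear
model in r-eccentricity with reciprocal-eccentricity weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import minimize

from .geometry import (
    FocealFrame,
    SphericalDirection,
    fwhm_from_sigma,
    r_eccentricity,
    sigma_from_fwhm,
)
from .stimuli import BarStimulus, VisualFieldGrid

logger = logging.getLogger(__name__)

R_THRESHOLD_DEFAULT = 0.75


@dataclass
class EvokedResponses:
    """Mean evoked response per stimulus for each pixel.

    responses has shape (H, W, n_stimuli); valid marks pixels whose baseline
    was positive in every trial.
    """

    responses: np.ndarray
    valid: np.ndarray
    n_trials: int = 0


@dataclass
class RetinotopyMaps:
    """Per-pixel retinotopy: azimuth, elevation, pRF size and fit quality."""

    azimuth: np.ndarray
    elevation: np.ndarray
    fwhm: np.ndarray
    r: np.ndarray
    valid: np.ndarray
    pixel_mm: float = 1.0
    interpolated: np.ndarray | None = None


@dataclass
class GaussianDictionary:
    """Candidate pRFs with precomputed predicted responses.

    centers: (n, 2) array of (azimuth, elevation); fwhm: (n,); R: (n, n_stim).
    Entries are sorted by (fwhm, r-eccentricity) so that SSE ties resolve to
    the smaller, more foceal Gaussian.
    """

    centers: np.ndarray
    fwhm: np.ndarray
    R: np.ndarray
    grid: VisualFieldGrid

    @property
    def sigma(self):
        return sigma_from_fwhm(self.fwhm)

    def __len__(self):
        return len(self.fwhm)


@dataclass
class PRFFit:
    """Best-fitting dictionary entry for one pixel."""

    center: tuple[float, float]
    fwhm: float
    beta: float
    sse: float
    pearson_r: float
    valid: bool
    entry: int = -1


@dataclass
class EccSizeFit:
    """Linear pRF-size model: FWHM = G * r_ecc + c."""

    slope: float
    intercept: float
    r2: float
    focea: tuple[float, float] = (0.0, 20.0)


# ------------------------------------------------------------ preprocessing

def preprocess_stack(stack: np.ndarray) -> np.ndarray:
    """2x2 mean pooling followed by a 7x7 moving-mean spatial filter.

    ``stack`` is (T, H, W) or a single (H, W) frame; H and W must be even.
    Input frames are assumed motion-corrected.
    """
    single = stack.ndim == 2
    s = stack[None] if single else stack
    t, h, w = s.shape
    if h % 2 or w % 2:
        raise ValueError("frame dimensions must be even for 2x2 pooling")
    pooled = s.reshape(t, h // 2, 2, w // 2, 2).mean(axis=(2, 4))
    smoothed = uniform_filter(pooled, size=(1, 7, 7), mode="nearest")
    return smoothed[0] if single else smoothed


def evoked_response(
    stack: np.ndarray,
    events,
    rate_hz: float,
    baseline_window=(-0.25, 0.0),
    response_window=(0.15, 0.4),
) -> EvokedResponses:
    """Fractional fluorescence change per stimulus, averaged over presentations.

    E_s = mean_i (F_{s,i} - F0_{s,i}) / F0_{s,i}, with F0 the mean over the
    baseline window and F the mean over the response window around each onset.
    ``events`` is a DataFrame with columns ``stimulus`` and ``onset_s``.
    Pixels with a non-positive baseline in any trial are flagged invalid.
    """
    t, h, w = stack.shape
    stims = np.asarray(events["stimulus"])
    onsets = np.asarray(events["onset_s"], dtype=float)
    uniq = np.unique(stims)
    sums = np.zeros((h, w, len(uniq)))
    counts = np.zeros(len(uniq), dtype=int)
    valid = np.ones((h, w), dtype=bool)
    for s_idx, s in enumerate(uniq):
        for onset in onsets[stims == s]:
            b0 = int(np.round((onset + baseline_window[0]) * rate_hz))
            b1 = int(np.round((onset + baseline_window[1]) * rate_hz))
            r0 = int(np.round((onset + response_window[0]) * rate_hz))
            r1 = int(np.round((onset + response_window[1]) * rate_hz))
            if b0 < 0 or r1 > t:
                continue
            f0 = stack[b0:max(b1, b0 + 1)].mean(axis=0)
            f = stack[r0:max(r1, r0 + 1)].mean(axis=0)
            bad = f0 <= 0
            valid &= ~bad
            with np.errstate(divide="ignore", invalid="ignore"):
                e = np.where(bad, 0.0, (f - f0) / np.where(bad, 1.0, f0))
            sums[:, :, s_idx] += e
            counts[s_idx] += 1
    if np.any(counts == 0):
        raise ValueError("some stimuli have no usable presentations")
    responses = sums / counts
    return EvokedResponses(responses, valid, n_trials=int(counts.min()))


# --------------------------------------------------------------- dictionary

def build_dictionary(
    stimuli: list[BarStimulus],
    grid: VisualFieldGrid,
    center_azi=(-90.0, 90.0),
    center_ele=(-60.0, 60.0),
    center_step: float = 2.0,
    fwhm_range=(20.0, 120.0),
    fwhm_step: float = 2.0,
    stimulated_mask: np.ndarray | None = None,
) -> GaussianDictionary:
    """Precompute predicted responses R = sum_a sum_e S * G for every entry.

    Gaussians are unnormalized (the gain absorbs scale), so R values compare
    only within one dictionary. Entries whose centers fall outside the
    stimulated region (``stimulated_mask``, a boolean field on ``grid``;
    default: the union of the stimulus apertures) are removed; the resulting
    entry count is logged, not asserted.
    """
    if not stimuli:
        raise ValueError("empty stimulus set")
    for b in stimuli:
        if b.aperture.shape != (len(grid.elevation), len(grid.azimuth)):
            raise ValueError("stimulus aperture does not match the grid")
    azis = np.arange(center_azi[0], center_azi[1] + center_step / 2, center_step)
    eles = np.arange(center_ele[0], center_ele[1] + center_step / 2, center_step)
    fwhms = np.arange(fwhm_range[0], fwhm_range[1] + fwhm_step / 2, fwhm_step)
    if stimulated_mask is None:
        stimulated_mask = np.zeros_like(stimuli[0].aperture, dtype=bool)
        for b in stimuli:
            stimulated_mask |= b.aperture.astype(bool)

    # keep centers whose nearest grid point lies in the stimulated region
    ai = np.clip(
        np.round((azis - grid.azimuth[0]) / grid.step).astype(int),
        0, len(grid.azimuth) - 1,
    )
    ei = np.clip(
        np.round((eles - grid.elevation[0]) / grid.step).astype(int),
        0, len(grid.elevation) - 1,
    )
    in_region = stimulated_mask[np.ix_(ei, ai)]  # (n_ele, n_azi)

    A, E = grid.mesh()
    pts_a = A.ravel()
    pts_e = E.ravel()
    S = np.stack([b.aperture.ravel().astype(float) for b in stimuli])  # (n_stim, P)

    centers = []
    fw = []
    blocks = []
    for j, ele in enumerate(eles):
        for i, azi in enumerate(azis):
            if not in_region[j, i]:
                continue
            d2 = (pts_a - azi) ** 2 + (pts_e - ele) ** 2
            for f in fwhms:
                sig = sigma_from_fwhm(f)
                g = np.exp(-d2 / (2.0 * sig * sig))
                blocks.append(S @ g)
                centers.append((azi, ele))
                fw.append(f)
    if not blocks:
        raise ValueError("no dictionary entries inside the stimulated region")
    centers = np.asarray(centers, dtype=float)
    fw = np.asarray(fw, dtype=float)
    R = np.stack(blocks)

    # sort by (fwhm, r-eccentricity) for deterministic tie-breaking
    ecc = r_eccentricity(
        np.clip(centers[:, 0], -89.9, 89.9), np.clip(centers[:, 1], -69.9, 89.9)
    )
    order = np.lexsort((ecc, fw))
    d = GaussianDictionary(centers[order], fw[order], R[order], grid)
    logger.info("dictionary built with %d entries", len(d))
    return d


def _fit_entries(E_mat: np.ndarray, dictionary: GaussianDictionary):
    """Vectorized winner selection. E_mat: (n_pixels, n_stim)."""
    R = dictionary.R
    denom = np.einsum("ms,ms->m", R, R)
    if np.count_nonzero(R.std(axis=1) > 0) < 1 or R.shape[1] < 2:
        raise ValueError("need >=2 stimuli with nonzero predicted variance")
    num = E_mat @ R.T  # (n, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(num > 0, num * num / denom, -np.inf)
    winner = np.argmax(score, axis=1)  # first max -> smallest fwhm, then ecc
    best_score = score[np.arange(len(winner)), winner]
    e_ss = np.einsum("ns,ns->n", E_mat, E_mat)
    sse = e_ss - np.where(np.isfinite(best_score), best_score, 0.0)
    beta = num[np.arange(len(winner)), winner] / denom[winner]
    valid = np.isfinite(best_score) & (e_ss > 0)
    return winner, beta, sse, valid


def _pearson(x, y):
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def fit_prf(E_s: np.ndarray, dictionary: GaussianDictionary) -> PRFFit:
    """Best-fitting Gaussian for one pixel's stimulus responses."""
    E_s = np.asarray(E_s, dtype=float)
    winner, beta, sse, valid = _fit_entries(E_s[None, :], dictionary)
    w = int(winner[0])
    if not valid[0]:
        return PRFFit((np.nan, np.nan), np.nan, np.nan, float(sse[0]), np.nan, False)
    model = beta[0] * dictionary.R[w]
    return PRFFit(
        tuple(dictionary.centers[w]),
        float(dictionary.fwhm[w]),
        float(beta[0]),
        float(sse[0]),
        _pearson(model, E_s),
        True,
        entry=w,
    )


def fit_prf_map(
    responses: EvokedResponses,
    dictionary: GaussianDictionary,
    stride: int = 2,
    r_threshold: float = R_THRESHOLD_DEFAULT,
    pixel_mm: float = 1.0,
) -> RetinotopyMaps:
    """Fit every ``stride``-th pixel and linearly interpolate the rest.

    Pixels with Pearson r below ``r_threshold`` (or with invalid responses)
    are marked invalid in the returned maps.
    """
    h, w, n_stim = responses.responses.shape
    azi = np.full((h, w), np.nan)
    ele = np.full((h, w), np.nan)
    fwhm = np.full((h, w), np.nan)
    rmap = np.full((h, w), np.nan)
    interp = np.zeros((h, w), dtype=bool)

    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    sub = responses.responses[np.ix_(rows, cols)].reshape(-1, n_stim)
    winner, beta, sse, valid = _fit_entries(sub, dictionary)
    k = 0
    for i in rows:
        for j in cols:
            if valid[k]:
                wi = winner[k]
                azi[i, j] = dictionary.centers[wi, 0]
                ele[i, j] = dictionary.centers[wi, 1]
                fwhm[i, j] = dictionary.fwhm[wi]
                rmap[i, j] = _pearson(beta[k] * dictionary.R[wi], sub[k])
            k += 1

    # linear interpolation of skipped pixels from the fitted lattice
    if stride > 1 and len(rows) > 1 and len(cols) > 1:
        from scipy.interpolate import RegularGridInterpolator

        for arr in (azi, ele, fwhm, rmap):
            lattice = arr[np.ix_(rows, cols)]
            f = RegularGridInterpolator(
                (rows.astype(float), cols.astype(float)),
                lattice,
                bounds_error=False,
                fill_value=np.nan,
            )
            ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            skipped = ~((ii % stride == 0) & (jj % stride == 0))
            pts = np.stack(
                [
                    np.clip(ii[skipped], rows[0], rows[-1]),
                    np.clip(jj[skipped], cols[0], cols[-1]),
                ],
                axis=1,
            ).astype(float)
            arr[skipped] = f(pts)
            interp |= skipped

    valid_map = responses.valid & np.isfinite(rmap) & (rmap >= r_threshold)
    return RetinotopyMaps(azi, ele, fwhm, rmap, valid_map, pixel_mm, interp)


# -------------------------------------------------- size-vs-eccentricity fit

def fit_ecc_size_model(
    maps: RetinotopyMaps,
    frame: FocealFrame | None = None,
    fit_focea: bool = False,
    ecc_floor: float = 0.5,
) -> EccSizeFit:
    """Fit FWHM = G * r_ecc + c by reciprocal-eccentricity-weighted least squares.

    The weighted objective sum (1/ecc) * (FWHM - G*ecc - c)^2 is minimized by
    derivative-free search seeded with the closed-form weighted solution.
    Eccentricities below ``ecc_floor`` deg share that floor's weight so the
    focea itself does not receive infinite weight. If ``fit_focea``, the focea
    (a_f, e_f) is searched on a 1-deg grid around the frame's focea and then
    refined jointly.
    """
    frame = frame or FocealFrame()
    ok = maps.valid & np.isfinite(maps.fwhm) & np.isfinite(maps.azimuth)
    azi = maps.azimuth[ok]
    ele = maps.elevation[ok]
    size = maps.fwhm[ok]
    if azi.size < 10:
        raise ValueError("need at least 10 valid pixels")

    def solve(focea):
        fr = FocealFrame(SphericalDirection(*focea))
        ecc = r_eccentricity(azi, ele, fr)
        wgt = 1.0 / np.maximum(ecc, ecc_floor)
        X = np.stack([ecc, np.ones_like(ecc)], axis=1)
        sw = np.sqrt(wgt)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], size * sw, rcond=None)

        def obj(p):
            resid = size - (p[0] * ecc + p[1])
            return float(np.sum(wgt * resid * resid))

        res = minimize(obj, coef, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        return res.x, res.fun, ecc

    f0 = (frame.focea.azimuth, frame.focea.elevation)
    ecc0 = r_eccentricity(azi, ele, frame)
    if ecc0.max() - ecc0.min() < 20.0:
        raise ValueError("eccentricity range too narrow (<20 deg)")

    if not fit_focea:
        (g, c), _, ecc = solve(f0)
        best_focea = f0
    else:
        best = None
        for da in np.arange(-10.0, 10.5, 1.0):
            for de in np.arange(-10.0, 10.5, 1.0):
                cand = (f0[0] + da, f0[1] + de)
                p, fun, _ = solve(cand)
                if best is None or fun < best[1]:
                    best = (cand, fun, p)
        cand0, _, p0 = best

        def obj4(q):
            fr = FocealFrame(SphericalDirection(q[2], q[3]))
            ecc = r_eccentricity(azi, ele, fr)
            wgt = 1.0 / np.maximum(ecc, ecc_floor)
            resid = size - (q[0] * ecc + q[1])
            return float(np.sum(wgt * resid * resid))

        res = minimize(obj4, [p0[0], p0[1], cand0[0], cand0[1]],
                       method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10})
        g, c = res.x[0], res.x[1]
        best_focea = (float(res.x[2]), float(res.x[3]))
        ecc = r_eccentricity(azi, ele, FocealFrame(SphericalDirection(*best_focea)))

    pred = g * ecc + c
    ss_res = float(np.sum((size - pred) ** 2))
    ss_tot = float(np.sum((size - size.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return EccSizeFit(float(g), float(c), r2, best_focea)


# --------------------------------------------------------------- CMF map

def cmf_map_from_retinotopy(maps: RetinotopyMaps, smooth_px: int = 0) -> np.ndarray:
    """Cortical magnification (mm/deg) from local retinotopic gradients.

    CMF = 1 / sqrt(|det J|) where J is the Jacobian of (azimuth, elevation)
    with respect to cortical position in mm — the isotropic-equivalent
    magnification, invariant to map rotation. Zero-gradient or invalid pixels
    return NaN.
    """
    azi = maps.azimuth.astype(float).copy()
    ele = maps.elevation.astype(float).copy()
    if smooth_px > 1:
        azi = uniform_filter(azi, smooth_px, mode="nearest")
        ele = uniform_filter(ele, smooth_px, mode="nearest")
    day, dax = np.gradient(azi, maps.pixel_mm)
    dey, dex = np.gradient(ele, maps.pixel_mm)
    det = np.abs(dax * dey - day * dex)
    with np.errstate(divide="ignore"):
        cmf = 1.0 / np.sqrt(det)
    cmf[~maps.valid | (det <= 0) | ~np.isfinite(cmf)] = np.nan
    return cmf


def write_maps(maps: RetinotopyMaps, out_dir, meta: dict | None = None):
    """Write 32-bit TIFF maps (azimuth, elevation, fwhm, r) plus a JSON sidecar."""
    import json
    import os

    import tifffile

    os.makedirs(out_dir, exist_ok=True)
    for name in ("azimuth", "elevation", "fwhm", "r"):
        tifffile.imwrite(
            os.path.join(out_dir, f"{name}.tif"),
            getattr(maps, name).astype(np.float32),
        )
    side = dict(pixel_mm=maps.pixel_mm, n_valid=int(maps.valid.sum()))
    side.update(meta or {})
    with open(os.path.join(out_dir, "maps.json"), "w") as fh:
        json.dump(side, fh, indent=2)
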