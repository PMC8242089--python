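"""Field-sign analysis and visual-area segmentation.

The field sign at a cortical point is the sine of the angle between the local
gradient directions of the elevation and azimuth retinotopic maps: mirror-image
areas (V1) have one sign, non-mirror-image neighbors (e.g. LM) the other.
Thresholded sign maps are cleaned with morphological operators and segmented
into connected regions; V1 is identified as the largest negative-sign region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import sobel
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing as binary_closing
from skimage.morphology import disk
from skimage.morphology import opening as binary_opening

from .prf_widefield import RetinotopyMaps

FIELDSIGN_THRESHOLD_DEFAULT = 0.3


@dataclass
class FieldSignMap:
    """Continuous field-sign values in [-1, 1] with a validity mask."""

    value: np.ndarray
    valid: np.ndarray
    pixel_mm: float


@dataclass
class AreaSegmentation:
    """Labeled visual areas with per-region geometry.

    regions is a DataFrame with columns id, sign, area_mm2, centroid_row,
    centroid_col, major_axis_px, minor_axis_px; v1_id indexes into it.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    v1_id: int
    pixel_mm: float

    @property
    def v1(self):
        return self.regions.loc[self.regions["id"] == self.v1_id].iloc[0]


def _nan_mean_filter(img, size):
    """Moving-window mean ignoring NaNs; NaN where the window holds no data."""
    from scipy.ndimage import uniform_filter

    data = np.nan_to_num(img, nan=0.0)
    ok = np.isfinite(img).astype(float)
    num = uniform_filter(data, size, mode="constant")
    den = uniform_filter(ok, size, mode="constant")
    with np.errstate(invalid="ignore"):
        out = num / den
    out[den <= 0] = np.nan
    return out


def compute_fieldsign(
    maps: RetinotopyMaps,
    downsample: int = 1,
    r_threshold: float = 0.75,
    presmooth: int = 7,
    postsmooth: int = 13,
) -> FieldSignMap:
    """sin(theta_ele - theta_azi) of Sobel gradient directions.

    Azimuth/elevation maps are nearest-neighbor downsampled by ``downsample``,
    mean-smoothed with a ``presmooth`` window, differentiated with a Sobel
    operator, converted to field sign and finally smoothed with a
    ``postsmooth`` window before any thresholding. Pixels failing the
    correlation threshold, or whose Sobel neighborhood has fewer than two
    valid pixels, are invalid. Gradient angles use the image convention with
    y inverted so anatomical orientation matches the maps.
    """
    azi = np.where(maps.valid & (maps.r >= r_threshold), maps.azimuth, np.nan)
    ele = np.where(maps.valid & (maps.r >= r_threshold), maps.elevation, np.nan)
    if downsample > 1:
        azi = azi[::downsample, ::downsample]
        ele = ele[::downsample, ::downsample]
    azi = _nan_mean_filter(azi, presmooth)
    ele = _nan_mean_filter(ele, presmooth)

    ok = np.isfinite(azi) & np.isfinite(ele)
    # Sobel windows need support: require >= 2 valid pixels in each 3x3 window
    from scipy.ndimage import uniform_filter

    support = uniform_filter(ok.astype(float), 3, mode="constant") * 9.0
    usable = ok & (support >= 2.0 - 1e-9)

    azi_f = np.nan_to_num(azi, nan=0.0)
    ele_f = np.nan_to_num(ele, nan=0.0)
    gx_a = sobel(azi_f, axis=1, mode="nearest")
    gy_a = sobel(azi_f, axis=0, mode="nearest")
    gx_e = sobel(ele_f, axis=1, mode="nearest")
    gy_e = sobel(ele_f, axis=0, mode="nearest")
    th_a = np.arctan2(-gy_a, gx_a)
    th_e = np.arctan2(-gy_e, gx_e)
    value = np.sin(th_e - th_a)
    value[~usable] = np.nan
    value = _nan_mean_filter(value, postsmooth)
    value = np.clip(value, -1.0, 1.0)
    valid = np.isfinite(value)
    value[~valid] = 0.0
    return FieldSignMap(value, valid, maps.pixel_mm * downsample)


def threshold_fieldsign(fsmap: FieldSignMap | np.ndarray, t: float = FIELDSIGN_THRESHOLD_DEFAULT):
    """Three-way labels: +1 if value > t, -1 if value < -t, else 0 (strict)."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    value = fsmap.value if isinstance(fsmap, FieldSignMap) else np.asarray(fsmap)
    labels = np.zeros(value.shape, dtype=int)
    labels[value > t] = 1
    labels[value < -t] = -1
    if isinstance(fsmap, FieldSignMap):
        labels[~fsmap.valid] = 0
    return labels


def segment_areas(
    labels: np.ndarray,
    pixel_mm: float,
    open_radius: int = 2,
    close_radius: int = 2,
    min_area_mm2: float = 0.05,
) -> AreaSegmentation:
    """Connected visual areas from a thresholded field-sign label map.

    Per sign: morphological opening then closing (disc structuring elements),
    connected-component labeling, and removal of regions below
    ``min_area_mm2``. V1 is the largest remaining negative region. This is a
    deliberately simple cleanup standing in for more elaborate published
    morphology pipelines; radii and area cutoff are configurable.
    """
    px_area = pixel_mm * pixel_mm
    out = np.zeros(labels.shape, dtype=int)
    rows = []
    next_id = 1
    for sign in (-1, 1):
        m = labels == sign
        if open_radius > 0:
            m = binary_opening(m, disk(open_radius))
        if close_radius > 0:
            m = binary_closing(m, disk(close_radius))
        cc = cc_label(m, connectivity=1)
        for prop in regionprops(cc):
            area = prop.area * px_area
            if area < min_area_mm2:
                continue
            out[cc == prop.label] = next_id
            rows.append(
                dict(
                    id=next_id,
                    sign=sign,
                    area_mm2=float(area),
                    centroid_row=float(prop.centroid[0]),
                    centroid_col=float(prop.centroid[1]),
                    major_axis_px=float(prop.axis_major_length),
                    minor_axis_px=float(prop.axis_minor_length),
                )
            )
            next_id += 1
    regions = pd.DataFrame(rows)
    neg = regions[regions["sign"] == -1] if len(regions) else regions
    if len(neg) == 0:
        raise ValueError("V1 not found: no negative-sign region survives cleanup")
    v1_id = int(neg.sort_values("area_mm2", ascending=False).iloc[0]["id"])
    return AreaSegmentation(out, regions, v1_id, pixel_mm)


def normalize_and_average_maps(
    items: list[tuple[RetinotopyMaps, AreaSegmentation]],
    grid_halfspan: float = 1.5,
    grid_step: float = 0.05,
    min_valid_fraction: float = 0.5,
):
    """Average maps across animals after V1-based recentering and rescaling.

    Each animal's maps are translated so the V1 centroid sits at the origin
    and scaled by dividing the column/row axes by V1's major/minor axis
    lengths. Output pixels are averaged over animals and kept where at least
    ``min_valid_fraction`` of animals contribute valid data. Returns a dict of
    averaged azimuth/elevation/fwhm arrays plus the normalized grid vectors.
    """
    if len(items) < 2:
        raise ValueError("need maps from at least two animals")
    u = np.arange(-grid_halfspan, grid_halfspan + grid_step / 2, grid_step)
    v = np.arange(-grid_halfspan, grid_halfspan + grid_step / 2, grid_step)
    uu, vv = np.meshgrid(u, v)
    stacks = {k: [] for k in ("azimuth", "elevation", "fwhm")}
    valid_stack = []
    for maps, seg in items:
        v1 = seg.v1
        major, minor = v1["major_axis_px"], v1["minor_axis_px"]
        if major <= 0 or minor <= 0:
            warnings.warn("animal excluded: degenerate V1 axes")
            continue
        rowc = vv * minor + v1["centroid_row"]
        colc = uu * major + v1["centroid_col"]
        ri = np.round(rowc).astype(int)
        ci = np.round(colc).astype(int)
        h, w = maps.azimuth.shape
        inside = (ri >= 0) & (ri < h) & (ci >= 0) & (ci < w)
        ok = np.zeros(uu.shape, dtype=bool)
        ok[inside] = maps.valid[ri[inside], ci[inside]]
        valid_stack.append(ok)
        for k in stacks:
            arr = np.full(uu.shape, np.nan)
            arr[inside] = getattr(maps, k)[ri[inside], ci[inside]]
            arr[~ok] = np.nan
            stacks[k].append(arr)
    if len(valid_stack) < 2:
        raise ValueError("fewer than two usable animals")
    valid_counts = np.sum(valid_stack, axis=0)
    keep = valid_counts >= min_valid_fraction * len(valid_stack)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k, arrs in stacks.items():
            mean = np.nanmean(np.stack(arrs), axis=0)
            mean[~keep] = np.nan
            out[k] = mean
    out["valid"] = keep
    out["grid_u"] = u
    out["grid_v"] = v
    return out
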