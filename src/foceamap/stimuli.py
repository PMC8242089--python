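"""Mapping stimuli on a visual-field grid.

Two stimulus families are built here: checkerboard *bars* seen through an
oriented rectangular aperture (for population receptive-field mapping) and
*sparse-noise* check sequences (for single-cell/site RF mapping). Both are
represented purely as binary apertures on a grid of visual-field directions —
luminance, gamma and rendering are out of scope because dark and light checks
are assumed to drive the calcium signal equally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import eccentricity_mask

# Presentation timings (s): bar mapping, ephys sparse noise, 2p sparse noise.
BAR_STIM_S, BAR_ISI_S = 0.5, 3.6
EPHYS_STIM_S, EPHYS_ISI_S = 0.25, 0.25
TWOP_STIM_S, TWOP_ISI_S = 0.25, 0.5


@dataclass(frozen=True)
class VisualFieldGrid:
    """Uniform sampling of visual directions (deg)."""

    azimuth: np.ndarray
    elevation: np.ndarray
    step: float

    @classmethod
    def from_ranges(cls, azi_range, ele_range, step):
        if step <= 0:
            raise ValueError("step must be positive")
        azi = np.arange(azi_range[0], azi_range[1] + step / 2, step)
        ele = np.arange(ele_range[0], ele_range[1] + step / 2, step)
        return cls(azi, ele, float(step))

    def mesh(self):
        """(A, E) meshgrid arrays, shape (n_ele, n_azi)."""
        return np.meshgrid(self.azimuth, self.elevation)


@dataclass
class BarStimulus:
    """One oriented bar aperture.

    orientation 0 is a vertical bar (constant azimuth band); offset is the
    signed distance (deg) of the bar's axis from the grid origin along the
    bar's normal.
    """

    orientation: float
    width: float
    offset: float
    aperture: np.ndarray  # (n_ele, n_azi) binary


@dataclass
class SparseNoiseFrame:
    """One sparse-noise frame: exactly four check positions (grid indices)."""

    positions: list[tuple[int, int]]  # (row, col) into the check grid
    check_size: float
    non_adjacent: bool = False


def _bar_aperture(grid: VisualFieldGrid, orientation, width, offset, mask):
    A, E = grid.mesh()
    th = np.deg2rad(orientation)
    # signed distance of each grid point from the bar axis (line through the
    # origin whose direction is `orientation` deg from vertical), measured
    # along the axis normal: orientation 0 -> vertical bar tiling azimuth
    dist = A * np.cos(th) - E * np.sin(th)
    ap = (np.abs(dist - offset) <= width / 2.0) & mask
    return ap.astype(np.uint8)


def build_bar_set(
    width: float,
    orientations,
    grid: VisualFieldGrid,
    ecc_limit: float = 70.0,
    spacing: float | None = None,
) -> list[BarStimulus]:
    """Tile the unmasked field with bars at each orientation.

    Bars step by ``spacing`` (default: the bar width, i.e. non-overlapping
    tiling) along the normal to their axis. Bars whose aperture is entirely
    outside the eccentricity mask are removed.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    spacing = width if spacing is None else spacing
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    A, E = grid.mesh()
    mask = eccentricity_mask(A, E, ecc_limit)
    bars: list[BarStimulus] = []
    for ori in orientations:
        th = np.deg2rad(ori)
        dist = A[mask] * np.cos(th) - E[mask] * np.sin(th)
        lo, hi = float(dist.min()), float(dist.max())
        offset = lo + width / 2.0
        while offset - width / 2.0 < hi - 1e-9:
            ap = _bar_aperture(grid, ori, width, offset, mask)
            if ap.any():
                bars.append(BarStimulus(float(ori), float(width), float(offset), ap))
            offset += spacing
    if not bars:
        raise ValueError("eccentricity mask excludes every bar")
    return bars


def _check_positions(azi_range, ele_range, check_size):
    n_azi = (azi_range[1] - azi_range[0]) / check_size
    n_ele = (ele_range[1] - ele_range[0]) / check_size
    if abs(n_azi - round(n_azi)) > 1e-9 or abs(n_ele - round(n_ele)) > 1e-9:
        raise ValueError("grid dimensions must be divisible by the check size")
    n_azi, n_ele = int(round(n_azi)), int(round(n_ele))
    azi_centers = azi_range[0] + check_size * (np.arange(n_azi) + 0.5)
    ele_centers = ele_range[0] + check_size * (np.arange(n_ele) + 0.5)
    return azi_centers, ele_centers


def check_grid_centers(azi_range, ele_range, check_size):
    """Check-center coordinates (azi_centers, ele_centers) for a sparse-noise grid."""
    return _check_positions(azi_range, ele_range, check_size)


def _adjacent(p, q):
    return abs(p[0] - q[0]) <= 1 and abs(p[1] - q[1]) <= 1


def build_sparse_noise(
    azi_range,
    ele_range,
    check_size: float,
    n_reps: int = 20,
    dialect: str = "ephys",
    seed: int | None = 0,
    n_simultaneous: int = 4,
) -> list[SparseNoiseFrame]:
    """Sparse-noise frame sequence covering every grid position >= n_reps times.

    dialect "ephys" uses 8-deg checks with no adjacency constraint; dialect
    "two-photon" uses 12-deg checks and forbids grid-adjacent checks within a
    frame (8-neighborhood). Presentation counts per position differ by at most
    one (positions padding the final partial frame get one extra showing).
    """
    if dialect not in ("ephys", "two-photon"):
        raise ValueError(f"unknown dialect {dialect!r}")
    azi_c, ele_c = _check_positions(azi_range, ele_range, check_size)
    positions = [(r, c) for r in range(len(ele_c)) for c in range(len(azi_c))]
    rng = np.random.default_rng(seed)
    non_adj = dialect == "two-photon"

    pool: list[tuple[int, int]] = []
    for _ in range(n_reps):
        pool.extend(positions)
    pad = (-len(pool)) % n_simultaneous
    if pad:
        extra = rng.choice(len(positions), size=pad, replace=False)
        pool.extend(positions[i] for i in extra)

    for attempt in range(50):
        order = list(rng.permutation(len(pool)))
        remaining = [pool[i] for i in order]
        frames: list[SparseNoiseFrame] = []
        ok = True
        while remaining:
            frame: list[tuple[int, int]] = []
            i = 0
            while i < len(remaining) and len(frame) < n_simultaneous:
                cand = remaining[i]
                if not non_adj or all(not _adjacent(cand, p) for p in frame):
                    frame.append(cand)
                    remaining.pop(i)
                else:
                    i += 1
            if len(frame) < n_simultaneous:
                ok = False
                break
            frames.append(SparseNoiseFrame(frame, float(check_size), non_adj))
        if ok:
            return frames
    raise ValueError("could not pack checks into non-adjacent frames")


def session_duration_min(n_stimuli: int, n_reps: int, stim_s: float, isi_s: float) -> float:
    """Total mapping-session duration in minutes (stimulus + inter-stimulus gap)."""
    return n_stimuli * n_reps * (stim_s + isi_s) / 60.0


def write_bar_set(bars: list[BarStimulus], npz_path, manifest_path,
                  stim_s: float = BAR_STIM_S, isi_s: float = BAR_ISI_S):
    """Write the aperture stack (NPZ) and a CSV manifest with onset/offset times."""
    stack = np.stack([b.aperture for b in bars])
    np.savez_compressed(npz_path, apertures=stack)
    rows = []
    t = 0.0
    for i, b in enumerate(bars):
        rows.append(
            dict(id=i, orientation=b.orientation, width=b.width, offset=b.offset,
                 onset_s=t, offset_s=t + stim_s)
        )
        t += stim_s + isi_s
    pd.DataFrame(rows).to_csv(manifest_path, index=False)


def write_sparse_noise(frames: list[SparseNoiseFrame], manifest_path,
                       stim_s: float, isi_s: float):
    """CSV manifest: one row per check presentation with frame id and timing."""
    rows = []
    t = 0.0
    for i, f in enumerate(frames):
        for (r, c) in f.positions:
            rows.append(dict(frame=i, row=r, col=c, onset_s=t, offset_s=t + stim_s))
        t += stim_s + isi_s
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
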