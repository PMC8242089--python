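"""Gaze geometry for freely moving mice.

The focea is a *cortical* specialization: the direction it represents in the
world depends on where the eyes point within the head and where the head is
relative to the ground. This module carries the rotation bookkeeping to project
the foceal direction into world coordinates ("foceal projection"), models eye
torsion as a linear function of head pitch, summarizes projection directions
with spherical histograms and circular statistics, and ray-traces a trapezoidal
experiment chamber to compute optic-flow fields around the focea during
locomotion.

Conventions: the head frame has x toward the nose, y to the animal's left and
z up. Azimuth is a rotation about z (positive = left hemifield), elevation is
measured from the ground plane. Head pitch is positive nose-up (about y), roll
is about x. Eye angular positions (h, v) are rotations of the eye about the
eye-socket frame whose forward axis is the optic axis (+-60 deg azimuth,
30 deg elevation); torsion rotates about the gaze axis itself.

Rotation order (chosen so the head-fixed reference state projects exactly to
the focea): torsion, then vertical, then horizontal eye rotation, then head
roll, then head pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DEFAULT_TORSION_GAIN = 0.325


# ---------------------------------------------------------------- rotations

def _rx(deg):
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(deg):
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(deg):
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def direction_vector(azimuth, elevation):
    """Unit vector for (azimuth, elevation) in deg; azimuth about z, from x."""
    a = np.deg2rad(np.asarray(azimuth, dtype=float))
    e = np.deg2rad(np.asarray(elevation, dtype=float))
    return np.stack(
        [np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e)], axis=-1
    )


def vector_angles(v):
    """(azimuth, elevation) in deg of direction vector(s) v (last axis = xyz)."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    u = v / n
    azi = np.rad2deg(np.arctan2(u[..., 1], u[..., 0]))
    ele = np.rad2deg(np.arcsin(np.clip(u[..., 2], -1.0, 1.0)))
    return azi, ele


def head_rotation(pitch, roll):
    """Head-to-world rotation: roll about x, then pitch about y (nose-up +)."""
    return _ry(-pitch) @ _rx(roll)


def torsion_from_pitch(pitch, gain: float = DEFAULT_TORSION_GAIN):
    """Eye torsion (deg) as a linear function of head pitch."""
    out = gain * np.asarray(pitch, dtype=float)
    return float(out) if out.ndim == 0 else out


# ------------------------------------------------------------- eye geometry

@dataclass
class EyeGeometry:
    """Placement of the optic axes in the head and reference eye positions.

    reference holds the mean head-fixed angular eye positions (h, v) per eye;
    the focea-in-eye vector is defined relative to these.
    """

    axis_azimuth: dict = field(default_factory=lambda: {"left": 60.0, "right": -60.0})
    axis_elevation: float = 30.0
    reference: dict = field(
        default_factory=lambda: {"left": (0.0, 0.0), "right": (0.0, 0.0)}
    )
    interocular_cm: float = 1.0
    eye_drop_cm: float = 1.0  # eyes sit ~1 cm below the eye-camera midpoint

    def axis_rotation(self, eye: str):
        """Eye-socket-to-head rotation (optic axis = eye-frame +x)."""
        return _rz(self.axis_azimuth[eye]) @ _ry(-self.axis_elevation)

    def eye_rotation(self, eye: str, h, v, torsion=0.0):
        """Full eye-to-head rotation at angular position (h, v) with torsion."""
        return self.axis_rotation(eye) @ _rz(h) @ _ry(-v) @ _rx(torsion)


def focea_in_eye_coords(geom: EyeGeometry, focea=(0.0, 20.0)):
    """Per-eye unit vector of the focea in eye coordinates.

    Obtained from the transpose (inverse) of the eye rotation at the reference
    (head-fixed mean) eye positions: forward-projecting this vector at the
    reference state with a level head points exactly at the focea.
    """
    d = direction_vector(*focea)
    out = {}
    for eye, (h0, v0) in geom.reference.items():
        r_ref = geom.eye_rotation(eye, h0, v0, 0.0)
        out[eye] = r_ref.T @ d
    return out


def foceal_projection(
    eye_h,
    eye_v,
    pitch,
    roll,
    geom: EyeGeometry,
    eye: str,
    torsion_gain: float = DEFAULT_TORSION_GAIN,
    focea=(0.0, 20.0),
):
    """World-frame direction of the focea for one eye.

    Accepts scalars or arrays of equal length. Returns (azimuth, elevation)
    in deg, azimuth relative to the world x-axis and elevation relative to the
    ground plane. Samples with |pitch| >= 90 are gimbal-degenerate and return
    NaN.
    """
    f = focea_in_eye_coords(geom, focea)[eye]
    h = np.atleast_1d(np.asarray(eye_h, dtype=float))
    v = np.atleast_1d(np.asarray(eye_v, dtype=float))
    p = np.broadcast_to(np.atleast_1d(np.asarray(pitch, dtype=float)), h.shape)
    r = np.broadcast_to(np.atleast_1d(np.asarray(roll, dtype=float)), h.shape)
    azi = np.empty(h.shape)
    ele = np.empty(h.shape)
    for i in range(h.size):
        if abs(p.flat[i]) >= 90.0:
            azi.flat[i] = np.nan
            ele.flat[i] = np.nan
            continue
        t = torsion_from_pitch(p.flat[i], torsion_gain)
        rot = head_rotation(p.flat[i], r.flat[i]) @ geom.eye_rotation(
            eye, h.flat[i], v.flat[i], t
        )
        a, e = vector_angles(rot @ f)
        azi.flat[i] = a
        ele.flat[i] = e
    if np.isscalar(eye_h) or np.asarray(eye_h).ndim == 0:
        return float(azi[0]), float(ele[0])
    return azi, ele


def compensatory_eye_positions(
    pitch,
    roll,
    geom: EyeGeometry,
    eye: str,
    torsion_gain: float = DEFAULT_TORSION_GAIN,
    focea=(0.0, 20.0),
):
    """Eye angular positions (h, v) that hold the foceal projection at ``focea``.

    Solves, per sample, for the horizontal/vertical eye rotation that undoes
    the head tilt (torsion follows the pitch-coupled linear model and is not a
    free parameter). Used by the gaze simulator's perfect-compensation limit.
    """
    f = focea_in_eye_coords(geom, focea)[eye]
    target = direction_vector(*focea)
    p = np.atleast_1d(np.asarray(pitch, dtype=float))
    r = np.broadcast_to(np.atleast_1d(np.asarray(roll, dtype=float)), p.shape)
    h0, v0 = geom.reference[eye]
    hs = np.empty(p.shape)
    vs = np.empty(p.shape)
    guess = np.array([h0, v0])
    for i in range(p.size):
        t = torsion_from_pitch(p.flat[i], torsion_gain)
        rhead = head_rotation(p.flat[i], r.flat[i])

        def resid(hv):
            rot = rhead @ geom.eye_rotation(eye, hv[0], hv[1], t)
            return rot @ f - target

        best = None
        starts = [guess] + [
            np.array([h0 + dh, v0 + dv])
            for dh in (-45.0, 0.0, 45.0)
            for dv in (-45.0, 0.0, 45.0)
        ]
        for g in starts:
            sol = least_squares(resid, g, xtol=1e-14, ftol=1e-14, gtol=1e-14)
            cost = float(np.sum(sol.fun**2))
            if best is None or cost < best[0]:
                best = (cost, sol.x)
            if cost < 1e-20:
                break
        hs.flat[i], vs.flat[i] = best[1]
        guess = best[1]
    return hs, vs


# ---------------------------------------------------------------- summaries

def projection_histogram(
    azimuth,
    elevation,
    eye_positions_cm=None,
    spacing_deg: float = 1.0,
    vector_length_cm: float = 15.0,
):
    """Spherical histogram of projection directions and circular elevation stats.

    For each sample the endpoint of a ``vector_length_cm`` vector starting at
    the eye center (``eye_positions_cm``, default the head center) is binned on
    a grid of directions with ``spacing_deg`` spacing as seen from the head
    center. Returns (counts, azi_edcenters, ele_centers, stats) where stats has
    circular mean and circular SD of the elevation marginal in deg.
    """
    azi = np.atleast_1d(np.asarray(azimuth, dtype=float))
    ele = np.atleast_1d(np.asarray(elevation, dtype=float))
    good = np.isfinite(azi) & np.isfinite(ele)
    azi, ele = azi[good], ele[good]
    if azi.size == 0:
        raise ValueError("no valid samples")
    dirs = direction_vector(azi, ele)
    if eye_positions_cm is None:
        pts = vector_length_cm * dirs
    else:
        pts = np.asarray(eye_positions_cm, dtype=float)[good] + vector_length_cm * dirs
    pa, pe = vector_angles(pts)

    azi_centers = np.arange(-180.0, 180.0, spacing_deg)
    ele_centers = np.arange(-90.0, 90.0 + spacing_deg / 2, spacing_deg)
    ai = np.clip(np.round((pa + 180.0) / spacing_deg).astype(int), 0, len(azi_centers) - 1) % len(azi_centers)
    ei = np.clip(np.round((pe + 90.0) / spacing_deg).astype(int), 0, len(ele_centers) - 1)
    counts = np.zeros((len(ele_centers), len(azi_centers)))
    np.add.at(counts, (ei, ai), 1)

    marg = counts.sum(axis=1)
    stats = dict(
        circ_mean_elevation=circular_mean(ele_centers, marg),
        circ_sd_elevation=circular_sd(ele_centers, marg),
    )
    return counts, azi_centers, ele_centers, stats


def circular_mean(angles_deg, weights=None):
    """Weighted circular mean of angles in deg."""
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(th) if weights is None else np.asarray(weights, dtype=float)
    return float(np.rad2deg(np.arctan2(np.sum(w * np.sin(th)), np.sum(w * np.cos(th)))))


def circular_sd(angles_deg, weights=None):
    """Weighted circular standard deviation (deg), sqrt(-2 ln R)."""
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(th) if weights is None else np.asarray(weights, dtype=float)
    c = np.sum(w * np.cos(th)) / np.sum(w)
    s = np.sum(w * np.sin(th)) / np.sum(w)
    r = np.hypot(c, s)
    r = min(r, 1.0)
    if r <= 0:
        return float("inf")
    return float(np.rad2deg(abs(np.sqrt(abs(-2.0 * np.log(r))))))


def stratified_sample(datasets: dict, bin_deg: float = 5.0, seed: int | None = 0):
    """Equalize joint pitch/roll histograms across condition datasets.

    Each dataset is a DataFrame with ``pitch`` and ``roll`` columns. Samples
    are binned jointly (``bin_deg`` for both axes); within each bin every
    condition keeps a random subset matching the smallest count across
    conditions. Bins empty in any condition are dropped everywhere.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two conditions")
    rng = np.random.default_rng(seed)

    def bin_key(df):
        pi = np.floor(df["pitch"].to_numpy() / bin_deg).astype(int)
        ri = np.floor(df["roll"].to_numpy() / bin_deg).astype(int)
        return list(zip(pi, ri))

    keys = {name: bin_key(df) for name, df in datasets.items()}
    common = None
    for k in keys.values():
        s = set(k)
        common = s if common is None else (common & s)
    out = {}
    for name, df in datasets.items():
        idx_by_bin: dict = {}
        for i, k in enumerate(keys[name]):
            idx_by_bin.setdefault(k, []).append(i)
        keep = []
        for b in sorted(common):
            counts = [sum(1 for kk in keys[n] if kk == b) for n in datasets]
            m = min(counts)
            cand = idx_by_bin[b]
            if len(cand) > m:
                cand = list(rng.choice(cand, size=m, replace=False))
            keep.extend(cand)
        out[name] = df.iloc[sorted(keep)].reset_index(drop=True)
    return out


def locomotion_filter(
    t,
    body_xy,
    head_xy,
    speed_min_cm_s: float = 10.0,
    max_vel_diff_cm_s: float = 1.0,
):
    """Maximal time intervals of straight forward locomotion.

    Requires body speed > ``speed_min_cm_s`` and the magnitude of the
    head-vs-body velocity difference < ``max_vel_diff_cm_s``. Returns a list of
    (t_start, t_end) tuples and the per-sample boolean mask.
    """
    t = np.asarray(t, dtype=float)
    body = np.asarray(body_xy, dtype=float)
    head = np.asarray(head_xy, dtype=float)
    vb = np.gradient(body, t, axis=0)
    vh = np.gradient(head, t, axis=0)
    speed = np.linalg.norm(vb, axis=1)
    diff = np.linalg.norm(vh - vb, axis=1)
    ok = (speed > speed_min_cm_s) & (diff < max_vel_diff_cm_s)
    intervals = []
    i = 0
    n = len(t)
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            intervals.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return intervals, ok


# ------------------------------------------------------------------ chamber

@dataclass
class ChamberModel:
    """Symmetric trapezoidal experiment chamber (cm).

    The wide (screen) wall sits at x = length with half-width wide/2; the
    narrow (reward-spout) wall at x = 0 with half-width narrow/2; side walls
    connect them linearly; floor z = 0, ceiling z = height.
    """

    wide_cm: float = 24.0
    narrow_cm: float = 6.0
    length_cm: float = 18.0
    height_cm: float = 20.0
    camera_height_cm: float = 30.0
    eye_cam_height_cm: float = 5.0  # at pitch 0; linear to 7/3 cm at +-90 deg
    body_height_cm: float = 4.0

    def half_width(self, x):
        """Half-width of the chamber at longitudinal position x."""
        w0, w1 = self.narrow_cm / 2.0, self.wide_cm / 2.0
        return w0 + (w1 - w0) * np.asarray(x, dtype=float) / self.length_cm

    def eye_camera_height(self, pitch):
        """Height of the eye-camera midpoint; linear in pitch, roll excluded."""
        return self.eye_cam_height_cm + 2.0 * np.asarray(pitch, dtype=float) / 90.0

    def contains(self, p, tol=1e-9):
        x, y, z = p
        return (
            -tol <= x <= self.length_cm + tol
            and -tol <= z <= self.height_cm + tol
            and abs(y) <= self.half_width(np.clip(x, 0, self.length_cm)) + tol
        )

    def _faces(self):
        L, H = self.length_cm, self.height_cm
        w0, w1 = self.narrow_cm / 2.0, self.wide_cm / 2.0
        # (point on plane, normal); normals need not be inward
        slope = (w1 - w0) / L
        faces = [
            (np.array([L, 0, 0]), np.array([1.0, 0, 0])),      # screen wall
            (np.array([0, 0, 0]), np.array([1.0, 0, 0])),      # spout wall
            (np.array([0, 0, 0]), np.array([0, 0, 1.0])),      # floor
            (np.array([0, 0, H]), np.array([0, 0, 1.0])),      # ceiling
            (np.array([0, w0, 0]), np.array([-slope, 1.0, 0])),   # left wall
            (np.array([0, -w0, 0]), np.array([-slope, -1.0, 0])),  # right wall
        ]
        return faces

    def ray_intersection(self, origin, direction, tol=1e-7):
        """First intersection of a ray with the chamber walls, or None."""
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        best_t = None
        best_p = None
        for p0, n in self._faces():
            dn = float(d @ n)
            if abs(dn) < 1e-12:
                continue
            t = float((p0 - o) @ n) / dn
            if t <= tol:
                continue
            p = o + t * d
            if self.contains(p, tol=1e-6) and (best_t is None or t < best_t):
                best_t, best_p = t, p
        return best_p


def flow_grid(center_azi: float, center_ele: float, spacing: float = 10.0,
              azi_extent: float = 50.0, ele_extent: float = 40.0):
    """Regular grid of directions around a center (focea), deg."""
    azis = center_azi + np.arange(-azi_extent, azi_extent + spacing / 2, spacing)
    eles = center_ele + np.arange(-ele_extent, ele_extent + spacing / 2, spacing)
    return azis, eles


def eye_world_positions(track: pd.DataFrame, chamber: ChamberModel, geom: EyeGeometry):
    """World (x, y, z) positions of both eyes from a tracked trajectory.

    ``track`` needs columns x, y (mid-eye ground position), heading_deg, pitch.
    The mid-eye height follows the camera-height model (pitch-linear, roll
    excluded) minus the eye drop; eyes sit +-interocular/2 along the head-left
    direction.
    """
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    yaw = np.deg2rad(track["heading_deg"].to_numpy(dtype=float))
    z = chamber.eye_camera_height(track["pitch"].to_numpy(dtype=float)) - geom.eye_drop_cm
    left_dir = np.stack([-np.sin(yaw), np.cos(yaw)], axis=1)
    half = geom.interocular_cm / 2.0
    mid = np.stack([x, y, z], axis=1)
    out = {}
    for eye, sgn in (("left", +1.0), ("right", -1.0)):
        p = mid.copy()
        p[:, 0] += sgn * half * left_dir[:, 0]
        p[:, 1] += sgn * half * left_dir[:, 1]
        out[eye] = p
    return out


def optic_flow(
    track: pd.DataFrame,
    chamber: ChamberModel,
    geom: EyeGeometry,
    eye: str,
    torsion_gain: float = DEFAULT_TORSION_GAIN,
    spacing: float = 10.0,
    azi_extent: float = 50.0,
    ele_extent: float = 40.0,
    focea=(0.0, 20.0),
):
    """Optic-flow field on a grid centered at the mean foceal projection.

    For each pair of successive frames, each grid direction is cast as a ray
    from the *previous* eye position and intersected with the chamber walls;
    the change in azimuth/elevation of the intersection point as seen from the
    previous vs current eye position is the local flow. Per-grid-point flows
    are circular-averaged across frame pairs.

    ``track`` columns: t, x, y, heading_deg, pitch, roll, eye{L,R}_h, eye{L,R}_v.
    Returns (d_azi, d_ele, n, grid_azis, grid_eles) with flow in deg/frame.
    """
    if len(track) < 2:
        raise ValueError("need at least two frames")
    hcol = "eyeL_h" if eye == "left" else "eyeR_h"
    vcol = "eyeL_v" if eye == "left" else "eyeR_v"
    h = track[hcol].to_numpy(dtype=float)
    v = track[vcol].to_numpy(dtype=float)
    pitch = track["pitch"].to_numpy(dtype=float)
    roll = track["roll"].to_numpy(dtype=float)
    yaw = track["heading_deg"].to_numpy(dtype=float)
    eye_pos = eye_world_positions(track, chamber, geom)[eye]

    # grid centered on the mean foceal projection over the track
    azi_p, ele_p = foceal_projection(h, v, pitch, roll, geom, eye, torsion_gain, focea)
    center_azi = circular_mean(azi_p + yaw)
    center_ele = circular_mean(ele_p)
    azis, eles = flow_grid(center_azi, center_ele, spacing, azi_extent, ele_extent)

    # grid directions expressed in eye coordinates at the reference state
    h0, v0 = geom.reference[eye]
    r_ref = geom.eye_rotation(eye, h0, v0, 0.0)
    ga, ge = np.meshgrid(azis - center_azi + focea[0], eles - center_ele + focea[1])
    g_eye = direction_vector(ga.ravel(), ge.ravel()) @ r_ref  # rows: R_ref.T @ d

    n_frames = len(track)
    shape = (len(eles), len(azis))
    sin_a = np.zeros(shape).ravel()
    cos_a = np.zeros(shape).ravel()
    sin_e = np.zeros(shape).ravel()
    cos_e = np.zeros(shape).ravel()
    n_ok = np.zeros(shape, dtype=int).ravel()

    for k in range(1, n_frames):
        t_prev = torsion_from_pitch(pitch[k - 1], torsion_gain)
        rot_prev = (
            _rz(yaw[k - 1])
            @ head_rotation(pitch[k - 1], roll[k - 1])
            @ geom.eye_rotation(eye, h[k - 1], v[k - 1], t_prev)
        )
        dirs_world = g_eye @ rot_prev.T
        for gi in range(dirs_world.shape[0]):
            w = chamber.ray_intersection(eye_pos[k - 1], dirs_world[gi])
            if w is None:
                continue
            a0, e0 = vector_angles(w - eye_pos[k - 1])
            a1, e1 = vector_angles(w - eye_pos[k])
            da = np.deg2rad(((a1 - a0) + 180.0) % 360.0 - 180.0)
            de = np.deg2rad(((e1 - e0) + 180.0) % 360.0 - 180.0)
            sin_a[gi] += np.sin(da)
            cos_a[gi] += np.cos(da)
            sin_e[gi] += np.sin(de)
            cos_e[gi] += np.cos(de)
            n_ok[gi] += 1

    with np.errstate(invalid="ignore"):
        d_azi = np.rad2deg(np.arctan2(sin_a, cos_a))
        d_ele = np.rad2deg(np.arctan2(sin_e, cos_e))
    d_azi[n_ok == 0] = np.nan
    d_ele[n_ok == 0] = np.nan
    return (
        d_azi.reshape(shape),
        d_ele.reshape(shape),
        n_ok.reshape(shape),
        azis,
        eles,
    )
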