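"""Coordinate conventions shared by every analysis stage.

All angles are in degrees. The mouse-centered spherical frame has azimuth 0
at the nose (negative azimuths in the right hemifield) and elevation 0 on the
horizontal plane (positive up). The *focea* — the direction whose cortical
representation carries the smallest population receptive fields — sits at
azimuth 0, elevation +20 by default; distances from it are measured with the
tangent-corrected "r-eccentricity" rather than the great-circle angle, because
the two differ for oblique offsets and all downstream slopes are defined in
r-eccentricity units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class SphericalDirection:
    """A direction in the mouse-centered frame.

    azimuth : deg, 0 at the nose, negative = right hemifield, in [-180, 180].
    elevation : deg, 0 = horizontal plane, positive = up, in [-90, 90].
    """

    azimuth: float
    elevation: float

    def __post_init__(self):
        if not (-180.0 <= self.azimuth <= 180.0):
            raise ValueError(f"azimuth {self.azimuth} outside [-180, 180]")
        if not (-90.0 <= self.elevation <= 90.0):
            raise ValueError(f"elevation {self.elevation} outside [-90, 90]")


@dataclass(frozen=True)
class FocealFrame:
    """Reference frame centered on the focea (default azimuth 0, elevation 20)."""

    focea: SphericalDirection = field(
        default_factory=lambda: SphericalDirection(0.0, 20.0)
    )


@dataclass(frozen=True)
class ScreenGeometry:
    """Flat presentation screen in front of the animal.

    center_pixel is the (x, y) pixel that lies at azimuth 0, elevation 0.
    """

    width_cm: float
    height_cm: float
    distance_cm: float
    pixels_x: int
    pixels_y: int
    center_pixel: tuple[float, float]

    def __post_init__(self):
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        cx, cy = self.center_pixel
        if not (0 <= cx < self.pixels_x and 0 <= cy < self.pixels_y):
            raise ValueError("center_pixel outside the pixel grid")

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.pixels_x

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.pixels_y


def r_eccentricity(azimuth, elevation, frame: FocealFrame | None = None):
    """Angular distance from the focea (deg), tangent-corrected.

    r_ecc = arctan( sqrt( tan(da)^2 + tan(de)^2 / cos(da)^2 ) )

    where da, de are the azimuth/elevation offsets from the focea. This is the
    azimuth-first spherical composition (algebraically arccos(cos da * cos de)),
    not the great-circle angle between the latitude/longitude points; see
    :func:`great_circle_angle` for the latter.

    Accepts scalars or arrays; offsets must satisfy |da| < 90 and |de| < 90.
    """
    frame = frame or FocealFrame()
    da = np.asarray(azimuth, dtype=float) - frame.focea.azimuth
    de = np.asarray(elevation, dtype=float) - frame.focea.elevation
    if np.any(np.abs(da) >= 90.0):
        bad = np.asarray(da)[np.abs(da) >= 90.0]
        raise ValueError(f"azimuth offset out of range (|da| >= 90): {np.ravel(bad)[0]}")
    if np.any(np.abs(de) >= 90.0):
        bad = np.asarray(de)[np.abs(de) >= 90.0]
        raise ValueError(f"elevation offset out of range (|de| >= 90): {np.ravel(bad)[0]}")
    da_r = np.deg2rad(da)
    de_r = np.deg2rad(de)
    arg = np.sqrt(np.tan(da_r) ** 2 + (np.tan(de_r) ** 2) / (np.cos(da_r) ** 2))
    out = np.rad2deg(np.arctan(arg))
    return float(out) if out.ndim == 0 else out


def ecc_offsets_from_polar(ecc, angle_deg):
    """Inverse of :func:`r_eccentricity` for a polar offset (ecc, direction).

    Returns (da, de) such that r_eccentricity of the offsets equals ``ecc``
    and the gnomonic-plane direction of the offset is ``angle_deg``. Used by
    the spherical variant of the conceptual cortex model.
    """
    ecc_r = np.deg2rad(np.asarray(ecc, dtype=float))
    phi = np.deg2rad(np.asarray(angle_deg, dtype=float))
    x = np.tan(ecc_r) * np.cos(phi)
    da = np.arctan(x)
    de = np.arctan(np.cos(da) * np.tan(ecc_r) * np.sin(phi))
    return np.rad2deg(da), np.rad2deg(de)


def great_circle_angle(azimuth, elevation, frame: FocealFrame | None = None):
    """Great-circle angle (deg) to the focea, for comparison with r-eccentricity.

    Treats (azimuth, elevation) as longitude/latitude on the unit sphere.
    """
    frame = frame or FocealFrame()
    a1 = np.deg2rad(np.asarray(azimuth, dtype=float))
    e1 = np.deg2rad(np.asarray(elevation, dtype=float))
    a0 = np.deg2rad(frame.focea.azimuth)
    e0 = np.deg2rad(frame.focea.elevation)
    c = np.sin(e1) * np.sin(e0) + np.cos(e1) * np.cos(e0) * np.cos(a1 - a0)
    out = np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def fwhm_from_sigma(sigma):
    """FWHM = 2 sqrt(2 ln 2) * sigma, for a Gaussian of SD ``sigma`` (deg)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    out = FWHM_PER_SIGMA * sigma
    return float(out) if out.ndim == 0 else out


def sigma_from_fwhm(fwhm):
    """Inverse of :func:`fwhm_from_sigma`."""
    fwhm = np.asarray(fwhm, dtype=float)
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be non-negative")
    out = np.asarray(fwhm, dtype=float) / FWHM_PER_SIGMA
    return float(out) if out.ndim == 0 else out


def screen_to_spherical(px, py, geom: ScreenGeometry):
    """Map screen pixels to spherical directions (inverse gnomonic).

    azimuth  = arctan(x_cm / d)
    elevation = arctan(y_cm / sqrt(d^2 + x_cm^2))

    with the azimuth-first asymmetry matching the r-eccentricity convention.
    The center pixel maps to (0, 0); positive x_cm maps to positive azimuth.
    Returns (azimuth, elevation) arrays in degrees.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    x_cm = (px - geom.center_pixel[0]) * geom.cm_per_px_x
    y_cm = (py - geom.center_pixel[1]) * geom.cm_per_px_y
    d = geom.distance_cm
    azi = np.rad2deg(np.arctan2(x_cm, d))
    ele = np.rad2deg(np.arctan2(y_cm, np.sqrt(d * d + x_cm * x_cm)))
    if azi.ndim == 0:
        return float(azi), float(ele)
    return azi, ele


def spherical_to_screen(azimuth, elevation, geom: ScreenGeometry):
    """Analytic inverse of :func:`screen_to_spherical` (pixels may fall off-screen)."""
    a = np.deg2rad(np.asarray(azimuth, dtype=float))
    e = np.deg2rad(np.asarray(elevation, dtype=float))
    d = geom.distance_cm
    x_cm = d * np.tan(a)
    y_cm = np.tan(e) * np.sqrt(d * d + x_cm * x_cm)
    px = x_cm / geom.cm_per_px_x + geom.center_pixel[0]
    py = y_cm / geom.cm_per_px_y + geom.center_pixel[1]
    if px.ndim == 0:
        return float(px), float(py)
    return px, py


def eccentricity_mask(azimuth, elevation, limit_deg: float):
    """True where the eccentricity from (0, 0) is <= ``limit_deg`` (closed boundary).

    Offsets at or beyond 90 deg (where the tangent correction is undefined) are
    treated as maximally eccentric and masked out rather than raising.
    """
    if not (0.0 < limit_deg < 90.0):
        raise ValueError("limit_deg must lie in (0, 90)")
    a = np.asarray(azimuth, dtype=float)
    e = np.asarray(elevation, dtype=float)
    ok = (np.abs(a) < 90.0) & (np.abs(e) < 90.0)
    ecc = np.full(np.broadcast(a, e).shape, np.inf)
    if np.any(ok):
        a_ok = np.broadcast_to(a, ecc.shape)[ok]
        e_ok = np.broadcast_to(e, ecc.shape)[ok]
        origin = FocealFrame(SphericalDirection(0.0, 0.0))
        ecc[ok] = np.atleast_1d(r_eccentricity(a_ok, e_ok, origin))
    out = ecc <= limit_deg
    return bool(out) if out.ndim == 0 else out
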