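"""Inviscid mechanistic model of the rotating liquid distribution.

Viewed from the flask, orbital shaking is the superposition of a
translation and an opposing rotation, so an inviscid liquid adopts the
equilibrium shape it would have under a steady centrifugal field about
the shaker's rotation axis.  The free surface is then a symmetric
paraboloid

    h(s) = z0 + c * s^2,      c = omega^2 / (2 g),

where ``s`` is the horizontal distance from the shaker axis — a vertical
line at distance ``d0/2`` from the flask axis, placed at azimuth 0° so
that the centrifugal direction is azimuth 180°.  The apex height ``z0``
is adjusted until the volume enclosed between flask wall, flat bottom
and paraboloid matches the filling volume; the contact line is the set
of heights where the surface crosses the wall, sampled per azimuth.

The model neglects viscosity, surface tension and contact-angle effects
entirely, so the contact line is exactly symmetric about the centrifugal
direction.  Lengths are in millimetres internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .extraction import AIR_TO_WATER, WATER_TO_AIR, ContactLineSet
from .geometry import FlaskGeometry
from .kinematics import OperatingCondition, angular_velocity

__all__ = [
    "ParaboloidSurface",
    "LiquidDistribution",
    "enclosed_volume",
    "solve_fill",
    "contact_line_of",
    "GRAVITY",
]

#: Standard gravity, m/s^2.
GRAVITY = 9.81

#: Relative tolerance on the volume match of :func:`solve_fill`.
FILL_TOL = 1e-3

#: z resolution (mm) of the dense scan used to locate wall crossings.
_SCAN_DZ = 0.05


@dataclass(frozen=True)
class ParaboloidSurface:
    """Free surface h(s) = z0 + c s^2 about the (offset) shaker axis.

    ``apex_height`` z0 in mm, ``curvature`` c = omega^2/(2g) in 1/mm,
    ``axis_offset`` = d0/2 in mm at azimuth ``axis_azimuth`` (0° by the
    package convention, putting the centrifugal direction at 180°).
    """

    apex_height: float
    curvature: float
    axis_offset: float
    axis_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.curvature < 0:
            raise ValueError("curvature must be >= 0")
        if self.axis_offset < 0:
            raise ValueError("axis_offset must be >= 0")

    @classmethod
    def from_condition(cls, cond: OperatingCondition, apex_height_mm: float = 0.0,
                       gravity: float = GRAVITY) -> "ParaboloidSurface":
        omega = angular_velocity(cond)
        c_per_m = omega**2 / (2.0 * gravity)  # 1/m
        return cls(
            apex_height=apex_height_mm,
            curvature=c_per_m / 1000.0,  # 1/mm
            axis_offset=cond.shaking_diameter / 2.0 * 1000.0,  # mm
        )

    def axis_xy(self) -> np.ndarray:
        a = math.radians(self.axis_azimuth)
        return self.axis_offset * np.array([math.cos(a), math.sin(a)])

    def height_at(self, x_mm, y_mm):
        """Surface height (mm) above horizontal position(s) (x, y) in mm."""
        ax, ay = self.axis_xy()
        s2 = (np.asarray(x_mm) - ax) ** 2 + (np.asarray(y_mm) - ay) ** 2
        return self.apex_height + self.curvature * s2

    def dry_radius_at(self, z):
        """Radius s (mm) around the shaker axis where the surface is below z.

        Points closer to the axis than this radius are above the surface
        (air) at height z; 0 where the whole plane is wetted.
        """
        z = np.asarray(z, dtype=float)
        if self.curvature == 0.0:
            # flat surface: everything above z0 is dry
            out = np.where(z > self.apex_height, np.inf, 0.0)
            return out if out.ndim else float(out)
        arg = (z - self.apex_height) / self.curvature
        out = np.sqrt(np.maximum(arg, 0.0))
        return out if out.ndim else float(out)


def _circle_overlap_area(R, rd, a):
    """Area of intersection of circles radius R (origin) and rd (distance a).

    Vectorised closed form (lens area); handles containment and
    separation limits.
    """
    R = np.asarray(R, dtype=float)
    rd = np.asarray(rd, dtype=float)
    a = np.asarray(a, dtype=float)
    R, rd, a = np.broadcast_arrays(R, rd, a)
    out = np.zeros(R.shape)
    sep = a >= R + rd
    small, big = np.minimum(R, rd), np.maximum(R, rd)
    contained = a <= big - small
    out = np.where(contained, math.pi * small**2, out)
    lens = ~(sep | contained) & (rd > 0) & (R > 0)
    if np.any(lens):
        Rl, rl, al = R[lens], rd[lens], a[lens]
        c1 = np.clip((al**2 + Rl**2 - rl**2) / (2 * al * Rl), -1.0, 1.0)
        c2 = np.clip((al**2 + rl**2 - Rl**2) / (2 * al * rl), -1.0, 1.0)
        t = (-al + Rl + rl) * (al + Rl - rl) * (al - Rl + rl) * (al + Rl + rl)
        area = (Rl**2 * np.arccos(c1) + rl**2 * np.arccos(c2)
                - 0.5 * np.sqrt(np.maximum(t, 0.0)))
        out[lens] = area
    return out


def _liquid_area(geom: FlaskGeometry, par: ParaboloidSurface, z):
    """Horizontal cross-sectional liquid area (mm^2) at height(s) z."""
    z = np.asarray(z, dtype=float)
    rw = geom.radius_at(np.clip(z, 0.0, geom.top_height))
    sd = par.dry_radius_at(z)
    flask_area = math.pi * rw**2
    finite_sd = np.where(np.isfinite(sd), sd, 0.0)
    dry = _circle_overlap_area(rw, finite_sd, par.axis_offset)
    area = np.where(np.isinf(sd), 0.0, flask_area - dry)
    return area if area.ndim else float(area)


def enclosed_volume(geom: FlaskGeometry, par: ParaboloidSurface) -> float:
    """Volume (mm^3) inside wall, above bottom and below the paraboloid."""
    z_top = geom.top_height
    # heights at which circle tangency / apex kinks occur help the quadrature
    pts = [p for p in (par.apex_height, geom.junction_height) if 0.0 < p < z_top]

    def integrand(z):
        return _liquid_area(geom, par, z)

    val, _ = quad(integrand, 0.0, z_top, points=sorted(pts) or None,
                  epsabs=0.05, limit=400)
    return val


@dataclass(frozen=True)
class LiquidDistribution:
    """A volume-matched paraboloid/wall intersection with its contact line."""

    geometry: FlaskGeometry
    paraboloid: ParaboloidSurface
    condition: OperatingCondition
    contact_line: ContactLineSet

    @property
    def max_height(self) -> float:
        """Maximal contact-line height (mm)."""
        return self.contact_line.max_height(0.0)

    @property
    def max_height_azimuth(self) -> float:
        return self.contact_line.apex_azimuth(0.0, tie_tol_mm=1e-9)


def _surface_minus_z(geom: FlaskGeometry, par: ParaboloidSurface, z, azimuth_deg):
    """f(z, az) = surface height at the wall minus z; water at wall iff >= 0."""
    z = np.asarray(z, dtype=float)
    az = np.radians(np.asarray(azimuth_deg, dtype=float))
    rw = geom.radius_at(np.clip(z, 0.0, geom.top_height))
    a = par.axis_offset
    rel = az - math.radians(par.axis_azimuth)
    s2 = rw**2 + a**2 - 2.0 * a * rw * np.cos(rel)
    return par.apex_height + par.curvature * s2 - z


def _wall_crossings(geom: FlaskGeometry, par: ParaboloidSurface,
                    azimuth_deg: float) -> List[float]:
    """All heights where the surface crosses the wall at one azimuth,
    found by a dense scan refined with Brent's method; descending order."""
    z_hi = geom.top_height
    zs = np.arange(0.0, z_hi + _SCAN_DZ / 2, _SCAN_DZ)
    f = _surface_minus_z(geom, par, zs, azimuth_deg)
    sign = f >= 0.0
    roots: List[float] = []
    flips = np.nonzero(sign[1:] != sign[:-1])[0]
    for i in flips:
        root = brentq(lambda z: _surface_minus_z(geom, par, z, azimuth_deg),
                      zs[i], zs[i + 1], xtol=1e-9)
        roots.append(float(root))
    return sorted(roots, reverse=True)


def contact_line_of(geom: FlaskGeometry, par: ParaboloidSurface,
                    azimuth_step_deg: float = 1.0) -> ContactLineSet:
    """Contact line of a paraboloid/wall intersection on an azimuth grid.

    Returned as a :class:`ContactLineSet` with a single pseudo-offset 0
    (the line lies exactly on the wall).  Multiple crossings per azimuth
    occur when the bottom centre is dry and the surface re-enters the
    wall (high shaking frequency, small fill).
    """
    az = np.arange(0.0, 360.0, azimuth_step_deg)
    per_az: List[List] = []
    for a in az:
        roots = _wall_crossings(geom, par, a)
        lst = []
        # descending from the top: the wall above the first root is air,
        # so crossings alternate starting with air_to_water.
        for k, h in enumerate(roots):
            lst.append((h, AIR_TO_WATER if k % 2 == 0 else WATER_TO_AIR))
        per_az.append(lst)
    return ContactLineSet(
        azimuths_deg=az, offsets_um=np.array([0.0]), crossings=[per_az],
        z_step_mm=_SCAN_DZ, geometry=geom,
    )


def solve_fill(geom: FlaskGeometry, cond: OperatingCondition,
               azimuth_step_deg: float = 1.0,
               gravity: float = GRAVITY) -> LiquidDistribution:
    """Find the paraboloid apex height matching the filling volume.

    Root-finds z0 so that the enclosed volume equals ``cond.fill_volume``
    within 0.1%, then samples the contact line on the azimuth grid.
    Raises if the filling volume cannot be held below the modelled top
    height at these shaking conditions.
    """
    v_target = cond.fill_volume * 1e9  # m^3 -> mm^3
    v_total = geom.total_volume()
    if v_target >= v_total:
        raise ValueError(
            f"fill volume {v_target/1000:.1f} mL exceeds flask volume "
            f"{v_total/1000:.1f} mL"
        )
    par0 = ParaboloidSurface.from_condition(cond, 0.0, gravity)
    c, a = par0.curvature, par0.axis_offset
    z_lo = -c * (a + geom.max_radius) ** 2  # surface everywhere below bottom
    z_hi = geom.top_height

    def vol_err(z0):
        return enclosed_volume(geom, ParaboloidSurface(z0, c, a)) - v_target

    z0 = brentq(vol_err, z_lo, z_hi, xtol=1e-7 * max(1.0, z_hi))
    par = ParaboloidSurface(z0, c, a)
    v = enclosed_volume(geom, par)
    if abs(v - v_target) > FILL_TOL * v_target:
        raise RuntimeError("volume matching failed to converge")
    line = contact_line_of(geom, par, azimuth_step_deg)
    try:
        hmax = line.max_height(0.0)
    except ValueError:
        hmax = 0.0
    if hmax >= geom.top_height - 1e-6:
        raise ValueError(
            "liquid would overflow the modelled flask height "
            f"({geom.top_height} mm) at these shaking conditions"
        )
    return LiquidDistribution(geometry=geom, paraboloid=par,
                              condition=cond, contact_line=line)
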