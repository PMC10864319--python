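"""Parametric model of the inner wall of an Erlenmeyer shake flask.

The inner surface is a solid of revolution built from two segments: a
partial torus forming the rounded lower part and a truncated cone forming
the upper part.  Two variants of the torus/cone junction are supported:

* ``sharp`` — the torus is exactly a quarter torus (arc angle 90°) and the
  cone connects the torus end to the top rim, leaving a slope
  discontinuity at the junction.
* ``smooth`` — the torus arc is extended past 90° until its tangent is
  collinear with the chord to the (fixed) top rim, so the wall profile is
  continuously differentiable everywhere.

All lengths in this module are in **millimetres**; angles in degrees.
The wall profile is parameterised as

    r(phi) = R_c + r_t * sin(phi),    z(phi) = r_t * (1 - cos(phi)),

with ``r_t`` the torus tube radius, ``R_c = max_diameter/2 - r_t`` the
radius of the torus centre circle, and ``phi`` measured from the flat
bottom rim (phi = 0) upward.  Azimuth 0° lies on the +x axis; the
convention used throughout the package places the centrifugal-force
direction at azimuth 180°.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "FlaskDimensions",
    "FlaskGeometry",
    "cone_half_angle_from_dims",
    "solve_smooth_transition",
    "wall_radius_at_height",
    "inner_volume_below_height",
    "wall_point_and_normal",
    "DEFAULT_DIMENSIONS",
]

#: Absolute tolerance for volume quadrature, in mm^3 (1e-4 mL).
VOLUME_QUAD_TOL_MM3 = 0.1
#: Tolerance for the tangency root find, degrees.
ANGLE_TOL_DEG = 1e-4


@dataclass(frozen=True)
class FlaskDimensions:
    """Printed inner dimensions of a 250 mL narrow-neck shake flask (mm).

    Defaults are the measured mean inner dimensions of three milled
    flasks: torus tube radius 14.5 mm, maximal diameter 81.6 mm at a
    height of 14.5 mm, tapering to 30.7 mm diameter at 99 mm, flat bottom
    of diameter 52.6 mm.
    """

    torus_radius: float = 14.5
    max_diameter: float = 81.6
    height_of_max_diameter: float = 14.5
    top_diameter: float = 30.7
    top_height: float = 99.0
    bottom_diameter: float = 52.6

    def __post_init__(self) -> None:
        vals = (
            self.torus_radius,
            self.max_diameter,
            self.height_of_max_diameter,
            self.top_diameter,
            self.top_height,
            self.bottom_diameter,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all flask dimensions must be positive")
        if self.max_diameter <= self.top_diameter:
            raise ValueError("max_diameter must exceed top_diameter")
        if self.top_height <= self.height_of_max_diameter:
            raise ValueError("top_height must exceed height_of_max_diameter")
        expected_bottom = self.max_diameter - 2.0 * self.torus_radius
        if abs(self.bottom_diameter - expected_bottom) > 1e-9:
            raise ValueError(
                "bottom_diameter inconsistent with torus construction: "
                f"expected {expected_bottom} mm, got {self.bottom_diameter} mm"
            )

    @property
    def center_circle_radius(self) -> float:
        """Radius R_c of the torus centre circle (mm)."""
        return 0.5 * self.max_diameter - self.torus_radius

    @property
    def top_radius(self) -> float:
        return 0.5 * self.top_diameter


DEFAULT_DIMENSIONS = FlaskDimensions()


def cone_half_angle_from_dims(dims: FlaskDimensions) -> float:
    """Half-angle of the upper cone from vertical, in degrees.

    Computed as the arctangent of the radial taper per unit height between
    the maximal-diameter circle and the top rim.  For the default
    dimensions this evaluates to 16.76°.
    """
    dz = dims.top_height - dims.height_of_max_diameter
    if dz <= 0:
        raise ValueError("degenerate cone: top_height must exceed height_of_max_diameter")
    dr = 0.5 * dims.max_diameter - 0.5 * dims.top_diameter
    return math.degrees(math.atan2(dr, dz))


def _tangency_residual(phi_deg: float, dims: FlaskDimensions) -> float:
    """Difference between torus tangent slope and chord slope at arc angle phi.

    Both slopes are expressed as dr/dz.  The chord runs from the torus end
    point at ``phi`` to the fixed top rim.
    """
    phi = math.radians(phi_deg)
    rt = dims.torus_radius
    r_end = dims.center_circle_radius + rt * math.sin(phi)
    z_end = rt * (1.0 - math.cos(phi))
    # torus tangent: dr/dz = cos(phi)/sin(phi)
    tangent = math.cos(phi) / math.sin(phi)
    chord = (dims.top_radius - r_end) / (dims.top_height - z_end)
    return tangent - chord


def solve_smooth_transition(dims: FlaskDimensions) -> Tuple[float, float]:
    """Torus arc angle and cone half-angle for the smooth-junction variant.

    The torus arc is extended past 90° until its wall tangent is collinear
    with the chord from the torus end point to the fixed top rim; the cone
    half-angle is then recomputed from that chord.  For the default
    dimensions the arc angle is 107.2°.

    Returns
    -------
    (torus_arc_angle_deg, cone_half_angle_deg)
    """
    lo, hi = 90.0 + 1e-9, 180.0 - 1e-9
    f_lo = _tangency_residual(lo, dims)
    f_hi = _tangency_residual(hi, dims)
    if f_lo * f_hi > 0:
        raise ValueError("no smooth tangency solution with arc angle in (90°, 180°)")
    phi_star = brentq(_tangency_residual, lo, hi, args=(dims,), xtol=ANGLE_TOL_DEG)
    phi = math.radians(phi_star)
    r_end = dims.center_circle_radius + dims.torus_radius * math.sin(phi)
    z_end = dims.torus_radius * (1.0 - math.cos(phi))
    cone_half = math.degrees(
        math.atan2(r_end - dims.top_radius, dims.top_height - z_end)
    )
    return phi_star, cone_half


@dataclass(frozen=True)
class FlaskGeometry:
    """A fully specified flask wall profile (sharp or smooth junction)."""

    dims: FlaskDimensions = field(default_factory=FlaskDimensions)
    transition: Literal["sharp", "smooth"] = "smooth"
    torus_arc_angle: float = field(init=False)
    cone_half_angle: float = field(init=False)

    def __post_init__(self) -> None:
        if self.transition == "sharp":
            arc = 90.0
            cone = cone_half_angle_from_dims(self.dims)
        elif self.transition == "smooth":
            arc, cone = solve_smooth_transition(self.dims)
        else:
            raise ValueError(f"unknown transition {self.transition!r}")
        object.__setattr__(self, "torus_arc_angle", arc)
        object.__setattr__(self, "cone_half_angle", cone)

    # --- derived junction quantities -------------------------------------

    @property
    def junction_height(self) -> float:
        """Height z (mm) at which the torus arc ends and the cone begins."""
        phi = math.radians(self.torus_arc_angle)
        return self.dims.torus_radius * (1.0 - math.cos(phi))

    @property
    def junction_radius(self) -> float:
        phi = math.radians(self.torus_arc_angle)
        return self.dims.center_circle_radius + self.dims.torus_radius * math.sin(phi)

    @property
    def top_height(self) -> float:
        return self.dims.top_height

    @property
    def bottom_radius(self) -> float:
        return 0.5 * self.dims.bottom_diameter

    @property
    def max_radius(self) -> float:
        return 0.5 * self.dims.max_diameter

    # --- profile queries ---------------------------------------------------

    def radius_at(self, z):
        """Inner wall radius (mm) at height(s) ``z`` (mm); vectorised."""
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-9) or np.any(z > self.dims.top_height + 1e-9):
            raise ValueError("height outside [0, top_height]")
        zc = np.clip(z, 0.0, self.dims.top_height)
        rt = self.dims.torus_radius
        Rc = self.dims.center_circle_radius
        zj = self.junction_height
        # torus branch: z = rt (1 - cos phi)  =>  phi = arccos(1 - z/rt)
        arg = np.clip(1.0 - np.minimum(zc, zj) / rt, -1.0, 1.0)
        phi = np.arccos(arg)
        r_torus = Rc + rt * np.sin(phi)
        # cone branch: linear between junction point and top rim
        frac = (zc - zj) / (self.dims.top_height - zj)
        r_cone = self.junction_radius + frac * (self.dims.top_radius - self.junction_radius)
        r = np.where(zc <= zj, r_torus, r_cone)
        return r if r.ndim else float(r)

    def _phi_at(self, z):
        """Torus parameter phi (radians) for heights on the torus branch."""
        rt = self.dims.torus_radius
        return np.arccos(np.clip(1.0 - np.asarray(z, dtype=float) / rt, -1.0, 1.0))

    def profile_slope(self, z):
        """dr/dz of the wall profile (vectorised; infinite at z=0)."""
        z = np.asarray(z, dtype=float)
        zj = self.junction_height
        phi = self._phi_at(np.minimum(z, zj))
        with np.errstate(divide="ignore"):
            slope_torus = np.cos(phi) / np.sin(phi)
        slope_cone = -math.tan(math.radians(self.cone_half_angle))
        s = np.where(z <= zj, slope_torus, slope_cone)
        return s if s.ndim else float(s)

    def total_volume(self) -> float:
        """Inner volume of the whole flask up to the top rim, mm^3."""
        return self.inner_volume_below_height(self.dims.top_height)

    def inner_volume_below_height(self, z: float) -> float:
        """Volume (mm^3) enclosed by wall and flat bottom up to height ``z``."""
        if z < -1e-12 or z > self.dims.top_height + 1e-9:
            raise ValueError("height outside [0, top_height]")
        z = min(max(z, 0.0), self.dims.top_height)
        if z == 0.0:
            return 0.0
        zj = self.junction_height

        def integrand(zz):
            r = self.radius_at(zz)
            return math.pi * r * r

        pts = [zj] if 0.0 < zj < z else None
        val, _ = quad(integrand, 0.0, z, points=pts, epsabs=VOLUME_QUAD_TOL_MM3, limit=200)
        return val

    def height_for_volume(self, volume_mm3: float) -> float:
        """Invert :meth:`inner_volume_below_height` (static fill height)."""
        vmax = self.total_volume()
        if not 0.0 <= volume_mm3 <= vmax:
            raise ValueError(f"volume outside [0, {vmax:.1f}] mm^3")
        if volume_mm3 == 0.0:
            return 0.0
        return brentq(
            lambda z: self.inner_volume_below_height(z) - volume_mm3,
            0.0,
            self.dims.top_height,
            xtol=1e-9,
        )

    def wall_point_and_normal(self, z, azimuth_deg):
        """Wall point(s) and inward unit normal(s) in flask-fixed coordinates.

        Parameters are broadcast; returns ``(points, normals)`` arrays of
        shape ``(..., 3)``.  z up, azimuth 0° on +x.
        """
        z = np.asarray(z, dtype=float)
        az = np.radians(np.asarray(azimuth_deg, dtype=float))
        z, az = np.broadcast_arrays(z, az)
        r = self.radius_at(z)
        zj = self.junction_height
        phi = self._phi_at(np.minimum(z, zj))
        # profile tangent (dr, dz) ∝ (cos phi, sin phi) on torus; inward
        # normal is the left-hand rotation (-sin phi, cos phi).
        n_r_t, n_z_t = -np.sin(phi), np.cos(phi)
        beta = math.radians(self.cone_half_angle)  # from vertical
        # cone: tangent (−sin beta, cos beta); inward normal (−cos beta, −sin beta)
        n_r_c, n_z_c = -math.cos(beta), -math.sin(beta)
        on_torus = z <= zj
        n_r = np.where(on_torus, n_r_t, n_r_c)
        n_z = np.where(on_torus, n_z_t, n_z_c)
        ca, sa = np.cos(az), np.sin(az)
        pts = np.stack([r * ca, r * sa, z], axis=-1)
        normals = np.stack([n_r * ca, n_r * sa, n_z], axis=-1)
        return pts, normals

    def contains(self, points_mm) -> np.ndarray:
        """Boolean mask: points (``(...,3)`` array, mm) inside the flask."""
        p = np.asarray(points_mm, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        inside_z = (z >= 0.0) & (z <= self.dims.top_height)
        r = np.hypot(x, y)
        rw = np.where(inside_z, self.radius_at(np.clip(z, 0.0, self.dims.top_height)), 0.0)
        return inside_z & (r <= rw)

    def wall_distance(self, r, z):
        """Shortest distance from interior points (r, z) to the side wall (mm).

        Exact for the torus+cone profile: distance to the torus tube is
        measured from the tube centre circle; distance to the cone is the
        point-to-segment distance to the cone generator line.  Vectorised.
        """
        r = np.asarray(r, dtype=float)
        z = np.asarray(z, dtype=float)
        r, z = np.broadcast_arrays(r, z)
        rt = self.dims.torus_radius
        Rc = self.dims.center_circle_radius
        # angle of the query point around the tube centre (R_c, r_t)
        dr_, dz_ = r - Rc, z - rt
        phi_q = np.arctan2(dr_, -dz_)  # phi=0 points down (bottom rim)
        phi_arc = math.radians(self.torus_arc_angle)
        on_arc = (phi_q >= 0.0) & (phi_q <= phi_arc)
        d_circle = np.abs(np.hypot(dr_, dz_) - rt)
        # endpoints of the arc (bottom rim, junction)
        e0 = np.array([Rc, 0.0])
        e1 = np.array([self.junction_radius, self.junction_height])
        d_end = np.minimum(np.hypot(r - e0[0], z - e0[1]),
                           np.hypot(r - e1[0], z - e1[1]))
        d_torus = np.where(on_arc, d_circle, d_end)
        # cone generator segment from junction point to top rim
        p0 = e1
        p1 = np.array([self.dims.top_radius, self.dims.top_height])
        seg = p1 - p0
        seg_len2 = seg @ seg
        t = ((r - p0[0]) * seg[0] + (z - p0[1]) * seg[1]) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d_cone = np.hypot(r - (p0[0] + t * seg[0]), z - (p0[1] + t * seg[1]))
        d = np.minimum(d_torus, d_cone)
        return d if d.ndim else float(d)

    # --- export --------------------------------------------------------------

    def to_json(self) -> str:
        """Dimensions plus solved angles as a JSON string."""
        payload = {
            "dims_mm": {
                "torus_radius": self.dims.torus_radius,
                "max_diameter": self.dims.max_diameter,
                "height_of_max_diameter": self.dims.height_of_max_diameter,
                "top_diameter": self.dims.top_diameter,
                "top_height": self.dims.top_height,
                "bottom_diameter": self.dims.bottom_diameter,
            },
            "transition": self.transition,
            "torus_arc_angle_deg": self.torus_arc_angle,
            "cone_half_angle_deg": self.cone_half_angle,
            "junction_height_mm": self.junction_height,
            "total_volume_mL": self.total_volume() / 1000.0,
        }
        return json.dumps(payload, indent=2)

    def surface_triangles(self, n_z: int = 120, n_az: int = 90) -> np.ndarray:
        """Triangulated inner surface, shape (n_tri, 3, 3), mm."""
        zs = np.linspace(0.0, self.dims.top_height, n_z)
        az = np.linspace(0.0, 360.0, n_az, endpoint=False)
        r = self.radius_at(zs)
        ang = np.radians(az)
        X = r[:, None] * np.cos(ang)[None, :]
        Y = r[:, None] * np.sin(ang)[None, :]
        Z = np.broadcast_to(zs[:, None], X.shape)
        tris = []
        for i in range(n_z - 1):
            for j in range(n_az):
                j2 = (j + 1) % n_az
                a = (X[i, j], Y[i, j], Z[i, j])
                b = (X[i, j2], Y[i, j2], Z[i, j2])
                c = (X[i + 1, j], Y[i + 1, j], Z[i + 1, j])
                d = (X[i + 1, j2], Y[i + 1, j2], Z[i + 1, j2])
                tris.append((a, b, c))
                tris.append((b, d, c))
        return np.asarray(tris)


# convenience wrappers matching the functional surface ------------------------

def wall_radius_at_height(geom: FlaskGeometry, z):
    return geom.radius_at(z)


def inner_volume_below_height(geom: FlaskGeometry, z: float) -> float:
    return geom.inner_volume_below_height(z)


def wall_point_and_normal(geom: FlaskGeometry, z, azimuth_deg):
    return geom.wall_point_and_normal(z, azimuth_deg)
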