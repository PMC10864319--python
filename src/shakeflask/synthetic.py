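"""Synthetic volume-of-fluid fields with known ground truth.

Stands in for interface-capturing solver output so that the contact-line
extraction and dissipation stages can be exercised against analytic
oracles.  The generated liquid distribution is the inviscid mechanistic
bulk (paraboloid/wall intersection, volume-matched to the fill volume),
optionally

* rotated about the flask axis by a ``phase_shift`` — emulating the
  viscous lag of the bulk behind the centrifugal direction (15–30° at
  moderate viscosity),
* dressed with a wall film of configurable thickness (realistic range
  50–800 µm depending on viscosity) up to a configurable height, slightly
  tapered near its top, and
* smeared across the interface over roughly one cell, mimicking the
  compressed interface of VOF schemes.

A wall-conforming cylindrical-shell mesh with geometric wall layers
supplies cell volumes and per-cell field values for the dissipation
stage; cell volumes come from per-layer quadrature so their sum matches
the flask volume, and all velocity gradients are analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .dissipation import BETA_STAR, FieldSet
from .extraction import VolumeFractionField
from .geometry import FlaskGeometry
from .kinematics import FluidProperties, OperatingCondition, angular_velocity
from .mechanistic import LiquidDistribution, ParaboloidSurface, solve_fill

__all__ = ["SyntheticSpec", "SyntheticField", "SyntheticMesh", "FlowField",
           "generate_alpha_field", "generate_flow_field", "build_mesh"]

# 3-point Gauss-Legendre on [0, 1]
_GAUSS_X = np.array([0.5 - math.sqrt(0.15), 0.5, 0.5 + math.sqrt(0.15)])
_GAUSS_W = np.array([5.0 / 18.0, 8.0 / 18.0, 5.0 / 18.0])


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic VOF field (geometry, conditions, artefacts)."""

    geometry: FlaskGeometry
    condition: OperatingCondition
    fluid: FluidProperties = dc_field(default_factory=FluidProperties)
    phase_shift_deg: float = 0.0
    film_thickness_um: float = 0.0
    film_top_height_mm: Optional[float] = None  # None: bulk maximal height
    film_taper_fraction: float = 0.1
    interface_smear_cells: float = 1.0
    n_radial: int = 24
    n_wall_layers: int = 12
    wall_layer_mm: float = 0.1
    n_azimuth: int = 72
    z_cell_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.film_thickness_um < 0:
            raise ValueError("film_thickness_um must be >= 0")
        if not 0.0 <= self.interface_smear_cells <= 2.0:
            raise ValueError("interface_smear_cells must lie in [0, 2]")
        if not 0.0 <= self.film_taper_fraction < 1.0:
            raise ValueError("film_taper_fraction must lie in [0, 1)")
        cells_across = 2 * (self.n_radial + self.n_wall_layers)
        if cells_across < 20:
            raise ValueError("resolution must give >= 20 cells across the diameter")

    @property
    def smear_width_mm(self) -> float:
        """Interface smearing width, mm (fraction of the z cell edge)."""
        return self.interface_smear_cells * self.z_cell_mm

    @property
    def cell_edge_mm(self) -> float:
        return self.z_cell_mm

    def film_is_subresolution(self) -> bool:
        """True when the film is thinner than half the thinnest wall cell."""
        return 0 < self.film_thickness_um < 500.0 * self.wall_layer_mm


class SyntheticField(VolumeFractionField):
    """Analytic alpha field (bulk + film + smear) with oracle accessors."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.geometry = spec.geometry
        self.distribution: LiquidDistribution = solve_fill(
            spec.geometry, spec.condition)
        self.paraboloid: ParaboloidSurface = self.distribution.paraboloid
        if spec.film_thickness_um > 0:
            self.film_top_mm = (spec.film_top_height_mm
                                if spec.film_top_height_mm is not None
                                else self.distribution.max_height)
        else:
            self.film_top_mm = 0.0
        self.subresolution_film = spec.film_is_subresolution()

    # --- signed indicator functions (mm; positive inside liquid) ---------

    def _bulk_signed(self, x, y, z):
        """Vertical distance below the (phase-shifted) paraboloid surface."""
        delta = math.radians(self.spec.phase_shift_deg)
        # rotate query points back by the phase shift
        c, s = math.cos(-delta), math.sin(-delta)
        xr = c * x - s * y
        yr = s * x + c * y
        return self.paraboloid.height_at(xr, yr) - z

    def _film_signed(self, r, z):
        """Positive inside the wall film (thickness along the wall normal)."""
        spec = self.spec
        if spec.film_thickness_um <= 0:
            return np.full(np.shape(r), -np.inf)
        t_mm = self.film_thickness_at(z) / 1000.0
        d_wall = self.geometry.wall_distance(r, z)
        return np.minimum(t_mm - d_wall, self.film_top_mm - np.asarray(z))

    def film_thickness_at(self, z):
        """Film thickness (µm) at height z: uniform with a linear taper
        over the top ``film_taper_fraction`` of the film height."""
        spec = self.spec
        z = np.asarray(z, dtype=float)
        t = np.full(z.shape, float(spec.film_thickness_um))
        if spec.film_taper_fraction > 0 and self.film_top_mm > 0:
            z_taper = (1.0 - spec.film_taper_fraction) * self.film_top_mm
            frac = np.clip((z - z_taper) / (self.film_top_mm - z_taper), 0.0, 1.0)
            t = t * (1.0 - spec.film_taper_fraction * frac)
        return t

    def signed_indicator(self, points_mm):
        """max(bulk, film) signed distance-like function; liquid iff >= 0."""
        p = np.asarray(points_mm, dtype=float)
        x, y, z = p[..., 0], p[..., 1], p[..., 2]
        r = np.hypot(x, y)
        f = np.maximum(self._bulk_signed(x, y, z), self._film_signed(r, z))
        inside = self.geometry.contains(p)
        return np.where(inside, f, -np.inf)

    def alpha(self, points_mm) -> np.ndarray:
        f = self.signed_indicator(points_mm)
        w = self.spec.smear_width_mm
        if w <= 0:
            return (f >= 0.0).astype(float)
        with np.errstate(invalid="ignore"):
            a = np.clip(0.5 + f / w, 0.0, 1.0)
        return np.where(np.isneginf(f), 0.0, a)

    # --- analytic oracles --------------------------------------------------

    def analytic_contact_line(self, azimuth_deg: float,
                              offset_um: float = 0.0,
                              scan_dz_mm: float = 0.02) -> List[float]:
        """Exact crossing heights along one wall-normal probe ray.

        Independent of the threshold extractor: classifies the continuous
        signed indicator on a dense z scan and refines each sign change
        with Brent's method.  Descending order.
        """
        geom = self.geometry
        zs = np.arange(0.0, geom.top_height + scan_dz_mm / 2, scan_dz_mm)
        pts, nrm = geom.wall_point_and_normal(zs, np.full(zs.shape, azimuth_deg))
        probe = pts + (offset_um / 1000.0) * nrm

        def f_of(zq):
            # interpolate the ray parametrically in z
            w, n = geom.wall_point_and_normal(zq, azimuth_deg)
            return float(self.signed_indicator(w + (offset_um / 1000.0) * n))

        f = self.signed_indicator(probe)
        wet = f >= 0.0
        roots = []
        for i in np.nonzero(wet[1:] != wet[:-1])[0]:
            lo, hi = zs[i], zs[i + 1]
            flo, fhi = f[i], f[i + 1]
            if not (np.isfinite(flo) and np.isfinite(fhi)):
                roots.append(0.5 * (lo + hi))
                continue
            roots.append(float(brentq(f_of, lo, hi, xtol=1e-9)))
        return sorted(roots, reverse=True)

    def expected_apex_azimuth(self) -> float:
        return (180.0 + self.spec.phase_shift_deg) % 360.0

    def ground_truth(self) -> dict:
        """Ground-truth sidecar metadata emitted alongside the field."""
        return {
            "fill_volume_mL": self.spec.condition.fill_volume * 1e6,
            "phase_shift_deg": self.spec.phase_shift_deg,
            "expected_apex_azimuth_deg": self.expected_apex_azimuth(),
            "bulk_max_height_mm": self.distribution.max_height,
            "film_thickness_um": self.spec.film_thickness_um,
            "film_top_height_mm": self.film_top_mm,
            "film_subresolution": self.subresolution_film,
            "paraboloid_apex_mm": self.paraboloid.apex_height,
            "paraboloid_curvature_per_mm": self.paraboloid.curvature,
            "seed": self.spec.seed,
        }


def generate_alpha_field(spec: SyntheticSpec) -> SyntheticField:
    """Build the analytic alpha field for a spec (with oracle attached)."""
    fld = SyntheticField(spec)
    if fld.subresolution_film:
        import logging

        logging.getLogger(__name__).warning(
            "film thickness %.0f µm is below half the wall-layer size; "
            "flagged sub-resolution", spec.film_thickness_um)
    return fld


# --- mesh -------------------------------------------------------------------


@dataclass
class SyntheticMesh:
    """Wall-conforming cylindrical-shell mesh of the flask interior.

    Radial edges are given per z as fractions of the local interior
    radius for the core, plus fixed-thickness wall layers; cell volumes
    are exact to quadrature accuracy.
    """

    spec: SyntheticSpec
    z_edges: np.ndarray  # (n_z+1,)
    theta_edges: np.ndarray  # (n_th+1,) radians
    centers_mm: np.ndarray  # (N, 3)
    volumes_m3: np.ndarray  # (N,)
    shape: Tuple[int, int, int]  # (n_z, n_r, n_th)
    _radial_edges_of_z = None  # callable set at build time

    def radial_edges_at(self, z):
        return self._radial_edges_of_z(z)


def _radial_edges(geom: FlaskGeometry, spec: SyntheticSpec, z):
    """Radial cell edges (mm) at height(s) z, shape (..., n_r+1).

    The outer ``n_wall_layers`` cells have fixed thickness
    ``wall_layer_mm`` (measured horizontally); the core is split
    uniformly.  Wall-layer zone is clamped to at most half the local
    radius so narrow sections stay valid.
    """
    z = np.asarray(z, dtype=float)
    rw = np.asarray(geom.radius_at(np.clip(z, 0.0, geom.top_height)))
    layer_zone = np.minimum(spec.n_wall_layers * spec.wall_layer_mm, 0.5 * rw)
    core = rw - layer_zone
    edges = []
    for i in range(spec.n_radial + 1):
        edges.append(core * (i / spec.n_radial))
    for j in range(1, spec.n_wall_layers + 1):
        edges.append(core + layer_zone * (j / spec.n_wall_layers))
    return np.stack(edges, axis=-1)


def build_mesh(spec: SyntheticSpec) -> SyntheticMesh:
    """Construct the mesh: centres and exact cell volumes."""
    geom = spec.geometry
    n_z = max(int(round(geom.top_height / spec.z_cell_mm)), 1)
    z_edges = np.linspace(0.0, geom.top_height, n_z + 1)
    n_th = spec.n_azimuth
    theta_edges = np.linspace(0.0, 2.0 * math.pi, n_th + 1)
    n_r = spec.n_radial + spec.n_wall_layers

    # per-layer quadrature of the annular areas
    z0, z1 = z_edges[:-1], z_edges[1:]
    dz = z1 - z0
    # quadrature points per layer: (n_z, 3)
    zq = z0[:, None] + dz[:, None] * _GAUSS_X[None, :]
    edges_q = _radial_edges(geom, spec, zq)  # (n_z, 3, n_r+1)
    r_in_q, r_out_q = edges_q[..., :-1], edges_q[..., 1:]  # (n_z, 3, n_r)
    # ring volume per full circle: pi * int (r_out^2 - r_in^2) dz
    ring = math.pi * np.einsum("q,zqr->zr", _GAUSS_W, r_out_q**2 - r_in_q**2) * dz[:, None]
    dtheta = theta_edges[1] - theta_edges[0]
    vol_mm3 = ring[:, :, None] * (dtheta / (2.0 * math.pi))  # (n_z, n_r, 1)
    vol_mm3 = np.broadcast_to(vol_mm3, (n_z, n_r, n_th)).copy()

    # cell centres at mid z, mid theta, area-centroid radius of the mid-z edges
    z_mid = 0.5 * (z0 + z1)
    edges_mid = _radial_edges(geom, spec, z_mid)  # (n_z, n_r+1)
    r_mid = np.sqrt(0.5 * (edges_mid[:, :-1] ** 2 + edges_mid[:, 1:] ** 2))
    th_mid = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    R = r_mid[:, :, None]
    TH = th_mid[None, None, :]
    X = R * np.cos(TH)
    Y = R * np.sin(TH)
    Z = np.broadcast_to(z_mid[:, None, None], X.shape)
    centers = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    mesh = SyntheticMesh(
        spec=spec, z_edges=z_edges, theta_edges=theta_edges,
        centers_mm=centers, volumes_m3=vol_mm3.reshape(-1) * 1e-9,
        shape=(n_z, n_r, n_th),
    )
    mesh._radial_edges_of_z = lambda z: _radial_edges(geom, spec, z)
    return mesh


def cell_alphas(fld: SyntheticField, mesh: SyntheticMesh,
                n_sub: int = 3) -> np.ndarray:
    """Volume-averaged alpha per cell via subsampling.

    Each cell is sampled on an ``n_sub``^3 grid: Gauss points in z
    (weighted by the local annular area), area-uniform radial points and
    uniform azimuthal midpoints — accurate enough to track a wall film a
    few wall layers thick.
    """
    spec = mesh.spec
    geom = spec.geometry
    n_z, n_r, n_th = mesh.shape
    z0, z1 = mesh.z_edges[:-1], mesh.z_edges[1:]
    dz = (z1 - z0)[:, None]
    zq = z0[:, None] + dz * _GAUSS_X[None, :]  # (n_z, q)
    edges_q = _radial_edges(geom, spec, zq)  # (n_z, q, n_r+1)
    a_in, a_out = edges_q[..., :-1] ** 2, edges_q[..., 1:] ** 2  # r^2 bounds
    # area weight of each z-quadrature point within its cell ring
    ring_w = _GAUSS_W[None, :, None] * (a_out - a_in)  # (n_z, q, n_r)
    ring_w = ring_w / np.maximum(ring_w.sum(axis=1, keepdims=True), 1e-300)

    th_mid = 0.5 * (mesh.theta_edges[:-1] + mesh.theta_edges[1:])
    dth = mesh.theta_edges[1] - mesh.theta_edges[0]
    th_sub = (th_mid[:, None] + dth * ((np.arange(n_sub) + 0.5) / n_sub - 0.5)[None, :])

    # radial subsample fractions, area-uniform quantiles
    fr = (np.arange(n_sub) + 0.5) / n_sub  # (n_sub,)
    r_sub = np.sqrt(a_in[..., None] + (a_out - a_in)[..., None] * fr)  # (n_z,q,n_r,n_sub)

    alpha = np.zeros((n_z, n_r, n_th))
    # loop over z-quadrature index to bound memory
    for q in range(len(_GAUSS_X)):
        rq = r_sub[:, q]  # (n_z, n_r, n_sub)
        zzq = np.broadcast_to(zq[:, q][:, None, None, None, None],
                              (n_z, n_r, n_sub, n_th, n_sub))
        rr = np.broadcast_to(rq[:, :, :, None, None], zzq.shape)
        tt = np.broadcast_to(th_sub[None, None, None, :, :], zzq.shape)
        pts = np.stack([rr * np.cos(tt), rr * np.sin(tt), zzq], axis=-1)
        a = fld.alpha(pts)  # (n_z, n_r, n_sub, n_th, n_sub)
        a_mean = a.mean(axis=(2, 4))  # (n_z, n_r, n_th)
        alpha += ring_w[:, q, :, None] * a_mean
    return np.clip(alpha, 0.0, 1.0).reshape(-1)


# --- flow fields -------------------------------------------------------------


@dataclass
class FlowField:
    """A synthetic flow field with its closed-form dissipation oracle."""

    fields: FieldSet
    mesh: SyntheticMesh
    alpha_field: SyntheticField
    profile: str
    expected: dict
    film_mask: np.ndarray  # cells belonging to the wall film


#: Turbulence levels assigned to the solid-body profile (uniform in the
#: liquid): k in m^2/s^2 and omega in 1/s, of the order seen in shaken
#: flasks at moderate frequency.
SOLID_BODY_K = 1.0e-3
SOLID_BODY_OMEGA = 10.0
#: Shear rate of the shear-layer profile, 1/s.
SHEAR_RATE = 100.0
#: Gradient attenuation inside the wall film (gravity-driven creep).
FILM_GRADIENT_FACTOR = 1.0e-3


def generate_flow_field(spec: SyntheticSpec, profile: str = "shear_layer",
                        shear_rate: float = SHEAR_RATE,
                        k_level: float = SOLID_BODY_K,
                        omega_level: float = SOLID_BODY_OMEGA) -> FlowField:
    """Analytic velocity-gradient / k / omega fields on the mesh.

    Profiles:

    * ``quiescent`` — everything zero; dissipation 0.
    * ``solid_body`` — rigid rotation at the shaking angular velocity
      (antisymmetric gradient, zero mean-flow dissipation) plus uniform
      k and omega in the liquid; eps = beta* k omega exactly.
    * ``shear_layer`` — uniform simple shear du_x/dz = shear_rate in the
      bulk liquid; eps = nu * shear_rate^2 exactly (no film), with the
      film region attenuated to near-zero gradients.
    """
    fld = generate_alpha_field(spec)
    mesh = build_mesh(spec)
    alpha = cell_alphas(fld, mesh)
    n = len(alpha)
    centers = mesh.centers_mm
    r = np.hypot(centers[:, 0], centers[:, 1])
    z = centers[:, 2]
    in_film = np.zeros(n, dtype=bool)
    if spec.film_thickness_um > 0:
        in_film = (fld._film_signed(r, z) >= 0.0)

    grads = np.zeros((n, 3, 3))
    k = np.zeros(n)
    om = np.zeros(n)
    liquid = alpha > 0.0
    if profile == "quiescent":
        expected_eps = 0.0
    elif profile == "solid_body":
        omega_rot = angular_velocity(spec.condition)
        grads[liquid, 0, 1] = -omega_rot
        grads[liquid, 1, 0] = omega_rot
        k[liquid] = k_level
        om[liquid] = omega_level
        expected_eps = BETA_STAR * k_level * omega_level
    elif profile == "shear_layer":
        factor = np.where(in_film, FILM_GRADIENT_FACTOR, 1.0)
        grads[:, 0, 2] = shear_rate * factor * liquid
        expected_eps = fld.spec.fluid.kinematic_viscosity * shear_rate**2
    else:
        raise ValueError(f"unknown profile {profile!r}")

    fields = FieldSet.from_gradients(mesh.volumes_m3, alpha, grads, k, om,
                                     spec.fluid)
    expected = {
        "profile": profile,
        "epsilon_bulk_W_per_kg": expected_eps,
        "has_film": bool(spec.film_thickness_um > 0),
    }
    return FlowField(fields=fields, mesh=mesh, alpha_field=fld,
                     profile=profile, expected=expected, film_mask=in_film)
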