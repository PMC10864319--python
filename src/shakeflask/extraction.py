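"""Probe-based extraction of liquid contact lines and wall films.

The liquid distribution in an orbitally shaken flask is summarised by its
contact line — the curve where liquid, gas and glass meet.  Given any
volume-fraction field alpha(x, y, z) (a synthetic field, or one loaded
from solver output), the extractor samples alpha on a probe grid hugging
the flask wall: heights every ``z_step`` (default 0.5 mm), azimuths every
``azimuth_step`` (default 1°), at one or more normal offsets into the
fluid (default ladder 50, 250, ..., 1050 µm).  A sample is classified as
water iff alpha >= 0.5, and every air/water transition descending from
the top of the flask is recorded.  Sampling at several wall-normal
offsets lets a thin wall film be told apart from the rotating bulk: small
offsets stay inside the film and report its (nearly constant) top height,
larger offsets overshoot the film and report the bulk contact line, so
the film thickness is bracketed by the offset ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np

from .geometry import FlaskGeometry

__all__ = [
    "VolumeFractionField",
    "FunctionField",
    "NearestPointField",
    "ContactLineSet",
    "extract_contact_lines",
    "estimate_film_thickness",
    "apex_shift",
    "DEFAULT_OFFSETS_UM",
]

logger = logging.getLogger(__name__)

#: Wall-normal sampling offsets (µm): 50 µm keeps the first probe inside
#: the first cell layer; further probes step 200 µm up to 1050 µm.
DEFAULT_OFFSETS_UM: Tuple[float, ...] = (50.0, 250.0, 450.0, 650.0, 850.0, 1050.0)

AIR_TO_WATER = "air_to_water"
WATER_TO_AIR = "water_to_air"


class VolumeFractionField:
    """Sampling contract: ``alpha(points_mm) -> array in [0, 1]``.

    ``points_mm`` is an ``(..., 3)`` array in flask-fixed millimetre
    coordinates.  Points outside the field's support must return 0 (air).
    """

    geometry: FlaskGeometry

    def alpha(self, points_mm: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class FunctionField(VolumeFractionField):
    """Wrap a plain callable as a volume-fraction field."""

    def __init__(self, func: Callable[[np.ndarray], np.ndarray], geometry: FlaskGeometry):
        self._func = func
        self.geometry = geometry

    def alpha(self, points_mm: np.ndarray) -> np.ndarray:
        a = np.asarray(self._func(np.asarray(points_mm, dtype=float)), dtype=float)
        bad = ~np.isfinite(a)
        if np.any(bad):
            logger.warning("field undefined at %d sample points; treated as air", bad.sum())
            a = np.where(bad, 0.0, a)
        return np.clip(a, 0.0, 1.0)


class NearestPointField(VolumeFractionField):
    """Nearest-cell lookup field built from scattered cell centres.

    Mirrors probe sampling of solver output: each query returns the alpha
    value of the nearest cell centre (no interpolation).  Queries farther
    than ``max_distance_mm`` from any cell are treated as outside the
    mesh and return 0.
    """

    def __init__(self, centers_mm: np.ndarray, alphas: np.ndarray,
                 geometry: FlaskGeometry, max_distance_mm: float = 5.0):
        from scipy.spatial import cKDTree

        centers_mm = np.asarray(centers_mm, dtype=float)
        if centers_mm.ndim != 2 or centers_mm.shape[1] != 3:
            raise ValueError("centers_mm must be (n, 3)")
        self._tree = cKDTree(centers_mm)
        self._alpha = np.asarray(alphas, dtype=float)
        if self._alpha.shape[0] != centers_mm.shape[0]:
            raise ValueError("alphas and centers length mismatch")
        self.geometry = geometry
        self.max_distance_mm = max_distance_mm

    def alpha(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.asarray(points_mm, dtype=float)
        flat = p.reshape(-1, 3)
        dist, idx = self._tree.query(flat)
        a = self._alpha[idx]
        outside = dist > self.max_distance_mm
        if np.any(outside):
            logger.warning("%d probe points outside mesh support; treated as air",
                           int(outside.sum()))
            a = np.where(outside, 0.0, a)
        return a.reshape(p.shape[:-1])


@dataclass
class ContactLineSet:
    """Air/water threshold crossings on the probe grid.

    ``crossings[i_off][i_az]`` is the ordered list of ``(height_mm,
    direction)`` pairs for that azimuth and offset, descending from the
    top of the flask; directions alternate starting with air-to-water.
    """

    azimuths_deg: np.ndarray
    offsets_um: np.ndarray
    crossings: List[List[List[Tuple[float, str]]]]
    z_step_mm: float
    geometry: FlaskGeometry = field(repr=False, default=None)

    @property
    def n_offsets(self) -> int:
        return len(self.offsets_um)

    def _offset_index(self, offset_um: float) -> int:
        idx = np.nonzero(np.isclose(self.offsets_um, offset_um))[0]
        if idx.size == 0:
            raise KeyError(f"offset {offset_um} µm not sampled")
        return int(idx[0])

    def contact_heights(self, offset_um: float | None = None) -> np.ndarray:
        """Per-azimuth contact height (first air->water crossing from top).

        NaN where the wall is dry at all heights.  Defaults to the
        smallest sampled offset.
        """
        i = self._offset_index(offset_um if offset_um is not None else self.offsets_um[0])
        out = np.full(len(self.azimuths_deg), np.nan)
        for j, lst in enumerate(self.crossings[i]):
            for h, d in lst:
                if d == AIR_TO_WATER:
                    out[j] = h
                    break
        return out

    def max_height(self, offset_um: float | None = None) -> float:
        h = self.contact_heights(offset_um)
        if np.all(np.isnan(h)):
            raise ValueError("no contact line at this offset")
        return float(np.nanmax(h))

    def apex_azimuth(self, offset_um: float | None = None, tie_tol_mm: float = 1e-9) -> float:
        """Azimuth of the maximal contact height; circular mean over ties."""
        h = self.contact_heights(offset_um)
        hmax = np.nanmax(h)
        ties = np.nonzero(np.isfinite(h) & (h >= hmax - tie_tol_mm))[0]
        ang = np.radians(self.azimuths_deg[ties])
        mean = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
        return float(np.degrees(mean) % 360.0)

    def to_records(self):
        """Flat records (azimuth_deg, offset_um, crossing_index, height_mm,
        direction) for delimited-text output."""
        rows = []
        for i, off in enumerate(self.offsets_um):
            for j, az in enumerate(self.azimuths_deg):
                for k, (h, d) in enumerate(self.crossings[i][j]):
                    rows.append((float(az), float(off), k, float(h), d))
        return rows

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.to_records(),
            columns=["azimuth_deg", "offset_um", "crossing_index", "height_mm", "direction"],
        )


def _crossings_from_alpha(alpha_col: np.ndarray, z: np.ndarray) -> List[Tuple[float, str]]:
    """Threshold crossings for one probe column, descending from the top.

    ``z`` ascending; returned heights are midpoints of the bracketing
    samples (exact to half a z-step on sharp fields).
    """
    water = alpha_col >= 0.5  # alpha exactly 0.5 counts as water
    out: List[Tuple[float, str]] = []
    # walk downward: index n-1 .. 0
    for i in range(len(z) - 1, 0, -1):
        upper, lower = water[i], water[i - 1]
        if upper != lower:
            h = 0.5 * (z[i] + z[i - 1])
            out.append((h, AIR_TO_WATER if lower and not upper else WATER_TO_AIR))
    if water[-1]:
        # water at the topmost sample: record the top itself as the entry
        out.insert(0, (float(z[-1]), AIR_TO_WATER))
    return out


def extract_contact_lines(
    fld: VolumeFractionField,
    z_step_mm: float = 0.5,
    azimuth_step_deg: float = 1.0,
    offsets_um: Sequence[float] = DEFAULT_OFFSETS_UM,
) -> ContactLineSet:
    """Sample a volume-fraction field along the wall and record crossings.

    For each azimuth and normal offset, alpha is sampled at
    ``wall_point + offset * inward_normal`` on the regular z grid; cells
    with alpha >= 0.5 count as water and every change of classification
    descending from the top is recorded.
    """
    offsets = np.asarray(sorted(offsets_um), dtype=float)
    if np.any(offsets <= 0):
        raise ValueError("offsets must be strictly positive (sampling inside the wall)")
    geom = fld.geometry
    z = np.arange(0.0, geom.top_height + z_step_mm / 4, z_step_mm)
    az = np.arange(0.0, 360.0, azimuth_step_deg)
    Z, AZ = np.meshgrid(z, az, indexing="ij")  # (n_z, n_az)
    pts, normals = geom.wall_point_and_normal(Z, AZ)
    crossings: List[List[List[Tuple[float, str]]]] = []
    for off in offsets:
        probe = pts + (off / 1000.0) * normals
        a = fld.alpha(probe)  # (n_z, n_az)
        per_az = [_crossings_from_alpha(a[:, j], z) for j in range(len(az))]
        crossings.append(per_az)
    return ContactLineSet(
        azimuths_deg=az, offsets_um=offsets, crossings=crossings,
        z_step_mm=z_step_mm, geometry=geom,
    )


def _window_mask(azimuths: np.ndarray, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window[0] % 360.0, window[1] % 360.0
    a = azimuths % 360.0
    if lo <= hi:
        return (a >= lo) & (a <= hi)
    return (a >= lo) | (a <= hi)


def estimate_film_thickness(
    cls: ContactLineSet,
    bulk_free_azimuth_window: Tuple[float, float] = (315.0, 45.0),
    height_tol_mm: float = 2.0,
) -> Tuple[float, float]:
    """Bracket the wall-film thickness from the multi-offset contact lines.

    Over azimuths far from the bulk's leading edge (default a 90° window
    around azimuth 0°, opposite the centrifugal direction at 180°),
    offsets that remain inside the film all report the film's top height,
    while offsets that overshoot it drop to the (much lower) bulk contact
    line.  Returns ``(lower, upper)`` in µm: the largest offset still at
    the film top and the smallest offset at the bulk line.  With no film,
    ``(0, smallest offset)``; with a film thicker than every offset,
    ``(largest offset, inf)``.
    """
    if cls.n_offsets < 2:
        raise ValueError("need at least two offsets to bracket a film")
    mask = _window_mask(cls.azimuths_deg, bulk_free_azimuth_window)
    if not np.any(mask):
        raise ValueError("empty azimuth window")
    med = np.empty(cls.n_offsets)
    for i, off in enumerate(cls.offsets_um):
        h = cls.contact_heights(off)[mask]
        med[i] = np.nanmedian(h) if np.any(np.isfinite(h)) else np.nan
    ref = med[0]
    if not np.isfinite(ref):
        # wall dry in the window even at the smallest offset: no film
        return 0.0, float(cls.offsets_um[0])
    # an offset has fallen through the film when it reports no contact at
    # all, or a contact line clearly below the film top
    dropped = ~np.isfinite(med) | (med < ref - height_tol_mm)
    if np.any(dropped):
        first = int(np.nonzero(dropped)[0].min())
        if first == 0:  # cannot happen (ref is offset 0) but keep safe
            return 0.0, float(cls.offsets_um[0])
        return float(cls.offsets_um[first - 1]), float(cls.offsets_um[first])
    # every offset reports the same height.  A film signature is an almost
    # constant line around the whole circumference at the largest offset;
    # otherwise the offsets simply all sit on the bulk line (no film).
    h_last = cls.contact_heights(cls.offsets_um[-1])
    if np.all(np.isfinite(h_last)) and (np.nanmax(h_last) - np.nanmin(h_last)
                                        <= height_tol_mm):
        return float(cls.offsets_um[-1]), float("inf")
    return 0.0, float(cls.offsets_um[0])


def apex_shift(
    cls: ContactLineSet,
    offset_um: float | None = None,
    reference_azimuth_deg: float = 180.0,
    flat_tol_mm: float = 1e-6,
) -> float:
    """Signed azimuthal shift of the contact-line apex from the reference.

    The reference is the centrifugal direction (180° by convention); a
    positive shift means the apex sits at a larger azimuth, i.e. shifted
    against the shaking direction.  Result in (-180°, 180°].
    """
    h = cls.contact_heights(offset_um)
    finite = h[np.isfinite(h)]
    if finite.size == 0:
        raise ValueError("no contact line at this offset")
    if finite.max() - finite.min() <= flat_tol_mm:
        raise ValueError("flat contact line: apex azimuth undefined")
    apex = cls.apex_azimuth(offset_um, tie_tol_mm=cls.z_step_mm / 4)
    shift = (apex - reference_azimuth_deg + 180.0) % 360.0 - 180.0
    return 180.0 if shift == -180.0 else float(shift)
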