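"""Structured run configuration (YAML) with strict validation.

A run configuration mirrors the "simulated conditions" blocks of a
shaken-flask study: a geometry block (printed dimensions plus the
junction variant), a condition block (shaking frequency, shaking
diameter, filling volume), a fluid block, an extraction block (probe
grids) and a synthetic block (phase shift, film, smear, mesh
resolution).  Unknown keys are rejected with a message naming them, so
typos fail loudly rather than silently using defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

from .extraction import DEFAULT_OFFSETS_UM
from .geometry import FlaskDimensions, FlaskGeometry
from .kinematics import FluidProperties, OperatingCondition
from .synthetic import SyntheticSpec

__all__ = ["RunConfig", "load_config", "config_from_dict"]


def _check_keys(block: dict, allowed: set, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}; "
            f"allowed: {sorted(allowed)}")


@dataclass
class RunConfig:
    geometry: FlaskGeometry
    condition: OperatingCondition
    fluid: FluidProperties
    z_step_mm: float = 0.5
    azimuth_step_deg: float = 1.0
    offsets_um: Tuple[float, ...] = DEFAULT_OFFSETS_UM
    synthetic_kwargs: dict = field(default_factory=dict)
    output_dir: Path = Path("shakeflask_out")
    seed: int = 0
    log_level: str = "INFO"

    def synthetic_spec(self, **overrides) -> SyntheticSpec:
        kw = dict(self.synthetic_kwargs)
        kw.update(overrides)
        kw.setdefault("seed", self.seed)
        return SyntheticSpec(geometry=self.geometry, condition=self.condition,
                             fluid=self.fluid, **kw)


_GEOM_KEYS = {"transition", "torus_radius_mm", "max_diameter_mm",
              "height_of_max_diameter_mm", "top_diameter_mm", "top_height_mm",
              "bottom_diameter_mm"}
_COND_KEYS = {"shaking_frequency_rpm", "shaking_diameter_m", "fill_volume_mL",
              "temperature_C", "run_time_s", "ramp_time_s"}
_FLUID_KEYS = {"density_kg_m3", "viscosity_mPas", "surface_tension_N_m",
               "contact_angle_deg"}
_EXTRACT_KEYS = {"z_step_mm", "azimuth_step_deg", "offsets_um"}
_SYNTH_KEYS = {"phase_shift_deg", "film_thickness_um", "film_top_height_mm",
               "film_taper_fraction", "interface_smear_cells", "n_radial",
               "n_wall_layers", "wall_layer_mm", "n_azimuth", "z_cell_mm",
               "seed"}
_TOP_KEYS = {"geometry", "condition", "fluid", "extraction", "synthetic",
             "output_dir", "seed", "log_level"}


def config_from_dict(raw: dict) -> RunConfig:
    _check_keys(raw, _TOP_KEYS, "<top level>")

    g = dict(raw.get("geometry", {}))
    _check_keys(g, _GEOM_KEYS, "geometry")
    dims_kw = {}
    for key, attr in (("torus_radius_mm", "torus_radius"),
                      ("max_diameter_mm", "max_diameter"),
                      ("height_of_max_diameter_mm", "height_of_max_diameter"),
                      ("top_diameter_mm", "top_diameter"),
                      ("top_height_mm", "top_height"),
                      ("bottom_diameter_mm", "bottom_diameter")):
        if key in g:
            dims_kw[attr] = float(g[key])
    geometry = FlaskGeometry(FlaskDimensions(**dims_kw),
                             g.get("transition", "smooth"))

    c = dict(raw.get("condition", {}))
    _check_keys(c, _COND_KEYS, "condition")
    cond_kw = {}
    if "temperature_C" in c:
        cond_kw["temperature"] = float(c["temperature_C"])
    if "run_time_s" in c:
        cond_kw["run_time"] = float(c["run_time_s"])
    if "ramp_time_s" in c:
        cond_kw["ramp_time"] = float(c["ramp_time_s"])
    condition = OperatingCondition.from_rpm(
        float(c.get("shaking_frequency_rpm", 250.0)),
        float(c.get("shaking_diameter_m", 0.025)),
        float(c.get("fill_volume_mL", 40.0)),
        **cond_kw)

    f = dict(raw.get("fluid", {}))
    _check_keys(f, _FLUID_KEYS, "fluid")
    fluid = FluidProperties(
        density=float(f.get("density_kg_m3", 1000.0)),
        viscosity=float(f.get("viscosity_mPas", 0.89)) * 1e-3,
        surface_tension=float(f.get("surface_tension_N_m", 0.070)),
        contact_angle=float(f.get("contact_angle_deg", 20.0)))

    e = dict(raw.get("extraction", {}))
    _check_keys(e, _EXTRACT_KEYS, "extraction")
    s = dict(raw.get("synthetic", {}))
    _check_keys(s, _SYNTH_KEYS, "synthetic")

    return RunConfig(
        geometry=geometry, condition=condition, fluid=fluid,
        z_step_mm=float(e.get("z_step_mm", 0.5)),
        azimuth_step_deg=float(e.get("azimuth_step_deg", 1.0)),
        offsets_um=tuple(e.get("offsets_um", DEFAULT_OFFSETS_UM)),
        synthetic_kwargs=s,
        output_dir=Path(raw.get("output_dir", "shakeflask_out")),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path: Optional[str]) -> RunConfig:
    """Load a YAML config file; ``None`` yields the default configuration."""
    if path is None:
        return config_from_dict({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return config_from_dict(raw)
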