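"""Dimensionless-number engine: Re, Ne' and the Ne'-Re power correlation.

For unbaffled shake flasks the volumetric power input is well described
by a correlation between the modified Newton number

    Ne' = P / (rho * n^3 * d^4 * V_L^(1/3))

and the flask Reynolds number Re = rho * n * d^2 / eta, with ``d`` the
maximum inner flask diameter (81.6 mm for the 250 mL flask modelled
here) and ``n`` the shaking frequency in 1/s:

    Ne' = 70 Re^-1 + 25 Re^-0.6 + 1.5 Re^-0.2

The shaking diameter is deliberately absent from Ne'.  All functions are
pure; inputs in SI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .kinematics import FluidProperties, OperatingCondition

__all__ = [
    "reynolds",
    "ne_prime",
    "power_from_correlation",
    "correlation_table",
    "DimensionlessPoint",
    "DEFAULT_FLASK_DIAMETER",
]

#: Maximum inner diameter of the default 250 mL flask, m.
DEFAULT_FLASK_DIAMETER = 0.0816


@dataclass(frozen=True)
class DimensionlessPoint:
    """One operating point: Re, Ne' and the resulting power."""

    reynolds: float
    ne_prime: float
    power: float  # W
    power_per_volume: float  # W/m^3
    density: float
    viscosity: float
    frequency: float  # 1/s
    flask_diameter: float  # m
    fill_volume: float  # m^3


def reynolds(density: float, frequency: float, flask_diameter: float,
             viscosity: float) -> float:
    """Flask Reynolds number rho n d^2 / eta (n in 1/s, d in m)."""
    if min(density, frequency, flask_diameter, viscosity) <= 0:
        raise ValueError("all Reynolds inputs must be positive")
    return density * frequency * flask_diameter**2 / viscosity


def ne_prime(re):
    """Modified Newton number from the Ne'-Re correlation; decreasing in Re."""
    re = np.asarray(re, dtype=float)
    if np.any(re <= 0):
        raise ValueError("Reynolds number must be positive")
    out = 70.0 / re + 25.0 * re**-0.6 + 1.5 * re**-0.2
    return out if out.ndim else float(out)


def power_from_correlation(cond: OperatingCondition, fluid: FluidProperties,
                           flask_diameter: float = DEFAULT_FLASK_DIAMETER
                           ) -> DimensionlessPoint:
    """Power input P = Ne'(Re) rho n^3 d^4 V_L^(1/3) and P/V for one point."""
    n = cond.shaking_frequency
    re = reynolds(fluid.density, n, flask_diameter, fluid.viscosity)
    ne = ne_prime(re)
    p = ne * fluid.density * n**3 * flask_diameter**4 * cond.fill_volume ** (1.0 / 3.0)
    return DimensionlessPoint(
        reynolds=re, ne_prime=ne, power=p,
        power_per_volume=p / cond.fill_volume,
        density=fluid.density, viscosity=fluid.viscosity, frequency=n,
        flask_diameter=flask_diameter, fill_volume=cond.fill_volume,
    )


def correlation_table(rpm_values: Iterable[float], fill_volumes_mL: Iterable[float],
                      viscosities_mPas: Iterable[float],
                      density: float = 1000.0,
                      flask_diameter: float = DEFAULT_FLASK_DIAMETER,
                      shaking_diameter: float = 0.025):
    """Correlation P/V over a grid of conditions, as a tidy DataFrame.

    Columns: n_rpm, V_L_mL, eta_mPas, Re, Ne_prime, P_W, PV_kW_m3.
    """
    import pandas as pd

    rows = []
    for rpm in rpm_values:
        for v_mL in fill_volumes_mL:
            for eta in viscosities_mPas:
                cond = OperatingCondition.from_rpm(rpm, shaking_diameter, v_mL)
                fluid = FluidProperties(density=density, viscosity=eta * 1e-3)
                pt = power_from_correlation(cond, fluid, flask_diameter)
                rows.append({
                    "n_rpm": rpm,
                    "V_L_mL": v_mL,
                    "eta_mPas": eta,
                    "Re": pt.reynolds,
                    "Ne_prime": pt.ne_prime,
                    "P_W": pt.power,
                    "PV_kW_m3": pt.power_per_volume / 1000.0,
                })
    return pd.DataFrame(rows)
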