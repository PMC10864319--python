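"""Orbital shaking kinematics: operating conditions and the rotating-force model.

Orbital shaking of a flask fixed to the shaker tray is equivalent (in the
flask frame) to a centrifugal body force of constant magnitude
``omega^2 * d0/2`` per unit mass, rotating at the shaking angular velocity
``omega = 2 pi n``.  At start-up the shaking frequency ramps linearly from
standstill to the target frequency over ``ramp_time`` (default 0.5 s of a
10 s run); both the force magnitude and the phase follow the ramped
frequency, the phase as the time integral of the instantaneous angular
velocity.

Units are SI throughout (frequency 1/s, shaking diameter m, volume m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "OperatingCondition",
    "FluidProperties",
    "angular_velocity",
    "centrifugal_force_components",
    "force_schedule",
    "WATER_LIKE",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class OperatingCondition:
    """Shaking frequency n (1/s), shaking diameter d0 (m), fill volume (m^3)."""

    shaking_frequency: float  # 1/s
    shaking_diameter: float  # m
    fill_volume: float  # m^3
    temperature: float = 25.0  # °C, metadata only
    run_time: float = 10.0  # s
    ramp_time: float = 0.5  # s

    def __post_init__(self) -> None:
        if self.shaking_frequency < 0:
            raise ValueError("shaking_frequency must be >= 0")
        if self.shaking_diameter <= 0:
            raise ValueError("shaking_diameter must be > 0")
        if self.fill_volume <= 0:
            raise ValueError("fill_volume must be > 0")
        if self.ramp_time > self.run_time:
            raise ValueError("ramp_time must not exceed run_time")

    @classmethod
    def from_rpm(cls, rpm: float, shaking_diameter_m: float, fill_volume_mL: float,
                 **kw) -> "OperatingCondition":
        """Build from the usual lab units: rpm, metres, millilitres."""
        return cls(rpm / 60.0, shaking_diameter_m, fill_volume_mL * 1e-6, **kw)

    @property
    def rpm(self) -> float:
        return self.shaking_frequency * 60.0

    def with_frequency_rpm(self, rpm: float) -> "OperatingCondition":
        return replace(self, shaking_frequency=rpm / 60.0)


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density (kg/m^3), dynamic viscosity (Pa s),
    surface tension (N/m), equilibrium contact angle (deg).

    Surface tension and contact angle are carried as metadata for the
    inviscid distribution model (which uses neither) and for provenance.
    """

    density: float = 1000.0
    viscosity: float = 0.89e-3
    surface_tension: float = 0.070
    contact_angle: float = 20.0

    def __post_init__(self) -> None:
        if min(self.density, self.viscosity, self.surface_tension) <= 0:
            raise ValueError("density, viscosity and surface tension must be > 0")
        if not 0.0 < self.contact_angle < 180.0:
            raise ValueError("contact_angle must lie in (0°, 180°)")

    @property
    def kinematic_viscosity(self) -> float:
        return self.viscosity / self.density


WATER_LIKE = FluidProperties()


def angular_velocity(cond: OperatingCondition) -> float:
    """Angular velocity omega = 2 pi n in rad/s."""
    return TWO_PI * cond.shaking_frequency


def _ramped_omega(cond: OperatingCondition, t):
    """Instantaneous angular velocity during/after the linear start-up ramp."""
    omega = angular_velocity(cond)
    t = np.asarray(t, dtype=float)
    if cond.ramp_time == 0.0:
        return np.broadcast_to(omega, t.shape).copy() if t.ndim else omega
    frac = np.clip(t / cond.ramp_time, 0.0, 1.0)
    return omega * frac


def _ramped_phase(cond: OperatingCondition, t):
    """Phase = integral of the ramped angular velocity from 0 to t."""
    omega = angular_velocity(cond)
    t = np.asarray(t, dtype=float)
    tr = cond.ramp_time
    if tr == 0.0:
        return omega * t
    in_ramp = omega * t**2 / (2.0 * tr)
    after = omega * tr / 2.0 + omega * (t - tr)
    return np.where(t < tr, in_ramp, after)


def centrifugal_force_components(cond: OperatingCondition, t) -> Tuple[np.ndarray, np.ndarray]:
    """Rotating centrifugal force per unit mass, (F_x, F_y) in m/s^2.

    After the ramp, ``F_x = omega^2 (d0/2) cos(omega t')`` and
    ``F_y = omega^2 (d0/2) sin(omega t')`` with constant magnitude
    ``omega^2 d0/2``; during the ramp the magnitude follows the ramped
    frequency squared and the phase the integrated angular velocity.
    """
    t = np.asarray(t, dtype=float)
    w = _ramped_omega(cond, t)
    phase = _ramped_phase(cond, t)
    mag = w**2 * cond.shaking_diameter / 2.0
    fx = mag * np.cos(phase)
    fy = mag * np.sin(phase)
    if t.ndim == 0:
        return float(fx), float(fy)
    return fx, fy


def force_schedule(cond: OperatingCondition, dt: float = 0.005) -> np.ndarray:
    """Tabulated force schedule ``(t, F_x, F_y)`` over the run, for export."""
    t = np.arange(0.0, cond.run_time + dt / 2, dt)
    fx, fy = centrifugal_force_components(cond, t)
    return np.column_stack([t, fx, fy])
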