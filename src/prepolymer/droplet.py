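"""Closed-form sedimentation/evaporation model of a falling water droplet.

A droplet of radius r falling through still air reaches the Stokes terminal
velocity v_t = 2 r^2 g (rho_water - rho_air) / (9 eta), so the fall from a
height H takes t_fall = H / v_t.  Evaporation limits its lifetime to
t_life = 2 r^2 / (q0 * dT), where dT is the wet-bulb depression (dry-bulb
minus wet-bulb temperature) and q0 an evaporation coefficient in
um^2 s^-1 K^-1 set by the ambient conditions.  t_fall falls with r while
t_life grows with it, so the two curves cross at a unique optimal radius

    r* = (9 eta H q0' dT / (4 g (rho_water - rho_air)))^(1/4),

with q0' = q0 converted to m^2 s^-1 K^-1.  All computation is in SI
internally; radii are accepted and reported in micrometres at the
interface, matching how droplet sizes are usually quoted.

Defaults: g = 9.81 m/s^2, eta = 1.81e-5 Pa s, rho_water = 998 kg/m^3,
rho_air = 1.204 kg/m^3 (standard air at 20 °C), dT = 6.1 °C and
q0 = 89.84 um^2 s^-1 K^-1 (20 °C, 50% relative humidity), H = 5 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "DropletParams",
    "DropletResult",
    "terminal_velocity",
    "fall_time",
    "evaporation_lifetime",
    "optimal_radius",
    "droplet_volume",
    "forces",
    "summarize",
    "timescale_curve",
]

#: 1 m = 1e6 um; 1 uL = 1e9 um^3
_UM = 1e-6
_UM3_PER_UL = 1e9


@dataclass(frozen=True)
class DropletParams:
    """Droplet and ambient-air parameters (radius in μm, the rest SI/°C)."""

    r: float = 100.0  # droplet radius, μm
    H: float = 5.0  # fall height, m
    g: float = 9.81  # m/s^2
    eta: float = 1.81e-5  # air dynamic viscosity, Pa s
    rho_water: float = 998.0  # kg/m^3
    rho_air: float = 1.204  # kg/m^3
    delta_T: float = 6.1  # wet-bulb depression, °C
    q0: float = 89.84  # evaporation coefficient, μm^2 s^-1 K^-1

    def __post_init__(self) -> None:
        for name in ("r", "H", "g", "eta", "rho_water", "rho_air", "delta_T", "q0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rho_water <= self.rho_air:
            raise ValueError("rho_water must exceed rho_air")


@dataclass(frozen=True)
class DropletResult:
    v_t: float  # m/s
    t_fall: float  # s
    t_life: float  # s
    volume: float  # μL
    F_g: float  # N
    F_B: float  # N
    F_Stokes: float  # N (at v = v_t)


def terminal_velocity(p: DropletParams) -> float:
    """Stokes terminal velocity 2 r^2 g (rho_w - rho_a) / (9 eta), in m/s."""
    r_m = p.r * _UM
    return 2.0 * r_m**2 * p.g * (p.rho_water - p.rho_air) / (9.0 * p.eta)


def fall_time(p: DropletParams) -> float:
    """Time to sediment from height H at terminal velocity, in s."""
    v = terminal_velocity(p)
    if v == 0:
        raise ValueError("terminal velocity is zero; fall time undefined")
    return p.H / v


def evaporation_lifetime(p: DropletParams) -> float:
    """Evaporation-limited lifetime 2 r^2 / (q0 dT), in s (r in μm)."""
    return 2.0 * p.r**2 / (p.q0 * p.delta_T)


def optimal_radius(p: Optional[DropletParams] = None) -> tuple[float, float]:
    """Radius (μm) where fall time equals evaporation lifetime, and that time.

    Closed form: r* = (9 eta H q0 dT / (4 g (rho_w - rho_a)))^(1/4) with q0
    converted to m^2 s^-1 K^-1; below r* a droplet evaporates before landing,
    above it the droplet hits the ground first.
    """
    p = p or DropletParams()
    q0_si = p.q0 * _UM**2  # m^2 s^-1 K^-1
    r4 = 9.0 * p.eta * p.H * q0_si * p.delta_T / (4.0 * p.g * (p.rho_water - p.rho_air))
    r_star_um = r4**0.25 / _UM
    return r_star_um, evaporation_lifetime(replace(p, r=r_star_um))


def droplet_volume(r_um: float) -> float:
    """Sphere volume (4/3) pi r^3 for a radius in μm, returned in μL."""
    if r_um <= 0:
        raise ValueError("radius must be positive")
    return (4.0 / 3.0) * math.pi * r_um**3 / _UM3_PER_UL


def forces(p: DropletParams, v: float) -> tuple[float, float, float]:
    """(F_g, F_B, F_Stokes) in N at fall speed v (m/s).

    F_g = rho_water V g (weight), F_B = rho_air V g (buoyancy),
    F_Stokes = 6 pi eta r v (viscous drag); the three balance at v = v_t.
    """
    r_m = p.r * _UM
    vol = (4.0 / 3.0) * math.pi * r_m**3
    return (
        p.rho_water * vol * p.g,
        p.rho_air * vol * p.g,
        6.0 * math.pi * p.eta * r_m * v,
    )


def summarize(p: Optional[DropletParams] = None) -> DropletResult:
    """All derived droplet quantities at the given parameters."""
    p = p or DropletParams()
    v = terminal_velocity(p)
    fg, fb, fs = forces(p, v)
    return DropletResult(
        v_t=v,
        t_fall=fall_time(p),
        t_life=evaporation_lifetime(p),
        volume=droplet_volume(p.r),
        F_g=fg,
        F_B=fb,
        F_Stokes=fs,
    )


def timescale_curve(radii_um, p: Optional[DropletParams] = None):
    """DataFrame of t_fall and t_life versus radius, for crossing plots."""
    import pandas as pd

    p = p or DropletParams()
    rows = []
    for r in radii_um:
        pr = replace(p, r=float(r))
        rows.append(
            {
                "r_um": float(r),
                "t_fall_s": fall_time(pr),
                "t_life_s": evaporation_lifetime(pr),
            }
        )
    return pd.DataFrame(rows)
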