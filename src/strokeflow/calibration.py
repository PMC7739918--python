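"""Outlet boundary-condition calibration.

Total systemic resistance and compliance follow from cardiac parameters
(mean arterial pressure over cardiac output; decay-time constant), are
corrected for the compliance stored in the resolved 1D network, and are then
distributed to every outlet by cardiac-output fractions per body part and a
cubed-radius (Murray) weighting within each part.  Each outlet receives a
three-element windkessel whose proximal resistance is the characteristic
impedance of the terminal vessel, minimizing artificial wave reflection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import (
    DEFAULT_VISCOSITY,
    DISTAL,
    MAJOR_CEREBRAL_LABELS,
    PROXIMAL,
    ArterialNetwork,
    ValidationError,
    poiseuille_resistance,
)

__all__ = [
    "CardiacParameters",
    "WindkesselOutlet",
    "total_resistance",
    "total_compliance",
    "network_compliance",
    "segment_compliance",
    "characteristic_impedance",
    "characteristic_impedance_split",
    "allocate_outlets",
    "calibrate",
    "windkessel_update",
    "calibration_report",
    "AllocationError",
]


class AllocationError(ValueError):
    """An outlet tag has no cardiac-output fraction (or vice versa)."""


@dataclass(frozen=True)
class CardiacParameters:
    """Heart and systemic pressure parameters (SI; defaults are the model's)."""

    hr_per_min: float = 60.0
    sv_ml: float = 70.0
    p_sys_pa: float = 17300.0
    p_dia_pa: float = 10100.0
    tau_s: float = 1.34
    venous_pressure_pa: float = 2500.0

    def __post_init__(self) -> None:
        for f in ("hr_per_min", "sv_ml", "p_sys_pa", "p_dia_pa", "tau_s", "venous_pressure_pa"):
            if getattr(self, f) <= 0:
                raise ValidationError(f"cardiac parameter {f} must be positive")
        if self.p_sys_pa <= self.p_dia_pa:
            raise ValidationError("systolic pressure must exceed diastolic")

    @property
    def period_s(self) -> float:
        return 60.0 / self.hr_per_min

    @property
    def mean_flow_m3s(self) -> float:
        """Cardiac output SV * HR in m^3/s."""
        return self.sv_ml * 1e-6 * self.hr_per_min / 60.0


@dataclass
class WindkesselOutlet:
    """Calibrated three-element windkessel at one network outlet."""

    outlet: str
    end: str
    tag: str
    label: str
    radius_mm: float
    total_resistance: float  # R1 + R2 [Pa s m^-3]
    proximal_resistance: float  # R1
    distal_resistance: float  # R2
    compliance: float  # [m^3/Pa]
    venous_pressure_pa: float
    capacitor_pressure_pa: float = 0.0  # state, set by the solver

    def __post_init__(self) -> None:
        if min(self.proximal_resistance, self.distal_resistance, self.compliance) <= 0:
            raise ValidationError(f"outlet {self.outlet}: R1, R2, C must be positive")
        rt = self.proximal_resistance + self.distal_resistance
        if not math.isclose(rt, self.total_resistance, rel_tol=1e-9):
            raise ValidationError(f"outlet {self.outlet}: RT != R1 + R2")


def total_resistance(cardiac: CardiacParameters) -> float:
    """Total systemic resistance ((1/3) Psys + (2/3) Pdia) / (SV HR) [Pa s m^-3]."""
    map_pa = cardiac.p_sys_pa / 3.0 + 2.0 * cardiac.p_dia_pa / 3.0
    return map_pa / cardiac.mean_flow_m3s


def total_compliance(tau_s: float, rtot: float) -> float:
    """Total arterial compliance tau / Rtot [m^3/Pa]."""
    if rtot <= 0:
        raise ValidationError("Rtot must be positive")
    return tau_s / rtot


def segment_compliance(r0_mm: float, length_mm: float, E_pa: float, nu: float = 0.5) -> float:
    """Volume compliance of one segment, dV/dp of the tube law at A0 [m^3/Pa].

    Equals 2 A0^{3/2} L / beta with beta = sqrt(pi) E h / (1 - nu^2); at
    nu = 0.5 this is the familiar 3 A0^{3/2} L / (2 sqrt(pi) E h).
    """
    from .anatomy import wall_thickness

    r0 = r0_mm * 1e-3
    L = length_mm * 1e-3
    h = wall_thickness(r0_mm) * 1e-3
    A0 = math.pi * r0 * r0
    beta = math.sqrt(math.pi) * E_pa * h / (1.0 - nu * nu)
    return 2.0 * A0**1.5 * L / beta


def network_compliance(net: ArterialNetwork) -> float:
    """Sum of segment compliances over the 1D network [m^3/Pa]."""
    return sum(
        segment_compliance(s.mean_radius_mm, s.length_mm, s.youngs_modulus_pa, s.poisson_ratio)
        for s in net.segments.values()
    )


def characteristic_impedance(r0_mm: float, E_pa: float, nu: float = 0.5, rho: float = 1050.0) -> float:
    """Terminal characteristic impedance rho c0 / A0 [Pa s m^-3].

    c0 is the linearized tube-law wave speed sqrt(beta / (2 rho sqrt(A0))).
    """
    from .anatomy import wall_thickness

    r0 = r0_mm * 1e-3
    h = wall_thickness(r0_mm) * 1e-3
    A0 = math.pi * r0 * r0
    beta = math.sqrt(math.pi) * E_pa * h / (1.0 - nu * nu)
    c0 = math.sqrt(beta / (2.0 * rho * math.sqrt(A0)))
    return rho * c0 / A0


def characteristic_impedance_split(
    rt: float, r0_mm: float, E_pa: float, nu: float = 0.5, rho: float = 1050.0
) -> tuple[float, float]:
    """Split a total outlet resistance into (R1, R2) with R1 = Z0.

    If the characteristic impedance reaches RT the outlet is degenerate and
    R2 is clamped to 0.05 RT (with a warning) so the capacitor keeps a drain.
    """
    z0 = characteristic_impedance(r0_mm, E_pa, nu, rho)
    if z0 >= rt:
        warnings.warn(
            f"characteristic impedance {z0:.3g} >= RT {rt:.3g}; clamping R2 to 0.05 RT"
        )
        return 0.95 * rt, 0.05 * rt
    return z0, rt - z0


def appended_path_resistance(
    net: ArterialNetwork, outlet_name: str, viscosity: float = DEFAULT_VISCOSITY
) -> float:
    """Serial Poiseuille resistance from the donor attachment point to an outlet.

    Appended segments are recognised by their ':' qualified names
    (``"<label>:<donor id>"``); the walk stops at the first host segment.
    """
    end_to_junction: dict[tuple[str, str], int] = {}
    for i, jct in enumerate(net.junctions):
        for nm, e in jct:
            end_to_junction[(nm, e)] = i
    total = 0.0
    name = outlet_name
    guard = 0
    while ":" in name:
        seg = net.segments[name]
        total += poiseuille_resistance(seg.length_mm, seg.mean_radius_mm, viscosity)
        j = end_to_junction.get((name, PROXIMAL))
        if j is None:
            break
        parent = [nm for nm, e in net.junctions[j] if e == DISTAL]
        if not parent:
            break
        name = parent[0]
        guard += 1
        if guard > 10000:  # pragma: no cover
            raise RuntimeError("cycle while walking appended tree")
    return total


def allocate_outlets(
    net: ArterialNetwork,
    cardiac: CardiacParameters | None = None,
    co_fractions: dict[str, float] | None = None,
    rho: float = 1050.0,
    viscosity: float = DEFAULT_VISCOSITY,
    subtract_tree_resistance: bool = True,
) -> list[WindkesselOutlet]:
    """Calibrate a three-element windkessel for every outlet of ``net``.

    Per outlet i with body-part tag T:
      RT_i = (Rtot / COf_T) * (sum_{j in T} r_j^3) / r_i^3
      C_i  = (Ctot - C1D) * Rtot / RT_i
    For cerebral outlets the serial Poiseuille resistance of the appended
    donor path is subtracted from RT_i (floored at 0.1 RT_i with a warning),
    since the 1D solver resolves that part of the vasculature explicitly.
    """
    cardiac = cardiac or CardiacParameters()
    cof = dict(co_fractions or net.co_fractions)
    if not cof:
        raise AllocationError("no cardiac-output fractions given")
    s = sum(cof.values())
    if not math.isclose(s, 1.0, rel_tol=1e-9, abs_tol=1e-12):
        raise AllocationError(f"cardiac-output fractions sum to {s}, expected 1")
    rtot = total_resistance(cardiac)
    ctot = total_compliance(cardiac.tau_s, rtot)
    c1d = network_compliance(net)
    cfree = ctot - c1d
    if cfree <= 0.05 * ctot:
        warnings.warn("network compliance nearly exhausts the total; flooring at 5%")
        cfree = 0.05 * ctot
    reg = net.outlet_registry()
    if reg.empty:
        raise AllocationError("network has no outlets")
    missing = set(reg["tag"]) - set(cof)
    if missing:
        raise AllocationError(f"no cardiac-output fraction for tags {sorted(missing)}")
    r3sum = reg.assign(r3=reg["radius_mm"] ** 3).groupby("tag")["r3"].sum().to_dict()
    outlets: list[WindkesselOutlet] = []
    for row in reg.itertuples(index=False):
        tag = row.tag
        rt = (rtot / cof[tag]) * r3sum[tag] / row.radius_mm**3
        compliance = cfree * rtot / rt
        if subtract_tree_resistance and row.label in MAJOR_CEREBRAL_LABELS and ":" in row.outlet:
            rpath = appended_path_resistance(net, row.outlet, viscosity)
            if rt - rpath < 0.1 * rt:
                warnings.warn(
                    f"outlet {row.outlet}: appended-path resistance {rpath:.3g} "
                    f"would exhaust RT {rt:.3g}; flooring at 0.1 RT"
                )
                rt = 0.1 * rt
            else:
                rt = rt - rpath
        seg = net.segments[row.outlet]
        r1, r2 = characteristic_impedance_split(
            rt, row.radius_mm, seg.youngs_modulus_pa, seg.poisson_ratio, rho
        )
        outlets.append(
            WindkesselOutlet(
                outlet=row.outlet,
                end=row.end,
                tag=tag,
                label=row.label,
                radius_mm=row.radius_mm,
                total_resistance=r1 + r2,
                proximal_resistance=r1,
                distal_resistance=r2,
                compliance=compliance,
                venous_pressure_pa=cardiac.venous_pressure_pa,
            )
        )
    return outlets


# main entry point used by the pipeline
calibrate = allocate_outlets


def windkessel_update(
    q_in: float, pc: float, dt: float, r1: float, r2: float, c: float, p_venous: float
) -> tuple[float, float]:
    """One implicit-Euler step of the windkessel capacitor.

    dp_c/dt = (Q_in - (p_c - p_venous)/R2) / C.  Returns (p_c_new, p) with
    the boundary pressure p = p_c_new + Q_in R1.
    """
    gam = 1.0 / (1.0 + dt / (r2 * c))
    pc_new = gam * (pc + dt * q_in / c + dt * p_venous / (r2 * c))
    return pc_new, pc_new + q_in * r1


def calibration_report(outlets: list[WindkesselOutlet]) -> pd.DataFrame:
    """Tabular calibration summary (one row per outlet)."""
    return pd.DataFrame(
        [
            {
                "outlet": o.outlet,
                "tag": o.tag,
                "label": o.label,
                "radius_mm": o.radius_mm,
                "RT": o.total_resistance,
                "R1": o.proximal_resistance,
                "R2": o.distal_resistance,
                "C": o.compliance,
            }
            for o in outlets
        ]
    )
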