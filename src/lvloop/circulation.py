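"""Lumped-parameter circulation (basic and extended) and the axial rotary pump.

Two circulation variants share the ventricle and pump:

* **basic** — the aorta sees a fixed arterial pressure ``m0`` and a fixed
  atrial filling pressure ``PR_const``; states are ventricular volume ``V``,
  aortic pressure ``m`` and pump flow ``n``.
* **extended** — the systemic arterial tree is dynamic (three-element
  Windkessel): aortic flow ``Fa`` through an inertance, dynamic atrial
  ``PR`` and arterial ``PS`` pressures.

Mitral and aortic valves are ideal diodes in series with a resistance.  The
pump is an axial rotary assist device in parallel with the aortic valve:
its head rises with speed as ``beta * omega**2`` (omega in rpm), and its
internal resistance grows sharply once ventricular pressure falls below a
1 mmHg suction threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "CirculationParams",
    "PumpParams",
    "PumpProtocol",
    "valve_flow",
    "pump_resistance",
    "pump_rhs",
    "basic_circ_rhs",
    "extended_circ_rhs",
    "omega_of_t",
]


@dataclass(frozen=True)
class CirculationParams:
    """Resistances (mmHg*s/mL), compliances (mL/mmHg) and aortic inertance.

    RA/RM: aortic/mitral valve resistances; RS: systemic vascular
    resistance; RC: characteristic (proximal aortic) resistance; CR/CS/CA:
    atrial, systemic and aortic compliances; LS: inertance of blood in the
    aorta; m0, PR_const: the basic variant's constant arterial and atrial
    pressures (mmHg).
    """

    RA: float = 0.001
    RM: float = 0.005
    RS: float = 0.5
    RC: float = 0.0398
    CR: float = 4.4
    CS: float = 1.33
    CA: float = 0.08
    LS: float = 0.0005
    m0: float = 70.0
    PR_const: float = 9.0

    def __post_init__(self) -> None:
        for name in ("RA", "RM", "RS", "RC", "CR", "CS", "CA", "LS"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def RE(self) -> float:
        """Effective resistance RC*CS/CA seen by the basic model's aorta.

        This is the series resistance that replaces the Windkessel when the
        aortic flow is assumed quasi-steady; it always exceeds RC.
        """
        return self.RC * self.CS / self.CA

    def with_overrides(self, **kwargs: float) -> "CirculationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PumpParams:
    """Axial rotary pump constants.

    delta_p: 1 if the pump is implanted, 0 otherwise; L_star: total pump
    inertance (mmHg*s^2/mL); R_star_base: pump resistance away from suction
    (mmHg*s/mL); suction_coeff / suction_threshold: slope and threshold of
    the resistance penalty applied as ventricular pressure falls below
    1 mmHg; beta: pump head coefficient (mmHg/rpm^2); r_star_cap: optional
    ceiling on the suction resistance to guard numerical blow-up (None =
    uncapped, the model as stated).
    """

    delta_p: int = 0
    L_star: float = 0.0472
    R_star_base: float = 0.3061
    suction_coeff: float = 3.5
    suction_threshold: float = 1.0
    beta: float = 9.9025e-7
    r_star_cap: float | None = None

    def __post_init__(self) -> None:
        if self.delta_p not in (0, 1):
            raise ValueError("delta_p must be 0 or 1")
        if self.L_star <= 0.0:
            raise ValueError("L_star must be positive")
        if self.R_star_base <= 0.0:
            raise ValueError("R_star_base must be positive")

    def with_overrides(self, **kwargs) -> "PumpParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PumpProtocol:
    """Pump speed schedule omega(t) in rpm.

    kind: "off" (always 0), "constant" (omega0_rpm), or "affine_ramp"
    (omega0_rpm + slope_rpm_per_s * (t - t_start), clamped at 0).
    """

    kind: str = "off"
    omega0_rpm: float = 0.0
    slope_rpm_per_s: float = 0.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("off", "constant", "affine_ramp"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind == "constant" and self.omega0_rpm < 0.0:
            raise ValueError("constant pump speed must be >= 0")

    def with_overrides(self, **kwargs) -> "PumpProtocol":
        return replace(self, **kwargs)


def valve_flow(upstream_p: float, downstream_p: float, resistance: float) -> float:
    """Flow (mL/s) through an ideal diode in series with a resistance.

    (upstream - downstream)/R when forward-biased, 0 otherwise; never
    negative.
    """
    if resistance <= 0.0:
        raise ValueError("valve resistance must be positive")
    dp = upstream_p - downstream_p
    return dp / resistance if dp > 0.0 else 0.0


def pump_resistance(PV: float, params: PumpParams) -> float:
    """Pump internal resistance R*(PV), mmHg*s/mL.

    Equal to the base value while ventricular pressure stays at or above
    the 1 mmHg suction threshold, and increasing linearly (slope 3.5 per
    mmHg) as PV drops below it — the lumped signature of inflow-cannula
    suction.  Continuous at the threshold.
    """
    r = params.R_star_base
    x = params.suction_threshold - PV
    if x > 0.0:
        r = params.R_star_base + params.suction_coeff * x
    if params.r_star_cap is not None and r > params.r_star_cap:
        r = params.r_star_cap
    return r


def pump_rhs(n: float, PV: float, m: float, omega_rpm: float, params: PumpParams) -> float:
    """dn/dt for the pump flow: (delta_p/L*)*(PV - m - R*(PV)*n + beta*omega^2).

    Identically zero without a pump.  Negative flow (regurgitation through
    the stopped or slow pump) is a valid regime.
    """
    if params.delta_p == 0:
        return 0.0
    r_star = pump_resistance(PV, params)
    head = params.beta * omega_rpm * omega_rpm
    return (PV - m - r_star * n + head) / params.L_star


def basic_circ_rhs(
    V: float, m: float, PV: float, n: float, params: CirculationParams, delta_p: int
) -> tuple[float, float]:
    """(dV/dt, dm/dt) for the basic variant.

    The ventricle fills from the constant atrial pressure through the
    mitral valve, ejects into the aortic compartment through the aortic
    valve, and is unloaded by the pump flow n.  The aortic pressure relaxes
    toward m0 through the effective systemic resistance.
    """
    q_mitral = valve_flow(params.PR_const, PV, params.RM)
    q_aortic = valve_flow(PV, m, params.RA)
    dV = q_mitral - q_aortic - delta_p * n
    dm = (
        -(m - params.m0) / (params.CS * params.RC)
        + q_aortic / params.CA
        + delta_p * n / params.CA
    )
    return dV, dm


def extended_circ_rhs(
    V: float,
    m: float,
    Fa: float,
    PR: float,
    PS: float,
    PV: float,
    n: float,
    params: CirculationParams,
    delta_p: int,
) -> tuple[float, float, float, float, float]:
    """(dV, dm, dFa, dPR, dPS)/dt for the extended variant.

    Every term moves volume between two compartments, so the total
    V + CA*m + CS*PS + CR*PR is conserved exactly (the pump and the valves
    only redistribute it).
    """
    q_mitral = valve_flow(PR, PV, params.RM)
    q_aortic = valve_flow(PV, m, params.RA)
    dV = q_mitral - q_aortic - delta_p * n
    dm = -Fa / params.CA + q_aortic / params.CA + delta_p * n / params.CA
    dFa = (m - PS) / params.LS - params.RC * Fa / params.LS
    dPR = (PS - PR) / (params.CR * params.RS) - q_mitral / params.CR
    dPS = (PR - PS) / (params.CS * params.RS) + Fa / params.CS
    return dV, dm, dFa, dPR, dPS


def omega_of_t(protocol: PumpProtocol, t: float) -> float:
    """Pump speed (rpm) at time t under the given schedule; clamped at 0."""
    if protocol.kind == "off":
        return 0.0
    if protocol.kind == "constant":
        return protocol.omega0_rpm
    w = protocol.omega0_rpm + protocol.slope_rpm_per_s * max(0.0, t - protocol.t_start)
    if w < 0.0:
        warnings.warn(f"pump speed clamped to 0 at t={t} (schedule gave {w})")
        return 0.0
    return w
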