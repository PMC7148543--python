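"""Contractile-element (sarcomere) dynamics and the micro-to-macro pressure map.

The microscale model is of Bestel-Clement-Sorine type: a chemically driven
active tension ``tau_c`` and stiffness ``k_c`` ride on a damped oscillator
for the contractile strain ``eps_c`` and its rate ``vc``.  A scalar chemical
activity ``u`` (1/s) activates tension when positive and deactivates it
through ``|u|`` regardless of sign; shortening velocity deactivates through
``alpha_l * |vc|``.

The macroscale link converts the active and passive wall stresses into a
left-ventricular pressure through a thin-walled cylindrical-geometry factor
``gamma * (V0/V)**alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from ._switch import heaviside

__all__ = [
    "MicroState",
    "SarcomereParams",
    "length_tension",
    "passive_stress",
    "ventricular_pressure",
    "micro_rhs",
]

#: mmHg per kPa, used only when a config opts into an explicit kPa regime.
KPA_TO_MMHG = 7.5006


class VentricularCollapse(RuntimeError):
    """Raised when the left-ventricular volume is driven to (or below) zero."""


@dataclass(frozen=True)
class MicroState:
    """State of the contractile element.

    vc : strain rate (1/s); eps_c : strain (dimensionless);
    tau_c : active tension; k_c : active stiffness (stress units of the
    parameter set).
    """

    vc: float
    eps_c: float
    tau_c: float
    k_c: float

    def __post_init__(self) -> None:
        for name in ("vc", "eps_c", "tau_c", "k_c"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite MicroState field {name!r}")


@dataclass(frozen=True)
class SarcomereParams:
    """Constants of the contractile element and of the pressure law.

    Stress-valued parameters (sigma0, k0, k2, and the tensions they drive)
    are carried in a single internal stress unit; ``stress_to_mmhg`` is the
    one conversion constant applied where stresses become pressures.  With
    the default parameter set the stress numbers enter the pressure law
    as printed, i.e. ``stress_to_mmhg = 1``.

    chi : damping rate (1/s); omega0 : microscale oscillation frequency
    (1/s); a : active-force coefficient; b : passive-force coefficient;
    alpha_l : deactivation-by-velocity coefficient; sigma0 : maximum active
    tension; k0 : maximum active stiffness; beta0 : width of the Gaussian
    length-tension curve; k1, k2 : passive-stress shape and scale; gamma :
    wall-geometry pressure factor; V0 : reference (zero-passive-stress)
    volume in mL; pv_volume_exponent : exponent of (V0/V) in the pressure
    law (0.5 for a constant-height cylinder whose radius scales as sqrt(V)).
    """

    chi: float = 100.0
    omega0: float = 100.0
    a: float = 100.0
    b: float = 6000.0
    alpha_l: float = 10.0
    sigma0: float = 240.0
    k0: float = 120.0
    beta0: float = 20.0
    k1: float = 0.002
    k2: float = 14.0
    gamma: float = 0.6
    V0: float = 144.0 / 1.5
    stress_to_mmhg: float = KPA_TO_MMHG
    pv_volume_exponent: float = 1.0

    def __post_init__(self) -> None:
        nonneg = (
            "chi", "omega0", "a", "b", "alpha_l", "sigma0", "k0",
            "beta0", "k1", "k2", "stress_to_mmhg",
        )
        for name in nonneg:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.V0 <= 0.0:
            raise ValueError("V0 must be positive")
        if self.gamma <= 0.0:
            raise ValueError("gamma must be positive")

    def with_overrides(self, **kwargs: float) -> "SarcomereParams":
        return replace(self, **kwargs)


def length_tension(eps_c: float, beta0: float) -> float:
    """Gaussian length-tension factor exp(-beta0 * eps_c**2), in (0, 1].

    Peak force at the reference length (eps_c = 0), falling off
    symmetrically for shortening or stretch.
    """
    if not (math.isfinite(eps_c) and math.isfinite(beta0)):
        raise ValueError("non-finite input to length_tension")
    if beta0 < 0.0:
        raise ValueError("beta0 must be >= 0")
    return math.exp(-beta0 * eps_c * eps_c)


def passive_stress(V: float, k1: float, k2: float, V0: float) -> float:
    """Exponential passive wall stress (k2/k1) * (exp(k1*(V/V0 - 1)) - 1).

    Zero at V = V0 and strictly increasing in V.  The k1 -> 0 limit is the
    linear law k2 * (V/V0 - 1), used analytically when k1 underflows.
    """
    if V <= 0.0:
        raise VentricularCollapse(f"passive stress undefined for V = {V} mL")
    x = V / V0 - 1.0
    if k1 < 1e-12:
        return k2 * x
    return (k2 / k1) * math.expm1(k1 * x)


def ventricular_pressure(micro: MicroState, V: float, params: SarcomereParams) -> float:
    """Left-ventricular pressure (mmHg) from active plus passive wall stress.

    PV = conv * gamma * (V0/V)**alpha * [d0(eps_c) * tau_c + sigma_P(V)].
    """
    if V <= 0.0:
        raise VentricularCollapse(f"ventricular collapse: V = {V} mL")
    d0 = length_tension(micro.eps_c, params.beta0)
    sig_p = passive_stress(V, params.k1, params.k2, params.V0)
    geom = params.gamma * (params.V0 / V) ** params.pv_volume_exponent
    return params.stress_to_mmhg * geom * (d0 * micro.tau_c + sig_p)


def micro_rhs(
    micro: MicroState, V: float, u: float, params: SarcomereParams
) -> tuple[float, float, float, float]:
    """Time derivatives (dvc, deps_c, dtau_c, dk_c) of the contractile element.

    dvc/dt    = -chi*vc - omega0^2*eps_c - a*tau_c*d0(eps_c) + b*(V/V0 - 1)
    deps_c/dt = vc
    dtau_c/dt = k_c*vc - (alpha_l*|vc| + |u|)*tau_c + sigma0*u*Theta(u)
    dk_c/dt   =         -(alpha_l*|vc| + |u|)*k_c   + k0*u*Theta(u)

    Activation sources act only for u > 0; both tension and stiffness decay
    through the same velocity/activity deactivation rate, which keeps them
    non-negative along any trajectory started non-negative.
    """
    d0 = length_tension(micro.eps_c, params.beta0)
    deact = params.alpha_l * abs(micro.vc) + abs(u)
    act = u * heaviside(u)
    dvc = (
        -params.chi * micro.vc
        - params.omega0 * params.omega0 * micro.eps_c
        - params.a * micro.tau_c * d0
        + params.b * (V / params.V0 - 1.0)
    )
    dtau = micro.k_c * micro.vc - deact * micro.tau_c + params.sigma0 * act
    dk = -deact * micro.k_c + params.k0 * act
    return dvc, micro.vc, dtau, dk
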