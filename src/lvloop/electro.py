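"""Electric activity: a forced relaxation oscillator with mechano-electric feedback.

A Van der Pol / FitzHugh-Nagumo hybrid drives the heartbeat: a fast variable
``q`` (action-potential-like) and a slow recovery variable ``p``, paced by a
sinusoidal forcing of amplitude 10 at the heart rate (1 Hz for the control
case).  Mechanics feeds back into the oscillator in two places: active
tension tau_c enters the slow equation with gain ``mu1`` (contraction-
induced stress on the action potential) and ventricular stretch beyond the
reference volume enters the fast equation with gain ``mu2``
(stretch-activated channels).  The chemical drive for the sarcomere is
simply u = alpha_u * q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from ._switch import heaviside

__all__ = ["ElectricState", "ElectricParams", "electric_rhs", "chemical_drive"]


@dataclass(frozen=True)
class ElectricState:
    """p: slow electric variable, q: fast electric variable (dimensionless)."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p) and math.isfinite(self.q)):
            raise ValueError("non-finite ElectricState")


@dataclass(frozen=True)
class ElectricParams:
    """mu1: feedback gain on active tension (1/stress-unit); mu2: stretch
    feedback gain (1/(s*mL)); alpha_u: chemical-drive gain (1/s per unit q);
    forcing amplitude fixed at 10 and frequency 1 Hz for a resting heart —
    the frequency is exposed so other heart rates remain reachable."""

    mu1: float = 0.0024
    mu2: float = 0.0
    alpha_u: float = 5.0
    forcing_amplitude: float = 10.0
    forcing_frequency_hz: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_u <= 0.0:
            raise ValueError("alpha_u must be positive")
        if self.forcing_frequency_hz <= 0.0:
            raise ValueError("forcing_frequency_hz must be positive")

    def with_overrides(self, **kwargs: float) -> "ElectricParams":
        return replace(self, **kwargs)


def electric_rhs(
    state: ElectricState,
    tau_c: float,
    V: float,
    t: float,
    params: ElectricParams,
    V0: float,
) -> tuple[float, float]:
    """Time derivatives (dp/dt, dq/dt) of the paced oscillator.

    dp/dt = 0.1 * (q - p + mu1 * tau_c)
    dq/dt = 10*q*(1 - q^2) - 10*(2*pi)^2*p + mu2*V*Theta(V - V0)
            + A*cos(2*pi*f*t)

    The stretch term contributes only when the ventricle is dilated beyond
    V0.
    """
    p, q = state.p, state.q
    two_pi_f = 2.0 * math.pi * params.forcing_frequency_hz
    dp = 0.1 * (q - p + params.mu1 * tau_c)
    dq = (
        10.0 * q * (1.0 - q * q)
        - 10.0 * (2.0 * math.pi) ** 2 * p
        + params.mu2 * V * heaviside(V - V0)
        + params.forcing_amplitude * math.cos(two_pi_f * t)
    )
    return dp, dq


def chemical_drive(q: float, alpha_u: float) -> float:
    """Chemical activity u = alpha_u * q (1/s).

    Positive u activates contraction; negative u contributes only to
    deactivation (the sarcomere equations use |u| for decay and u*Theta(u)
    for the source).
    """
    if alpha_u <= 0.0:
        raise ValueError("alpha_u must be positive")
    return alpha_u * q
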