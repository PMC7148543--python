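"""Switching functions shared by every subsystem.

The model's right-hand sides contain ideal-switch terms (valve diodes,
activation gating, stretch gating, pump suction penalty) written with a
Heaviside step.  The step is hard by default; a logistic smoothing with
width ``eps`` is available for integrators that struggle on the switching
surfaces.
"""

from __future__ import annotations

import math

__all__ = ["heaviside", "smooth_heaviside"]


def heaviside(x: float) -> float:
    """Unit step with the convention Θ(0) = 0.

    The zero-at-threshold convention makes every switched term vanish
    exactly on its switching surface (a closed valve carries no flow at
    zero pressure difference; the suction penalty is off at exactly the
    threshold pressure).
    """
    return 1.0 if x > 0.0 else 0.0


def smooth_heaviside(x: float, eps: float) -> float:
    """Logistic approximation 1/(1+exp(-x/eps)); reduces to :func:`heaviside`
    as eps -> 0.  ``eps`` must be positive."""
    if eps <= 0.0:
        raise ValueError("eps must be positive")
    # clamp the argument so exp never overflows
    z = x / eps
    if z > 40.0:
        return 1.0
    if z < -40.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-z))
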