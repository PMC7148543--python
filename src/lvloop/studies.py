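"""Pre-composed study protocols.

Each function runs one of the package's headline experiments from scratch —
simulation, sweep, analysis — and returns the derived quantities.  They are
thin compositions of the library operations, provided so scripts and
notebooks reproduce the canonical numbers with one call.
"""

from __future__ import annotations

import numpy as np

from .analysis import (
    ElastanceSeries,
    EspvrFit,
    SuctionReport,
    detect_suction_onset,
    elastance_series,
    espvr_from_sweep,
    segment_cycles,
)
from .circulation import PumpParams, PumpProtocol
from .engine import SimulationResult, simulate
from .presets import make_preset

__all__ = [
    "TRANSIENT_CUT",
    "basic_afterload_sweep",
    "extended_preload_sweep",
    "basic_control_elastance",
    "extended_control_elastance",
    "dcm_ramp_suction",
    "activation_duration",
]

TRANSIENT_CUT = 10.0
M0_SWEEP = (50.0, 60.0, 70.0)
V0_FRACTIONS = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def basic_afterload_sweep(
    m0_values: tuple[float, ...] = M0_SWEEP, t_end: float = 30.0
) -> tuple[dict[float, SimulationResult], EspvrFit]:
    """Steady-state basic-model control runs across afterloads, with the
    pooled ESPVR fit (slope and zero-pressure volume V*)."""
    runs = {}
    for m0 in m0_values:
        scen = make_preset("control_basic")
        scen = scen.with_overrides(
            circulation=scen.circulation.with_overrides(m0=m0), t_end=t_end
        )
        runs[m0] = simulate(scen)
    fit = espvr_from_sweep(list(runs.values()), TRANSIENT_CUT)
    return runs, fit


def extended_preload_sweep(
    fractions: tuple[float, ...] = V0_FRACTIONS, t_end: float = 30.0
) -> tuple[dict[float, SimulationResult], EspvrFit]:
    """Extended-model control runs across initial volumes (fractions of V0),
    with the pooled ESPVR fit."""
    runs = {}
    for frac in fractions:
        scen = make_preset("control_extended")
        runs[frac] = simulate(
            scen.with_overrides(initial={"V": frac * scen.sarcomere.V0}, t_end=t_end)
        )
    fit = espvr_from_sweep(list(runs.values()), TRANSIENT_CUT)
    return runs, fit


def basic_control_elastance() -> tuple[ElastanceSeries, EspvrFit]:
    """Elastance extrema of the basic control run, with V* taken from the
    afterload-sweep ESPVR."""
    runs, fit = basic_afterload_sweep()
    es = elastance_series(runs[70.0], fit.v_star, TRANSIENT_CUT)
    return es, fit


def extended_control_elastance() -> tuple[ElastanceSeries, EspvrFit]:
    """Elastance extrema of the extended control run (V(0) = 0.9 V0), with
    V* from the preload sweep."""
    runs, fit = extended_preload_sweep()
    es = elastance_series(runs[0.9], fit.v_star, TRANSIENT_CUT)
    return es, fit


def dcm_ramp_suction(
    omega0_rpm: float = 8000.0,
    slope_rpm_per_s: float = 100.0 / 3.0,
    t_end: float = 180.0,
) -> tuple[SimulationResult, SuctionReport]:
    """Extended dilated-cardiomyopathy heart under a linear pump-speed ramp,
    with suction-onset detection."""
    scen = make_preset("dcm_extended")
    scen = scen.with_overrides(
        pump=PumpParams(delta_p=1),
        protocol=PumpProtocol(
            kind="affine_ramp", omega0_rpm=omega0_rpm, slope_rpm_per_s=slope_rpm_per_s
        ),
        t_end=t_end,
    )
    result = simulate(scen)
    return result, detect_suction_onset(result)


def activation_duration(result: SimulationResult, transient_cut: float = TRANSIENT_CUT) -> float:
    """Mean duration per beat of the chemically active phase (u > 0), the
    interval over which tension builds before relaxing."""
    mask = result.t >= transient_cut
    t = result.t[mask]
    u = result.u[mask]
    flips = np.diff((u > 0.0).astype(int))
    starts = t[1:][flips == 1]
    ends = t[1:][flips == -1]
    if len(ends) and len(starts) and ends[0] < starts[0]:
        ends = ends[1:]
    n = min(len(starts), len(ends))
    if n == 0:
        raise ValueError("no activation episodes found")
    return float(np.mean(ends[:n] - starts[:n]))
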