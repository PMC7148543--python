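"""Shared simulation fixtures.

The expensive trajectories (30 s control runs, loading sweeps, the 180 s
pump ramp) are computed once per session and shared across unit, property
and acceptance tests.
"""

from __future__ import annotations

import pytest

from lvloop import PumpParams, PumpProtocol, espvr_from_sweep, make_preset, simulate

TRANSIENT_CUT = 10.0
M0_SWEEP = (50.0, 60.0, 70.0)
V0_FRACTIONS = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@pytest.fixture(scope="session")
def basic_sweep():
    """Control basic runs across the afterload sweep m0 = 50, 60, 70 mmHg."""
    runs = {}
    for m0 in M0_SWEEP:
        scen = make_preset("control_basic")
        scen = scen.with_overrides(circulation=scen.circulation.with_overrides(m0=m0))
        runs[m0] = simulate(scen)
    return runs


@pytest.fixture(scope="session")
def control_basic_run(basic_sweep):
    """The control basic scenario itself (m0 = 70 mmHg, 30 s)."""
    return basic_sweep[70.0]


@pytest.fixture(scope="session")
def basic_espvr(basic_sweep):
    return espvr_from_sweep([basic_sweep[m] for m in M0_SWEEP], TRANSIENT_CUT)


@pytest.fixture(scope="session")
def control_extended_run(extended_sweep):
    """Control extended scenario: V(0) = 0.9 V0 and the stated pressures."""
    return extended_sweep[0.9]


@pytest.fixture(scope="session")
def extended_sweep():
    """Extended control runs across initial volumes {0.4..0.9} V0."""
    runs = {}
    for frac in V0_FRACTIONS:
        scen = make_preset("control_extended")
        runs[frac] = simulate(
            scen.with_overrides(initial={"V": frac * scen.sarcomere.V0})
        )
    return runs


@pytest.fixture(scope="session")
def extended_espvr(extended_sweep):
    return espvr_from_sweep([extended_sweep[f] for f in V0_FRACTIONS], TRANSIENT_CUT)


@pytest.fixture(scope="session")
def dcm_ramp_run():
    """Extended dilated-cardiomyopathy heart under the slow pump ramp
    omega = 8000 + 100 t / 3 rpm (180 s)."""
    scen = make_preset("dcm_extended")
    scen = scen.with_overrides(
        pump=PumpParams(delta_p=1),
        protocol=PumpProtocol(kind="affine_ramp", omega0_rpm=8000.0, slope_rpm_per_s=100.0 / 3.0),
        t_end=180.0,
    )
    return simulate(scen)


@pytest.fixture(scope="session")
def dcm_pump_runs():
    """Basic dilated-cardiomyopathy heart with the pump at constant speeds."""
    runs = {}
    for omega in (0.0, 8000.0, 16000.0):
        scen = make_preset("dcm_basic")
        scen = scen.with_overrides(
            pump=PumpParams(delta_p=1),
            protocol=PumpProtocol(kind="constant", omega0_rpm=omega),
        )
        runs[omega] = simulate(scen)
    return runs
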