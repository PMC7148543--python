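"""Assembled right-hand side, integration, determinism and solver cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvloop import (
    PumpParams,
    PumpProtocol,
    Scenario,
    VentricularCollapse,
    assemble_rhs,
    cross_validate_solvers,
    make_preset,
    simulate,
)
from lvloop.engine import BASIC_FIELDS, EXTENDED_FIELDS, reference_rhs


def _random_state(rng, extended: bool) -> np.ndarray:
    y = np.array(
        [
            rng.uniform(-3, 3),  # vc
            rng.uniform(-0.4, 0.4),  # eps_c
            rng.uniform(0, 150),  # tau_c
            rng.uniform(0, 80),  # k_c
            rng.uniform(-0.05, 0.05),  # p
            rng.uniform(-1.5, 1.5),  # q
            rng.uniform(40, 140),  # V
            rng.uniform(40, 120),  # m
            rng.uniform(-100, 200),  # n
        ]
    )
    if extended:
        y = np.concatenate([y, [rng.uniform(-100, 500), rng.uniform(0, 25), rng.uniform(30, 100)]])
    return y


class TestAssembledRhs:
    @pytest.mark.parametrize("variant", ["basic", "extended"])
    @pytest.mark.parametrize("delta_p", [0, 1])
    def test_matches_composed_subsystems(self, variant, delta_p):
        """The speed-optimised closure and the straightforward composition
        of the module operations agree to machine precision."""
        scen = Scenario(
            variant=variant,
            pump=PumpParams(delta_p=delta_p),
            protocol=PumpProtocol(kind="constant", omega0_rpm=9000.0) if delta_p else PumpProtocol(),
        )
        rhs = assemble_rhs(scen)
        rng = np.random.default_rng(7)
        for _ in range(25):
            t = rng.uniform(0, 5)
            y = _random_state(rng, variant == "extended")
            np.testing.assert_allclose(rhs(t, y), reference_rhs(scen, t, y), rtol=1e-13, atol=1e-13)

    def test_dimensions(self):
        assert len(assemble_rhs(Scenario(variant="basic"))(0.0, Scenario(variant="basic").initial_state())) == 9
        scen = Scenario(variant="extended")
        assert len(assemble_rhs(scen)(0.0, scen.initial_state())) == 12
        assert len(BASIC_FIELDS) == 9
        assert len(EXTENDED_FIELDS) == 12

    def test_rest_heart_only_fills(self):
        """At the rest state (zero micro/electric, V = V0, m = m0) at the
        forcing's zero crossing, the only non-zero derivative is mitral
        filling from the constant atrial pressure."""
        scen = Scenario(variant="basic")
        y = scen.initial_state()
        y[BASIC_FIELDS.index("V")] = scen.sarcomere.V0
        d = assemble_rhs(scen)(0.25, y)
        i_v = BASIC_FIELDS.index("V")
        assert d[i_v] == pytest.approx((9.0 - 0.0) / 0.005)
        others = np.delete(d, i_v)
        np.testing.assert_allclose(others, 0.0, atol=1e-12)

    def test_no_pump_flow_without_pump(self):
        scen = Scenario(variant="basic")
        rng = np.random.default_rng(3)
        rhs = assemble_rhs(scen)
        for _ in range(10):
            y = _random_state(rng, False)
            assert rhs(0.5, y)[BASIC_FIELDS.index("n")] == 0.0

    def test_collapse_raises(self):
        scen = Scenario(variant="basic")
        y = scen.initial_state()
        y[BASIC_FIELDS.index("V")] = -1.0
        with pytest.raises(VentricularCollapse):
            assemble_rhs(scen)(0.0, y)


class TestSimulate:
    def test_deterministic_rerun(self):
        scen = Scenario(variant="basic", t_end=2.0, output_dt=0.01)
        a = simulate(scen)
        b = simulate(scen)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.t, b.t)

    def test_output_grid(self):
        scen = Scenario(variant="basic", t_end=1.0, output_dt=0.01)
        res = simulate(scen)
        assert len(res.t) == 101
        assert np.all(np.diff(res.t) > 0)

    def test_pump_flow_stays_zero_without_pump(self, control_basic_run):
        assert np.all(control_basic_run["n"] == 0.0)

    def test_volume_floor_aborts(self):
        """Crossing the configured volume floor from above raises the
        collapse diagnostic (floor set inside the normal systolic excursion
        to exercise the abort path)."""
        scen = Scenario(variant="basic", t_end=30.0, v_floor=85.0)
        with pytest.raises(VentricularCollapse, match="collapse"):
            simulate(scen)

    def test_steady_state_one_periodic(self, control_basic_run):
        """The control run settles to a 1 s periodic steady state."""
        res = control_basic_run
        dt = res.t[1] - res.t[0]
        per = int(round(1.0 / dt))
        i = int(round(20.0 / dt))
        a = res.states[i : i + per]
        b = res.states[i + per : i + 2 * per]
        scale = np.maximum(np.abs(a).max(axis=0), 1e-3)
        assert np.max(np.abs(a - b) / scale) < 1e-2

    def test_extended_steady_state_periodic(self, control_extended_run):
        res = control_extended_run
        dt = res.t[1] - res.t[0]
        per = int(round(1.0 / dt))
        i = int(round(25.0 / dt))
        a = res.states[i : i + per]
        b = res.states[i - per : i]
        scale = np.maximum(np.abs(a).max(axis=0), 1e-3)
        assert np.max(np.abs(a - b) / scale) < 2e-2

    def test_derived_signals_consistent(self, control_basic_run):
        """Stored states regenerate PV through the same pressure law the
        integrator used (no drift between trajectory and derived signal)."""
        res = control_basic_run
        rhs_pv = []
        from lvloop import MicroState, ventricular_pressure

        for k in range(0, len(res.t), 5000):
            micro = MicroState(*res.states[k, :4])
            rhs_pv.append(ventricular_pressure(micro, res.states[k, 6], res.scenario.sarcomere))
        np.testing.assert_allclose(rhs_pv, res.PV[::5000], rtol=1e-10)


class TestCrossValidation:
    def test_zero_length_is_exact(self):
        assert cross_validate_solvers(Scenario(variant="basic"), 0.0) == 0.0

    def test_control_agreement(self):
        """Adaptive stiff solver and independent fixed-step RK4 agree to
        better than 1e-3 relative on the control basic run."""
        assert cross_validate_solvers(Scenario(variant="basic"), 20.0, dt=1e-4) < 1e-3

    def test_pumped_dcm_agreement(self):
        """Looser bound for a pump-assisted failing heart (suction-free
        constant speed)."""
        scen = make_preset("dcm_extended").with_overrides(
            pump=PumpParams(delta_p=1),
            protocol=PumpProtocol(kind="constant", omega0_rpm=8000.0),
        )
        assert cross_validate_solvers(scen, 5.0, dt=1e-4) < 1e-2


class TestBasicVsExtended:
    def test_control_stroke_volumes_comparable(self, control_basic_run, control_extended_run):
        """The fixed-afterload approximation tracks the full circulation
        for a resting heart: stroke volumes agree to within a factor."""
        from lvloop import segment_cycles

        sv_b = np.mean([c.sv for c in segment_cycles(control_basic_run, 10.0)])
        sv_e = np.mean([c.sv for c in segment_cycles(control_extended_run, 10.0)])
        assert sv_b > 0 and sv_e > 0
        assert abs(sv_b - sv_e) / sv_e < 0.8
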