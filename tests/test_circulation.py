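"""Valve diodes, pump law, circulation derivatives and conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvloop import (
    CirculationParams,
    PumpParams,
    PumpProtocol,
    omega_of_t,
    pump_resistance,
    valve_flow,
)
from lvloop.circulation import basic_circ_rhs, extended_circ_rhs, pump_rhs


class TestValveFlow:
    def test_forward_biased(self):
        assert valve_flow(9.0, 5.0, 0.005) == pytest.approx(800.0)

    def test_reverse_biased_blocks(self):
        assert valve_flow(5.0, 9.0, 0.005) == 0.0

    def test_zero_gradient_blocks(self):
        assert valve_flow(7.0, 7.0, 0.001) == 0.0

    @given(st.floats(-50.0, 150.0), st.floats(-50.0, 150.0))
    @settings(max_examples=50, deadline=None)
    def test_rectification(self, up, down):
        assert valve_flow(up, down, 0.005) >= 0.0


class TestPumpResistance:
    def test_base_value_away_from_suction(self):
        assert pump_resistance(10.0, PumpParams(delta_p=1)) == pytest.approx(0.3061)

    def test_penalty_below_threshold(self):
        assert pump_resistance(0.5, PumpParams(delta_p=1)) == pytest.approx(2.0561)

    def test_continuous_at_threshold(self):
        assert pump_resistance(1.0, PumpParams(delta_p=1)) == pytest.approx(0.3061)

    @given(st.floats(-30.0, 120.0))
    @settings(max_examples=50, deadline=None)
    def test_never_below_base(self, pv):
        r = pump_resistance(pv, PumpParams(delta_p=1))
        assert r >= 0.3061
        assert (r > 0.3061) == (pv < 1.0)

    def test_optional_cap(self):
        p = PumpParams(delta_p=1, r_star_cap=5.0)
        assert pump_resistance(-100.0, p) == 5.0


class TestPumpRhs:
    def test_absent_pump_is_inert(self):
        assert pump_rhs(50.0, 5.0, 80.0, 12000.0, PumpParams(delta_p=0)) == 0.0

    def test_quasi_steady_flow(self):
        # dn/dt = 0 at n* = (PV - m + beta*omega^2)/R*; PV - m = -80 mmHg,
        # omega = 10 krpm -> n* ~ 62.2 mL/s
        p = PumpParams(delta_p=1)
        n_star = (-80.0 + p.beta * 10000.0**2) / 0.3061
        assert n_star == pytest.approx(62.2, abs=0.2)
        assert pump_rhs(n_star, 10.0, 90.0, 10000.0, p) == pytest.approx(0.0, abs=1e-9)

    def test_backflow_tendency_at_zero_speed(self):
        # stopped pump, ventricular pressure below aortic: flow driven negative
        assert pump_rhs(0.0, 10.0, 90.0, 0.0, PumpParams(delta_p=1)) < 0.0


class TestBasicCirculation:
    def test_equilibrium(self):
        cp = CirculationParams()
        dV, dm = basic_circ_rhs(70.0, cp.m0, 30.0, 0.0, cp, 0)
        assert (dV, dm) == (0.0, 0.0)

    def test_windkessel_relaxation(self):
        cp = CirculationParams()
        _, dm = basic_circ_rhs(70.0, 80.0, 30.0, 0.0, cp, 0)
        assert dm == pytest.approx(-10.0 / (1.33 * 0.0398), rel=1e-6)

    def test_filling_phase(self):
        cp = CirculationParams()
        dV, _ = basic_circ_rhs(50.0, 70.0, 5.0, 0.0, cp, 0)
        assert dV == pytest.approx(800.0)

    def test_mitral_never_empties_aortic_never_fills(self):
        cp = CirculationParams()
        # high PV: aortic valve open, mitral closed -> dV < 0
        dV_eject, _ = basic_circ_rhs(100.0, 70.0, 100.0, 0.0, cp, 0)
        assert dV_eject < 0.0
        # low PV: mitral open -> dV > 0
        dV_fill, _ = basic_circ_rhs(50.0, 70.0, 2.0, 0.0, cp, 0)
        assert dV_fill > 0.0


class TestExtendedCirculation:
    def test_uniform_pressure_equilibrium(self):
        cp = CirculationParams()
        d = extended_circ_rhs(70.0, 75.0, 0.0, 75.0, 75.0, 75.0, 0.0, cp, 0)
        assert d == (0.0, 0.0, 0.0, 0.0, 0.0)

    def test_aortic_flow_stiffness(self):
        cp = CirculationParams()
        _, _, dFa, _, _ = extended_circ_rhs(70.0, 80.0, 0.0, 10.0, 70.0, 30.0, 0.0, cp, 0)
        assert dFa == pytest.approx((80.0 - 70.0) / 0.0005)

    @given(
        st.floats(20.0, 150.0),  # V
        st.floats(10.0, 150.0),  # m
        st.floats(-200.0, 500.0),  # Fa
        st.floats(0.0, 30.0),  # PR
        st.floats(20.0, 120.0),  # PS
        st.floats(-40.0, 160.0),  # PV
        st.floats(-100.0, 300.0),  # n
        st.integers(0, 1),  # delta_p
    )
    @settings(max_examples=100, deadline=None)
    def test_total_volume_conserved_algebraically(self, V, m, Fa, PR, PS, PV, n, dp):
        """Every transfer term cancels pairwise, so
        d/dt [V + CA*m + CS*PS + CR*PR] = 0 identically."""
        cp = CirculationParams()
        dV, dm, dFa, dPR, dPS = extended_circ_rhs(V, m, Fa, PR, PS, PV, n, cp, dp)
        total_rate = dV + cp.CA * dm + cp.CS * dPS + cp.CR * dPR
        assert total_rate == pytest.approx(0.0, abs=1e-9)

    @given(
        st.floats(20.0, 150.0),
        st.floats(10.0, 150.0),
        st.floats(-40.0, 160.0),
        st.floats(-100.0, 300.0),
        st.floats(40.0, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_basic_limit_recovery(self, V, m, PV, n, m0):
        """Substituting the quasi-steady aortic flow Fa = (m - m0)/RE with
        RE = RC*CS/CA into the extended aortic-pressure equation reproduces
        the basic model's dm/dt exactly."""
        cp = CirculationParams(m0=m0)
        Fa_steady = (m - m0) / cp.RE
        for dp in (0, 1):
            _, dm_ext, _, _, _ = extended_circ_rhs(
                V, m, Fa_steady, cp.PR_const, m0, PV, n, cp, dp
            )
            _, dm_basic = basic_circ_rhs(V, m, PV, n, cp, dp)
            assert dm_ext == pytest.approx(dm_basic, rel=1e-12, abs=1e-12)

    def test_effective_resistance_exceeds_characteristic(self):
        cp = CirculationParams()
        assert cp.RE == pytest.approx(cp.RC * cp.CS / cp.CA)
        assert cp.RE > cp.RC


class TestPumpProtocol:
    def test_slow_ramp_value(self):
        proto = PumpProtocol(kind="affine_ramp", omega0_rpm=8000.0, slope_rpm_per_s=100.0 / 3.0)
        assert omega_of_t(proto, 120.0) == pytest.approx(12000.0)

    def test_constant(self):
        assert omega_of_t(PumpProtocol(kind="constant", omega0_rpm=8000.0), 57.3) == 8000.0

    def test_ramp_from_zero(self):
        proto = PumpProtocol(kind="affine_ramp", omega0_rpm=0.0, slope_rpm_per_s=400.0)
        assert omega_of_t(proto, 0.0) == 0.0

    def test_off_and_negative_clamp(self):
        assert omega_of_t(PumpProtocol(kind="off"), 5.0) == 0.0
        proto = PumpProtocol(kind="affine_ramp", omega0_rpm=100.0, slope_rpm_per_s=-400.0)
        with pytest.warns(UserWarning):
            assert omega_of_t(proto, 10.0) == 0.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            PumpProtocol(kind="sinusoidal")


def test_extended_run_conserves_total_volume(control_extended_run):
    """Numeric drift of V + CA*m + CS*PS + CR*PR over a 30 s extended run
    stays below 1e-3 mL."""
    res = control_extended_run
    cp = res.scenario.circulation
    total = res["V"] + cp.CA * res["m"] + cp.CS * res["PS"] + cp.CR * res["PR"]
    assert np.ptp(total) < 1e-3
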