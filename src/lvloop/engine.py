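"""Assembly and integration of the coupled heart-pump system.

The full state is the concatenation of the contractile element
(vc, eps_c, tau_c, k_c), the electric oscillator (p, q) and the circulation
(V, m, n for the basic variant; plus Fa, PR, PS for the extended one) —
9 or 12 ordinary differential equations.  The right-hand side contains
ideal switches (valves, activation gating, suction penalty), so the system
is integrated with a stiff-capable adaptive method whose maximum step is
bounded, keeping every switching surface resolved; an independent
fixed-step integrator is provided as a cross-check.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from . import circulation as circ
from . import electro, sarcomere
from ._switch import heaviside, smooth_heaviside
from .circulation import CirculationParams, PumpParams, PumpProtocol, omega_of_t
from .electro import ElectricParams, ElectricState
from .sarcomere import MicroState, SarcomereParams, VentricularCollapse

__all__ = [
    "BASIC_FIELDS",
    "EXTENDED_FIELDS",
    "SolverSettings",
    "Scenario",
    "SimulationResult",
    "assemble_rhs",
    "reference_rhs",
    "simulate",
    "integrate_fixed_step",
    "cross_validate_solvers",
]

BASIC_FIELDS = ("vc", "eps_c", "tau_c", "k_c", "p", "q", "V", "m", "n")
EXTENDED_FIELDS = BASIC_FIELDS + ("Fa", "PR", "PS")


@dataclass(frozen=True)
class SolverSettings:
    """Adaptive-integrator configuration.

    max_step is kept at or below 10 ms so that valve openings and gating
    switches are never stepped over by more than a fraction of a beat.
    theta_eps > 0 replaces every hard switch with a logistic ramp of that
    width (an escape hatch for integrators that chatter on the switching
    surfaces; the default is the hard switch, as the model is stated).
    """

    method: str = "LSODA"
    rtol: float = 1e-7
    atol: float = 1e-9
    max_step: float = 0.01
    theta_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.max_step <= 0.0 or self.rtol <= 0.0 or self.atol <= 0.0:
            raise ValueError("solver settings must be positive")


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation: model variant, parameters, protocol,
    initial state and integration settings."""

    variant: str = "basic"
    sarcomere: SarcomereParams = field(default_factory=SarcomereParams)
    electric: ElectricParams = field(default_factory=ElectricParams)
    circulation: CirculationParams = field(default_factory=CirculationParams)
    pump: PumpParams = field(default_factory=PumpParams)
    protocol: PumpProtocol = field(default_factory=PumpProtocol)
    initial: dict[str, float] = field(default_factory=dict)
    t_end: float = 30.0
    output_dt: float = 0.001
    solver: SolverSettings = field(default_factory=SolverSettings)
    v_floor: float = 1e-3
    name: str = ""

    def __post_init__(self) -> None:
        if self.variant not in ("basic", "extended"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.t_end <= 0.0 or self.output_dt <= 0.0:
            raise ValueError("t_end and output_dt must be positive")
        unknown = set(self.initial) - set(self.state_fields)
        if unknown:
            raise ValueError(f"initial-state keys not in {self.variant} variant: {sorted(unknown)}")

    @property
    def state_fields(self) -> tuple[str, ...]:
        return BASIC_FIELDS if self.variant == "basic" else EXTENDED_FIELDS

    def initial_state(self) -> np.ndarray:
        """Resolve the initial state vector.

        Unspecified components default to rest: zeros for the microscale,
        electric and pump-flow variables; V = 0.5*V0 (basic) or 0.9*V0
        (extended); m = m0; and for the extended variant Fa = 90 mL/s,
        PR = 10 mmHg, PS = 70 mmHg.
        """
        defaults = {f: 0.0 for f in self.state_fields}
        defaults["m"] = self.circulation.m0
        if self.variant == "basic":
            defaults["V"] = 0.5 * self.sarcomere.V0
        else:
            defaults["V"] = 0.9 * self.sarcomere.V0
            defaults["Fa"] = 90.0
            defaults["PR"] = 10.0
            defaults["PS"] = 70.0
        defaults.update(self.initial)
        return np.array([defaults[f] for f in self.state_fields], dtype=float)

    def with_overrides(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)

    def content_hash(self) -> str:
        """Stable hash of everything that determines the trajectory."""
        payload = json.dumps(_scenario_dict(self), sort_keys=True, default=repr)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _scenario_dict(s: Scenario) -> dict:
    from dataclasses import asdict

    d = asdict(s)
    d.pop("name", None)
    return d


def assemble_rhs(scenario: Scenario) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the full state-derivative function f(t, y).

    The returned closure inlines all subsystem equations over plain floats
    for speed; :func:`reference_rhs` composes the module-level operations
    directly and is used to verify the closure.
    """
    sp = scenario.sarcomere
    ep = scenario.electric
    cp = scenario.circulation
    pp = scenario.pump
    protocol = scenario.protocol
    extended = scenario.variant == "extended"
    ndim = 12 if extended else 9

    chi, w0sq, a_c, b_c = sp.chi, sp.omega0**2, sp.a, sp.b
    alpha_l, sigma0, k0, beta0 = sp.alpha_l, sp.sigma0, sp.k0, sp.beta0
    k1, k2, gamma, V0 = sp.k1, sp.k2, sp.gamma, sp.V0
    conv, alpha_pv = sp.stress_to_mmhg, sp.pv_volume_exponent
    k1_linear = k1 < 1e-12

    mu1, mu2, alpha_u = ep.mu1, ep.mu2, ep.alpha_u
    amp = ep.forcing_amplitude
    two_pi_f = 2.0 * math.pi * ep.forcing_frequency_hz
    ten_4pi2 = 10.0 * (2.0 * math.pi) ** 2

    RA, RM, RC, RS = cp.RA, cp.RM, cp.RC, cp.RS
    CR, CS, CA, LS = cp.CR, cp.CS, cp.CA, cp.LS
    m0, PR_const = cp.m0, cp.PR_const

    dp_flag = pp.delta_p
    L_star, R_base = pp.L_star, pp.R_star_base
    s_coeff, s_thresh = pp.suction_coeff, pp.suction_threshold
    beta_pump, r_cap = pp.beta, pp.r_star_cap

    eps = scenario.solver.theta_eps
    if eps > 0.0:
        theta = lambda x: smooth_heaviside(x, eps)  # noqa: E731
    else:
        theta = heaviside

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        vc, eps_c, tau_c, k_c, p, q, V, m, n = y[:9]
        if V <= 0.0:
            raise VentricularCollapse(f"V = {V} mL at t = {t} s")

        x = V / V0 - 1.0
        sig_p = k2 * x if k1_linear else (k2 / k1) * math.expm1(k1 * x)
        d0 = math.exp(-beta0 * eps_c * eps_c)
        PV = conv * gamma * (V0 / V) ** alpha_pv * (d0 * tau_c + sig_p)

        u = alpha_u * q
        deact = alpha_l * abs(vc) + abs(u)
        act = u * theta(u)

        dvc = -chi * vc - w0sq * eps_c - a_c * tau_c * d0 + b_c * x
        dtau = k_c * vc - deact * tau_c + sigma0 * act
        dk = -deact * k_c + k0 * act

        dp = 0.1 * (q - p + mu1 * tau_c)
        dq = (
            10.0 * q * (1.0 - q * q)
            - ten_4pi2 * p
            + mu2 * V * theta(V - V0)
            + amp * math.cos(two_pi_f * t)
        )

        q_aortic = (PV - m) / RA * theta(PV - m)

        if dp_flag:
            omega = omega_of_t(protocol, t)
            r_star = R_base + s_coeff * (s_thresh - PV) * theta(s_thresh - PV)
            if r_cap is not None and r_star > r_cap:
                r_star = r_cap
            dn = (PV - m - r_star * n + beta_pump * omega * omega) / L_star
        else:
            dn = 0.0

        out = np.empty(ndim)
        out[0], out[1], out[2], out[3] = dvc, vc, dtau, dk
        out[4], out[5] = dp, dq

        if extended:
            Fa, PR, PS = y[9], y[10], y[11]
            q_mitral = (PR - PV) / RM * theta(PR - PV)
            out[6] = q_mitral - q_aortic - dp_flag * n
            out[7] = -Fa / CA + q_aortic / CA + dp_flag * n / CA
            out[8] = dn
            out[9] = (m - PS) / LS - RC * Fa / LS
            out[10] = (PS - PR) / (CR * RS) - q_mitral / CR
            out[11] = (PR - PS) / (CS * RS) + Fa / CS
        else:
            q_mitral = (PR_const - PV) / RM * theta(PR_const - PV)
            out[6] = q_mitral - q_aortic - dp_flag * n
            out[7] = -(m - m0) / (CS * RC) + q_aortic / CA + dp_flag * n / CA
            out[8] = dn
        return out

    return rhs


def reference_rhs(scenario: Scenario, t: float, y: np.ndarray) -> np.ndarray:
    """The same derivative assembled by composing the subsystem operations.

    Slower than the closure from :func:`assemble_rhs`; exists as an
    independent construction for verification (hard switches only).
    """
    sp, ep, cp, pp = scenario.sarcomere, scenario.electric, scenario.circulation, scenario.pump
    micro = MicroState(*y[:4])
    estate = ElectricState(p=y[4], q=y[5])
    V, m, n = y[6], y[7], y[8]

    PV = sarcomere.ventricular_pressure(micro, V, sp)
    u = electro.chemical_drive(estate.q, ep.alpha_u)
    dvc, deps, dtau, dk = sarcomere.micro_rhs(micro, V, u, sp)
    dpe, dqe = electro.electric_rhs(estate, micro.tau_c, V, t, ep, sp.V0)
    omega = omega_of_t(scenario.protocol, t)
    dn = circ.pump_rhs(n, PV, m, omega, pp)

    if scenario.variant == "basic":
        dV, dm = circ.basic_circ_rhs(V, m, PV, n, cp, pp.delta_p)
        return np.array([dvc, deps, dtau, dk, dpe, dqe, dV, dm, dn])
    Fa, PR, PS = y[9], y[10], y[11]
    dV, dm, dFa, dPR, dPS = circ.extended_circ_rhs(V, m, Fa, PR, PS, PV, n, cp, pp.delta_p)
    return np.array([dvc, deps, dtau, dk, dpe, dqe, dV, dm, dn, dFa, dPR, dPS])


@dataclass
class SimulationResult:
    """Sampled trajectory plus derived signals.

    t: sample times (s); states: array (n_samples, n_states) in the order
    of ``fields``; derived signals PV (mmHg), d0, sigma_p (stress units),
    u (1/s), omega_rpm are recomputed from the stored states.
    """

    t: np.ndarray
    states: np.ndarray
    fields: tuple[str, ...]
    scenario: Scenario
    solver_stats: dict

    def __getitem__(self, field_name: str) -> np.ndarray:
        return self.states[:, self.fields.index(field_name)]

    @property
    def PV(self) -> np.ndarray:
        sp = self.scenario.sarcomere
        V = self["V"]
        geom = sp.gamma * (sp.V0 / V) ** sp.pv_volume_exponent
        return sp.stress_to_mmhg * geom * (self.d0 * self["tau_c"] + self.sigma_p)

    @property
    def d0(self) -> np.ndarray:
        sp = self.scenario.sarcomere
        return np.exp(-sp.beta0 * self["eps_c"] ** 2)

    @property
    def sigma_p(self) -> np.ndarray:
        sp = self.scenario.sarcomere
        x = self["V"] / sp.V0 - 1.0
        if sp.k1 < 1e-12:
            return sp.k2 * x
        return (sp.k2 / sp.k1) * np.expm1(sp.k1 * x)

    @property
    def u(self) -> np.ndarray:
        return self.scenario.electric.alpha_u * self["q"]

    @property
    def omega_rpm(self) -> np.ndarray:
        proto = self.scenario.protocol
        return np.array([omega_of_t(proto, ti) for ti in self.t])

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.fields))
        df.insert(0, "t", self.t)
        df["PV"] = self.PV
        df["u"] = self.u
        df["omega_rpm"] = self.omega_rpm
        return df


def simulate(scenario: Scenario) -> SimulationResult:
    """Integrate the scenario from t = 0 to t_end.

    Deterministic for a fixed scenario.  Aborts with
    :class:`VentricularCollapse` if the ventricular volume reaches the
    configured floor (default 1e-3 mL) — distinguishing a numerical
    collapse from the suction regime, in which ventricular *pressure* may
    validly go negative while the volume stays finite.
    """
    rhs = assemble_rhs(scenario)
    y0 = scenario.initial_state()
    t_eval = np.arange(0.0, scenario.t_end + 0.5 * scenario.output_dt, scenario.output_dt)
    t_eval = t_eval[t_eval <= scenario.t_end]
    s = scenario.solver

    v_index = scenario.state_fields.index("V")

    def collapse_event(t: float, y: np.ndarray) -> float:
        return y[v_index] - scenario.v_floor

    collapse_event.terminal = True
    collapse_event.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, scenario.t_end),
        y0,
        method=s.method,
        t_eval=t_eval,
        rtol=s.rtol,
        atol=s.atol,
        max_step=s.max_step,
        events=collapse_event,
        dense_output=False,
    )
    if sol.t_events and len(sol.t_events[0]) > 0:
        raise VentricularCollapse(
            f"ventricular collapse (V <= {scenario.v_floor} mL) at t = {sol.t_events[0][0]:.4f} s"
        )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 0.0:.4f} s: {sol.message}"
        )
    stats = {
        "method": s.method,
        "nfev": int(sol.nfev),
        "njev": int(getattr(sol, "njev", 0) or 0),
        "scenario_hash": scenario.content_hash(),
    }
    return SimulationResult(
        t=sol.t, states=sol.y.T.copy(), fields=scenario.state_fields, scenario=scenario, solver_stats=stats
    )


def integrate_fixed_step(
    scenario: Scenario, t_end: float, dt: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Classical fixed-step 4th-order Runge-Kutta integration.

    Independent of scipy's adaptive machinery; used to cross-check that
    the switching terms are handled correctly.  Returns (t_final, state).
    """
    rhs = assemble_rhs(scenario)
    y = scenario.initial_state()
    n_steps = int(round(t_end / dt))
    t = 0.0
    for _ in range(n_steps):
        k1 = rhs(t, y)
        k2 = rhs(t + 0.5 * dt, y + 0.5 * dt * k1)
        k3 = rhs(t + 0.5 * dt, y + 0.5 * dt * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t += dt
    return np.array(t), y


def cross_validate_solvers(scenario: Scenario, t_check: float, dt: float = 1e-4) -> float:
    """Max relative state discrepancy between the adaptive stiff solver and
    an independent fixed-step RK4 run at time t_check."""
    if t_check == 0.0:
        return 0.0
    scen = scenario.with_overrides(t_end=t_check, output_dt=t_check)
    res = simulate(scen)
    y_adaptive = res.states[-1]
    _, y_fixed = integrate_fixed_step(scenario, t_check, dt)
    scale = np.maximum(np.abs(y_fixed), 1.0)
    return float(np.max(np.abs(y_adaptive - y_fixed) / scale))
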