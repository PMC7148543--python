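"""Pressure-volume loop analysis.

Turns simulated trajectories into the standard hemodynamic summary
quantities: per-beat loop metrics (EDV, ESV, SV), the end-systolic
pressure-volume relation (ESPVR) across a loading sweep with its
volume-axis intercept V* (the volume at zero pressure), the instantaneous
elastance E(t) = PV/(V - V*) with its per-cycle extrema Emax and Emin, and
detection of pump-suction onset during speed ramps.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .circulation import PumpProtocol, omega_of_t
from .engine import SimulationResult

__all__ = [
    "CycleMetrics",
    "EspvrFit",
    "ElastanceSeries",
    "SuctionReport",
    "segment_cycles",
    "end_systolic_point",
    "espvr_fit",
    "espvr_from_sweep",
    "elastance_series",
    "detect_suction_onset",
]

#: minimum separation between end-diastolic volume maxima (s); prevents
#: double-detection of a beat on noisy envelopes at 1 Hz pacing
CYCLE_REFRACTORY_S = 0.5


@dataclass(frozen=True)
class CycleMetrics:
    """Summary of a single cardiac cycle (end-diastole to end-diastole)."""

    index: int
    t_start: float
    t_end: float
    edv: float
    esv: float
    sv: float
    v_es: float
    p_es: float
    peak_pv: float
    mean_pump_flow: float
    pump_flow_ptp: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EspvrFit:
    """Least-squares ESPVR line P = slope*(V - V_star) through end-systolic
    points of a loading sweep."""

    points: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    v_star: float
    residual: float
    iterated: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["points"] = [list(p) for p in self.points]
        return d


@dataclass(frozen=True)
class ElastanceSeries:
    """Instantaneous elastance E(t) = PV/(V - V_star) on a post-transient
    window, with extrema taken over one steady cycle."""

    t: np.ndarray
    E: np.ndarray
    v_star: float
    e_max: float
    e_min: float

    def to_dict(self) -> dict:
        return {"v_star": self.v_star, "e_max": self.e_max, "e_min": self.e_min}


@dataclass(frozen=True)
class SuctionReport:
    """Outcome of suction-onset detection on a pump-speed ramp.

    ``criterion`` names the branch that fired first: "pv_threshold"
    (cycle-minimum ventricular pressure fell below the pump-resistance
    suction threshold) or "flow_envelope" (per-beat peak-to-peak pump-flow
    amplitude jumped by more than 50% over the recent median).
    """

    detected: bool
    onset_time: float | None
    onset_speed_rpm: float | None
    criterion: str | None
    beat_times: tuple[float, ...] = field(default=())
    beat_flow_ptp: tuple[float, ...] = field(default=())
    beat_min_pv: tuple[float, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "detected": self.detected,
            "onset_time_s": self.onset_time,
            "onset_speed_rpm": self.onset_speed_rpm,
            "criterion": self.criterion,
            "beat_times": list(self.beat_times),
            "beat_flow_ptp": list(self.beat_flow_ptp),
            "beat_min_pv": list(self.beat_min_pv),
        }


def _cycle_bounds(result: SimulationResult, transient_cut: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Indices of end-diastolic volume maxima past the transient."""
    mask = result.t >= transient_cut
    if mask.sum() < 3:
        raise ValueError("trajectory does not extend beyond the transient cut")
    t = result.t[mask]
    V = result["V"][mask]
    PV = result.PV[mask]
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(CYCLE_REFRACTORY_S / dt)))
    # prominence rejects the flat ripples of a non-beating trajectory
    peaks, _ = find_peaks(V, distance=distance, prominence=1e-6 * max(1.0, float(np.ptp(V))))
    if len(peaks) < 2 or np.ptp(V) < 1e-9:
        raise ValueError("no cycles found in trajectory")
    return t, V, PV, peaks


def end_systolic_point(
    V: np.ndarray, PV: np.ndarray, v_ref: float
) -> tuple[float, float]:
    """End-systolic point of one loop: the sample maximizing P/(V - v_ref).

    This is the loop's upper-left corner relative to the reference volume
    ``v_ref`` — the point of maximal chamber elastance.
    """
    if np.any(V <= v_ref):
        raise ValueError("reference volume not below all loop volumes")
    i = int(np.argmax(PV / (V - v_ref)))
    return float(V[i]), float(PV[i])


def segment_cycles(
    result: SimulationResult,
    transient_cut: float = 10.0,
    v_ref: float | None = None,
) -> list[CycleMetrics]:
    """Split the post-transient trajectory into cardiac cycles.

    Cycle boundaries are successive end-diastolic instants (local maxima of
    V at least 0.5 s apart).  Per cycle: EDV = max V, ESV = min V,
    SV = EDV - ESV, the end-systolic point relative to ``v_ref`` (default
    0.9 times the minimum post-transient volume), peak pressure, and pump
    flow statistics.
    """
    t, V, PV, peaks = _cycle_bounds(result, transient_cut)
    n_flow = result["n"][result.t >= transient_cut]
    if v_ref is None:
        v_ref = 0.9 * float(V.min())
    out = []
    for i in range(len(peaks) - 1):
        lo, hi = peaks[i], peaks[i + 1] + 1
        Vw, Pw, nw = V[lo:hi], PV[lo:hi], n_flow[lo:hi]
        v_es, p_es = end_systolic_point(Vw, Pw, v_ref)
        out.append(
            CycleMetrics(
                index=i,
                t_start=float(t[lo]),
                t_end=float(t[peaks[i + 1]]),
                edv=float(Vw.max()),
                esv=float(Vw.min()),
                sv=float(Vw.max() - Vw.min()),
                v_es=v_es,
                p_es=p_es,
                peak_pv=float(Pw.max()),
                mean_pump_flow=float(nw.mean()),
                pump_flow_ptp=float(np.ptp(nw)),
            )
        )
    return out


def espvr_fit(points: list[tuple[float, float]]) -> EspvrFit:
    """Least-squares line through end-systolic (V, P) points.

    Returns slope, intercept, the volume-axis crossing
    V* = -intercept/slope, and the RMS residual.
    """
    if len(points) < 2:
        raise ValueError("ESPVR fit needs at least two end-systolic points")
    Vs = np.array([p[0] for p in points], dtype=float)
    Ps = np.array([p[1] for p in points], dtype=float)
    if np.ptp(Vs) < 1e-12:
        raise ValueError("degenerate ESPVR: end-systolic volumes are identical")
    A = np.vstack([Vs, np.ones_like(Vs)]).T
    (slope, intercept), res, *_ = np.linalg.lstsq(A, Ps, rcond=None)
    if abs(slope) < 1e-12:
        raise ValueError("degenerate ESPVR: zero slope")
    rms = float(np.sqrt(res[0] / len(Vs))) if res.size else 0.0
    return EspvrFit(
        points=tuple((float(v), float(p)) for v, p in points),
        slope=float(slope),
        intercept=float(intercept),
        v_star=float(-intercept / slope),
        residual=rms,
    )


def espvr_from_sweep(
    results: list[SimulationResult], transient_cut: float = 10.0
) -> EspvrFit:
    """ESPVR across a loading sweep (one steady-state run per condition).

    End-systolic points are first located with the reference volume
    0.9 times the minimum volume seen across the whole sweep; after a first
    line fit the reference is replaced by the estimated V* and the points
    and fit are recomputed once (the refinement is skipped if the first
    intercept is not below every loop volume).
    """
    if len(results) < 2:
        raise ValueError("ESPVR sweep needs at least two runs")
    sweep_min_v = min(float(r["V"][r.t >= transient_cut].min()) for r in results)

    def points_for(v_ref: float) -> list[tuple[float, float]]:
        pts = []
        for r in results:
            cycles = segment_cycles(r, transient_cut, v_ref=v_ref)
            pts.append(
                (
                    float(np.mean([c.v_es for c in cycles])),
                    float(np.mean([c.p_es for c in cycles])),
                )
            )
        return pts

    first = espvr_fit(points_for(0.9 * sweep_min_v))
    if first.v_star < sweep_min_v:
        refined = espvr_fit(points_for(first.v_star))
        if refined.v_star < sweep_min_v:
            return replace(refined, iterated=True)
    return first


def elastance_series(
    result: SimulationResult, v_star: float, transient_cut: float = 10.0
) -> ElastanceSeries:
    """Instantaneous elastance E(t) = PV(t)/(V(t) - V*) past the transient.

    Emax and Emin are the extrema over the last complete steady cycle.
    Raises if the volume reaches V* anywhere in the analysed window.
    """
    mask = result.t >= transient_cut
    t = result.t[mask]
    V = result["V"][mask]
    PV = result.PV[mask]
    bad = V <= v_star
    if np.any(bad):
        raise ValueError(
            f"elastance undefined: V <= V* = {v_star} mL at t = {t[bad][0]:.4f} s"
        )
    E = PV / (V - v_star)
    _, _, _, peaks = _cycle_bounds(result, transient_cut)
    lo, hi = peaks[-2], peaks[-1] + 1
    return ElastanceSeries(
        t=t,
        E=E,
        v_star=float(v_star),
        e_max=float(E[lo:hi].max()),
        e_min=float(E[lo:hi].min()),
    )


def detect_suction_onset(
    result: SimulationResult,
    protocol: PumpProtocol | None = None,
    transient_cut: float = 0.0,
    envelope_jump: float = 0.5,
    envelope_window: int = 5,
) -> SuctionReport:
    """Detect the onset of pump suction during a speed ramp.

    Two per-beat criteria are evaluated and the earliest firing one wins:

    * **pv_threshold** — the cycle-minimum ventricular pressure first falls
      below the pump's suction threshold (1 mmHg), the pressure at which
      the pump resistance penalty activates;
    * **flow_envelope** — the peak-to-peak amplitude of the pump flow over
      a beat exceeds the median amplitude of the preceding ``envelope_window``
      beats by more than ``envelope_jump`` (default 50%).

    Without a pump the report is returned with ``detected=False``.
    """
    if protocol is None:
        protocol = result.scenario.protocol
    if result.scenario.pump.delta_p == 0:
        return SuctionReport(detected=False, onset_time=None, onset_speed_rpm=None, criterion=None)

    threshold = result.scenario.pump.suction_threshold
    t, V, PV, peaks = _cycle_bounds(result, transient_cut)
    n_flow = result["n"][result.t >= transient_cut]

    beat_times, beat_ptp, beat_minpv = [], [], []
    onset_time, criterion = None, None
    for i in range(len(peaks) - 1):
        lo, hi = peaks[i], peaks[i + 1] + 1
        tw, Pw, nw = t[lo:hi], PV[lo:hi], n_flow[lo:hi]
        ptp = float(np.ptp(nw))
        beat_times.append(float(tw[0]))
        beat_ptp.append(ptp)
        beat_minpv.append(float(Pw.min()))

        if onset_time is None and Pw.min() < threshold:
            onset_time = float(tw[np.argmax(Pw < threshold)])
            criterion = "pv_threshold"
        if (
            onset_time is None
            and len(beat_ptp) > envelope_window
        ):
            recent = np.median(beat_ptp[-1 - envelope_window : -1])
            if recent > 0 and ptp > (1.0 + envelope_jump) * recent:
                onset_time = float(tw[0])
                criterion = "flow_envelope"
        if onset_time is not None:
            break

    if onset_time is None:
        return SuctionReport(
            detected=False,
            onset_time=None,
            onset_speed_rpm=None,
            criterion=None,
            beat_times=tuple(beat_times),
            beat_flow_ptp=tuple(beat_ptp),
            beat_min_pv=tuple(beat_minpv),
        )
    return SuctionReport(
        detected=True,
        onset_time=onset_time,
        onset_speed_rpm=float(omega_of_t(protocol, onset_time)),
        criterion=criterion,
        beat_times=tuple(beat_times),
        beat_flow_ptp=tuple(beat_ptp),
        beat_min_pv=tuple(beat_minpv),
    )
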