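"""Quantitative readouts of the pathway model.

Steady states and their linear stability, limit-cycle detection and period
estimation, peak metrics of transient responses (time to peak, fold change,
full width at half maximum, area under the curve), desensitization profiles
under repeated stimulation, circadian phase-response scans, one-parameter
sensitivity scans against calibration windows, and two-parameter stability
diagrams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import calcium_signals as cs
from .model_core import (
    DriverSignals,
    ParameterError,
    PathwayParameters,
    STATE_NAMES,
    N_STATES,
    initial_state,
    pathway_rhs,
)
from .protocols import (
    ClockParams,
    Protocol,
    SimulationResult,
    make_circadian_shock,
    make_cold_shock,
    run_simulation,
)

__all__ = [
    "PeakMetrics",
    "StabilityReport",
    "LimitCycleReport",
    "find_steady_states",
    "linear_stability",
    "jacobian",
    "detect_limit_cycle",
    "peak_metrics",
    "desensitization_profile",
    "phase_response_scan",
    "sensitivity_scan",
    "stability_diagram",
]


# ---------------------------------------------------------------------------
# steady states and linear stability
# ---------------------------------------------------------------------------

def find_steady_states(
    p: PathwayParameters,
    drivers: DriverSignals | None = None,
    n_starts: int = 200,
    seed: int = 1234,
    merge_tol: float = 1e-6,
) -> list[np.ndarray]:
    """Multi-start root finding on the pathway right-hand side.

    Starting points are drawn log-uniformly within ``[1e-3, 1e3]`` times a
    per-variable reference scale (conserved totals for cycle variables, a
    nominal 1 nM for synthesized species), plus the forward-integrated basal
    state.  Roots are kept if non-negative, below the conserved totals and
    with residual below 1e-8 nM/h; duplicates are merged at relative
    tolerance ``merge_tol``.  Deterministic for a given seed.
    """
    from scipy.optimize import root

    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")
    if drivers is None:
        drivers = DriverSignals.basal(p)
    rng = np.random.default_rng(seed)

    totals = p.totals()
    scale = np.array([totals.get(name, 1.0) for name in STATE_NAMES])
    caps = np.array([totals.get(name, np.inf) for name in STATE_NAMES])

    starts = []
    try:
        starts.append(initial_state(p, drivers))
    except Exception:
        pass
    for _ in range(n_starts):
        u = rng.uniform(-3.0, 3.0, N_STATES)
        starts.append(np.minimum(scale * 10.0**u, caps * 0.999))

    found: list[np.ndarray] = []
    for y0 in starts:
        res = root(lambda x: pathway_rhs(0.0, x, p, drivers), y0, method="hybr", tol=1e-12)
        # acceptance is by residual, not the solver flag: hybr reports "not
        # making good progress" when started at (or converging onto) a root
        y = res.x
        if np.any(y < -1e-9) or np.any(y > caps * (1.0 + 1e-9)):
            continue
        y = np.clip(y, 0.0, None)
        if np.max(np.abs(pathway_rhs(0.0, y, p, drivers))) > 1e-8:
            continue
        if any(
            np.allclose(y, z, rtol=merge_tol, atol=1e-9) for z in found
        ):
            continue
        found.append(y)
    found.sort(key=lambda y: y[STATE_NAMES.index("M_CBF3")])
    return found


def jacobian(
    p: PathwayParameters,
    s: np.ndarray,
    drivers: DriverSignals | None = None,
) -> np.ndarray:
    """Jacobian of the pathway right-hand side by central finite differences.

    Step per coordinate: ``1e-6 * max(|x_i|, 1)``.  Perturbed states are kept
    inside the admissible box (non-negative, below conserved totals).
    """
    if drivers is None:
        drivers = DriverSignals.basal(p)
    caps = np.array([p.totals().get(name, np.inf) for name in STATE_NAMES])
    J = np.empty((N_STATES, N_STATES))
    for i in range(N_STATES):
        h = 1e-6 * max(abs(s[i]), 1.0)
        up = s.copy()
        dn = s.copy()
        up[i] = min(s[i] + h, caps[i])
        dn[i] = max(s[i] - h, 0.0)
        fu = pathway_rhs(0.0, up, p, drivers)
        fd = pathway_rhs(0.0, dn, p, drivers)
        J[:, i] = (fu - fd) / (up[i] - dn[i])
    return J


@dataclass
class StabilityReport:
    """Linear stability of one steady state."""

    state: np.ndarray
    eigenvalues: np.ndarray
    classification: str            # "stable node" | "stable focus" | "unstable focus" | "saddle"
    residual: float

    @property
    def stable(self) -> bool:
        return self.classification.startswith("stable")


def linear_stability(
    p: PathwayParameters,
    s: np.ndarray,
    drivers: DriverSignals | None = None,
    residual_tol: float = 1e-6,
    eig_tol: float = 1e-9,
) -> StabilityReport:
    """Eigenvalue classification of a steady state of the pathway ODEs."""
    if drivers is None:
        drivers = DriverSignals.basal(p)
    resid = float(np.max(np.abs(pathway_rhs(0.0, s, p, drivers))))
    if resid > residual_tol:
        raise ParameterError(
            f"linear_stability requires a steady state; residual {resid:.3e} nM/h"
        )
    eig = np.linalg.eigvals(jacobian(p, s, drivers))
    re = eig.real
    has_complex = np.any(np.abs(eig.imag) > eig_tol)
    if np.all(re < -eig_tol):
        cls = "stable focus" if has_complex else "stable node"
    elif np.any(re > eig_tol) and np.any(re < -eig_tol) and not has_complex:
        cls = "saddle"
    elif np.any(re > eig_tol):
        cls = "unstable focus" if has_complex else "saddle"
    else:
        cls = "marginal"
    return StabilityReport(state=np.asarray(s), eigenvalues=eig, classification=cls, residual=resid)


def label_steady_states(states: list[np.ndarray]) -> dict[str, np.ndarray]:
    """P1/P2/P3... labels by ascending CBF3 mRNA level."""
    return {f"P{i+1}": s for i, s in enumerate(states)}


# ---------------------------------------------------------------------------
# limit-cycle detection
# ---------------------------------------------------------------------------

#: Pathway variables upstream of the CBF3-ZAT12 transcriptional loop.
UPSTREAM_VARIABLES = (
    "CRLK1a", "CRPK1a", "MPK6P", "MPK4P", "ICE1", "ICE1P", "MYB15P", "HOS1n", "TTFP",
)


@dataclass
class LimitCycleReport:
    """Outcome of limit-cycle detection on the unstressed pathway."""

    oscillating: bool
    status: str                    # "oscillating" | "steady" | "transient"
    period: float | None
    amplitudes: dict[str, float]
    period_cv: float | None = None

    @property
    def participating(self) -> list[str]:
        if not self.oscillating:
            return []
        floor = 1e-3 * max(self.amplitudes.values())
        return [k for k, v in self.amplitudes.items() if v > floor]


def detect_limit_cycle(
    p: PathwayParameters,
    t_transient: float = 400.0,
    t_measure: float = 400.0,
    drivers: DriverSignals | None = None,
    y0: np.ndarray | None = None,
    cv_tol: float = 0.02,
) -> LimitCycleReport:
    """Detect sustained oscillations by peak-interval statistics.

    The system is integrated for ``t_transient`` hours to shed transients and
    then for ``t_measure`` hours; successive maxima of CBF3 mRNA are located.
    The trajectory is classified oscillating when at least 3 maxima occur,
    their inter-peak intervals have a coefficient of variation below 2% and
    the peak-to-trough amplitude exceeds ``1e-3`` of the mean level.  A
    drifting-amplitude outcome is reported as status "transient" rather than
    an error.
    """
    from scipy.integrate import solve_ivp
    from scipy.signal import find_peaks

    if drivers is None:
        drivers = DriverSignals.basal(p)
    if y0 is None:
        y0 = np.zeros(N_STATES)
        y0[STATE_NAMES.index("ICE1")] = 1.0
        y0[STATE_NAMES.index("M_CBF3")] = 1.0

    t_end = t_transient + t_measure
    dt = 0.05
    sol = solve_ivp(
        lambda t, y: pathway_rhs(t, y, p, drivers),
        (0.0, t_end),
        y0,
        method="LSODA",
        rtol=1e-8,
        atol=1e-10,
        t_eval=np.arange(0.0, t_end, dt),
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"integration failed: {sol.message}")
    tail = sol.t >= t_transient
    tt = sol.t[tail]
    amplitudes = {
        name: float(np.ptp(sol.y[i][tail])) for i, name in enumerate(STATE_NAMES)
    }
    m = sol.y[STATE_NAMES.index("M_CBF3")][tail]
    amp = float(np.ptp(m))
    mean = float(np.mean(m))
    if amp <= 1e-3 * max(mean, 1e-12):
        return LimitCycleReport(False, "steady", None, amplitudes)
    peaks, _ = find_peaks(m, prominence=0.3 * amp)
    if peaks.size < 3:
        return LimitCycleReport(False, "transient", None, amplitudes)
    intervals = np.diff(tt[peaks])
    period = float(np.mean(intervals))
    cv = float(np.std(intervals) / period)
    heights = m[peaks]
    drifting = np.ptp(heights) > 0.05 * np.mean(heights)
    if cv >= cv_tol or drifting:
        return LimitCycleReport(False, "transient", period, amplitudes, period_cv=cv)
    return LimitCycleReport(True, "oscillating", period, amplitudes, period_cv=cv)


# ---------------------------------------------------------------------------
# peak metrics
# ---------------------------------------------------------------------------

@dataclass
class PeakMetrics:
    """Shape of a transient response peak relative to its pre-stress baseline."""

    peak_time: float               # h after pulse onset
    fold_change: float             # peak / baseline
    fwhm: float                    # h, at half of the baseline-subtracted peak
    auc: float                     # nM h above baseline
    baseline: float
    peak_value: float
    has_peak: bool = True


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def peak_metrics(
    result: SimulationResult,
    variable: str = "M_CBF3",
    pulse_onset: float = 2.0,
) -> PeakMetrics:
    """Peak time, fold change, FWHM and AUC of a trajectory variable.

    The baseline is the value at pulse onset.  FWHM is the width of the
    baseline-subtracted peak at half its height, with linear interpolation
    between grid points; plateaus at the maximum resolve to the earliest
    time.  A trajectory that never rises 1% above baseline is reported as
    "no peak".
    """
    t = result.times
    v = result[variable]
    i0 = int(np.searchsorted(t, pulse_onset))
    if i0 >= t.size - 2:
        raise ParameterError("trajectory must extend beyond the pulse onset")
    baseline = float(v[i0])
    seg_t = t[i0:]
    seg_v = v[i0:]
    ipk = int(np.argmax(seg_v))       # argmax returns the earliest maximum
    peak = float(seg_v[ipk])
    if peak <= baseline * 1.01 + 1e-12:
        return PeakMetrics(
            peak_time=math.nan, fold_change=1.0, fwhm=math.nan, auc=0.0,
            baseline=baseline, peak_value=peak, has_peak=False,
        )
    half = baseline + 0.5 * (peak - baseline)
    # left crossing
    il = ipk
    while il > 0 and seg_v[il - 1] >= half:
        il -= 1
    t_left = (
        _interp_crossing(seg_t[il - 1], seg_t[il], seg_v[il - 1], seg_v[il], half)
        if il > 0
        else seg_t[0]
    )
    ir = ipk
    while ir < seg_v.size - 1 and seg_v[ir + 1] >= half:
        ir += 1
    t_right = (
        _interp_crossing(seg_t[ir], seg_t[ir + 1], seg_v[ir], seg_v[ir + 1], half)
        if ir < seg_v.size - 1
        else seg_t[-1]
    )
    auc = float(np.trapezoid(np.clip(seg_v - baseline, 0.0, None), seg_t))
    return PeakMetrics(
        peak_time=float(seg_t[ipk] - pulse_onset),
        fold_change=peak / baseline if baseline > 0 else math.inf,
        fwhm=float(t_right - t_left),
        auc=auc,
        baseline=baseline,
        peak_value=peak,
    )


# ---------------------------------------------------------------------------
# desensitization
# ---------------------------------------------------------------------------

def desensitization_profile(
    result: SimulationResult,
    pulse_times: list[float] | None = None,
    variable: str = "M_CBF3",
) -> dict:
    """Per-cycle peak amplitudes of a repetitively stimulated run.

    Returns the list of per-cycle maxima of ``variable`` between consecutive
    pulses (the last window extends to the end of the trajectory) and the
    amplitude ratio of the last peak to the first.
    """
    if pulse_times is None:
        pulse_times = [pu.t_p for pu in result.protocol.pulses]
    pulse_times = sorted(pulse_times)
    if len(pulse_times) < 1:
        raise ParameterError("desensitization_profile needs at least one pulse")
    dt = float(np.median(np.diff(result.times)))
    if any(b - a < 10 * dt for a, b in zip(pulse_times[:-1], pulse_times[1:])):
        raise ParameterError("pulse windows overlap (separation < 10 output steps)")
    t = result.times
    v = result[variable]
    edges = pulse_times + [t[-1] + dt]
    peaks = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (t >= a) & (t < b)
        peaks.append(float(v[sel].max()))
    return {
        "peaks": peaks,
        "ratio_last_to_first": peaks[-1] / peaks[0] if peaks[0] > 0 else math.nan,
    }


# ---------------------------------------------------------------------------
# circadian phase-response scan
# ---------------------------------------------------------------------------

def phase_response_scan(
    p: PathwayParameters,
    clock: ClockParams | None = None,
    pulse: cs.CalciumPulse | None = None,
    phases: np.ndarray | list[float] | None = None,
    entrain: float = 72.0,
    output_dt: float = 0.01,
) -> dict:
    """Maximum CBF3 mRNA response vs. the Zeitgeber time of the cold pulse.

    For each phase the clock-gated model is entrained for ``entrain`` hours
    and an identical Ca2+ pulse is applied at that ZT; the response is the
    baseline-subtracted maximum of CBF3 mRNA after the pulse.  The report
    includes the max/min response ratio and the permissive window (phases
    with at least 80% of the maximal response).
    """
    if clock is None:
        clock = ClockParams()
    if phases is None:
        phases = np.arange(0.0, 24.0, 1.0)
    phases = np.asarray(phases, dtype=float)
    if np.any((phases < 0) | (phases >= 24.0)):
        raise ParameterError("phases must lie in [0, 24)")
    responses = {}
    for zt in phases:
        proto = make_circadian_shock(float(zt), clock, pulse=pulse, entrain=entrain)
        res = run_simulation(p, proto, output_dt=output_dt)
        t_p = proto.pulses[0].t_p
        i0 = int(np.searchsorted(res.times, t_p))
        m = res["M_CBF3"]
        responses[float(zt)] = float(m[i0:].max() - m[i0])
    vals = np.array(list(responses.values()))
    zts = np.array(list(responses.keys()))
    permissive = zts[vals >= 0.8 * vals.max()]
    return {
        "responses": responses,
        "max_over_min": float(vals.max() / vals.min()) if vals.min() > 0 else math.inf,
        "best_phase": float(zts[int(np.argmax(vals))]),
        "worst_phase": float(zts[int(np.argmin(vals))]),
        "permissive_window": [float(z) for z in permissive],
    }


# ---------------------------------------------------------------------------
# sensitivity scan
# ---------------------------------------------------------------------------

def sensitivity_scan(
    p: PathwayParameters,
    param_name: str,
    grid: np.ndarray | list[float],
    windows: dict | None = None,
    output_dt: float = 0.01,
) -> dict:
    """One-at-a-time parameter scan against the response calibration windows.

    For each grid value the wild-type single-shock protocol is run and the
    CBF3 mRNA peak metrics are checked against the three windows (peak time,
    fold change, FWHM).  Returns per-point pass/fail records and the maximal
    passing sub-intervals of the grid.
    """
    if windows is None:
        windows = {"peak_time": (1.0, 6.0), "fold_change": (20.0, 500.0), "fwhm": (3.0, 6.0)}
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ParameterError("grid values must be > 0")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("grid must be sorted ascending")
    records = []
    for val in grid:
        rec = {"value": float(val), "ok": False, "error": None, "metrics": None}
        try:
            pv = p.with_overrides({param_name: float(val)})
            res = run_simulation(pv, make_cold_shock(t_p=2.0, t_span=40.0), output_dt=output_dt)
            m = peak_metrics(res, "M_CBF3", 2.0)
            rec["metrics"] = m
            rec["ok"] = bool(
                m.has_peak
                and windows["peak_time"][0] <= m.peak_time <= windows["peak_time"][1]
                and windows["fold_change"][0] <= m.fold_change <= windows["fold_change"][1]
                and windows["fwhm"][0] <= m.fwhm <= windows["fwhm"][1]
            )
        except Exception as exc:  # per-point failures are recorded, not raised
            rec["error"] = str(exc)
        records.append(rec)
    intervals = []
    start = None
    for i, rec in enumerate(records):
        if rec["ok"] and start is None:
            start = grid[i]
        if not rec["ok"] and start is not None:
            intervals.append((float(start), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(start), float(grid[-1])))
    return {"param": param_name, "records": records, "admissible_intervals": intervals}


# ---------------------------------------------------------------------------
# stability diagram
# ---------------------------------------------------------------------------

def stability_diagram(
    p: PathwayParameters,
    p1: tuple[str, np.ndarray | list[float]],
    p2: tuple[str, np.ndarray | list[float]],
    n_starts: int = 40,
    seed: int = 1234,
    t_transient: float = 250.0,
    t_measure: float = 250.0,
) -> "pd.DataFrame":
    """Two-parameter classification grid of the unstressed pathway.

    For each cell the steady states are located (multi-start root finding),
    their stability is classified, and sustained oscillations are probed with
    :func:`detect_limit_cycle`.  Returns a tidy table with columns
    ``p1, p2, n_states, n_stable, oscillating, period``; per-cell failures
    are recorded in an ``error`` column and do not stop the scan.
    """
    import pandas as pd

    name1, grid1 = p1
    name2, grid2 = p2
    rows = []
    for v1 in np.asarray(grid1, dtype=float):
        for v2 in np.asarray(grid2, dtype=float):
            row = {name1: v1, name2: v2, "n_states": 0, "n_stable": 0,
                   "oscillating": False, "period": np.nan, "error": ""}
            try:
                pv = p.with_overrides({name1: float(v1), name2: float(v2)})
                states = find_steady_states(pv, n_starts=n_starts, seed=seed)
                row["n_states"] = len(states)
                row["n_stable"] = sum(
                    linear_stability(pv, s).stable for s in states
                )
                lc = detect_limit_cycle(pv, t_transient=t_transient, t_measure=t_measure)
                row["oscillating"] = lc.oscillating
                if lc.oscillating:
                    row["period"] = lc.period
            except Exception as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)
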