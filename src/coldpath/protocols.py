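"""Driver schedules and simulation runner for in-silico cold-stress experiments.

A :class:`Protocol` bundles the three external drivers of the pathway —
Ca2+ signal(s), the cold/warm temperature schedule (which switches the CBF3
mRNA degradation rate), and an optional circadian gate — over a simulation
span.  Ready-made constructors cover the canonical experiments: a single cold
shock, a shock eliciting a train of Ca2+ spikes, repetitive warm-cold cycles
with identical pulses at each cold-phase onset, a circadian-gated shock, and
the unstressed control.

Mutants and overexpression lines are represented purely as parameter
overrides (:class:`MutantSpec`); the shipped registry contains the four lines
with literature-anchored values (ice1, HOS1-OX, myb15, ZAT12-OX) plus ICE1-OX.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import calcium_signals as cs
from .model_core import (
    DEFAULT_RTOL,
    DEFAULT_ATOL,
    DriverSignals,
    ParameterError,
    PathwayParameters,
    STATE_NAMES,
    initial_state,
    pathway_rhs,
)

__all__ = [
    "ClockParams",
    "clock_gate",
    "MutantSpec",
    "MUTANTS",
    "apply_mutant",
    "Protocol",
    "make_unstressed",
    "make_cold_shock",
    "make_spike_train_shock",
    "make_warm_cold_cycles",
    "make_circadian_shock",
    "SimulationResult",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# circadian gate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockParams:
    """Phenomenological circadian clock signal gating CBF3 transcription.

    The clock variable is a sine of fixed 24-h period,
    ``C(t) = 0.5 * (1 + sin(2 pi (t - phase_offset) / 24))``, and the gate is
    the Michaelian read-out ``g = C_0 + (1 - C_0) * C / (K_c + C)`` which
    multiplies the maximum CBF3 transcription rate.  ``C_0`` sets the gate
    floor at the trough of the clock; ``phase_offset`` is calibrated once so
    that the basal (unstressed) CBF3 mRNA maximum falls at ZT8 (the default
    0.86 h realizes this with the default parameter set) and is then frozen.
    """

    period: float = 24.0
    phase_offset: float = 0.86
    K_c: float = 0.15
    C_0: float = 0.01

    def __post_init__(self) -> None:
        if self.period != 24.0:
            raise ParameterError("the clock period is fixed at 24 h")
        if self.K_c <= 0:
            raise ParameterError("K_c must be > 0")
        if not (0.0 < self.C_0 < 1.0):
            raise ParameterError("C_0 must lie in (0, 1)")


def clock_gate(t: float, clock: ClockParams) -> float:
    """Circadian multiplier of CBF3 transcription, in (0, 1]."""
    C = 0.5 * (1.0 + math.sin(2.0 * math.pi * (t - clock.phase_offset) / clock.period))
    return clock.C_0 + (1.0 - clock.C_0) * C / (clock.K_c + C)


# ---------------------------------------------------------------------------
# mutants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutantSpec:
    """Named set of parameter overrides representing a mutant line."""

    name: str
    overrides: dict[str, float] = field(default_factory=dict)


#: Shipped mutant lines.  Values for ice1, HOS1-OX, myb15 and ZAT12-OX are the
#: literature-anchored ones (ICE1 synthesis 0.18 -> 0.036 nM/h; HOS1 total 2 -> 10 nM;
#: MYB15 total 2 -> 0.2 nM; ZAT12 synthesis 2.2 -> 11 nM/h).  ICE1-OX scales
#: the ICE1 synthesis rate up 5-fold.
MUTANTS: dict[str, MutantSpec] = {
    "ice1": MutantSpec("ice1", {"v_s1": 0.036}),
    "HOS1-OX": MutantSpec("HOS1-OX", {"HOS1_t": 10.0}),
    "myb15": MutantSpec("myb15", {"MYB15_t": 0.2}),
    "ZAT12-OX": MutantSpec("ZAT12-OX", {"v_s3": 11.0}),
    "ICE1-OX": MutantSpec("ICE1-OX", {"v_s1": 0.9}),
}


def apply_mutant(p: PathwayParameters, m: MutantSpec) -> PathwayParameters:
    """Parameter set of mutant ``m`` on background ``p`` (validated)."""
    return p.with_overrides(m.overrides)


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

PROTOCOL_KINDS = (
    "unstressed",
    "single_shock",
    "spike_train",
    "warm_cold_cycles",
    "circadian_shock",
)


@dataclass
class Protocol:
    """Complete driver schedule for one simulation.

    ``pulses`` lists single Ca2+ pulses (identical shape in cycle protocols);
    ``trace`` optionally supplies an external or CICR-generated Ca2+ trace
    which then takes precedence over pulses.  ``schedule`` is an ordered,
    contiguous list of ``(start, end, phase)`` intervals with phase "cold" or
    "warm" controlling the CBF3 mRNA degradation rate; an empty schedule means
    the pathway reference (cold-phase) rate applies throughout.
    """

    kind: str
    t_span: float
    pulses: tuple[cs.CalciumPulse, ...] = ()
    trace: cs.CalciumTrace | None = None
    schedule: tuple[tuple[float, float, str], ...] = ()
    clock: ClockParams | None = None
    cam: cs.CaMParams = field(default_factory=cs.CaMParams)
    ca_basal: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in PROTOCOL_KINDS:
            raise ParameterError(f"unknown protocol kind {self.kind!r}")
        if self.t_span <= 0:
            raise ParameterError("t_span must be > 0")
        prev_end = None
        for start, end, phase in self.schedule:
            if phase not in ("cold", "warm"):
                raise ParameterError(f"unknown temperature phase {phase!r}")
            if end <= start:
                raise ParameterError("schedule intervals must have end > start")
            if prev_end is not None and not math.isclose(start, prev_end):
                raise ParameterError("schedule intervals must be contiguous")
            prev_end = end

    # -- drivers -----------------------------------------------------------
    def calcium_value(self, t: float) -> float:
        if self.trace is not None:
            return self.trace.value_at(t)
        ca = self.ca_basal
        for pulse in self.pulses:
            ca += max(cs.pulse_value(t, pulse) - pulse.Ca_basal, 0.0)
        return ca

    def v_d3_value(self, t: float, p: PathwayParameters) -> float:
        for start, end, phase in self.schedule:
            if start <= t < end:
                return p.v_d3_cold if phase == "cold" else p.v_d3_warm
        return p.v_d3_cold

    def gate_value(self, t: float) -> float:
        return 1.0 if self.clock is None else clock_gate(t, self.clock)

    def drivers(self, p: PathwayParameters) -> DriverSignals:
        disc = sorted(
            {pulse.t_p for pulse in self.pulses}
            | {s for s, _, _ in self.schedule}
            | {e for _, e, _ in self.schedule}
        )
        return DriverSignals(
            cam_fraction=lambda t: cs.cam_fraction(self.calcium_value(t), self.cam),
            gate=self.gate_value,
            v_d3_of_t=lambda t: self.v_d3_value(t, p),
            discontinuities=tuple(d for d in disc if 0.0 < d < self.t_span),
        )


def make_unstressed(
    t_span: float = 100.0,
    clock: ClockParams | None = None,
    ca_basal: float = 100.0,
) -> Protocol:
    """Control protocol: constant basal Ca2+, no temperature switching."""
    return Protocol(kind="unstressed", t_span=t_span, clock=clock, ca_basal=ca_basal)


def make_cold_shock(
    t_p: float = 2.0,
    pulse: cs.CalciumPulse | None = None,
    t_span: float = 50.0,
    clock: ClockParams | None = None,
) -> Protocol:
    """Single cold shock: basal equilibration on [0, t_p), pulse at ``t_p``.

    The temperature stays cold for the rest of the run, so the CBF3 mRNA
    degradation rate keeps its cold-phase value throughout (as in the
    single-shock simulations the protocol reproduces).
    """
    if t_p <= 0:
        raise ParameterError("t_p must be > 0")
    if pulse is None:
        pulse = cs.CalciumPulse(t_p=t_p)
    elif pulse.t_p != t_p:
        pulse = replace(pulse, t_p=t_p)
    return Protocol(
        kind="single_shock",
        t_span=t_span,
        pulses=(pulse,),
        clock=clock,
        ca_basal=pulse.Ca_basal,
    )


def make_spike_train_shock(
    env: cs.BetaEnvelope | None = None,
    cicr: cs.CICRParams | None = None,
    t_span: float = 50.0,
) -> Protocol:
    """Cold shock whose Ca2+ signature is a transient train of CICR spikes."""
    env = env or cs.BetaEnvelope()
    cicr = cicr or cs.CICRParams()
    trace = cs.simulate_calcium_train(env, cicr, t_span=min(t_span, env.t_p + 6.0))
    return Protocol(
        kind="spike_train",
        t_span=t_span,
        trace=trace,
        pulses=(cs.CalciumPulse(t_p=env.t_p, Ca_basal=trace.basal),),  # onset marker
        ca_basal=trace.basal,
    )


def make_warm_cold_cycles(
    cycle_period: float,
    n_cycles: int,
    pulse: cs.CalciumPulse | None = None,
    t_start: float = 2.0,
    tail: float = 0.0,
) -> Protocol:
    """Repetitive warm-cold cycles with identical pulses at cold-phase onsets.

    Each cycle is a cold half-phase followed by a warm half-phase of equal
    duration; the CBF3 mRNA degradation rate switches 10-fold between the two
    (0.55 nM/h cold, 5.5 nM/h warm with default parameters).  The canonical
    in-vivo periods are 3 h (90 min + 90 min), 6 h and 24 h (12 h + 12 h).
    """
    if cycle_period <= 0 or n_cycles < 1:
        raise ParameterError("cycle_period must be > 0 and n_cycles >= 1")
    base = pulse or cs.CalciumPulse()
    half = cycle_period / 2.0
    schedule: list[tuple[float, float, str]] = [(0.0, t_start, "warm")]
    pulses = []
    t = t_start
    for _ in range(n_cycles):
        schedule.append((t, t + half, "cold"))
        schedule.append((t + half, t + cycle_period, "warm"))
        pulses.append(replace(base, t_p=t))
        t += cycle_period
    t_span = t + tail
    if tail > 0:
        schedule.append((t, t_span, "warm"))
    return Protocol(
        kind="warm_cold_cycles",
        t_span=t_span,
        pulses=tuple(pulses),
        schedule=tuple(schedule),
        ca_basal=base.Ca_basal,
    )


def make_circadian_shock(
    zt: float,
    clock: ClockParams,
    pulse: cs.CalciumPulse | None = None,
    entrain: float = 72.0,
    t_span: float | None = None,
) -> Protocol:
    """Clock-gated cold shock applied at Zeitgeber time ``zt`` (h, in [0, 24)).

    The model is first entrained to the gate for ``entrain`` hours (a whole
    number of days keeps ZT aligned with simulation time modulo 24); the pulse
    then arrives at absolute time ``entrain + zt``.
    """
    if not (0.0 <= zt < 24.0):
        raise ParameterError("zt must lie in [0, 24)")
    base = pulse or cs.CalciumPulse()
    t_p = entrain + zt
    if t_span is None:
        t_span = t_p + 36.0
    return Protocol(
        kind="circadian_shock",
        t_span=t_span,
        pulses=(replace(base, t_p=t_p),),
        clock=clock,
        ca_basal=base.Ca_basal,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory on a regular output grid plus sampled drivers and metadata."""

    times: np.ndarray
    states: np.ndarray                 # shape (n_times, 14), canonical order
    ca: np.ndarray
    gate: np.ndarray
    v_d3: np.ndarray
    parameters: PathwayParameters
    protocol: Protocol
    solver: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times}
        for i, name in enumerate(STATE_NAMES):
            data[name] = self.states[:, i]
        data["ca_nM"] = self.ca
        data["gate"] = self.gate
        data["v_d3"] = self.v_d3
        return pd.DataFrame(data)


def run_simulation(
    p: PathwayParameters,
    proto: Protocol,
    output_dt: float = 0.01,
    y0: np.ndarray | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the pathway ODEs under protocol ``proto``.

    The integration restarts at every driver discontinuity (pulse onsets and
    temperature phase switches) so no discontinuity falls inside a solver
    step.  The initial state defaults to the pre-stress steady state for the
    protocol's basal drivers (gate value at t = 0 for clock-gated runs).
    """
    from scipy.integrate import solve_ivp

    d = proto.drivers(p)
    if y0 is None:
        cam0 = cs.cam_fraction(proto.ca_basal, proto.cam)
        basal = DriverSignals.basal(
            p,
            cam_basal=cam0,
            gate_value=proto.gate_value(0.0),
            v_d3=proto.v_d3_value(0.0, p),
        )
        y0 = initial_state(p, basal)

    t_grid = np.arange(0.0, proto.t_span + output_dt / 2.0, output_dt)
    edges = [0.0] + [t for t in d.discontinuities if 0.0 < t < proto.t_span] + [proto.t_span]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = t_grid[(t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.concatenate([[a], t_eval])
        if t_eval[-1] < b:
            t_eval = np.concatenate([t_eval, [b]])
        sol = solve_ivp(
            lambda t, x: pathway_rhs(t, x, p, d),
            (a, b),
            y,
            t_eval=t_eval,
            method=method,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            # one retry with tighter tolerances before giving up
            sol = solve_ivp(
                lambda t, x: pathway_rhs(t, x, p, d),
                (a, b),
                y,
                t_eval=t_eval,
                method="BDF",
                rtol=rtol * 1e-2,
                atol=atol * 1e-2,
            )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        keep = np.ones(sol.t.size, dtype=bool)
        if times_out and sol.t[0] <= times_out[-1][-1] + 1e-12:
            keep[0] = False
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep].T)

    times = np.concatenate(times_out)
    states = np.clip(np.concatenate(states_out, axis=0), 0.0, None)
    ca = np.array([proto.calcium_value(t) for t in times])
    gate = np.array([proto.gate_value(t) for t in times])
    v_d3 = np.array([proto.v_d3_value(t, p) for t in times])
    return SimulationResult(
        times=times,
        states=states,
        ca=ca,
        gate=gate,
        v_d3=v_d3,
        parameters=p,
        protocol=proto,
        solver={"method": method, "rtol": rtol, "atol": atol, "output_dt": output_dt},
    )
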