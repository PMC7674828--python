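"""Shared fixtures: heavy simulations are run once per session and reused."""

import numpy as np
import pytest

import coldpath as cp


@pytest.fixture(scope="session")
def params():
    return cp.DEFAULT_PARAMETERS


@pytest.fixture(scope="session")
def wt_shock(params):
    """Wild-type single cold shock (pulse at t = 2 h), 102 h trajectory."""
    proto = cp.make_cold_shock(t_p=2.0, t_span=102.0)
    return cp.run_simulation(params, proto, output_dt=0.01)


@pytest.fixture(scope="session")
def wt_metrics(wt_shock):
    return cp.peak_metrics(wt_shock, "M_CBF3", 2.0)


@pytest.fixture(scope="session")
def mutant_shocks(params):
    """Single-shock trajectories for every shipped mutant line."""
    out = {}
    for name, spec in cp.MUTANTS.items():
        p = cp.apply_mutant(params, spec)
        out[name] = cp.run_simulation(p, cp.make_cold_shock(t_p=2.0, t_span=40.0), output_dt=0.01)
    return out


@pytest.fixture(scope="session")
def cycle_runs(params):
    """Warm-cold cycle trajectories for the 3 h, 6 h and 24 h periods."""
    out = {}
    for period, n in ((3.0, 6), (6.0, 6), (24.0, 5)):
        proto = cp.make_warm_cold_cycles(period, n, t_start=2.0)
        out[period] = cp.run_simulation(params, proto, output_dt=0.01)
    return out


@pytest.fixture(scope="session")
def oscillating_params(params):
    return params.with_overrides(cp.OSCILLATION_OVERRIDES)


@pytest.fixture(scope="session")
def limit_cycle(oscillating_params):
    return cp.detect_limit_cycle(oscillating_params, t_transient=400.0, t_measure=400.0)


@pytest.fixture(scope="session")
def train_results(params):
    """Spike-train shock plus its AUC-matched single-pulse counterpart."""
    out = {}
    for label, a in (("short", 6.0), ("canonical", 4.0), ("long", 2.1)):
        env = cp.BetaEnvelope(beta_f=0.95 if a > 3 else 0.90, a=a)
        trace = cp.simulate_calcium_train(env)
        proto = cp.make_spike_train_shock(env)
        train = cp.run_simulation(params, proto, output_dt=0.01)
        auc = cp.trace_auc(trace)
        pulse = cp.matched_pulse(auc)
        matched = cp.run_simulation(
            params, cp.make_cold_shock(t_p=2.0, pulse=pulse), output_dt=0.01
        )
        out[label] = {
            "envelope": env,
            "trace": trace,
            "auc": auc,
            "train": train,
            "matched": matched,
            "n_spikes": cp.count_spikes(trace),
        }
    return out


@pytest.fixture(scope="session")
def phase_scan(params):
    """Clock-gated phase-response scan on a 2-h ZT grid."""
    return cp.phase_response_scan(params, phases=np.arange(0.0, 24.0, 2.0))
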