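"""Ca2+ pulse, CICR spike train, calmodulin activation and trace utilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import coldpath as cp
from coldpath.calcium_signals import SECONDS_PER_HOUR, _store_steady_state


# ---------------------------------------------------------------------------
# single pulse
# ---------------------------------------------------------------------------

def test_pulse_values():
    p = cp.CalciumPulse(t_p=2.0, A=600.0, k_Ca=30.0, Ca_basal=100.0)
    assert cp.pulse_value(1.9, p) == 100.0
    assert cp.pulse_value(2.0, p) == 700.0                       # jump at onset
    assert cp.pulse_value(2.0 + math.log(2.0) / 30.0, p) == pytest.approx(400.0)
    assert cp.pulse_value(10.0, p) == pytest.approx(100.0, abs=1e-6)


def test_pulse_validation():
    with pytest.raises(cp.ParameterError):
        cp.CalciumPulse(A=-1.0)
    with pytest.raises(cp.ParameterError):
        cp.CalciumPulse(Ca_basal=50.0)       # below the physiological range
    with pytest.raises(cp.ParameterError):
        cp.CalciumPulse(k_Ca=2.0)            # pulse would last > 0.5 h
    # default pulse is over (5% of amplitude) within 2-15 minutes
    assert 2.0 <= cp.CalciumPulse().duration_to_5pct * 60.0 <= 15.0


# ---------------------------------------------------------------------------
# calmodulin
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ca, expected",
    [(0.0, 0.0), (500.0, 0.5), (1000.0, 16.0 / 17.0)],
)
def test_cam_fraction_closed_forms(ca, expected):
    # default K_CaM = 500 nM, Hill coefficient fixed at 4
    assert cp.cam_fraction(ca) == pytest.approx(expected, rel=1e-12)


@given(ca=st.floats(0.0, 1e5))
@settings(max_examples=100, derandomize=True)
def test_cam_fraction_bounded(ca):
    assert 0.0 <= cp.cam_fraction(ca) <= 1.0


def test_cam_params_validation():
    with pytest.raises(cp.ParameterError):
        cp.CaMParams(n_CaM=2)                # the cooperativity is fixed at 4
    assert cp.cam_fraction(100.0) < 0.02     # quiet at basal Ca2+


# ---------------------------------------------------------------------------
# CICR oscillator
# ---------------------------------------------------------------------------

def test_cicr_reduced_linear_system():
    """With pumping, release and leak switched (effectively) off the cytosolic
    equation reduces to dZ/dt = (v0 - k_out Z) / s, zero at Z = v0 / k_out."""
    p = cp.CICRParams(V_M2=1e-30, V_M3=1e-30, k_f=1e-30)
    dZ, dY = cp.cicr_rhs(0.0, p.Z_basal, 0.0, 0.0, p)
    assert dZ == pytest.approx(0.0, abs=1e-9)
    dZ2, _ = cp.cicr_rhs(0.0, 2 * p.Z_basal, 0.0, 0.0, p)
    assert dZ2 == pytest.approx(-p.v0 / p.time_scale_factor, rel=1e-9)


def test_cicr_no_release_from_empty_store():
    p = cp.CICRParams()
    dZ_empty, dY_empty = cp.cicr_rhs(0.0, 300.0, 0.0, 0.5, p)
    # with Y = 0 the store terms vanish: dY/dt is pure pumping
    v2 = p.V_M2 * 300.0**2 / (p.K_2**2 + 300.0**2) / p.time_scale_factor
    assert dY_empty == pytest.approx(v2, rel=1e-12)


def test_cicr_rejects_beta_outside_unit_interval():
    with pytest.raises(cp.ParameterError):
        cp.cicr_rhs(0.0, 100.0, 100.0, 1.5, cp.CICRParams())


def test_cicr_interspike_interval_near_150_seconds():
    """Default oscillatory parameters at constant mid-range stimulus spike
    with an interspike interval of about 150 s."""
    from coldpath.calibration import measure_cicr_period

    period = measure_cicr_period(beta=0.5)
    assert period is not None
    assert 120.0 <= period <= 180.0


def test_cicr_basal_is_stable_and_at_100_nM():
    from scipy.integrate import solve_ivp

    p = cp.CICRParams()
    assert p.Z_basal == pytest.approx(100.0, rel=1e-3)
    y0 = [p.Z_basal * 1.1, _store_steady_state(p.Z_basal, p)]
    sol = solve_ivp(
        lambda t, y: cp.cicr_rhs(t, y[0], y[1], 0.0, p), (0.0, 3600.0), y0,
        method="LSODA", rtol=1e-9, atol=1e-9,
    )
    assert sol.y[0, -1] == pytest.approx(p.Z_basal, rel=1e-3)


# ---------------------------------------------------------------------------
# beta envelope and spike trains
# ---------------------------------------------------------------------------

def test_beta_envelope_values():
    env = cp.BetaEnvelope(beta_f=0.95, a=4.0, t_p=2.0)
    assert cp.beta_value(1.0, env) == 0.0
    assert cp.beta_value(2.0, env) == pytest.approx(0.95)
    assert cp.beta_value(2.0 + math.log(2.0) / 4.0, env) == pytest.approx(0.475)


def test_spike_count_grows_with_train_duration(train_results):
    """Slower envelope decay sustains the stimulus longer: more Ca2+ spikes.
    The canonical envelopes give a few spikes vs. a larger number."""
    n_short = train_results["short"]["n_spikes"]
    n_canon = train_results["canonical"]["n_spikes"]
    n_long = train_results["long"]["n_spikes"]
    assert n_short < n_canon < n_long
    assert 2 <= n_canon <= 12          # "a few" spikes
    assert n_long >= n_canon + 3       # "a larger number"


def test_train_terminates_before_span_end(train_results):
    tr = train_results["canonical"]["trace"]
    tail = tr.values[tr.times > tr.times[-1] - 0.5]
    assert np.all(np.abs(tail - tr.basal) < 0.05 * tr.basal)


def test_instant_envelope_collapse_gives_at_most_one_spike():
    env = cp.BetaEnvelope(beta_f=0.95, a=400.0, t_p=2.0)
    trace = cp.simulate_calcium_train(env)
    assert cp.count_spikes(trace) <= 1


def test_spike_count_matches_brute_force_reference():
    """Spike count agrees with a dt = 0.01 s fixed-step reference integration
    of the same two-variable oscillator."""
    env = cp.BetaEnvelope(beta_f=0.95, a=6.0, t_p=0.0)
    p = cp.CICRParams()
    trace = cp.count_spikes(cp.simulate_calcium_train(env, p, t_span=2.0), min_height=300.0)

    s = p.time_scale_factor
    dt = 0.01
    Z = p.Z_basal
    Y = _store_steady_state(Z, p)

    def rhs(ts, Z, Y):
        beta = 0.95 * math.exp(-6.0 * ts / SECONDS_PER_HOUR)
        v2 = p.V_M2 * Z**2 / (p.K_2**2 + Z**2)
        v3 = p.V_M3 * (Y**2 / (p.K_R**2 + Y**2)) * (Z**4 / (p.K_A**4 + Z**4))
        return (
            (p.v0 + p.v1 * beta - v2 + v3 + p.k_f * Y - p.k_out * Z) / s,
            (v2 - v3 - p.k_f * Y) / s,
        )

    # count local maxima above the spike threshold on the fine trajectory
    n_peaks = 0
    threshold = p.Z_basal + 300.0
    t = 0.0
    hist = [Z, Z]
    for _ in range(int(1.2 * SECONDS_PER_HOUR / dt)):
        dZ1, dY1 = rhs(t, Z, Y)
        dZ2, dY2 = rhs(t + dt / 2, Z + dt / 2 * dZ1, Y + dt / 2 * dY1)
        dZ3, dY3 = rhs(t + dt / 2, Z + dt / 2 * dZ2, Y + dt / 2 * dY2)
        dZ4, dY4 = rhs(t + dt, Z + dt * dZ3, Y + dt * dY3)
        Z += dt / 6 * (dZ1 + 2 * dZ2 + 2 * dZ3 + dZ4)
        Y += dt / 6 * (dY1 + 2 * dY2 + 2 * dY3 + dY4)
        t += dt
        if hist[0] < hist[1] >= Z and hist[1] > threshold:
            n_peaks += 1
        hist = [hist[1], Z]
    assert trace == n_peaks


# ---------------------------------------------------------------------------
# traces, AUC, matched pulses
# ---------------------------------------------------------------------------

def test_trace_auc_closed_forms():
    t = np.linspace(0.0, 10.0, 5001)
    flat = cp.CalciumTrace(times=t, values=np.full(t.size, 100.0), basal=100.0)
    assert cp.trace_auc(flat) == 0.0
    rect = np.full(t.size, 100.0)
    rect[(t >= 2.0) & (t < 4.0)] = 150.0     # height 50 nM, width 2 h
    assert cp.trace_auc(cp.CalciumTrace(times=t, values=rect, basal=100.0)) == pytest.approx(100.0, rel=0.01)
    # exponential pulse sampled from its onset: AUC = A / k
    tt = np.arange(0.5, 3.0, 1e-3)
    pulse = cp.CalciumPulse(t_p=0.5, A=200.0, k_Ca=20.0)
    vals = np.array([cp.pulse_value(x, pulse) for x in tt])
    assert cp.trace_auc(cp.CalciumTrace(times=tt, values=vals, basal=100.0)) == pytest.approx(10.0, rel=1e-3)


def test_trace_auc_requires_two_points():
    with pytest.raises(cp.ParameterError):
        cp.trace_auc(cp.CalciumTrace(times=[1.0], values=[100.0], basal=100.0))


def test_matched_pulse_amplitude_and_roundtrip():
    p = cp.matched_pulse(1.0, k_Ca=20.0)
    assert p.A == pytest.approx(20.0)
    t = np.arange(p.t_p, p.t_p + 6.0, 1e-3)
    vals = np.array([cp.pulse_value(x, p) for x in t])
    auc = cp.trace_auc(cp.CalciumTrace(times=t, values=vals, basal=p.Ca_basal))
    assert auc == pytest.approx(1.0, rel=5e-3)
    with pytest.raises(cp.ParameterError):
        cp.matched_pulse(-1.0)


def test_trace_csv_roundtrip(tmp_path):
    t = np.linspace(0.0, 1.0, 11)
    tr = cp.CalciumTrace(times=t, values=100.0 + 10.0 * t, basal=100.0)
    path = tmp_path / "trace.csv"
    tr.to_csv(path)
    back = cp.CalciumTrace.from_csv(path, basal=100.0)
    np.testing.assert_allclose(back.times, tr.times)
    np.testing.assert_allclose(back.values, tr.values)


def test_trace_validation():
    with pytest.raises(cp.ParameterError):
        cp.CalciumTrace(times=[0.0, 0.0, 1.0], values=[1.0, 1.0, 1.0], basal=1.0)
    with pytest.raises(cp.ParameterError):
        cp.CalciumTrace(times=[0.0, 1.0], values=[1.0, -1.0], basal=1.0)
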