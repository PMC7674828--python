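"""Protocol construction, mutants, the circadian gate and the runner contract."""

import json
import math

import numpy as np
import pytest

import coldpath as cp
from coldpath import io_cli


# ---------------------------------------------------------------------------
# circadian gate
# ---------------------------------------------------------------------------

def test_clock_gate_closed_forms():
    clock = cp.ClockParams(phase_offset=0.0, K_c=0.15, C_0=0.01)
    # clock trough (C = 0) at t = 18 h: gate at its floor C_0
    assert cp.clock_gate(18.0, clock) == pytest.approx(0.01, abs=1e-12)
    # clock crest (C = 1) at t = 6 h
    assert cp.clock_gate(6.0, clock) == pytest.approx(0.01 + 0.99 / 1.15, rel=1e-12)


def test_clock_gate_periodic_and_bounded():
    clock = cp.ClockParams()
    for t in np.linspace(0.0, 24.0, 49):
        g = cp.clock_gate(t, clock)
        assert clock.C_0 - 1e-12 <= g <= 1.0
        assert cp.clock_gate(t + 24.0, clock) == pytest.approx(g, rel=1e-12)


def test_clock_params_validation():
    with pytest.raises(cp.ParameterError):
        cp.ClockParams(period=12.0)
    with pytest.raises(cp.ParameterError):
        cp.ClockParams(C_0=0.0)


# ---------------------------------------------------------------------------
# mutants
# ---------------------------------------------------------------------------

def test_shipped_mutant_values(params):
    assert cp.apply_mutant(params, cp.MUTANTS["ice1"]).v_s1 == pytest.approx(0.036)
    hos = cp.apply_mutant(params, cp.MUTANTS["HOS1-OX"])
    assert hos.HOS1_t == pytest.approx(10.0)
    # all other parameters untouched
    diff = {
        k: (v, getattr(params, k))
        for k, v in hos.as_dict().items()
        if v != getattr(params, k)
    }
    assert set(diff) == {"HOS1_t"}
    assert cp.apply_mutant(params, cp.MUTANTS["myb15"]).MYB15_t == pytest.approx(0.2)
    assert cp.apply_mutant(params, cp.MUTANTS["ZAT12-OX"]).v_s3 == pytest.approx(11.0)


def test_apply_mutant_identity_and_validation(params):
    assert cp.apply_mutant(params, cp.MutantSpec("none", {})) == params
    with pytest.raises(cp.ParameterError, match="valid names"):
        cp.apply_mutant(params, cp.MutantSpec("bad", {"no_such": 1.0}))


# ---------------------------------------------------------------------------
# protocol construction
# ---------------------------------------------------------------------------

def test_cold_shock_timing():
    proto = cp.make_cold_shock(t_p=2.0)
    assert proto.calcium_value(1.99) == pytest.approx(100.0)
    assert proto.calcium_value(2.0) == pytest.approx(100.0 + proto.pulses[0].A)
    assert proto.drivers(cp.DEFAULT_PARAMETERS).discontinuities == (2.0,)
    with pytest.raises(cp.ParameterError):
        cp.make_cold_shock(t_p=-1.0)


@pytest.mark.parametrize(
    "period, half", [(3.0, 1.5), (6.0, 3.0), (24.0, 12.0)],
)
def test_warm_cold_cycle_schedule(period, half, params):
    proto = cp.make_warm_cold_cycles(period, 3, t_start=2.0)
    # pulses at each cold-phase start
    assert [pu.t_p for pu in proto.pulses] == [2.0, 2.0 + period, 2.0 + 2 * period]
    # degradation rate switches 10-fold between phases
    assert proto.v_d3_value(2.0 + half / 2, params) == params.v_d3_cold
    assert proto.v_d3_value(2.0 + half + 0.01, params) == params.v_d3_warm
    cold = sum(e - s for s, e, ph in proto.schedule if ph == "cold")
    assert cold == pytest.approx(3 * half)


def test_single_cycle_reduces_to_shock_plus_warm_phase(params):
    proto = cp.make_warm_cold_cycles(6.0, 1, t_start=2.0)
    assert len(proto.pulses) == 1
    phases = [ph for _, _, ph in proto.schedule]
    assert phases == ["warm", "cold", "warm"]


def test_near_zero_amplitude_pulse_behaves_as_unstressed(params):
    tiny = cp.CalciumPulse(t_p=2.0, A=1e-9)
    shock = cp.run_simulation(params, cp.make_cold_shock(t_p=2.0, pulse=tiny, t_span=20.0), output_dt=0.05)
    flat = cp.run_simulation(params, cp.make_unstressed(t_span=20.0), output_dt=0.05)
    scale = np.maximum(np.abs(flat.states), 1e-9)
    assert np.max(np.abs(shock.states - flat.states) / scale) < 1e-5


def test_response_is_time_translation_invariant(params):
    """The pathway is autonomous: shifting the pulse onset shifts the whole
    response without changing its shape."""
    r1 = cp.run_simulation(params, cp.make_cold_shock(t_p=2.0, t_span=22.0), output_dt=0.01)
    r2 = cp.run_simulation(params, cp.make_cold_shock(t_p=5.0, t_span=25.0), output_dt=0.01)
    i1 = np.searchsorted(r1.times, 2.0)
    i2 = np.searchsorted(r2.times, 5.0)
    n = min(r1.states.shape[0] - i1, r2.states.shape[0] - i2)
    a = r1.states[i1:i1 + n]
    b = r2.states[i2:i2 + n]
    assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-9)) < 1e-6


def test_output_grid_refinement_only_changes_interpolation(params):
    r1 = cp.run_simulation(params, cp.make_cold_shock(t_span=12.0), output_dt=0.02)
    r2 = cp.run_simulation(params, cp.make_cold_shock(t_span=12.0), output_dt=0.01)
    sel = np.searchsorted(r2.times, r1.times)
    sel = np.clip(sel, 0, r2.times.size - 1)
    scale = np.maximum(np.abs(r1.states), 1e-8)
    assert np.max(np.abs(r2.states[sel] - r1.states) / scale) < 1e-4


def test_protocol_schedule_validation():
    with pytest.raises(cp.ParameterError, match="contiguous"):
        cp.Protocol(kind="warm_cold_cycles", t_span=10.0,
                    schedule=((0.0, 2.0, "cold"), (3.0, 4.0, "warm")))
    with pytest.raises(cp.ParameterError):
        cp.Protocol(kind="nope", t_span=10.0)


# ---------------------------------------------------------------------------
# I/O and CLI
# ---------------------------------------------------------------------------

def test_parameter_file_roundtrip(tmp_path, params):
    path = tmp_path / "params.yaml"
    io_cli.save_parameters(params, path)
    again = io_cli.load_parameters(path)
    assert io_cli.parameters_hash(again) == io_cli.parameters_hash(params)
    # partial maps merge over the defaults
    (tmp_path / "partial.json").write_text(json.dumps({"v_s1": 0.036}))
    merged = io_cli.load_parameters(tmp_path / "partial.json")
    assert merged.v_s1 == 0.036 and merged.v_s2 == params.v_s2
    assert merged.v_d3_warm == pytest.approx(5.5)


def test_unknown_parameter_key_is_rejected(tmp_path):
    (tmp_path / "bad.json").write_text(json.dumps({"vd3": 1.0}))
    with pytest.raises(cp.ParameterError, match="v_d3_cold"):
        io_cli.load_parameters(tmp_path / "bad.json")


def test_metadata_hash_changes_iff_parameters_change(params):
    h0 = io_cli.parameters_hash(params)
    assert io_cli.parameters_hash(cp.PathwayParameters()) == h0
    assert io_cli.parameters_hash(params.with_overrides({"v_s2": 5.51})) != h0


def test_write_result_contract(tmp_path, params):
    res = cp.run_simulation(params, cp.make_unstressed(t_span=2.0), output_dt=0.1)
    out = tmp_path / "traj.csv"
    io_cli.write_result(res, out, seed=7)
    df = io_cli.read_result(out)
    assert list(df.columns) == ["time_h", *cp.STATE_NAMES, "ca_nM", "gate", "v_d3"]
    assert df.shape[1] == 1 + 14 + 3
    np.testing.assert_array_equal(df["time_h"].to_numpy(), res.times)
    np.testing.assert_array_equal(df["M_CBF3"].to_numpy(), res["M_CBF3"])
    meta = json.loads((tmp_path / "traj.csv.meta.json").read_text())
    assert meta["parameters_hash"] == io_cli.parameters_hash(params)
    assert meta["seed"] == 7


def test_cli_simulate_roundtrip(tmp_path):
    proto_file = tmp_path / "shock.json"
    proto_file.write_text(json.dumps({"kind": "single_shock", "t_p": 2.0, "t_span": 6.0}))
    out = tmp_path / "out.csv"
    with pytest.raises(SystemExit) as exc:
        io_cli.main(["simulate", "--protocol", str(proto_file), "--out", str(out), "--dt", "0.1"])
    assert exc.value.code in (0, None)
    assert out.exists() and out.with_suffix(".csv.meta.json").exists()


def test_cli_rejects_bad_protocol(tmp_path):
    proto_file = tmp_path / "bad.json"
    proto_file.write_text(json.dumps({"kind": "single_shock", "bogus_key": 1}))
    out = tmp_path / "out.csv"
    with pytest.raises(SystemExit) as exc:
        io_cli.main(["simulate", "--protocol", str(proto_file), "--out", str(out)])
    assert exc.value.code == io_cli.EXIT_VALIDATION


def test_protocol_file_with_mutant_and_clock(tmp_path, params):
    proto_file = tmp_path / "p.yaml"
    proto_file.write_text(
        "kind: single_shock\nt_p: 2.0\nt_span: 5.0\nmutant: ice1\nclock: true\n"
    )
    proto, p = io_cli.load_protocol(proto_file, params)
    assert p.v_s1 == pytest.approx(0.036)
    assert proto.clock is not None
    assert proto.gate_value(0.0) != 1.0
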