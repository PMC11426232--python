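"""Streaming controller, burst bookkeeping, protocol registry."""

import numpy as np
import pytest

import seizureloop as sl
from seizureloop.closed_loop import (ControllerConfig, _episode_bursts,
                                     check_registry, load_protocols)
from seizureloop.core import SEIZURE
from seizureloop.synthetic import GeneratorConfig


@pytest.fixture(scope="module")
def protocols():
    return load_protocols()


@pytest.fixture(scope="module")
def protocol(protocols):
    return protocols["row3"]  # 20 Hz PRF, 15 min, 0.9 MPa


def _run(recording, online_model, protocol, **cfg_kw):
    model, norm = online_model
    config = ControllerConfig(**cfg_kw)
    return sl.run_closed_loop(recording, model, config, protocol, norm=norm)


# ---------------------------------------------------------------- registry

def test_registry_has_seven_consistent_rows(protocols):
    assert len(protocols) == 7
    check_registry(protocols, tol_mw_cm2=0.1)
    assert {p.prf_hz for p in protocols.values()} == {1, 20, 1000}
    for p in protocols.values():
        assert p.fundamental_khz == 250
        assert (p.sd_s, p.isi_s, p.duty_pct) == (5, 5, 10)
        # 5 s on / 5 s off burst train: 50% on-time within an episode
        assert p.sd_s / (p.sd_s + p.isi_s) == 0.5


def test_ispta_squared_pressure_scaling():
    ref = (0.9, 328.7)
    assert sl.ispta_from_pressure(1.8, ref) == pytest.approx(1314.9, abs=0.101)
    assert sl.ispta_from_pressure(0.45, ref) == pytest.approx(82.2, abs=0.101)
    assert sl.ispta_from_pressure(0.9, ref) == 328.7
    with pytest.raises(ValueError):
        sl.ispta_from_pressure(-1.0, ref)


# ------------------------------------------------------------- controller

def test_quiet_recording_never_stimulates(online_model, protocol):
    rec = sl.generate_recording(GeneratorConfig(n_seizures=0, seed=8,
                                                duration_s=300.0))
    trace, decisions = _run(rec, online_model, protocol, mode="closed_loop")
    assert trace.trigger_events == []
    assert trace.burst_intervals == []
    assert all(d.label != SEIZURE for d in decisions)


def test_episode_burst_arithmetic(protocol):
    # 60 s episode at SD 5 / ISI 5: six bursts, 30 s total on-time
    bursts = _episode_bursts(100.0, 160.0, protocol)
    assert len(bursts) == 6
    assert sum(off - on for on, off in bursts) == pytest.approx(30.0)
    assert bursts[0] == (100.0, 105.0)
    assert bursts[-1] == (150.0, 155.0)
    # non-multiple duration: final burst truncated at episode end
    trunc = _episode_bursts(0.0, 13.0, protocol)
    assert trunc == [(0.0, 5.0), (10.0, 13.0)]


def test_detection_triggers_full_episode(online_model, protocol):
    cfg = GeneratorConfig(n_seizures=1, duration_s=400.0, seed=21)
    rec = sl.generate_recording(cfg)
    trace, decisions = _run(rec, online_model, protocol, mode="closed_loop")
    onset, offset = rec.annotations[0]
    assert trace.trigger_events, "the seizure event must be detected"
    t0, cause = trace.trigger_events[0]
    assert cause == "detector"
    # decisions are emitted at window end: trigger within two windows of onset
    assert onset < t0 <= onset + 2 * 3.0
    # first episode: six 5-s bursts within [t0, t0 + 60)
    first = [b for b in trace.burst_intervals if t0 <= b[0] < t0 + 60.0]
    assert len(first) == 6
    assert sum(off - on for on, off in first) == pytest.approx(30.0)
    assert all(b[0] >= t0 for b in trace.burst_intervals)


def test_sham_and_closed_loop_same_decisions(recording, online_model, protocol):
    """Stimulation does not feed back into the signal, so sham and
    closed-loop runs must produce identical decision logs."""
    trace_cl, dec_cl = _run(recording, online_model, protocol, mode="closed_loop")
    trace_sham, dec_sham = _run(recording, online_model, protocol, mode="sham")
    assert [(d.t0, d.label) for d in dec_cl] == [(d.t0, d.label) for d in dec_sham]
    assert trace_sham.trigger_events == []
    assert trace_sham.burst_intervals == []
    assert trace_cl.trigger_events  # the default recording has seizures


def test_causality_future_samples_irrelevant(recording, online_model, protocol):
    """Decisions for windows before time T are unchanged when every sample
    after T is corrupted."""
    _, base = _run(recording, online_model, protocol, mode="sham")
    T = 900.0
    corrupted = sl.Recording(samples=recording.samples.copy(), fs=recording.fs,
                             annotations=[])
    corrupted.samples[int(T * recording.fs):] = 1e6
    _, mangled = _run(corrupted, online_model, protocol, mode="sham")
    before = [(d.t0, d.label) for d in base if d.t_decision <= T]
    after = [(d.t0, d.label) for d in mangled if d.t_decision <= T]
    assert before == after


def test_fs_mismatch_rejected(online_model, protocol):
    model, norm = online_model
    rec = sl.Recording(samples=np.zeros(5000), fs=500.0)
    with pytest.raises(ValueError, match="mismatch"):
        sl.run_closed_loop(rec, model, ControllerConfig(), protocol, norm=norm)


def test_normalized_model_requires_norm(recording, online_model, protocol):
    model, _ = online_model
    with pytest.raises(ValueError, match="normalized"):
        sl.run_closed_loop(recording, model, ControllerConfig(), protocol)


# ----------------------------------------------------------- random mode

def test_random_schedule_contracts():
    assert sl.random_schedule(1800, 0, 3.0, seed=0).size == 0
    a = sl.random_schedule(1800, 10, 3.0, seed=5)
    b = sl.random_schedule(1800, 10, 3.0, seed=5)
    assert np.array_equal(a, b)
    assert np.all(a % 3.0 == 0) and np.all(a > 0) and np.all(a <= 1800)
    with pytest.raises(ValueError):
        sl.random_schedule(30, 100, 3.0, seed=0)
    with pytest.raises(ValueError):
        sl.random_schedule(100, 3, 3.0, seed=0, episode_s=60.0)


def test_random_schedule_matches_expected_dose():
    """Mean trigger count over many seeds sits within 3 standard errors of
    the requested dose (binomial expectation check)."""
    n_seeds, n_triggers = 1000, 10
    counts = [sl.random_schedule(1800, n_triggers, 3.0, seed=s).size
              for s in range(n_seeds)]
    p = n_triggers / 600
    se = np.sqrt(600 * p * (1 - p) / n_seeds)
    assert abs(np.mean(counts) - n_triggers) <= 3 * se


def test_random_mode_triggers_ignore_decisions(online_model, protocol):
    rec = sl.generate_recording(GeneratorConfig(n_seizures=0, seed=30,
                                                duration_s=600.0))
    trace, _ = _run(rec, online_model, protocol, mode="random",
                    random_n_triggers=3, random_seed=7)
    assert all(cause == "random" for _, cause in trace.trigger_events)
    # bursts only follow triggers
    if trace.trigger_events:
        first_trigger = trace.trigger_events[0][0]
        assert all(on >= first_trigger for on, _ in trace.burst_intervals)


def test_trace_csv_export(tmp_path, recording, online_model, protocol):
    trace, _ = _run(recording, online_model, protocol, mode="closed_loop")
    out = tmp_path / "trace.csv"
    trace.to_csv(out)
    import pandas as pd
    df = pd.read_csv(out)
    assert set(df.columns) == {"event_type", "t_on", "t_off"}
    assert (df.event_type == "burst").sum() == len(trace.burst_intervals)
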