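"""Closed-loop controller simulation and ultrasound protocol registry.

Streams a recording through the online pipeline — causal band-pass filter,
per-window feature extraction, threshold classification — and drives the
stimulation state machine. A seizure decision (emitted at the end of its
3 s window) opens a stimulation episode: a burst train of ``sd_s`` seconds
on / ``isi_s`` seconds off for at least ``stim_duration_s``; with
``retrigger`` enabled the episode keeps running while windows remain
seizure-classified and closes on the first non-seizure decision after the
minimum episode. The simulator records stimulation, it does not alter the
EEG — ultrasound physiology is out of scope — so sham and closed-loop runs
produce identical decision logs by construction.

The random comparator triggers every window tick with probability
``n_triggers / n_ticks``, matching the closed-loop dose in expectation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .core import SEIZURE, Recording
from .detector import Decision, ThresholdSet, classify
from .features import (THRESHOLD_FEATURES, NormalizationParams, coastline,
                       log_energy_entropy, std_dev)
from .preprocess import DEFAULT_BAND, DEFAULT_ORDER, design_bandpass

MODES = ("sham", "closed_loop", "random")


@dataclass(frozen=True)
class StimulationProtocol:
    """One ultrasound parameter set (burst timing + acoustic intensity)."""

    name: str
    fundamental_khz: float
    prf_hz: float
    duty_pct: float
    sd_s: float
    isi_s: float
    insonation_min: float
    pressure_mpa: float
    ispta_mw_cm2: float

    @property
    def burst_period_s(self) -> float:
        return self.sd_s + self.isi_s


def load_protocols(path: str | Path | None = None) -> dict[str, StimulationProtocol]:
    """Load the protocol registry (the packaged YAML by default)."""
    if path is None:
        ref = importlib.resources.files("seizureloop.data") / "protocols.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return {name: StimulationProtocol(name=name, **fields)
            for name, fields in raw.items()}


def ispta_from_pressure(
    p_new_mpa: float, reference: tuple[float, float] = (0.9, 328.7)
) -> float:
    """Scale spatial-peak temporal-average intensity by pressure squared.

    I_new = I_ref * (p_new / p_ref)^2, valid when all timing parameters are
    held fixed."""
    p_ref, i_ref = reference
    if p_new_mpa <= 0 or p_ref <= 0 or i_ref <= 0:
        raise ValueError("pressures and reference intensity must be positive")
    return i_ref * (p_new_mpa / p_ref) ** 2


def check_registry(protocols: dict[str, StimulationProtocol],
                   tol_mw_cm2: float = 0.1) -> None:
    """Verify squared-pressure Ispta consistency across every protocol pair
    that differs only in acoustic pressure (and therefore intensity)."""
    items = list(protocols.values())
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            same_timing = (
                a.fundamental_khz == b.fundamental_khz and a.prf_hz == b.prf_hz
                and a.duty_pct == b.duty_pct and a.sd_s == b.sd_s
                and a.isi_s == b.isi_s and a.insonation_min == b.insonation_min
            )
            if not same_timing or a.pressure_mpa == b.pressure_mpa:
                continue
            predicted = ispta_from_pressure(
                b.pressure_mpa, (a.pressure_mpa, a.ispta_mw_cm2))
            # small epsilon absorbs binary representation error at the tol edge
            if abs(predicted - b.ispta_mw_cm2) > tol_mw_cm2 + 1e-6:
                raise ValueError(
                    f"registry inconsistency {a.name}->{b.name}: predicted "
                    f"{predicted:.2f}, tabulated {b.ispta_mw_cm2}"
                )


@dataclass
class ControllerConfig:
    """Controller behaviour knobs.

    ``stim_duration_s`` is the minimum stimulation episode length; when it
    is not a multiple of the burst period the final burst is truncated at
    episode end. ``retrigger`` keeps the episode open while seizure
    decisions continue past the minimum. ``random_n_triggers`` sets the
    expected dose of the random comparator.
    """

    window_s: float = 3.0
    stim_duration_s: float = 60.0
    retrigger: bool = False
    mode: str = "closed_loop"
    band: tuple[float, float] = DEFAULT_BAND
    order: int = DEFAULT_ORDER
    random_n_triggers: int = 0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.stim_duration_s <= 0 or self.window_s <= 0:
            raise ValueError("window_s and stim_duration_s must be positive")


@dataclass(frozen=True)
class WindowDecision:
    """Per-window entry of the decision log (time of emission = window end)."""

    t0: float
    t_decision: float
    label: str
    rule_path: str
    features: dict[str, float]


@dataclass
class StimulationTrace:
    """Timeline of controller outputs for one run."""

    trigger_events: list[tuple[float, str]] = field(default_factory=list)
    burst_intervals: list[tuple[float, float]] = field(default_factory=list)
    protocol: str = ""

    def to_csv(self, path: str | Path) -> None:
        rows = [{"event_type": f"trigger:{cause}", "t_on": t, "t_off": t}
                for t, cause in self.trigger_events]
        rows += [{"event_type": "burst", "t_on": on, "t_off": off}
                 for on, off in self.burst_intervals]
        pd.DataFrame(rows, columns=["event_type", "t_on", "t_off"]).to_csv(
            path, index=False)


def random_schedule(
    duration_s: float,
    n_triggers: int,
    window_s: float = 3.0,
    seed: int = 0,
    episode_s: float | None = None,
) -> np.ndarray:
    """Dose-matched random trigger times on the window-tick grid.

    Every ``window_s`` tick triggers independently with probability
    ``n_triggers / n_ticks``, so the expected trigger count equals
    ``n_triggers``. Returns the trigger times (window ends), seeded."""
    if n_triggers < 0:
        raise ValueError("n_triggers must be non-negative")
    n_ticks = int(duration_s // window_s)
    if n_triggers > n_ticks:
        raise ValueError(f"{n_triggers} triggers infeasible in {n_ticks} ticks")
    if episode_s is not None and n_triggers * episode_s > duration_s:
        raise ValueError("requested dose exceeds the recording duration")
    if n_triggers == 0 or n_ticks == 0:
        return np.empty(0)
    p = n_triggers / n_ticks
    rng = np.random.default_rng(seed)
    hits = rng.random(n_ticks) < p
    return (np.nonzero(hits)[0] + 1) * window_s


def _episode_bursts(t_start: float, t_end: float,
                    protocol: StimulationProtocol) -> list[tuple[float, float]]:
    """sd_s on / isi_s off bursts from t_start, truncated at t_end."""
    bursts = []
    t = t_start
    while t < t_end - 1e-9:
        on_end = min(t + protocol.sd_s, t_end)
        bursts.append((t, on_end))
        t += protocol.burst_period_s
    return bursts


def run_closed_loop(
    recording: Recording,
    model: ThresholdSet,
    config: ControllerConfig,
    protocol: StimulationProtocol,
    norm: NormalizationParams | None = None,
) -> tuple[StimulationTrace, list[WindowDecision]]:
    """Stream a recording through the online pipeline.

    Windows are processed strictly in time order through a causal filter
    whose state persists across windows: the decision for window k uses only
    samples up to the window's end. ``norm`` must be supplied when the model
    was fitted on normalized features.

    Returns the stimulation trace and the full per-window decision log.
    """
    if model.fs is not None and model.fs != recording.fs:
        raise ValueError(
            f"sampling-rate mismatch: model fitted at {model.fs} Hz, "
            f"recording is {recording.fs} Hz"
        )
    if model.normalized and norm is None:
        raise ValueError("model was fitted on normalized features; supply norm")
    sos = design_bandpass(config.order, config.band, recording.fs)
    zi = signal.sosfilt_zi(sos) * (recording.samples[0] if recording.n_samples else 0.0)

    n_win = int(round(config.window_s * recording.fs))
    n_epochs = recording.n_samples // n_win

    random_triggers: set[float] = set()
    if config.mode == "random":
        times = random_schedule(recording.duration_s, config.random_n_triggers,
                                config.window_s, config.random_seed)
        random_triggers = {round(float(t), 9) for t in times}

    decisions: list[WindowDecision] = []
    trace = StimulationTrace(protocol=protocol.name)
    episode_start: float | None = None
    episode_min_end = 0.0
    episode_end: float | None = None

    for k in range(n_epochs):
        chunk = recording.samples[k * n_win:(k + 1) * n_win]
        filtered, zi = signal.sosfilt(sos, chunk, zi=zi)
        feats = {
            "cl": coastline(filtered),
            "std": std_dev(filtered),
            "e_log": log_energy_entropy(filtered),
        }
        if norm is not None:
            feats = {
                f: 0.0 if f in norm.degenerate else
                (feats[f] - norm.mins[norm.names.index(f)])
                / (norm.maxs[norm.names.index(f)] - norm.mins[norm.names.index(f)])
                for f in THRESHOLD_FEATURES
            }
        decision: Decision = classify(feats, model)
        t_dec = (k + 1) * config.window_s
        decisions.append(WindowDecision(
            t0=k * config.window_s, t_decision=t_dec,
            label=decision.label, rule_path=decision.rule_path,
            features=decision.features))

        in_episode = episode_start is not None and episode_end is None
        if config.mode == "closed_loop":
            if decision.label == SEIZURE:
                if not in_episode:
                    episode_start, episode_min_end = t_dec, t_dec + config.stim_duration_s
                    episode_end = None
                    trace.trigger_events.append((t_dec, "detector"))
                elif config.retrigger:
                    trace.trigger_events.append((t_dec, "detector"))
            elif in_episode and config.retrigger and t_dec >= episode_min_end:
                # first non-seizure decision after the minimum episode
                trace.burst_intervals.extend(
                    _episode_bursts(episode_start, t_dec, protocol))
                episode_start, episode_end = None, None
            if (episode_start is not None and episode_end is None
                    and not config.retrigger and t_dec >= episode_min_end):
                trace.burst_intervals.extend(
                    _episode_bursts(episode_start, episode_min_end, protocol))
                episode_start, episode_end = None, None
        elif config.mode == "random":
            if round(t_dec, 9) in random_triggers and not in_episode:
                episode_start, episode_min_end = t_dec, t_dec + config.stim_duration_s
                episode_end = None
                trace.trigger_events.append((t_dec, "random"))
            if (episode_start is not None and episode_end is None
                    and t_dec >= episode_min_end):
                trace.burst_intervals.extend(
                    _episode_bursts(episode_start, episode_min_end, protocol))
                episode_start, episode_end = None, None

    # close any episode still open at end of recording
    if episode_start is not None and episode_end is None:
        end = min(episode_min_end, recording.duration_s) if not config.retrigger \
            else min(max(episode_min_end, n_epochs * config.window_s),
                     recording.duration_s)
        trace.burst_intervals.extend(_episode_bursts(episode_start, end, protocol))

    trace.burst_intervals.sort()
    return trace, decisions
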