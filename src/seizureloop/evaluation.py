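"""Scoring: epoch-level confusion metrics and event-level seizure metrics.

Epoch-level scores are sensitivity Sen = TP/(TP+FN), specificity
Spe = TN/(TN+FP) and accuracy Acc = (TP+TN)/all, reported as percentages.
A metric whose denominator is zero is flagged undefined (``None``), never
silently reported as zero. Detector benchmarking averages these scores
over several independent subsample/split/fit/test cycles.

Event-level scoring compares a per-window decision log against annotated
seizure intervals: consecutive seizure-classified windows (with short
gaps debounced) merge into detected events, which are matched to
annotations by overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import SEIZURE, Epoch
from .preprocess import DatasetSplit


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true: Sequence[str], y_pred: Sequence[str]
                    ) -> "ConfusionCounts":
        if len(y_true) != len(y_pred):
            raise ValueError("label sequences differ in length")
        tp = sum(t == SEIZURE and p == SEIZURE for t, p in zip(y_true, y_pred))
        tn = sum(t != SEIZURE and p != SEIZURE for t, p in zip(y_true, y_pred))
        fp = sum(t != SEIZURE and p == SEIZURE for t, p in zip(y_true, y_pred))
        fn = sum(t == SEIZURE and p != SEIZURE for t, p in zip(y_true, y_pred))
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sen/Spe/Acc in percent; undefined metrics (zero denominator) are None."""
    sen = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    spe = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total > 0 else None
    return {"sen": sen, "spe": spe, "acc": acc}


def repeated_evaluation(
    dataset_factory: Callable[[int], DatasetSplit],
    decoder_factory: Callable[[DatasetSplit, int], Callable[[list[Epoch]], list[str]]],
    n_runs: int = 5,
    seed: int = 0,
) -> dict:
    """Average detector scores over independent subsample/split/fit/test runs.

    Run i uses the derived seed ``seed + i`` for both factories. The
    ``decoder_factory`` returns a callable mapping test epochs to predicted
    labels. Any run failure aborts with the failing seed in the message.

    Returns {"per_run": DataFrame, "mean": {sen, spe, acc}} where means skip
    undefined per-run values.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for i in range(n_runs):
        run_seed = seed + i
        try:
            split = dataset_factory(run_seed)
            predict = decoder_factory(split, run_seed)
            y_pred = predict(split.test)
            y_true = [e.label for e in split.test]
            counts = ConfusionCounts.from_labels(y_true, y_pred)
            rows.append({"run": i, "seed": run_seed,
                         **confusion_metrics(counts),
                         "tp": counts.tp, "tn": counts.tn,
                         "fp": counts.fp, "fn": counts.fn})
        except Exception as exc:
            raise RuntimeError(f"evaluation run with seed {run_seed} failed: {exc}"
                               ) from exc
    per_run = pd.DataFrame(rows)
    mean = {m: (float(per_run[m].dropna().mean())
                if per_run[m].notna().any() else None)
            for m in ("sen", "spe", "acc")}
    return {"per_run": per_run, "mean": mean}


@dataclass
class EventMetrics:
    """Event-level summary of detected seizures.

    ``single_durations_s`` are the detected-event durations; latency is the
    first seizure-decision emission time minus the annotated onset, averaged
    over detected events."""

    n_seizures: int
    total_duration_s: float
    single_durations_s: list[float] = field(default_factory=list)
    mean_latency_s: float | None = None
    n_missed: int = 0
    n_false_detections: int = 0


def _decision_runs(decisions, window_s: float, merge_gap_windows: int
                   ) -> list[tuple[float, float, float]]:
    """Merge seizure-classified windows into runs.

    Returns (start_s, end_s, first_decision_emission_s) per run; runs
    separated by <= merge_gap_windows non-seizure windows are joined."""
    seiz = sorted(d.t0 for d in decisions if d.label == SEIZURE)
    runs: list[list[float]] = []
    for t0 in seiz:
        if runs and t0 - runs[-1][1] <= (merge_gap_windows + 1) * window_s + 1e-9:
            runs[-1][1] = t0
        else:
            runs.append([t0, t0])
    return [(a, b + window_s, a + window_s) for a, b in runs]


def event_metrics(
    annotations: list[tuple[float, float]],
    decisions,
    window_s: float = 3.0,
    tolerance_s: float = 0.0,
    merge_gap_windows: int = 1,
) -> EventMetrics:
    """Score a per-window decision log against annotated seizure intervals.

    An annotation counts as detected when any merged seizure-decision run
    overlaps it (expanded by ``tolerance_s`` on both sides). Runs that
    overlap no annotation are false detections.
    """
    runs = _decision_runs(decisions, window_s, merge_gap_windows)
    matched_runs: set[int] = set()
    durations: list[float] = []
    latencies: list[float] = []
    n_missed = 0
    for onset, offset in annotations:
        lo, hi = onset - tolerance_s, offset + tolerance_s
        hits = [i for i, (a, b, _) in enumerate(runs) if a < hi and b > lo]
        if not hits:
            n_missed += 1
            continue
        matched_runs.update(hits)
        durations.append(sum(runs[i][1] - runs[i][0] for i in hits))
        first_emit = min(runs[i][2] for i in hits)
        latencies.append(first_emit - onset)
    n_false = len(runs) - len(matched_runs)
    return EventMetrics(
        n_seizures=len(durations),
        total_duration_s=float(sum(durations)),
        single_durations_s=durations,
        mean_latency_s=float(np.mean(latencies)) if latencies else None,
        n_missed=n_missed,
        n_false_detections=n_false,
    )
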