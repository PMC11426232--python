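"""Seizure decoders: the multi-level threshold model and comparators.

The multi-level threshold model is a two-tier rule over the three features
{CL, STD, Elog} of one analysis window. Stage-1 thresholds are the
per-feature minima over the training seizure epochs; stage-2 thresholds are
the per-feature means. A window is classified seizure when

* all three features strictly exceed their stage-1 thresholds, or
* at least two features strictly exceed their stage-2 thresholds.

Comparisons are strict (">"), so the training epoch that attains a
per-feature minimum fails rule path 1 on that feature; it is still caught
by path 2 whenever it exceeds two stage-2 thresholds.

The SVM comparator is an RBF-kernel support vector machine over all six
range-normalized features, with a small seeded hyperparameter grid search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .core import NON_SEIZURE, SEIZURE, Epoch
from .features import (FEATURE_NAMES, THRESHOLD_FEATURES, NormalizationParams,
                       apply_normalization, feature_table, fit_normalization)
from .preprocess import DatasetSplit

RULE_STAGE1 = "all-three-stage1"
RULE_STAGE2 = "two-of-three-stage2"
RULE_NONE = "none"


@dataclass
class ThresholdSet:
    """Stage-1 (min) and stage-2 (mean) per-feature thresholds.

    ``normalized`` records whether the thresholds live in range-normalized
    feature space; classification refuses features from the other space.
    """

    stage1: dict[str, float]
    stage2: dict[str, float]
    fitted_on: str = ""
    normalized: bool = True
    fs: float | None = None

    def __post_init__(self) -> None:
        for f in THRESHOLD_FEATURES:
            if f not in self.stage1 or f not in self.stage2:
                raise ValueError(f"thresholds must cover {THRESHOLD_FEATURES}")
            if self.stage1[f] > self.stage2[f] + 1e-12:
                raise ValueError(
                    f"stage1 > stage2 for {f}: a minimum cannot exceed the mean"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": "multi-level-threshold",
            "stage1": self.stage1,
            "stage2": self.stage2,
            "fitted_on": self.fitted_on,
            "normalized": self.normalized,
            "fs": self.fs,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        d = json.loads(Path(path).read_text())
        return cls(stage1=d["stage1"], stage2=d["stage2"],
                   fitted_on=d.get("fitted_on", ""),
                   normalized=d.get("normalized", True), fs=d.get("fs"))


@dataclass(frozen=True)
class Decision:
    """One classification outcome with the rule path that produced it."""

    label: str
    rule_path: str
    features: dict[str, float] = field(default_factory=dict)


def fit_thresholds(
    seizure_features: pd.DataFrame,
    normalized: bool = True,
    fitted_on: str = "",
    fs: float | None = None,
) -> ThresholdSet:
    """Fit stage-1 (per-feature minimum) and stage-2 (per-feature mean)
    thresholds from the training *seizure* epochs only.

    ``seizure_features`` must contain the columns cl, std, e_log; if a
    ``label`` column is present every row must be seizure-labeled.
    """
    if len(seizure_features) == 0:
        raise ValueError("fit_thresholds requires at least one seizure sample")
    if "label" in seizure_features.columns:
        bad = seizure_features["label"] != SEIZURE
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} non-seizure rows supplied; thresholds are "
                "fitted on seizure epochs only"
            )
    sub = seizure_features.loc[:, list(THRESHOLD_FEATURES)]
    return ThresholdSet(
        stage1={f: float(sub[f].min()) for f in THRESHOLD_FEATURES},
        stage2={f: float(sub[f].mean()) for f in THRESHOLD_FEATURES},
        fitted_on=fitted_on, normalized=normalized, fs=fs,
    )


def classify(
    features: Mapping[str, float],
    thresholds: ThresholdSet,
    features_normalized: bool | None = None,
) -> Decision:
    """Apply the two-tier rule to one window's {cl, std, e_log}.

    ``features_normalized``, when given, is checked against the space the
    thresholds were fitted in; a mismatch is an error, never a silent
    misclassification.
    """
    if features_normalized is not None and features_normalized != thresholds.normalized:
        raise ValueError(
            "feature space mismatch: thresholds fitted on "
            f"{'normalized' if thresholds.normalized else 'raw'} features but "
            f"{'normalized' if features_normalized else 'raw'} features supplied"
        )
    snap = {f: float(features[f]) for f in THRESHOLD_FEATURES}
    above1 = [snap[f] > thresholds.stage1[f] for f in THRESHOLD_FEATURES]
    above2 = [snap[f] > thresholds.stage2[f] for f in THRESHOLD_FEATURES]
    if all(above1):
        return Decision(SEIZURE, RULE_STAGE1, snap)
    if sum(above2) >= 2:
        return Decision(SEIZURE, RULE_STAGE2, snap)
    return Decision(NON_SEIZURE, RULE_NONE, snap)


def classify_table(table: pd.DataFrame, thresholds: ThresholdSet,
                   features_normalized: bool | None = None) -> list[Decision]:
    """Classify every row of a feature table."""
    return [classify(row, thresholds, features_normalized)
            for row in table.to_dict("records")]


class SvmDecoder:
    """RBF-kernel SVM over the six range-normalized features.

    Normalization is fitted on the training feature table and carried with
    the decoder, so streaming epochs are mapped through the same affine
    transform the model saw in training.
    """

    def __init__(self, svc: SVC, norm: NormalizationParams):
        self.svc = svc
        self.norm = norm

    def predict_table(self, table: pd.DataFrame) -> list[str]:
        normed = apply_normalization(table, self.norm)
        X = normed.loc[:, list(FEATURE_NAMES)].to_numpy()
        return list(self.svc.predict(X))

    def predict_epochs(self, epochs: Sequence[Epoch]) -> list[str]:
        return self.predict_table(feature_table(list(epochs)))


def train_svm(split: DatasetSplit, seed: int = 0) -> SvmDecoder:
    """Train the RBF SVM comparator on a dataset split.

    A small grid over the box constraint C and kernel scale gamma is
    optimized by 3-fold cross-validation on the training set (seeded).
    Raises if the training set contains a single class.
    """
    table = feature_table(split.train)
    labels = table["label"].to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("SVM training requires both classes in the training set")
    norm = fit_normalization(table)
    X = apply_normalization(table, norm).loc[:, list(FEATURE_NAMES)].to_numpy()
    grid = GridSearchCV(
        SVC(kernel="rbf", random_state=seed),
        {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1, 1.0]},
        cv=3,
    )
    grid.fit(X, labels)
    return SvmDecoder(svc=grid.best_estimator_, norm=norm)


def predict_svm(decoder: SvmDecoder, table: pd.DataFrame) -> list[str]:
    """Predict labels for a raw (un-normalized) feature table."""
    return decoder.predict_table(table)


class RecurrentBackendUnavailable(RuntimeError):
    """No sequence-model backend (torch/tensorflow) is installed."""


def train_recurrent_baseline(split: DatasetSplit, config: dict | None = None):
    """Optional recurrent (LSTM) comparator over raw epoch sequences.

    Default hyperparameters follow the reference configuration: one input
    per time step, 250 hidden units, two-way output, learning rate 0.001.
    The model requires a deep-learning backend; when neither torch nor
    tensorflow is importable this raises
    :class:`RecurrentBackendUnavailable` — a feature-flagged skip, never a
    silent failure.
    """
    for backend in ("torch", "tensorflow"):
        try:
            __import__(backend)
            break
        except ImportError:
            continue
    else:
        raise RecurrentBackendUnavailable(
            "the recurrent comparator needs torch or tensorflow; neither is "
            "installed. The threshold and SVM decoders are unaffected."
        )
    raise NotImplementedError(
        "recurrent baseline training is not implemented for the detected backend"
    )
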