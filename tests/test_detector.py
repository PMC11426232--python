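"""Multi-level threshold detector and SVM comparator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seizureloop as sl
from seizureloop.core import NON_SEIZURE, SEIZURE, Epoch
from seizureloop.detector import (RULE_NONE, RULE_STAGE1, RULE_STAGE2,
                                  RecurrentBackendUnavailable, ThresholdSet,
                                  train_recurrent_baseline)
from seizureloop.preprocess import DatasetSplit


def _thr(s1, s2):
    keys = ("cl", "std", "e_log")
    return ThresholdSet(stage1=dict(zip(keys, s1)), stage2=dict(zip(keys, s2)))


def test_fit_min_and_mean():
    table = pd.DataFrame({"cl": [3.0, 5.0, 7.0], "std": [1.0, 2.0, 3.0],
                          "e_log": [10.0, 20.0, 30.0]})
    t = sl.fit_thresholds(table)
    assert t.stage1 == {"cl": 3.0, "std": 1.0, "e_log": 10.0}
    assert t.stage2 == {"cl": 5.0, "std": 2.0, "e_log": 20.0}


def test_fit_single_sample_min_equals_mean():
    t = sl.fit_thresholds(pd.DataFrame({"cl": [4.0], "std": [2.0], "e_log": [9.0]}))
    assert t.stage1 == t.stage2


def test_fit_rejects_empty_and_mislabeled():
    with pytest.raises(ValueError):
        sl.fit_thresholds(pd.DataFrame({"cl": [], "std": [], "e_log": []}))
    bad = pd.DataFrame({"cl": [1.0], "std": [1.0], "e_log": [1.0],
                        "label": [NON_SEIZURE]})
    with pytest.raises(ValueError, match="non-seizure"):
        sl.fit_thresholds(bad)


def test_fit_on_synthetic_matches_brute_force(split, fitted_model):
    model, norm = fitted_model
    table = sl.apply_normalization(sl.feature_table(split.train), norm)
    seiz = table[table.label == SEIZURE]
    for f in ("cl", "std", "e_log"):
        assert model.stage1[f] == pytest.approx(min(seiz[f]), rel=1e-12)
        assert model.stage2[f] == pytest.approx(float(np.mean(seiz[f])), rel=1e-12)
        assert model.stage1[f] <= model.stage2[f]


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError, match="minimum cannot exceed"):
        _thr((5.0, 1.0, 1.0), (2.0, 2.0, 2.0))


@pytest.mark.parametrize("features, expected_label, expected_path", [
    ((1.5, 1.5, 1.5), SEIZURE, RULE_STAGE1),   # all three above stage 1
    ((0.5, 2.5, 2.5), SEIZURE, RULE_STAGE2),   # two above stage 2
    ((0.5, 1.5, 2.5), NON_SEIZURE, RULE_NONE),  # path 1 blocked, one above stage 2
    ((1.0, 2.5, 2.5), SEIZURE, RULE_STAGE2),   # at the stage-1 minimum: strict
                                               # '>' fails path 1, stage 2 catches
    ((1.0, 1.5, 1.5), NON_SEIZURE, RULE_NONE),  # at the minimum, below means
])
def test_two_tier_rule_paths(features, expected_label, expected_path):
    t = _thr((1.0, 1.0, 1.0), (2.0, 2.0, 2.0))
    d = sl.classify(dict(zip(("cl", "std", "e_log"), features)), t)
    assert (d.label, d.rule_path) == (expected_label, expected_path)


def test_classify_space_mismatch_raises():
    t = _thr((1.0, 1.0, 1.0), (2.0, 2.0, 2.0))  # normalized=True default
    with pytest.raises(ValueError, match="space mismatch"):
        sl.classify({"cl": 1, "std": 1, "e_log": 1}, t, features_normalized=False)


@settings(deadline=None, max_examples=60)
@given(st.lists(st.floats(0, 10), min_size=6, max_size=6),
       st.floats(0, 10), st.integers(0, 2))
def test_classify_monotone_in_each_feature(vals, bump, idx):
    """Increasing any feature never flips a seizure decision to non-seizure."""
    t = _thr((min(vals[:3]),) * 3, (max(vals[:3]),) * 3)
    feats = dict(zip(("cl", "std", "e_log"), vals[3:]))
    before = sl.classify(feats, t)
    key = ("cl", "std", "e_log")[idx]
    feats[key] += bump
    after = sl.classify(feats, t)
    if before.label == SEIZURE:
        assert after.label == SEIZURE


def test_min_attaining_training_epoch_rescued_by_stage2(split, fitted_model):
    """The training epoch that attains a per-feature minimum fails the strict
    stage-1 path on that feature; when it sits above both other stage-2
    means it is still caught via the two-of-three path."""
    model, norm = fitted_model
    table = sl.apply_normalization(sl.feature_table(split.train), norm)
    seiz = table[table.label == SEIZURE].reset_index(drop=True)
    for f in ("cl", "std", "e_log"):
        row = seiz.loc[seiz[f].idxmin()]
        d = sl.classify(row, model)
        assert d.rule_path != RULE_STAGE1  # strict '>' fails at the minimum
        others = [g for g in ("cl", "std", "e_log") if g != f]
        if all(row[g] > model.stage2[g] for g in others):
            assert d.label == SEIZURE and d.rule_path == RULE_STAGE2


def _cluster_split(seed=0):
    """Two well-separated Gaussian clusters as labeled epochs."""
    rng = np.random.default_rng(seed)
    epochs = []
    for label, mu in ((SEIZURE, 200.0), (NON_SEIZURE, 5.0)):
        for _ in range(40):
            x = rng.normal(loc=0.0, scale=mu, size=375)
            epochs.append(Epoch(x=x, fs=125.0, label=label))
    rng.shuffle(epochs)
    return DatasetSplit(train=epochs[:60], test=epochs[60:], ratio=0.75, seed=seed)


def test_svm_separable_clusters_perfect():
    split = _cluster_split()
    decoder = sl.train_svm(split, seed=0)
    preds = decoder.predict_epochs(split.test)
    assert preds == [e.label for e in split.test]


def test_svm_predicts_training_point_its_own_label():
    split = _cluster_split(seed=1)
    decoder = sl.train_svm(split, seed=0)
    assert decoder.predict_epochs(split.train[:5]) == [
        e.label for e in split.train[:5]]


def test_svm_single_class_rejected():
    rng = np.random.default_rng(0)
    epochs = [Epoch(rng.normal(size=375), 125.0, SEIZURE) for _ in range(10)]
    with pytest.raises(ValueError, match="both classes"):
        sl.train_svm(DatasetSplit(train=epochs, test=[], ratio=1.0, seed=0))


def test_svm_and_threshold_comparable_on_same_split(split, fitted_model):
    """Both decoders score within 5 accuracy points on the identical split."""
    model, norm = fitted_model
    test_table = sl.apply_normalization(sl.feature_table(split.test), norm)
    thr_pred = [d.label for d in sl.classify_table(test_table, model)]
    svm_pred = sl.train_svm(split, seed=0).predict_epochs(split.test)
    truth = [e.label for e in split.test]
    acc_thr = np.mean([p == t for p, t in zip(thr_pred, truth)])
    acc_svm = np.mean([p == t for p, t in zip(svm_pred, truth)])
    assert abs(acc_thr - acc_svm) <= 0.05


def test_threshold_model_json_roundtrip(tmp_path, fitted_model):
    model, _ = fitted_model
    path = tmp_path / "model.json"
    model.to_json(path)
    back = ThresholdSet.from_json(path)
    assert back.stage1 == model.stage1
    assert back.stage2 == model.stage2
    assert back.normalized == model.normalized
    assert back.fs == model.fs


def test_recurrent_baseline_flags_missing_backend():
    split = _cluster_split()
    with pytest.raises(RecurrentBackendUnavailable, match="torch or tensorflow"):
        train_recurrent_baseline(split)
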