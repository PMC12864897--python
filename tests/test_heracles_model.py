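"""Stacked model: sub-models, stacking, calibration, prediction, governance."""

import numpy as np
import pandas as pd
import pytest

from slhs._lstm import LSTMClassifier
from slhs.config import GeneratorConfig, RunConfig
from slhs.evaluation import pairwise_auroc
from slhs.heracles_model import (
    CVReport,
    _aggregate_stay,
    assemble_windows,
    calibrate_threshold,
    champion_challenger_gate,
    cross_validate,
    fit_heracles,
    predict_registry,
    predict_stay,
    train_stacker,
    train_submodels,
)
from slhs.registry_io import Registry
from slhs.synthetic_registry import generate_registry


def _fast_config(seed=1, folds=3):
    return RunConfig(seed=seed, cv_folds=folds, rf_n_estimators=40,
                     lstm_epochs=3, lstm_hidden=8)


@pytest.fixture(scope="module")
def trained():
    """Small end-to-end fit shared by the prediction tests."""
    reg = generate_registry(GeneratorConfig(seed=31, n_stays=150,
                                            sepsis_prevalence=0.2))
    cfg = _fast_config(seed=31)
    ds = assemble_windows(reg, cfg)
    bundle, stay_pred = fit_heracles(reg, cfg, dataset=ds)
    return reg, cfg, ds, bundle, stay_pred


# ---------------------------------------------------------------------------
# calibration


def brute_force_threshold(probs, is_cs, floor):
    """Largest candidate threshold with recall >= floor, by scanning."""
    candidates = sorted(set(probs), reverse=True)
    for tau in candidates:
        flagged = probs >= tau
        if flagged[is_cs].mean() >= floor:
            return tau
    raise AssertionError("floor unattainable")


def test_calibration_documented_example():
    # CS probabilities {0.9, 0.8, 0.2}: at floor 0.7 the threshold must
    # drop to 0.2 (recall 2/3 < 0.7 above it), giving recall 1.0
    probs = np.array([0.9, 0.8, 0.2, 0.5, 0.1])
    is_cs = np.array([True, True, True, False, False])
    res = calibrate_threshold(probs, is_cs, 0.7)
    assert res.threshold == pytest.approx(0.2)
    assert res.recall == 1.0


def test_calibration_floor_one_takes_min_cs_probability():
    probs = np.array([0.9, 0.4, 0.6])
    is_cs = np.array([True, True, True])
    res = calibrate_threshold(probs, is_cs, 1.0)
    assert res.threshold == pytest.approx(0.4)


def test_calibration_floor_zero_rejected():
    with pytest.raises(ValueError):
        calibrate_threshold(np.array([0.5]), np.array([True]), 0.0)


def test_calibration_requires_cs_stays():
    with pytest.raises(ValueError, match="no confirmed-sepsis"):
        calibrate_threshold(np.array([0.5]), np.array([False]), 0.7)


def test_calibration_matches_brute_force(rng):
    for _ in range(200):
        n = int(rng.integers(3, 40))
        probs = np.round(rng.random(n), 2)
        is_cs = rng.random(n) < 0.4
        if not is_cs.any():
            is_cs[0] = True
        floor = float(rng.choice([0.3, 0.5, 0.7, 0.9, 1.0]))
        res = calibrate_threshold(probs, is_cs, floor)
        assert res.recall >= floor
        assert res.threshold == pytest.approx(
            brute_force_threshold(probs, is_cs, floor)
        )


# ---------------------------------------------------------------------------
# sub-models and stacking


def _toy_windows(rng, n=400):
    """Half the windows separable by the feature model, half by the sequence."""
    y = np.where(rng.random(n) < 0.5, "CS", "NS")
    half = n // 2
    X_feat = rng.normal(0, 1, (n, 4))
    X_feat[:half, 0] = (y[:half] == "CS") * 2.0 + rng.normal(0, 0.1, half)
    X_seq = rng.normal(0, 1, (n, 8, 2))
    X_seq[half:, :, 0] = ((y[half:] == "CS") * 2.0)[:, None] + rng.normal(
        0, 0.1, (n - half, 8)
    )
    groups = np.arange(n) // 2  # two windows per synthetic patient
    return X_feat, X_seq, y, groups


def test_submodels_oof_triples_normalized_and_deterministic(rng):
    X_feat, X_seq, y, groups = _toy_windows(np.random.default_rng(0))
    cfg = _fast_config()
    rf1, lstm1, oof1 = train_submodels(X_feat, X_seq, y, groups, cfg, seed=5)
    _, _, oof2 = train_submodels(X_feat, X_seq, y, groups, cfg, seed=5)
    np.testing.assert_allclose(oof1[:, :3].sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(oof1[:, 3:].sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_array_equal(oof1, oof2)


def test_submodel_accuracy_on_separable_labels(rng):
    r = np.random.default_rng(1)
    n = 300
    X_feat = r.normal(0, 1, (n, 3))
    y = np.where(X_feat[:, 0] > 0, "CS", "NS")
    X_seq = r.normal(0, 1, (n, 6, 2))
    groups = np.arange(n)
    cfg = _fast_config()
    _, _, oof = train_submodels(X_feat, X_seq, y, groups, cfg, seed=2)
    pred = np.where(oof[:, 2] > oof[:, 0], "CS", "NS")  # RF triple: NS,PS,CS
    assert (pred == y).mean() > 0.95


def test_single_class_labels_rejected():
    cfg = _fast_config()
    X = np.zeros((10, 2))
    S = np.zeros((10, 4, 2))
    with pytest.raises(ValueError, match="single class"):
        train_submodels(X, S, np.array(["NS"] * 10), np.arange(10), cfg, 0)


def test_stacker_requires_six_columns(rng):
    cfg = _fast_config()
    with pytest.raises(ValueError, match="6 columns"):
        train_stacker(np.zeros((10, 5)), np.array(["NS", "CS"] * 5), cfg, 0)


def test_stacker_not_worse_than_best_single_model():
    r = np.random.default_rng(3)
    X_feat, X_seq, y, groups = _toy_windows(r, n=600)
    test_mask = groups % 3 == 0
    tr = ~test_mask
    cfg = _fast_config()
    rf, lstm, oof = train_submodels(
        X_feat[tr], X_seq[tr], y[tr], groups[tr], cfg, seed=4
    )
    stacker = train_stacker(oof, y[tr], cfg, seed=4)

    from slhs.heracles_model import _proba_3class

    p_rf = _proba_3class(rf, X_feat[test_mask])
    p_lstm = _proba_3class(lstm, X_seq[test_mask])
    p_stack = _proba_3class(stacker, np.hstack([p_rf, p_lstm]))
    t = y[test_mask]
    auc_rf = pairwise_auroc(t, p_rf[:, 2], ("CS",), ("NS",))
    auc_lstm = pairwise_auroc(t, p_lstm[:, 2], ("CS",), ("NS",))
    auc_stack = pairwise_auroc(t, p_stack[:, 2], ("CS",), ("NS",))
    assert auc_stack >= max(auc_rf, auc_lstm) - 0.02


def test_lstm_learns_simple_sequence_rule():
    r = np.random.default_rng(8)
    n = 400
    y = np.where(r.random(n) < 0.5, 1, 0)
    X = r.normal(0, 1, (n, 10, 3))
    X[:, :, 1] += y[:, None] * 1.5
    clf = LSTMClassifier(hidden=8, epochs=10, seed=0).fit(X[:300], y[:300])
    acc = (clf.predict(X[300:]) == y[300:]).mean()
    assert acc > 0.9


# ---------------------------------------------------------------------------
# stay aggregation and prediction


def test_aggregate_stay_max_rule(rng):
    for _ in range(100):
        W = int(rng.integers(1, 30))
        raw = rng.random((W, 3)) + 1e-6
        probs = raw / raw.sum(axis=1, keepdims=True)
        pred = _aggregate_stay("S", probs, threshold=0.5)
        assert pred.stay_cs_prob == pytest.approx(probs[:, 2].max())
        assert pred.flag == (probs[:, 2].max() >= 0.5)
        k = pred.argmax_window
        assert probs[k, 2] == probs[:, 2].max()


def test_aggregate_stay_tie_breaks_toward_severity():
    probs = np.array([[0.4, 0.4, 0.2]])
    pred = _aggregate_stay("S", probs, threshold=0.9)
    assert pred.label == "PS"  # NS ties PS at 0.4; severity wins


def test_aggregate_single_window_identity():
    probs = np.array([[0.1, 0.2, 0.7]])
    pred = _aggregate_stay("S", probs, threshold=0.5)
    assert pred.stay_cs_prob == pytest.approx(0.7)
    assert pred.label == "CS" and pred.flag


def test_unnormalized_triples_rejected():
    from slhs.heracles_model import StayPrediction

    with pytest.raises(ValueError, match="sum to 1"):
        StayPrediction("S", np.array([[0.5, 0.2, 0.2]]), 0.2, False, "NS")


def test_predict_stay_matches_registry_table(trained):
    reg, cfg, ds, bundle, stay_pred = trained
    table = predict_registry(bundle, ds).set_index("stay_id")
    for sid in list(ds.tracks)[:5]:
        pred = predict_stay(bundle, ds.tracks[sid])
        assert pred.stay_cs_prob == pytest.approx(table.loc[sid, "cs_prob"])
        assert pred.label == table.loc[sid, "label"]
        np.testing.assert_allclose(pred.window_probs.sum(axis=1), 1.0, atol=1e-6)


def test_fit_calibration_meets_floor(trained):
    reg, cfg, ds, bundle, stay_pred = trained
    truth_cs = np.array([ds.stay_truth[s] == "CS" for s in stay_pred["stay_id"]])
    flagged = stay_pred["flag"].to_numpy()
    assert flagged[truth_cs].mean() >= cfg.recall_floor
    assert 0.0 < bundle.threshold <= 1.0


def test_bundle_save_load_round_trip(trained, tmp_path):
    reg, cfg, ds, bundle, _ = trained
    bundle.save(tmp_path / "model")
    from slhs.heracles_model import ModelBundle

    again = ModelBundle.load(tmp_path / "model")
    sid = next(iter(ds.tracks))
    a = predict_stay(bundle, ds.tracks[sid])
    b = predict_stay(again, ds.tracks[sid])
    np.testing.assert_allclose(a.window_probs, b.window_probs)
    assert (tmp_path / "model" / "manifest.json").exists()


# ---------------------------------------------------------------------------
# cross-validation and governance


def test_cross_validate_partitions_patients():
    reg = generate_registry(GeneratorConfig(seed=77, n_stays=90,
                                            sepsis_prevalence=0.25))
    cfg = _fast_config(seed=77, folds=3)
    report = cross_validate(reg, cfg)
    assert len(report.folds) == 3
    seen = [p for fold in report.folds for p in fold["val_patients"]]
    assert len(seen) == len(set(seen))  # no patient in two validation folds
    assert set(seen) == set(reg.stays["patient_id"])
    n_total = sum(fold["counts"]["n"] for fold in report.folds)
    assert n_total == len(reg.stays)
    assert "f1_cs" in report.pooled


def test_gate_strict_improvement():
    champ = CVReport(pooled={"f1_cs": (0.68, 0.01)})
    chal = CVReport(pooled={"f1_cs": (0.70, 0.01)})
    assert champion_challenger_gate(chal, champ).deploy is True
    assert champion_challenger_gate(champ, chal).deploy is False


def test_gate_tie_keeps_champion():
    a = CVReport(pooled={"f1_cs": (0.68, 0.01)})
    b = CVReport(pooled={"f1_cs": (0.68, 0.02)})
    assert champion_challenger_gate(a, b).deploy is False


def test_gate_missing_metric_rejected():
    a = CVReport(pooled={"f1_cs": (0.68, 0.01)})
    with pytest.raises(KeyError):
        champion_challenger_gate(a, a, metric="auroc_missing")


def test_gate_no_champion_deploys():
    a = CVReport(pooled={"f1_cs": (0.1, 0.0)})
    d = champion_challenger_gate(a, None)
    assert d.deploy and d.champion_value is None
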