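"""Stacked sepsis classifier: training, calibration, prediction, governance.

The classifier scores every 6-hour window of a stay with a three-class
probability triple (NS, PS, CS) by stacking two heterogeneous sub-models:

* a random forest on rolling-window aggregate features;
* a recurrent (LSTM) net on right-aligned sequence tensors.

A second-stage random forest consumes the six sub-model class probabilities
(three per sub-model) and emits the final triples. Stay-level predictions
aggregate by the *highest* recorded confirmed-sepsis probability across the
stay's windows, and a decision threshold is calibrated on the training set
as the largest cut-off that keeps confirmed-sepsis recall at or above a
configured floor (default 0.7). Retrained models are deployed under a
champion-challenger rule: strict improvement on the selection metric.

The stacking layer is fitted on out-of-fold sub-model probabilities
(patient-grouped folds) to avoid leakage.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold

from ._lstm import LSTMClassifier
from .config import RunConfig
from .feature_engineering import (
    WindowTrack,
    build_sequences_matrix,
    build_tracks,
    rolling_features_matrix,
)
from .registry_io import Registry
from .sepsis_labeling import CoarseLabel, label_windows, stay_truth_label

__all__ = [
    "CLASSES",
    "WindowDataset",
    "assemble_windows",
    "train_submodels",
    "train_stacker",
    "calibrate_threshold",
    "CalibrationResult",
    "ModelBundle",
    "StayPrediction",
    "predict_stay",
    "predict_registry",
    "fit_heracles",
    "cross_validate",
    "CVReport",
    "champion_challenger_gate",
    "GateDecision",
    "subset_registry",
]

CLASSES = ("NS", "PS", "CS")
_CLASS_IDX = {c: i for i, c in enumerate(CLASSES)}


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class WindowDataset:
    """All windows of a registry with features, labels and grouping keys."""

    rows: pd.DataFrame                  # stay_id, k, label
    X_feat: np.ndarray                  # (N, F) float32
    groups: np.ndarray                  # patient_id per row
    tracks: dict[str, WindowTrack]
    fill_values: dict[str, float]
    stay_truth: dict[str, str]
    config: RunConfig

    @property
    def y(self) -> np.ndarray:
        return self.rows["label"].to_numpy()

    def sequences(self, row_idx: np.ndarray) -> np.ndarray:
        """Sequence tensors for the given row indices (built stay by stay)."""
        cfg = self.config
        sub = self.rows.iloc[row_idx]
        out = np.empty(
            (len(sub), cfg.lookback_windows, 2 * len(cfg.sequence_concepts)),
            dtype=np.float32,
        )
        pos = {idx: i for i, idx in enumerate(sub.index)}
        for sid, grp in sub.groupby("stay_id", sort=False):
            seqs = build_sequences_matrix(
                self.tracks[sid],
                sequence_concepts=list(cfg.sequence_concepts),
                lookback_windows=cfg.lookback_windows,
                fill_values=self.fill_values,
            )
            for idx, k in zip(grp.index, grp["k"]):
                out[pos[idx]] = seqs[k]
        return out


def population_fill_values(registry: Registry) -> dict[str, float]:
    """Per-concept population medians used to impute empty spans."""
    med = registry.observations.groupby("concept_id")["value"].median()
    return {str(k): float(v) for k, v in med.items()}


def assemble_windows(registry: Registry, config: RunConfig) -> WindowDataset:
    """Grid, labels and tree features for every window of every stay."""
    tracks = build_tracks(registry, config)
    fill_values = population_fill_values(registry)

    events_by_stay = dict(tuple(registry.events.groupby("stay_id", sort=False)))
    patient_of = dict(zip(registry.stays["stay_id"], registry.stays["patient_id"]))

    rows = []
    feats = []
    truth: dict[str, str] = {}
    for sid in registry.stays["stay_id"]:
        track = tracks[sid]
        ev = events_by_stay.get(sid)
        labels = label_windows(
            track.window_starts(),
            ev,
            window_hours=config.window_hours,
            lookback_days=config.lookback_days,
        )
        track.labels = labels
        truth[sid] = stay_truth_label(ev).value
        feats.append(
            rolling_features_matrix(
                track,
                lookback_windows=config.lookback_windows,
                feature_registry=config.feature_registry,
                fill_values=fill_values,
            ).astype(np.float32)
        )
        rows.append(
            pd.DataFrame(
                {"stay_id": sid, "k": np.arange(track.n_windows), "label": labels}
            )
        )
    rows_df = pd.concat(rows, ignore_index=True)
    X_feat = np.vstack(feats)
    groups = rows_df["stay_id"].map(patient_of).to_numpy()
    return WindowDataset(
        rows=rows_df,
        X_feat=X_feat,
        groups=groups,
        tracks=tracks,
        fill_values=fill_values,
        stay_truth=truth,
        config=config,
    )


def subsample_negatives(
    y: np.ndarray, ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Row indices keeping all PS/CS windows and ``ratio`` x as many NS."""
    pos = np.nonzero(y != "NS")[0]
    neg = np.nonzero(y == "NS")[0]
    n_keep = min(len(neg), int(np.ceil(ratio * max(len(pos), 1))))
    keep_neg = rng.choice(neg, size=n_keep, replace=False) if n_keep else neg[:0]
    return np.sort(np.concatenate([pos, keep_neg]))


# ---------------------------------------------------------------------------
# sub-models and stacker


def _proba_3class(model, X) -> np.ndarray:
    """predict_proba remapped onto the canonical (NS, PS, CS) column order."""
    raw = model.predict_proba(X)
    out = np.zeros((len(raw), 3))
    for j, cls in enumerate(model.classes_):
        out[:, _CLASS_IDX[str(cls)]] = raw[:, j]
    return out


def _new_rf(config: RunConfig, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.rf_n_estimators,
        max_depth=config.rf_max_depth,
        class_weight="balanced",
        random_state=seed,
        n_jobs=1,
    )


def _new_lstm(config: RunConfig, seed: int) -> LSTMClassifier:
    return LSTMClassifier(
        hidden=config.lstm_hidden,
        epochs=config.lstm_epochs,
        batch_size=config.lstm_batch,
        lr=config.lstm_lr,
        seed=seed,
    )


def train_submodels(
    X_feat: np.ndarray,
    X_seq: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: RunConfig,
    seed: int,
) -> tuple[RandomForestClassifier, LSTMClassifier, np.ndarray]:
    """Fit both sub-models; return them with out-of-fold probability triples.

    The out-of-fold matrix (N, 6) = [RF NS/PS/CS, LSTM NS/PS/CS] is produced
    by patient-grouped K-fold so the stacking layer never sees in-fold
    sub-model probabilities. Deterministic under a fixed seed.
    """
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty training data")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    n_folds = min(config.cv_folds, len(np.unique(groups)))
    if n_folds < 2:
        raise ValueError("need at least two patient groups for out-of-fold stacking")
    oof = np.zeros((len(y), 6))
    gkf = GroupKFold(n_splits=n_folds)
    for fold, (tr, va) in enumerate(gkf.split(X_feat, y, groups)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("a stacking fold lost all but one class")
        rf = _new_rf(config, seed + 101 + fold).fit(X_feat[tr], y[tr])
        oof[va, :3] = _proba_3class(rf, X_feat[va])
        lstm = _new_lstm(config, seed + 201 + fold).fit(X_seq[tr], y[tr])
        oof[va, 3:] = _proba_3class(lstm, X_seq[va])

    rf_final = _new_rf(config, seed + 1).fit(X_feat, y)
    lstm_final = _new_lstm(config, seed + 2).fit(X_seq, y)
    return rf_final, lstm_final, oof


def train_stacker(
    six_probability_features: np.ndarray,
    y: np.ndarray,
    config: RunConfig,
    seed: int,
) -> RandomForestClassifier:
    """Second-stage forest over exactly the six sub-model probabilities."""
    X = np.asarray(six_probability_features)
    if X.ndim != 2 or X.shape[1] != 6:
        raise ValueError(
            f"stacker input must have exactly 6 columns, got shape {X.shape}"
        )
    return _new_rf(config, seed + 3).fit(X, np.asarray(y))


# ---------------------------------------------------------------------------
# threshold calibration


@dataclass
class CalibrationResult:
    threshold: float
    recall: float
    precision: float
    recall_floor: float


def calibrate_threshold(
    stay_cs_probs: np.ndarray,
    stay_is_cs: np.ndarray,
    recall_floor: float,
) -> CalibrationResult:
    """Largest threshold keeping confirmed-sepsis recall >= the floor.

    A stay is flagged when its CS probability is >= the threshold, so the
    optimum is the ceil(floor * n_cs)-th largest CS-stay probability.
    """
    if not (0.0 < recall_floor <= 1.0):
        raise ValueError("recall_floor must be in (0, 1]")
    probs = np.asarray(stay_cs_probs, dtype=float)
    is_cs = np.asarray(stay_is_cs, dtype=bool)
    cs_probs = probs[is_cs]
    if len(cs_probs) == 0:
        raise ValueError("no confirmed-sepsis stay in the training data")
    if np.isnan(cs_probs).any():
        raise ValueError("CS probabilities contain NaN")

    k = int(np.ceil(recall_floor * len(cs_probs)))
    tau = float(np.sort(cs_probs)[::-1][k - 1])
    flagged = probs >= tau
    recall = float(flagged[is_cs].mean())
    n_flagged = int(flagged.sum())
    precision = float(is_cs[flagged].mean()) if n_flagged else float("nan")
    return CalibrationResult(
        threshold=tau, recall=recall, precision=precision, recall_floor=recall_floor
    )


# ---------------------------------------------------------------------------
# bundle and prediction


@dataclass
class ModelBundle:
    """The trained ensemble with its calibrated threshold and provenance."""

    rf: RandomForestClassifier
    lstm: LSTMClassifier
    stacker: RandomForestClassifier
    threshold: float
    recall_floor: float
    config: RunConfig
    fill_values: dict[str, float]
    version: str = ""
    fingerprint: str = ""
    cv_metrics: dict | None = None

    def stacked_probs(self, X_feat: np.ndarray, X_seq: np.ndarray) -> np.ndarray:
        """(N, 3) final probability triples for prepared windows."""
        six = np.hstack(
            [_proba_3class(self.rf, X_feat), _proba_3class(self.lstm, X_seq)]
        )
        return _proba_3class(self.stacker, six)

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "bundle.pkl", "wb") as fh:
            pickle.dump(self, fh)
        manifest = {
            "version": self.version,
            "fingerprint": self.fingerprint,
            "threshold": self.threshold,
            "recall_floor": self.recall_floor,
            "seed": self.config.seed,
            "cv_metrics": self.cv_metrics,
        }
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")

    @staticmethod
    def load(path) -> "ModelBundle":
        with open(Path(path) / "bundle.pkl", "rb") as fh:
            return pickle.load(fh)


@dataclass
class StayPrediction:
    stay_id: str
    window_probs: np.ndarray            # (W, 3) NS/PS/CS triples
    stay_cs_prob: float
    flag: bool
    label: str                          # 3-class label of the argmax window
    argmax_window: int = 0

    def __post_init__(self) -> None:
        sums = self.window_probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("window probability triples must sum to 1")


def _aggregate_stay(stay_id: str, probs: np.ndarray, threshold: float) -> StayPrediction:
    cs = probs[:, _CLASS_IDX["CS"]]
    k = int(np.argmax(cs))
    triple = probs[k]
    # argmax class of the peak window; ties resolved toward higher severity
    best = max(range(3), key=lambda j: (triple[j], j))
    return StayPrediction(
        stay_id=stay_id,
        window_probs=probs,
        stay_cs_prob=float(cs[k]),
        flag=bool(cs[k] >= threshold),
        label=CLASSES[best],
        argmax_window=k,
    )


def predict_stay(bundle: ModelBundle, track: WindowTrack) -> StayPrediction:
    """Per-window triples and the stay-level max-probability aggregate."""
    cfg = bundle.config
    X_feat = rolling_features_matrix(
        track,
        lookback_windows=cfg.lookback_windows,
        feature_registry=cfg.feature_registry,
        fill_values=bundle.fill_values,
    )
    X_seq = build_sequences_matrix(
        track,
        sequence_concepts=list(cfg.sequence_concepts),
        lookback_windows=cfg.lookback_windows,
        fill_values=bundle.fill_values,
    )
    probs = bundle.stacked_probs(X_feat, X_seq)
    track.probs = probs
    return _aggregate_stay(track.stay_id, probs, bundle.threshold)


def predict_registry(
    bundle: ModelBundle,
    registry: Registry | WindowDataset,
    chunk_stays: int = 200,
) -> pd.DataFrame:
    """Stay-level prediction table (stay_id, cs_prob, flag, label).

    Accepts a pre-assembled :class:`WindowDataset` to avoid recomputing
    features. Sequence tensors are materialized in chunks of stays to bound
    memory.
    """
    ds = (
        registry
        if isinstance(registry, WindowDataset)
        else assemble_windows(registry, bundle.config)
    )
    rows = ds.rows
    recs = []
    stay_ids = rows["stay_id"].unique()
    for start in range(0, len(stay_ids), chunk_stays):
        batch = stay_ids[start:start + chunk_stays]
        idx = np.nonzero(rows["stay_id"].isin(batch).to_numpy())[0]
        probs = bundle.stacked_probs(ds.X_feat[idx], ds.sequences(idx))
        sub = rows.iloc[idx].reset_index(drop=True)
        for sid, grp in sub.groupby("stay_id", sort=False):
            pred = _aggregate_stay(sid, probs[grp.index.to_numpy()], bundle.threshold)
            recs.append(
                (sid, pred.stay_cs_prob, pred.flag, pred.label, pred.argmax_window)
            )
    return pd.DataFrame(
        recs, columns=["stay_id", "cs_prob", "flag", "label", "argmax_window"]
    )


# ---------------------------------------------------------------------------
# end-to-end fit


def _fingerprint(ds: WindowDataset) -> str:
    h = hashlib.md5()
    h.update(str(len(ds.rows)).encode())
    h.update(str(sorted(pd.Series(ds.y).value_counts().items())).encode())
    return h.hexdigest()[:12]


def _training_row_mask(registry: Registry, ds: WindowDataset, config: RunConfig):
    if config.train_ward_groups is None:
        return np.ones(len(ds.rows), dtype=bool)
    seg = registry.ward_segments
    keep_stays = set(seg.loc[seg["ward_group"].isin(config.train_ward_groups), "stay_id"])
    return ds.rows["stay_id"].isin(keep_stays).to_numpy()


def fit_heracles(
    registry: Registry,
    config: RunConfig,
    dataset: WindowDataset | None = None,
) -> tuple[ModelBundle, pd.DataFrame]:
    """Train sub-models, stacker and threshold on a registry.

    Returns the bundle and the training-set stay-level prediction table the
    threshold was calibrated on.
    """
    ds = dataset if dataset is not None else assemble_windows(registry, config)
    rng = np.random.default_rng(config.seed)

    mask = _training_row_mask(registry, ds, config)
    y_all = ds.y
    cand = np.nonzero(mask)[0]
    keep = subsample_negatives(y_all[cand], config.negative_subsample_ratio, rng)
    train_idx = cand[keep]

    X_feat = ds.X_feat[train_idx]
    X_seq = ds.sequences(train_idx)
    y = y_all[train_idx]
    groups = ds.groups[train_idx]

    rf, lstm, oof = train_submodels(X_feat, X_seq, y, groups, config, config.seed)
    stacker = train_stacker(oof, y, config, config.seed)

    bundle = ModelBundle(
        rf=rf,
        lstm=lstm,
        stacker=stacker,
        threshold=0.5,
        recall_floor=config.recall_floor,
        config=config,
        fill_values=ds.fill_values,
        fingerprint=_fingerprint(ds),
    )
    bundle.version = f"heracles-{bundle.fingerprint}-s{config.seed}"

    # calibrate on the training set: stay-level max CS probability
    stay_pred = predict_registry(bundle, ds)
    truth_cs = np.array(
        [ds.stay_truth[s] == "CS" for s in stay_pred["stay_id"]]
    )
    cal = calibrate_threshold(
        stay_pred["cs_prob"].to_numpy(), truth_cs, config.recall_floor
    )
    bundle.threshold = cal.threshold
    stay_pred["flag"] = stay_pred["cs_prob"] >= cal.threshold
    return bundle, stay_pred


# ---------------------------------------------------------------------------
# cross-validation and governance


def subset_registry(registry: Registry, stay_ids) -> Registry:
    """Registry restricted to the given stays (patients pruned accordingly)."""
    keep = set(stay_ids)
    stays = registry.stays.loc[registry.stays["stay_id"].isin(keep)].reset_index(drop=True)
    pids = set(stays["patient_id"])
    return Registry(
        patients=registry.patients.loc[
            registry.patients["patient_id"].isin(pids)
        ].reset_index(drop=True),
        stays=stays,
        ward_segments=registry.ward_segments.loc[
            registry.ward_segments["stay_id"].isin(keep)
        ].reset_index(drop=True),
        observations=registry.observations.loc[
            registry.observations["stay_id"].isin(keep)
        ].reset_index(drop=True),
        medications=registry.medications.loc[
            registry.medications["stay_id"].isin(keep)
        ].reset_index(drop=True),
        events=registry.events.loc[
            registry.events["stay_id"].isin(keep)
        ].reset_index(drop=True),
        icd_codes=registry.icd_codes.loc[
            registry.icd_codes["stay_id"].isin(keep)
        ].reset_index(drop=True),
    )


@dataclass
class CVReport:
    """Per-fold and pooled stay-level metrics."""

    folds: list = field(default_factory=list)   # list of MetricsReport dicts
    pooled: dict = field(default_factory=dict)  # metric -> (mean, sd)
    selection_metric: str = "f1_cs"

    def metric(self, name: str | None = None) -> float:
        name = name or self.selection_metric
        if name not in self.pooled:
            raise KeyError(f"metric {name!r} not in report")
        return self.pooled[name][0]

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "pooled": {k: list(v) for k, v in self.pooled.items()},
            "selection_metric": self.selection_metric,
        }


_POOLED_KEYS = ("f1_cs", "precision_cs", "recall_cs", "macro_f1",
                "auroc_cs_vs_ns", "auroc_csps_vs_ns")


def cross_validate(registry: Registry, config: RunConfig) -> CVReport:
    """Patient-grouped K-fold internal validation at stay level."""
    from .evaluation import class_metrics, pairwise_auroc

    stays = registry.stays
    patients = stays["patient_id"].to_numpy()
    n_unique = len(np.unique(patients))
    if n_unique < config.cv_folds:
        raise ValueError(
            f"{n_unique} patients cannot fill {config.cv_folds} folds"
        )

    report = CVReport()
    gkf = GroupKFold(n_splits=config.cv_folds)
    per_fold: dict[str, list[float]] = {k: [] for k in _POOLED_KEYS}
    for fold, (tr, va) in enumerate(
        gkf.split(stays["stay_id"], groups=patients)
    ):
        train_reg = subset_registry(registry, stays["stay_id"].iloc[tr])
        val_reg = subset_registry(registry, stays["stay_id"].iloc[va])
        fold_cfg = RunConfig(**{**config.__dict__, "seed": config.seed + fold})
        bundle, _ = fit_heracles(train_reg, fold_cfg)

        val_ds = assemble_windows(val_reg, fold_cfg)
        pred = predict_registry(bundle, val_ds)
        truth = np.array([val_ds.stay_truth[s] for s in pred["stay_id"]])
        mr = class_metrics(truth, pred["label"].to_numpy())
        cs_probs = pred["cs_prob"].to_numpy()
        mr.auroc_cs_vs_ns = pairwise_auroc(truth, cs_probs, ("CS",), ("NS",))
        mr.auroc_csps_vs_ns = pairwise_auroc(truth, cs_probs, ("CS", "PS"), ("NS",))
        d = mr.to_dict()
        d["fold"] = fold
        d["val_patients"] = sorted(set(val_reg.stays["patient_id"]))
        report.folds.append(d)
        per_fold["f1_cs"].append(d["per_class"]["CS"]["f1"])
        per_fold["precision_cs"].append(d["per_class"]["CS"]["precision"])
        per_fold["recall_cs"].append(d["per_class"]["CS"]["recall"])
        per_fold["macro_f1"].append(d["macro_f1"])
        per_fold["auroc_cs_vs_ns"].append(d["auroc_cs_vs_ns"])
        per_fold["auroc_csps_vs_ns"].append(d["auroc_csps_vs_ns"])

    for k, vals in per_fold.items():
        arr = np.array(vals, dtype=float)
        report.pooled[k] = (float(np.nanmean(arr)), float(np.nanstd(arr)))
    return report


@dataclass
class GateDecision:
    deploy: bool
    metric: str
    challenger_value: float
    champion_value: float | None


def champion_challenger_gate(
    challenger: CVReport,
    champion: CVReport | None,
    metric: str = "f1_cs",
) -> GateDecision:
    """Deploy the challenger only on strict improvement (ties keep champion)."""
    chal = challenger.metric(metric)
    if champion is None:
        return GateDecision(True, metric, chal, None)
    champ = champion.metric(metric)
    return GateDecision(bool(chal > champ), metric, chal, champ)
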