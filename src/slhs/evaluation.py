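"""Evaluation surfaces: confusion matrices, per-class metrics, AUROC, kappa.

All metrics are implemented explicitly because their edge-case behaviour is
part of the contract: zero-denominator precision/recall cells are reported
as undefined-with-flag (NaN, listed in ``undefined``), never silently 0;
AUROC uses midrank tie handling; Cohen's kappa ships with its large-sample
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "MetricsReport",
    "class_metrics",
    "pairwise_auroc",
    "cohens_kappa",
    "KappaResult",
]

CLASSES = ("NS", "PS", "CS")
_IDX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class MetricsReport:
    """3-class classification metrics (rows = truth, columns = prediction)."""

    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro_f1: float
    counts: dict[str, int]
    undefined: list[str] = field(default_factory=list)
    auroc_cs_vs_ns: float = float("nan")
    auroc_csps_vs_ns: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro_f1": self.macro_f1,
            "counts": self.counts,
            "undefined": list(self.undefined),
            "auroc_cs_vs_ns": self.auroc_cs_vs_ns,
            "auroc_csps_vs_ns": self.auroc_csps_vs_ns,
        }


def class_metrics(truth, predicted) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class plus the confusion matrix.

    Undefined rates (zero denominator) are NaN and the affected cells are
    named in ``undefined``. Macro-F1 is the unweighted mean over classes
    with defined F1.
    """
    t = np.asarray(truth, dtype=object)
    p = np.asarray(predicted, dtype=object)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} truth vs {len(p)} predicted")
    unknown = (set(t) | set(p)) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown label(s): {sorted(unknown)}")

    cm = np.zeros((3, 3), dtype=int)
    for a, b in zip(t, p):
        cm[_IDX[a], _IDX[b]] += 1

    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    f1s = []
    for c in CLASSES:
        i = _IDX[c]
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0:
            prec = float("nan")
            undefined.append(f"precision_{c}")
        else:
            prec = tp / (tp + fp)
        if tp + fn == 0:
            rec = float("nan")
            undefined.append(f"recall_{c}")
        else:
            rec = tp / (tp + fn)
        if np.isnan(prec) or np.isnan(rec) or (prec + rec) == 0:
            f1 = float("nan") if (np.isnan(prec) or np.isnan(rec)) else 0.0
            if np.isnan(f1):
                undefined.append(f"f1_{c}")
        else:
            f1 = 2 * prec * rec / (prec + rec)
        per_class[c] = {"precision": float(prec), "recall": float(rec),
                        "f1": float(f1)}
        if not np.isnan(f1):
            f1s.append(f1)

    macro = float(np.mean(f1s)) if f1s else float("nan")
    counts = {c: int(cm[_IDX[c], :].sum()) for c in CLASSES}
    counts["n"] = int(cm.sum())
    return MetricsReport(
        confusion=cm, per_class=per_class, macro_f1=macro, counts=counts,
        undefined=undefined,
    )


def pairwise_auroc(truth, scores, positive_set, negative_set) -> float:
    """Rank-based AUROC for one label contrast, midrank tie handling.

    Rows whose truth label is in neither set are dropped (e.g. PS rows in
    the CS-vs-NS contrast); pooling CS and PS as positive gives the second
    contrast.
    """
    t = np.asarray(truth, dtype=object)
    s = np.asarray(scores, dtype=float)
    if len(t) != len(s):
        raise ValueError("truth and scores must have equal length")
    pos = np.isin(t, list(positive_set))
    neg = np.isin(t, list(negative_set))
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"empty group in AUROC contrast ({n_pos} positives, {n_neg} negatives)"
        )
    keep = pos | neg
    ranks = rankdata(s[keep])  # midranks
    r_pos = ranks[pos[keep]].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float
    p_observed: float
    p_expected: float

    def __float__(self) -> float:
        return self.kappa


def cohens_kappa(rater_a, rater_b, confidence: float = 0.95) -> KappaResult:
    """Unweighted Cohen's kappa with its large-sample Wald interval.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is observed agreement and
    p_e the chance agreement from the marginal label distributions; the
    standard error is the classic large-sample approximation
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    a = np.asarray(rater_a, dtype=object)
    b = np.asarray(rater_b, dtype=object)
    if len(a) != len(b):
        raise ValueError("rater sequences must have equal length")
    if len(a) == 0:
        raise ValueError("empty rating sequences")
    labels = sorted(set(a) | set(b), key=str)
    idx = {l: i for i, l in enumerate(labels)}
    k = len(labels)
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e == 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
        return KappaResult(kappa, kappa, kappa, 0.0, p_o, p_e)
    kappa = (p_o - p_e) / (1 - p_e)
    se = float(np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2)))
    z = norm.ppf(0.5 + confidence / 2.0)
    return KappaResult(
        kappa=float(kappa),
        ci_low=float(kappa - z * se),
        ci_high=float(kappa + z * se),
        se=se,
        p_observed=float(p_o),
        p_expected=p_e,
    )
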