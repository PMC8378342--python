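"""Presence–absence skill metrics from first principles.

Confusion matrices, the true skill statistic (TSS = sensitivity +
specificity − 1), rank-based AUC with ties counted half, TSS-maximizing
thresholds, and the retention gate applied to per-algorithm cross-validation
means.  Weighted confusion entries are supported so class-balanced case
weights can flow into TSS; the default evaluation uses unweighted counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "Confusion",
    "EvalRecord",
    "confusion_at",
    "tss",
    "auc",
    "optimal_threshold",
    "aggregate_and_gate",
]

#: Retention gates: a model is kept iff mean TSS > TSS_GATE and mean AUC > AUC_GATE.
TSS_GATE = 0.80
AUC_GATE = 0.85


@dataclass(frozen=True)
class Confusion:
    """Confusion counts (possibly weighted reals)."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn <= 0:
            raise ValueError("sensitivity undefined: no positives")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp <= 0:
            raise ValueError("specificity undefined: no negatives")
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class EvalRecord:
    """One model × repetition × fold evaluation result."""

    algorithm: str
    repetition: int
    fold: int
    tss: float
    auc: float
    threshold: float


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels lengths differ")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present")
    return scores, labels


def confusion_at(scores, labels, t: float, weights=None) -> Confusion:
    """Confusion matrix with the score-≥-threshold positive convention."""
    scores, labels = _check_labels(scores, labels)
    w = np.ones_like(scores) if weights is None else np.asarray(weights, dtype=float)
    pred = scores >= t
    pos, neg = labels == 1, labels == 0
    return Confusion(
        tp=float(w[pred & pos].sum()),
        fp=float(w[pred & neg].sum()),
        tn=float(w[~pred & neg].sum()),
        fn=float(w[~pred & pos].sum()),
    )


def tss(c: Confusion) -> float:
    """True skill statistic: sensitivity + specificity − 1, in [−1, 1]."""
    return c.sensitivity + c.specificity - 1.0


def auc(scores, labels) -> float:
    """Rank-based (Mann–Whitney) AUC; ties across classes count half.

    Equals the trapezoidal area under the empirical ROC curve.
    """
    scores, labels = _check_labels(scores, labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct scores, plus 0 and 1."""
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if s.size > 1 else np.array([])
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def optimal_threshold(scores, labels, weights=None) -> tuple[float, float]:
    """TSS-maximizing threshold; ties broken toward the smallest threshold.

    Returns ``(threshold, tss_at_threshold)``.
    """
    scores, labels = _check_labels(scores, labels)
    w = np.ones_like(scores) if weights is None else np.asarray(weights, dtype=float)
    pos = labels == 1
    w_pos_tot, w_neg_tot = w[pos].sum(), w[~pos].sum()
    best_t, best_tss = 0.0, -np.inf
    for t in _candidate_thresholds(scores):
        pred = scores >= t
        sens = w[pred & pos].sum() / w_pos_tot
        spec = w[~pred & ~pos].sum() / w_neg_tot
        val = sens + spec - 1.0
        if val > best_tss + 1e-12:
            best_t, best_tss = float(t), float(val)
    return best_t, best_tss


def aggregate_and_gate(
    records: list[EvalRecord] | pd.DataFrame,
    tss_min: float = TSS_GATE,
    auc_min: float = AUC_GATE,
) -> tuple[list[str], pd.DataFrame]:
    """Per-algorithm means over repetitions × folds and the strict retention gate.

    Retained iff mean TSS > ``tss_min`` AND mean AUC > ``auc_min``.
    Returns ``(retained algorithm names, means table)``; the means table has
    columns ``tss``, ``auc``, ``threshold``, ``retained``.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [
                {
                    "algorithm": r.algorithm,
                    "repetition": r.repetition,
                    "fold": r.fold,
                    "tss": r.tss,
                    "auc": r.auc,
                    "threshold": r.threshold,
                }
                for r in records
            ]
        )
    if df.empty:
        raise ValueError("no evaluation records")
    means = df.groupby("algorithm")[["tss", "auc", "threshold"]].mean()
    means["retained"] = (means["tss"] > tss_min) & (means["auc"] > auc_min)
    retained = list(means.index[means["retained"]])
    return retained, means
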