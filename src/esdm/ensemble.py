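"""Weighted-average ensembling, permutation importance, response curves.

Models that pass the TSS/AUC gates are combined with weights proportional to
their (cross-validation mean) score on the gating metric, so a stronger
member pulls the ensemble harder.  Variable importance is the randomization
measure 1 − Pearson(predictions, predictions with one predictor shuffled),
reported as mean ± SE over permutation runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sdm_core import FittedModel, TrainingTable

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleModel",
    "ImportanceResult",
    "ResponseCurve",
    "build_ensemble",
    "permutation_importance",
    "importance_table",
    "response_curve",
]


@dataclass
class EnsembleModel:
    """Convex combination of retained member models."""

    members: list[FittedModel]
    weights: np.ndarray
    weighting_metric: str = "tss"

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def predictors(self) -> list[str]:
        return self.members[0].predictors

    @property
    def member_names(self) -> list[str]:
        return [m.spec.algorithm for m in self.members]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Weighted-average suitability; convex, so stays within member range."""
        out = np.zeros(len(X), dtype=float)
        for w, m in zip(self.weights, self.members):
            out += w * m.predict(X)
        return out


def build_ensemble(
    models: list[FittedModel],
    eval_means: pd.Series | dict,
    metric: str = "tss",
) -> EnsembleModel:
    """Weight each retained model by its mean metric score: w_i = s_i / Σ s_j.

    ``eval_means`` maps algorithm name → mean gating-metric score (TSS by
    default; AUC selectable).  All scores must not be ≤ 0.
    """
    if not models:
        raise ValueError("need at least one retained model")
    scores = np.array(
        [float(eval_means[m.spec.algorithm]) for m in models], dtype=float
    )
    if np.all(scores <= 0):
        raise ValueError("all metric scores are <= 0; cannot form weights")
    scores = np.clip(scores, 0.0, None)
    return EnsembleModel(
        members=list(models), weights=scores / scores.sum(), weighting_metric=metric
    )


def permutation_importance(
    model,
    table: TrainingTable,
    predictor: str,
    n_perm: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Randomization importance of one predictor: mean ± SE of 1 − r over runs.

    Per run the predictor column is shuffled (seeded) and importance is
    1 − Pearson correlation between the reference predictions and the
    shuffled-column predictions.  Values are reported unclamped (1 − r can
    exceed 1 when r < 0).  Constant predictions give importance 0 (logged).
    """
    if predictor not in table.predictors:
        raise ValueError(f"unknown predictor {predictor!r}")
    X = table.X.copy()
    ref = model.predict(X)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        Xp = X.copy()
        Xp[predictor] = rng.permutation(Xp[predictor].to_numpy())
        perm = model.predict(Xp)
        if np.std(ref) == 0 or np.std(perm) == 0:
            logger.info(
                "constant predictions while permuting %r; importance set to 0", predictor
            )
            vals[i] = 0.0
        else:
            vals[i] = 1.0 - float(np.corrcoef(ref, perm)[0, 1])
    se = float(np.std(vals, ddof=1) / np.sqrt(n_perm)) if n_perm > 1 else 0.0
    return float(np.mean(vals)), se


@dataclass
class ImportanceResult:
    table: pd.DataFrame  # index: predictor; columns: mean, se

    def ranking(self) -> list[str]:
        return list(self.table.sort_values("mean", ascending=False).index)


def importance_table(
    model, table: TrainingTable, n_perm: int = 10, seed: int = 0
) -> ImportanceResult:
    """Permutation importance of every predictor (mean ± SE), one table."""
    rows = {}
    for j, name in enumerate(table.predictors):
        mean, se = permutation_importance(model, table, name, n_perm=n_perm, seed=seed + j)
        rows[name] = {"mean": mean, "se": se}
    return ImportanceResult(pd.DataFrame.from_dict(rows, orient="index"))


@dataclass
class ResponseCurve:
    predictor: str
    x: np.ndarray
    suitability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"predictor": self.predictor, "x": self.x, "suitability": self.suitability}
        )


def response_curve(
    model,
    table: TrainingTable,
    predictor: str,
    n_points: int = 100,
    conditioning: str = "mean",
) -> ResponseCurve:
    """Evaluation-strip response curve along one predictor's training range.

    The predictor varies over an evenly spaced grid spanning its training
    range while every other predictor is held at its training mean (median
    selectable).
    """
    if predictor not in table.predictors:
        raise ValueError(f"unknown predictor {predictor!r}")
    X = table.X
    grid = np.linspace(X[predictor].min(), X[predictor].max(), n_points)
    if conditioning == "mean":
        fixed = X.mean()
    elif conditioning == "median":
        fixed = X.median()
    else:
        raise ValueError("conditioning must be 'mean' or 'median'")
    strip = pd.DataFrame({c: np.full(n_points, fixed[c]) for c in table.predictors})
    strip[predictor] = grid
    return ResponseCurve(predictor=predictor, x=grid, suitability=model.predict(strip))
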