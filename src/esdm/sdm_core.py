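"""The learner zoo: ten algorithms behind one fit/predict contract.

Every fitted model maps a predictor vector to a habitat-suitability score in
[0, 1].  Nine learners are probabilistic classifiers built on scikit-learn;
the surface range envelope (SRE, the BIOCLIM-style model) is implemented from
first principles and predicts {0, 1}.  Repeated stratified k-fold splitting
and the fit-evaluate loop over algorithms × repetitions × folds live here too.

Default hyperparameters are recorded in :data:`ALGORITHM_DEFAULTS`; all are
overridable through :class:`LearnerSpec` and logged on the fitted model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .evaluation import EvalRecord, auc, optimal_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "ALGORITHMS",
    "ALGORITHM_DEFAULTS",
    "TrainingTable",
    "LearnerSpec",
    "FittedModel",
    "SREnvelope",
    "FitError",
    "sre_fit",
    "sre_predict",
    "fit",
    "make_splits",
    "fit_evaluate",
]

ALGORITHMS = ("GLM", "GAM", "CTA", "GBM", "ANN", "SRE", "FDA", "MARS", "RF", "MAXENT")

#: One config block of framework-default-like settings, all overridable.
ALGORITHM_DEFAULTS: dict[str, dict] = {
    "GLM": {},
    "GAM": {"n_knots": 5, "degree": 3, "C": 1000.0},
    "CTA": {"min_samples_split": 20, "min_samples_leaf": 7},
    "GBM": {"n_estimators": 2500, "max_depth": 3, "learning_rate": 0.01},
    "ANN": {"size": 8, "max_iter": 400},      # size=None → internal CV over {2,4,6,8}
    "SRE": {"quantile": 0.025},
    "FDA": {"n_knots": 5},
    "MARS": {"n_knots": 10, "C": 100.0},
    "RF": {"n_estimators": 500},
    "MAXENT": {"C": 1.0},
}


class FitError(RuntimeError):
    """A model failed to fit; carries the algorithm name."""

    def __init__(self, algorithm: str, message: str):
        super().__init__(f"{algorithm}: {message}")
        self.algorithm = algorithm


# ---------------------------------------------------------------------------
# Training data
# ---------------------------------------------------------------------------

@dataclass
class TrainingTable:
    """Point rows with predictor values, binary response, and case weights.

    ``data`` holds one column per predictor plus ``response`` (1 presence /
    0 pseudo-absence) and ``weight``.  Weights are class-balanced so each
    class carries equal total weight (prevalence 0.5) regardless of the
    presence : pseudo-absence imbalance.
    """

    data: pd.DataFrame
    predictors: list[str]
    split_assignments: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in (*self.predictors, "response", "weight") if c not in self.data]
        if missing:
            raise ValueError(f"training table missing columns {missing}")
        if self.data[self.predictors].isna().any().any():
            raise ValueError("missing predictor values in training table")
        y = self.data["response"]
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("response must be binary 0/1")
        if not (np.any(y == 1) and np.any(y == 0)):
            raise ValueError("both classes must be present")
        if (self.data["weight"] <= 0).any():
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.predictors]

    @property
    def y(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=int)

    @property
    def w(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)


def balanced_weights(y: np.ndarray) -> np.ndarray:
    """Class-balanced case weights with mean 1 (each class sums to n/2)."""
    y = np.asarray(y, dtype=int)
    n = len(y)
    w = np.empty(n, dtype=float)
    for cls in (0, 1):
        m = y == cls
        w[m] = n / (2.0 * m.sum())
    return w


def make_training_table(stack, presences, background, predictors=None) -> TrainingTable:
    """Assemble presences (1) and pseudo-absences (0) into one table.

    Predictor values are read from the stack at each point's grid cell; rows
    falling on invalid cells are dropped with a warning.
    """
    predictors = stack.names if predictors is None else list(predictors)
    frames = []
    for pts, resp in ((presences, 1), (background, 0)):
        lon, lat = pts.lon, pts.lat
        rows, cols = stack.grid.cell_of(lon, lat)
        df = stack.extract(rows, cols, predictors)
        df["response"] = resp
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    bad = data[predictors].isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d training points on invalid cells", int(bad.sum()))
        data = data[~bad].reset_index(drop=True)
    data["weight"] = balanced_weights(data["response"].to_numpy())
    return TrainingTable(data=data, predictors=predictors)


# ---------------------------------------------------------------------------
# Surface range envelope (BIOCLIM-style), from first principles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SREnvelope:
    """Per-predictor [lower, upper] bounds from presence data quantiles."""

    lower: dict[str, float]
    upper: dict[str, float]
    quantile: float


def sre_fit(presence_predictors: pd.DataFrame, quantile: float = 0.025) -> SREnvelope:
    """Envelope bounds = empirical [q, 1−q] quantiles of presence values.

    Uses the linear-interpolation quantile definition.  ``quantile`` must lie
    in [0, 0.5); 0 gives the min/max envelope.
    """
    if not (0 <= quantile < 0.5):
        raise ValueError("quantile must be in [0, 0.5)")
    if len(presence_predictors) < 2:
        raise ValueError("need at least 2 presence rows")
    lower, upper = {}, {}
    for name in presence_predictors.columns:
        v = presence_predictors[name].to_numpy(dtype=float)
        lower[name] = float(np.quantile(v, quantile))
        upper[name] = float(np.quantile(v, 1.0 - quantile))
    return SREnvelope(lower=lower, upper=upper, quantile=quantile)


def sre_predict(envelope: SREnvelope, x: pd.DataFrame | dict) -> np.ndarray:
    """1 iff every predictor lies within its [lower, upper] bound (inclusive)."""
    if isinstance(x, dict):
        x = pd.DataFrame({k: np.atleast_1d(v) for k, v in x.items()})
    missing = [n for n in envelope.lower if n not in x.columns]
    if missing:
        raise ValueError(f"missing predictor(s) {missing} in query")
    inside = np.ones(len(x), dtype=bool)
    for name in envelope.lower:
        v = x[name].to_numpy(dtype=float)
        inside &= (v >= envelope.lower[name]) & (v <= envelope.upper[name])
    return inside.astype(float)


# ---------------------------------------------------------------------------
# Uniform fit/predict contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LearnerSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def params(self) -> dict:
        p = dict(ALGORITHM_DEFAULTS[self.algorithm])
        p.update(self.hyperparameters)
        return p


@dataclass
class FittedModel:
    """A fitted learner with a deterministic predict contract into [0, 1]."""

    spec: LearnerSpec
    predictors: list[str]
    n: int
    prevalence: float
    _impl: object = None          # sklearn estimator, or SREnvelope

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Suitability in [0, 1] for each row of ``X``."""
        X = X[self.predictors]
        if self.spec.algorithm == "SRE":
            return sre_predict(self._impl, X)
        p = self._impl.predict_proba(X.to_numpy())[:, 1]
        return np.clip(p, 0.0, 1.0)


def _spline_logistic(n_knots, degree, C, seed, max_iter=2000):
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=n_knots, degree=degree, include_bias=False)),
            ("clf", LogisticRegression(C=C, max_iter=max_iter, random_state=seed)),
        ]
    )


def _build_estimator(algorithm: str, p: dict, seed: int, n_features: int):
    if algorithm == "GLM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(C=1e6, max_iter=2000, random_state=seed)),
            ]
        )
    if algorithm == "GAM":
        return _spline_logistic(p["n_knots"], p["degree"], p["C"], seed)
    if algorithm == "MARS":
        # first-order adaptive splines: piecewise-linear basis + logistic fit
        return _spline_logistic(p["n_knots"], 1, p["C"], seed)
    if algorithm == "CTA":
        return DecisionTreeClassifier(
            min_samples_split=p["min_samples_split"],
            min_samples_leaf=p["min_samples_leaf"],
            random_state=seed,
        )
    if algorithm == "GBM":
        return GradientBoostingClassifier(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            random_state=seed,
        )
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"], random_state=seed, n_jobs=1
        )
    if algorithm == "ANN":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=(p.get("size") or 8,),
                        max_iter=p["max_iter"],
                        random_state=seed,
                    ),
                ),
            ]
        )
    if algorithm == "FDA":
        # flexible discriminant: linear discriminant on a spline basis,
        # equal class priors standing in for case weights
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("spline", SplineTransformer(n_knots=p["n_knots"], degree=1, include_bias=False)),
                (
                    "clf",
                    LinearDiscriminantAnalysis(
                        solver="lsqr", shrinkage="auto", priors=[0.5, 0.5]
                    ),
                ),
            ]
        )
    if algorithm == "MAXENT":
        # maxent-equivalent: L2-regularized logistic on linear+quadratic
        # features, presences vs. background
        return Pipeline(
            [
                ("poly", PolynomialFeatures(degree=2, include_bias=False)),
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(C=p["C"], max_iter=2000, random_state=seed)),
            ]
        )
    raise ValueError(algorithm)


def _ann_select_size(X, y, w, p, seed):
    """3-fold internal CV over hidden sizes {2, 4, 6, 8}; returns best size."""
    from .evaluation import auc as _auc

    sizes = (2, 4, 6, 8)
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    best_size, best_score = sizes[0], -np.inf
    for size in sizes:
        scores = []
        for tr, te in skf.split(X, y):
            est = _build_estimator("ANN", {**p, "size": size}, seed, X.shape[1])
            est.fit(X[tr], y[tr], clf__sample_weight=w[tr])
            scores.append(_auc(est.predict_proba(X[te])[:, 1], y[te]))
        score = float(np.mean(scores))
        if score > best_score:
            best_size, best_score = size, score
    return best_size


def fit(spec: LearnerSpec, table: TrainingTable, rows=None) -> FittedModel:
    """Fit one learner on a row subset of the training table.

    All learners except SRE see both classes with class-balanced case
    weights; SRE is fitted on the presence rows only.  Fitting is
    deterministic given (spec, data, seed).
    """
    data = table.data if rows is None else table.data.iloc[rows]
    y = data["response"].to_numpy(dtype=int)
    p = spec.params()

    if spec.algorithm == "SRE":
        pres = data.loc[data["response"] == 1, table.predictors]
        if len(pres) < 2:
            raise FitError("SRE", "need at least 2 presence rows")
        env = sre_fit(pres, quantile=p["quantile"])
        return FittedModel(
            spec=spec,
            predictors=list(table.predictors),
            n=len(pres),
            prevalence=1.0,
            _impl=env,
        )

    if not (np.any(y == 1) and np.any(y == 0)):
        raise FitError(spec.algorithm, "training subset contains a single class")
    X = data[table.predictors].to_numpy(dtype=float)
    if np.allclose(X.std(axis=0), 0):
        raise FitError(spec.algorithm, "zero variance in all predictors")
    w = data["weight"].to_numpy(dtype=float)

    if spec.algorithm == "ANN" and p.get("size") is None:
        p = {**p, "size": _ann_select_size(X, y, w, p, spec.seed)}
        logger.info("ANN internal CV selected hidden size %d", p["size"])

    est = _build_estimator(spec.algorithm, p, spec.seed, X.shape[1])
    try:
        if isinstance(est, Pipeline):
            if spec.algorithm == "FDA":
                est.fit(X, y)  # LDA takes no case weights; equal priors instead
            else:
                est.fit(X, y, clf__sample_weight=w)
        else:
            est.fit(X, y, sample_weight=w)
    except Exception as exc:  # noqa: BLE001 - re-raise with algorithm context
        raise FitError(spec.algorithm, str(exc)) from exc
    return FittedModel(
        spec=LearnerSpec(spec.algorithm, p, spec.seed),
        predictors=list(table.predictors),
        n=len(data),
        prevalence=float(np.mean(y)),
        _impl=est,
    )


# ---------------------------------------------------------------------------
# Repeated stratified k-fold splitting and the fit-evaluate loop
# ---------------------------------------------------------------------------

def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic fan-out of one master seed into n child seeds < 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_splits(
    table: TrainingTable, k: int = 5, repetitions: int = 10, seed: int = 0
) -> dict[int, np.ndarray]:
    """Stratified k-fold assignments per repetition.

    Each repetition partitions all rows into k class-stratified folds; each
    row is the test fold exactly once per repetition, so every fit trains on
    (k−1)/k of the data (80% at k=5).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = table.y
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    assignments = {}
    for rep, rep_seed in enumerate(_spawn_seeds(seed, repetitions)):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        folds = np.empty(table.n, dtype=int)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(table.n), y)):
            folds[test_idx] = f
        assignments[rep] = folds
    table.split_assignments = assignments
    return assignments


def fit_evaluate(
    table: TrainingTable,
    algorithms=ALGORITHMS,
    k: int = 5,
    repetitions: int = 10,
    seed: int = 0,
    hyperparameters: dict[str, dict] | None = None,
) -> list[EvalRecord]:
    """Fit every algorithm on every repetition × fold and score the held-out fold.

    Held-out scoring is unweighted: rank AUC plus TSS at the TSS-maximizing
    threshold.  Returns one :class:`EvalRecord` per algorithm × repetition ×
    fold (``len(algorithms) · repetitions · k`` records).
    """
    hyperparameters = hyperparameters or {}
    splits = make_splits(table, k=k, repetitions=repetitions, seed=seed)
    algo_seeds = dict(zip(ALGORITHMS, _spawn_seeds(seed + 1, len(ALGORITHMS))))
    records: list[EvalRecord] = []
    for rep, folds in splits.items():
        for f in range(k):
            train_rows = np.nonzero(folds != f)[0]
            test_rows = np.nonzero(folds == f)[0]
            y_test = table.y[test_rows]
            X_test = table.data.iloc[test_rows][table.predictors]
            for algo in algorithms:
                spec = LearnerSpec(
                    algo, hyperparameters.get(algo, {}), algo_seeds[algo] + rep * k + f
                )
                model = fit(spec, table, rows=train_rows)
                scores = model.predict(X_test)
                t, tss_val = optimal_threshold(scores, y_test)
                records.append(
                    EvalRecord(
                        algorithm=algo,
                        repetition=rep,
                        fold=f,
                        tss=tss_val,
                        auc=auc(scores, y_test),
                        threshold=t,
                    )
                )
        logger.info("repetition %d: evaluated %d algorithms × %d folds", rep, len(algorithms), k)
    return records
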