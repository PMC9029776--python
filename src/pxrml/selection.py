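"""Hyperparameter selection by cross-validated MCC, plain or gap-penalized.

The selection criterion is the point of this module.  Classical grid search
picks the configuration maximizing the mean validation-fold MCC,

    validation score = (1/k) * sum_i MCC_val_i .

The gap-penalized score additionally subtracts the mean train-validation gap,

    gap score = (1/k) * sum_i MCC_val_i  -  (1/k) * sum_i (MCC_train_i - MCC_val_i),

which algebraically equals (1/k) * sum_i (2*MCC_val_i - MCC_train_i).  The gap
term is signed: a model whose validation score exceeds its training score is
rewarded, not clipped.  Penalizing the gap biases selection toward simpler,
more regularized models (larger leaves for forests, smaller C for SVMs) that
transfer better to compounds dissimilar from the training set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

SCORING_MODES = ("validation", "gap_penalized")


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient from confusion-matrix counts.

    Any zero factor in the denominator yields 0 (the neutral convention for
    degenerate, single-class predictions or truths).
    """
    for v in (tp, fp, fn, tn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def mcc_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return mcc(tp, fp, fn, tn)


@dataclass(frozen=True)
class ModelConfig:
    """One point of the hyperparameter grid.

    RF hyperparameters: n_estimators, max_features, min_samples_split,
    min_samples_leaf, max_depth.  SVM: kernel, C, gamma.
    """

    algorithm: str  # "random_forest" | "svm"
    hyperparameters: tuple  # tuple of (name, value) pairs, hashable
    feature_set: str = "PC+FP"
    seed: int = 0

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)

    @staticmethod
    def make(algorithm: str, feature_set: str = "PC+FP", seed: int = 0, **params) -> "ModelConfig":
        if algorithm not in ("random_forest", "svm"):
            raise ValueError(f"unknown algorithm {algorithm!r}")
        if algorithm == "svm" and params.get("C", 1.0) <= 0:
            raise ValueError("C must be positive")
        if algorithm == "random_forest" and params.get("n_estimators", 100) < 1:
            raise ValueError("n_estimators must be >= 1")
        return ModelConfig(
            algorithm=algorithm,
            hyperparameters=tuple(sorted(params.items(), key=lambda kv: kv[0])),
            feature_set=feature_set,
            seed=seed,
        )


def build_estimator(config: ModelConfig, class_weight: Optional[str] = None):
    """Instantiate the sklearn estimator for a config.

    Forests consume features unscaled; the margin classifier is wrapped in a
    pipeline whose standardization is learned on the training folds only
    (fold-safe because the whole pipeline is refit per fold).
    """
    p = config.params
    if config.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=p.get("n_estimators", 100),
            max_features=p.get("max_features", "sqrt"),
            min_samples_split=p.get("min_samples_split", 2),
            min_samples_leaf=p.get("min_samples_leaf", 1),
            max_depth=p.get("max_depth", None),
            random_state=config.seed,
            n_jobs=1,
            class_weight=class_weight,
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    kernel=p.get("kernel", "rbf"),
                    C=p.get("C", 1.0),
                    gamma=p.get("gamma", "scale"),
                    probability=True,
                    random_state=config.seed,
                    class_weight=class_weight,
                ),
            ),
        ]
    )


def stratified_folds(labels: Sequence[int], k: int = 5, seed: int = 0) -> np.ndarray:
    """Seeded stratified k-fold assignment; returns the fold index per record."""
    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels, minlength=2)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"each class needs at least k={k} members, got {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for i, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[val_idx] = i
    return assignment


@dataclass
class CVResult:
    """Per-fold (train MCC, validation MCC) pairs for one configuration."""

    mcc_train: list[float]
    mcc_val: list[float]

    @property
    def k(self) -> int:
        return len(self.mcc_val)


def cross_validate(
    config: ModelConfig,
    X: np.ndarray,
    y: Sequence[int],
    folds: np.ndarray,
    class_weight: Optional[str] = None,
) -> CVResult:
    """Fit the config on each fold complement; score MCC on the training
    folds and the held-out fold."""
    y = np.asarray(y).astype(int)
    mcc_train: list[float] = []
    mcc_val: list[float] = []
    for i in sorted(set(folds.tolist())):
        val_mask = folds == i
        est = clone(build_estimator(config, class_weight))
        est.fit(X[~val_mask], y[~val_mask])
        mcc_train.append(mcc_from_predictions(y[~val_mask], est.predict(X[~val_mask])))
        mcc_val.append(mcc_from_predictions(y[val_mask], est.predict(X[val_mask])))
    return CVResult(mcc_train=mcc_train, mcc_val=mcc_val)


def score_validation(cv: CVResult) -> float:
    """Mean validation-fold MCC."""
    return float(np.mean(cv.mcc_val))


def score_gap_penalized(cv: CVResult) -> float:
    """Mean validation MCC minus the mean signed train-validation gap."""
    val = np.asarray(cv.mcc_val)
    train = np.asarray(cv.mcc_train)
    return float(val.mean() - (train - val).mean())


def _complexity_key(config: ModelConfig) -> tuple:
    """Sort key preferring more-regularized configs on score ties."""
    p = config.params
    if config.algorithm == "random_forest":
        return (-p.get("min_samples_leaf", 1), -p.get("min_samples_split", 2))
    return (p.get("C", 1.0),)


@dataclass
class ModelArtifact:
    """A fitted estimator plus the manifest needed to reuse it safely."""

    estimator: object
    config: ModelConfig
    n_features: int
    feature_set: str

    def manifest(self) -> dict:
        return {
            "algorithm": self.config.algorithm,
            "hyperparameters": self.config.params,
            "feature_set": self.feature_set,
            "n_features": self.n_features,
            "seed": self.config.seed,
        }


@dataclass
class SelectionOutcome:
    """Winner of a grid search under one scoring mode, with the full table."""

    scoring_mode: str
    best_config: ModelConfig
    best_score: float
    table: list[dict] = field(default_factory=list)  # one row per config
    model: Optional[ModelArtifact] = None


def fit_final(
    config: ModelConfig,
    X: np.ndarray,
    y: Sequence[int],
    class_weight: Optional[str] = None,
) -> ModelArtifact:
    """Refit a configuration on the full training set."""
    y = np.asarray(y).astype(int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    est = build_estimator(config, class_weight)
    est.fit(X, y)
    return ModelArtifact(
        estimator=est, config=config, n_features=X.shape[1], feature_set=config.feature_set
    )


def predict(artifact: ModelArtifact, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict binary labels and a ranking score (activator probability).

    The label is ``score >= 0.5``.  A feature-count mismatch against the
    artifact manifest is an error, never a silent truncation.
    """
    if X.shape[1] != artifact.n_features:
        raise ValueError(
            f"feature-count mismatch: model expects {artifact.n_features}, got {X.shape[1]}"
        )
    proba = artifact.estimator.predict_proba(X)
    classes = list(artifact.estimator.classes_)
    scores = proba[:, classes.index(1)]
    return (scores >= 0.5).astype(int), scores


def grid_search(
    grid: Sequence[ModelConfig],
    X: np.ndarray,
    y: Sequence[int],
    folds: np.ndarray,
    scoring_mode: str = "gap_penalized",
    class_weight: Optional[str] = None,
    fit_winner: bool = True,
) -> SelectionOutcome:
    """Evaluate every config once with the shared folds and pick the winner.

    Both the plain-validation and gap-penalized scores are stored for every
    config, so the two selection modes can be compared post hoc from one run.
    Ties break toward the more regularized config, then grid order.
    """
    if scoring_mode not in SCORING_MODES:
        raise ValueError(f"scoring_mode must be one of {SCORING_MODES}")
    if len(grid) == 0:
        raise ValueError("empty grid")
    table: list[dict] = []
    for idx, config in enumerate(grid):
        cv = cross_validate(config, X, y, folds, class_weight)
        table.append(
            {
                "index": idx,
                "config": config,
                "cv": cv,
                "score_validation": score_validation(cv),
                "score_gap_penalized": score_gap_penalized(cv),
            }
        )
    outcome = select_winner(table, scoring_mode)
    if fit_winner:
        outcome.model = fit_final(outcome.best_config, X, y, class_weight)
    return outcome


def select_winner(table: list[dict], scoring_mode: str) -> SelectionOutcome:
    """Pick the winning row of a score table for one scoring mode."""
    key = "score_validation" if scoring_mode == "validation" else "score_gap_penalized"
    best = min(
        table,
        key=lambda row: (-row[key], _complexity_key(row["config"]), row["index"]),
    )
    return SelectionOutcome(
        scoring_mode=scoring_mode,
        best_config=best["config"],
        best_score=best[key],
        table=table,
    )


def default_rf_grid(feature_set: str = "PC+FP", seed: int = 0) -> list[ModelConfig]:
    """Default forest grid bracketing shallow-to-deep configurations."""
    grid = []
    for n_estimators in (100, 500):
        for max_features in ("sqrt", 0.3):
            for min_samples_split in (2, 8, 32, 128):
                for min_samples_leaf in (1, 4, 16, 64, 256):
                    for max_depth in (None, 4, 8, 16):
                        grid.append(
                            ModelConfig.make(
                                "random_forest",
                                feature_set=feature_set,
                                seed=seed,
                                n_estimators=n_estimators,
                                max_features=max_features,
                                min_samples_split=min_samples_split,
                                min_samples_leaf=min_samples_leaf,
                                max_depth=max_depth,
                            )
                        )
    return grid


def default_svm_grid(feature_set: str = "PC+FP", seed: int = 0) -> list[ModelConfig]:
    """Default RBF-SVM grid spanning four decades of C."""
    grid = []
    for C in (0.01, 0.1, 1.0, 10.0, 100.0):
        for gamma in ("scale", 0.001, 0.01, 0.1):
            grid.append(
                ModelConfig.make(
                    "svm", feature_set=feature_set, seed=seed, kernel="rbf", C=C, gamma=gamma
                )
            )
    return grid
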