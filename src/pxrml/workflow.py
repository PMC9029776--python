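"""End-to-end benchmark experiments comparing the two selection modes.

One seed of the experiment: generate a synthetic analogue-series benchmark,
grid-search forest and SVM hyperparameters under shared 5-fold CV, select a
winner under each scoring mode (plain validation MCC vs gap-penalized), and
measure both winners on the in-distribution and scaffold-held-out test sets,
together with forest-complexity and similarity-stratified diagnostics.

The default experiment uses the 17 physicochemical descriptors and reduced
grids (a min_samples_leaf ladder for forests, a C ladder for SVMs) so a full
multi-seed sweep stays laptop-sized; the grids still span the
shallow-to-deep / soft-to-hard-margin range where the two selection modes
disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import evaluate, featurize, selection, synthbench

#: reduced forest grid: a regularization ladder over leaf sizes
SWEEP_RF_LEAVES = (1, 2, 4, 8, 16)
#: reduced SVM grid: four decades of the margin-softness parameter
SWEEP_SVM_C = (0.1, 1.0, 10.0, 100.0)
SWEEP_TREES = 150
SWEEP_FRACTIONS = (0.5, 0.2, 0.3)
SWEEP_FEATURE_SET = "PC"
LOW_SIMILARITY_THRESHOLD = 0.4


def rf_leaf_grid(seed: int, feature_set: str = SWEEP_FEATURE_SET) -> list[selection.ModelConfig]:
    return [
        selection.ModelConfig.make(
            "random_forest",
            feature_set=feature_set,
            seed=seed,
            n_estimators=SWEEP_TREES,
            max_features="sqrt",
            min_samples_split=2,
            min_samples_leaf=leaf,
            max_depth=None,
        )
        for leaf in SWEEP_RF_LEAVES
    ]


def svm_c_grid(seed: int, feature_set: str = SWEEP_FEATURE_SET) -> list[selection.ModelConfig]:
    return [
        selection.ModelConfig.make(
            "svm", feature_set=feature_set, seed=seed, kernel="rbf", C=c, gamma="scale"
        )
        for c in SWEEP_SVM_C
    ]


@dataclass
class SeedResult:
    """Both selection modes' winners and their test performance for one seed."""

    seed: int
    rf_gap_leaf: int
    rf_val_leaf: int
    rf_gap_cv_val_mcc: float
    rf_val_cv_val_mcc: float
    rf_gap_ood_mcc: float
    rf_val_ood_mcc: float
    rf_gap_iid_mcc: float
    rf_val_iid_mcc: float
    rf_gap_median_height: float
    rf_val_median_height: float
    rf_gap_median_leaf: float
    rf_val_median_leaf: float
    rf_gap_lowsim_mcc: float
    rf_val_lowsim_mcc: float
    svm_gap_c: float
    svm_val_c: float


def _test_mcc(artifact, X, y) -> float:
    preds, _ = selection.predict(artifact, X)
    return selection.mcc_from_predictions(y, preds)


def run_seed(seed: int, spec: Optional[synthbench.LibrarySpec] = None) -> SeedResult:
    """Run the full two-mode selection experiment for one seed."""
    if spec is None:
        spec = synthbench.LibrarySpec(seed=seed)
    split = synthbench.make_benchmark(spec, fractions=SWEEP_FRACTIONS)

    X_train = featurize.build_matrix(split.train, SWEEP_FEATURE_SET).X
    X_iid = featurize.build_matrix(split.iid_test, SWEEP_FEATURE_SET).X
    X_ood = featurize.build_matrix(split.ood_test, SWEEP_FEATURE_SET).X
    y_train = np.array(split.train.labels)
    y_iid = np.array(split.iid_test.labels)
    y_ood = np.array(split.ood_test.labels)

    folds = selection.stratified_folds(y_train, k=5, seed=seed)

    # one CV pass serves both scoring modes: every row stores both scores
    gap = selection.grid_search(rf_leaf_grid(seed), X_train, y_train, folds, "gap_penalized")
    val = selection.select_winner(gap.table, "validation")
    val.model = selection.fit_final(val.best_config, X_train, y_train)

    svm_gap = selection.grid_search(
        svm_c_grid(seed), X_train, y_train, folds, "gap_penalized", fit_winner=False
    )
    svm_val = selection.select_winner(svm_gap.table, "validation")

    gap_complexity = evaluate.rf_complexity(gap.model)
    val_complexity = evaluate.rf_complexity(val.model)

    # similarity-stratified diagnostics on the pooled test sets
    train_fps = featurize.fingerprint_matrix(split.train.smiles)
    pooled_smiles = split.iid_test.smiles + split.ood_test.smiles
    pooled_y = np.concatenate([y_iid, y_ood])
    profile = evaluate.max_similarity_profile(
        featurize.fingerprint_matrix(pooled_smiles), train_fps
    )
    X_pooled = np.vstack([X_iid, X_ood])

    def lowsim_mcc(artifact) -> float:
        preds, _ = selection.predict(artifact, X_pooled)
        strata = evaluate.stratified_mcc(preds, pooled_y, profile)
        row = strata.loc[
            np.isclose(strata["threshold"], LOW_SIMILARITY_THRESHOLD), "mcc"
        ]
        return float(row.iloc[0])

    def cv_val_of(outcome):
        winner = next(r for r in outcome.table if r["config"] == outcome.best_config)
        return selection.score_validation(winner["cv"])

    return SeedResult(
        seed=seed,
        rf_gap_leaf=gap.best_config.params["min_samples_leaf"],
        rf_val_leaf=val.best_config.params["min_samples_leaf"],
        rf_gap_cv_val_mcc=cv_val_of(gap),
        rf_val_cv_val_mcc=cv_val_of(val),
        rf_gap_ood_mcc=_test_mcc(gap.model, X_ood, y_ood),
        rf_val_ood_mcc=_test_mcc(val.model, X_ood, y_ood),
        rf_gap_iid_mcc=_test_mcc(gap.model, X_iid, y_iid),
        rf_val_iid_mcc=_test_mcc(val.model, X_iid, y_iid),
        rf_gap_median_height=gap_complexity.median_height,
        rf_val_median_height=val_complexity.median_height,
        rf_gap_median_leaf=gap_complexity.median_leaf_size_weighted,
        rf_val_median_leaf=val_complexity.median_leaf_size_weighted,
        rf_gap_lowsim_mcc=lowsim_mcc(gap.model),
        rf_val_lowsim_mcc=lowsim_mcc(val.model),
        svm_gap_c=svm_gap.best_config.params["C"],
        svm_val_c=svm_val.best_config.params["C"],
    )


def run_sweep(seeds: Sequence[int]) -> list[SeedResult]:
    """Run the selection experiment over a list of seeds."""
    return [run_seed(int(s)) for s in seeds]


def sweep_summary(results: Sequence[SeedResult]) -> dict:
    """Aggregate win fractions and mean deltas from a sweep."""
    n = len(results)
    ood_wins = sum(r.rf_gap_ood_mcc > r.rf_val_ood_mcc for r in results)
    leaf_geq = sum(r.rf_gap_leaf >= r.rf_val_leaf for r in results)
    c_leq = sum(r.svm_gap_c <= r.svm_val_c for r in results)
    height_less = sum(r.rf_gap_median_height < r.rf_val_median_height for r in results)
    leaf_more = sum(r.rf_gap_median_leaf > r.rf_val_median_leaf for r in results)
    lowsim_wins = sum(
        r.rf_gap_lowsim_mcc > r.rf_val_lowsim_mcc
        for r in results
        if not (np.isnan(r.rf_gap_lowsim_mcc) or np.isnan(r.rf_val_lowsim_mcc))
    )
    return {
        "n_seeds": n,
        "ood_win_fraction": ood_wins / n,
        "rf_leaf_geq_fraction": leaf_geq / n,
        "svm_c_leq_fraction": c_leq / n,
        "height_less_fraction": height_less / n,
        "leaf_occupancy_more_fraction": leaf_more / n,
        "lowsim_win_fraction": lowsim_wins / n,
        "mean_ood_gain": float(
            np.mean([r.rf_gap_ood_mcc - r.rf_val_ood_mcc for r in results])
        ),
        "mean_iid_degradation": float(
            np.mean([r.rf_val_iid_mcc - r.rf_gap_iid_mcc for r in results])
        ),
        "mean_cv_mcc_validation_mode": float(
            np.mean([r.rf_val_cv_val_mcc for r in results])
        ),
        "mean_cv_mcc_gap_mode": float(np.mean([r.rf_gap_cv_val_mcc for r in results])),
        "mean_ood_mcc_gap_mode": float(np.mean([r.rf_gap_ood_mcc for r in results])),
        "mean_ood_mcc_validation_mode": float(
            np.mean([r.rf_val_ood_mcc for r in results])
        ),
    }
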