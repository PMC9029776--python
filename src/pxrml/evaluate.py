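"""Out-of-distribution diagnostics.

A model trained on one assay's chemical space degrades on compounds outside
it; these diagnostics quantify where.  The applicability-domain proxy is the
maximum Tanimoto similarity of each test compound to the training set
(similarity fingerprints: radius 2, 2048 bits).  Performance is reported per
similarity stratum, chemical-space coverage as nearest-neighbor curves,
library composition via Bemis-Murcko scaffolds, and model complexity via the
tree geometry of fitted forests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chemprep import LabeledDataset
from .featurize import tanimoto_matrix
from .selection import ModelArtifact, mcc_from_predictions

#: similarity thresholds for stratified evaluation, 0.1 .. 1.0
STRATIFICATION_THRESHOLDS = tuple(round(0.1 * i, 1) for i in range(1, 11))

#: reserved scaffold key for acyclic molecules (empty Murcko framework)
EMPTY_SCAFFOLD = ""


def max_similarity_profile(test_fps: np.ndarray, train_fps: np.ndarray) -> np.ndarray:
    """Per-test-molecule maximum Tanimoto similarity to any training molecule."""
    if train_fps.shape[0] == 0:
        raise ValueError("empty training set")
    return tanimoto_matrix(test_fps, train_fps).max(axis=1)


def stratified_mcc(
    predictions: np.ndarray, truth: np.ndarray, profile: np.ndarray
) -> pd.DataFrame:
    """MCC on nested test subsets S_t = {max similarity <= t}, t = 0.1 .. 1.0.

    Empty or single-class (in truth) strata report NaN rather than a
    fabricated 0.  The t = 1.0 row always covers the full test set.
    """
    predictions = np.asarray(predictions).astype(int)
    truth = np.asarray(truth).astype(int)
    profile = np.asarray(profile, dtype=float)
    n = len(truth)
    rows = []
    for t in STRATIFICATION_THRESHOLDS:
        mask = profile <= t + 1e-12
        size = int(mask.sum())
        if size == 0 or len(set(truth[mask].tolist())) < 2:
            value = np.nan
        else:
            value = mcc_from_predictions(truth[mask], predictions[mask])
        rows.append(
            {"threshold": t, "n": size, "fraction": size / n if n else 0.0, "mcc": value}
        )
    return pd.DataFrame(rows)


def coverage_fraction(
    reference_fps: np.ndarray, query_fps: np.ndarray, thresholds
) -> pd.DataFrame:
    """Fraction of reference molecules with a query neighbor at Tanimoto >=
    threshold, for each threshold.  Non-increasing in the threshold."""
    if reference_fps.shape[0] == 0 or query_fps.shape[0] == 0:
        raise ValueError("both sets must be non-empty")
    nearest = tanimoto_matrix(reference_fps, query_fps).max(axis=1)
    rows = [
        {"threshold": float(t), "fraction": float(np.mean(nearest >= t - 1e-12))}
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko framework SMILES (ring systems plus linkers;
    side chains removed).  Acyclic molecules map to the empty scaffold."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaffold)


@dataclass
class ScaffoldReport:
    """Scaffold composition of a dataset and its overlap with a reference."""

    n_molecules: int
    n_scaffolds: int
    scaffolds: set
    reference_n_scaffolds: int
    n_overlap: int
    overlap_percent: float  # overlap / reference scaffold count * 100
    molecules_per_scaffold: float


def scaffold_report(dataset: LabeledDataset, reference: LabeledDataset) -> ScaffoldReport:
    scaffolds = {murcko_scaffold(s) for s in dataset.smiles}
    ref_scaffolds = {murcko_scaffold(s) for s in reference.smiles}
    overlap = scaffolds & ref_scaffolds
    return ScaffoldReport(
        n_molecules=len(dataset),
        n_scaffolds=len(scaffolds),
        scaffolds=scaffolds,
        reference_n_scaffolds=len(ref_scaffolds),
        n_overlap=len(overlap),
        overlap_percent=100.0 * len(overlap) / len(ref_scaffolds) if ref_scaffolds else 0.0,
        molecules_per_scaffold=len(dataset) / len(scaffolds) if scaffolds else 0.0,
    )


@dataclass
class ComplexityStats:
    """Structural statistics of a fitted random forest.

    ``leaf_sizes``/``leaf_weights`` describe the occupancy-weighted leaf
    distribution: each leaf is weighted by the fraction of training samples
    it holds within its tree (the probability that a training sample selects
    that leaf), averaged over trees.
    """

    tree_heights: np.ndarray
    leaf_sizes: np.ndarray
    leaf_weights: np.ndarray
    median_height: float
    median_leaf_size_weighted: float


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    values = values[order]
    cum = np.cumsum(weights[order])
    cum /= cum[-1]
    return float(values[np.searchsorted(cum, 0.5)])


def rf_complexity(artifact: ModelArtifact) -> ComplexityStats:
    """Tree-height histogram and occupancy-weighted leaf-size distribution."""
    est = artifact.estimator
    if not hasattr(est, "estimators_"):
        raise TypeError("rf_complexity requires a fitted random-forest artifact")
    heights = []
    sizes: list[int] = []
    weights: list[float] = []
    n_trees = len(est.estimators_)
    for tree in est.estimators_:
        t = tree.tree_
        heights.append(t.max_depth)
        leaf_mask = t.children_left == -1
        # weighted counts include bootstrap multiplicity, so they sum to the
        # training-set size per tree
        leaf_counts = t.weighted_n_node_samples[leaf_mask]
        total = leaf_counts.sum()
        sizes.extend(leaf_counts.tolist())
        weights.extend((leaf_counts / total / n_trees).tolist())
    tree_heights = np.array(heights)
    leaf_sizes = np.array(sizes)
    leaf_weights = np.array(weights)
    return ComplexityStats(
        tree_heights=tree_heights,
        leaf_sizes=leaf_sizes,
        leaf_weights=leaf_weights,
        median_height=float(np.median(tree_heights)),
        median_leaf_size_weighted=_weighted_median(leaf_sizes, leaf_weights),
    )


def importance_audit(
    artifact: ModelArtifact, column_names: list[str]
) -> tuple[int, pd.DataFrame]:
    """Count strictly positive feature importances and rank all features.

    The table labels each feature as belonging to the physicochemical (PC) or
    fingerprint (FP) block.  Models without intrinsic importances (RBF SVMs)
    are rejected explicitly.
    """
    est = artifact.estimator
    if not hasattr(est, "feature_importances_"):
        raise TypeError(
            f"model of type {type(est).__name__} does not expose feature importances"
        )
    imp = np.asarray(est.feature_importances_)
    if len(column_names) != len(imp):
        raise ValueError("column manifest length does not match model feature count")
    table = pd.DataFrame(
        {
            "feature": column_names,
            "block": ["FP" if c.startswith("fp_") else "PC" for c in column_names],
            "importance": imp,
        }
    ).sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)
    return int((imp > 0).sum()), table
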