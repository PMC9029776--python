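"""Virtual screening: rank a library, apply the six-model consensus rule,
and report nearest-training-neighbor similarity for novelty triage.

The guiding model orders the library by its activator probability; a
candidate survives the consensus filter only when every configured model
votes it active.  Because the goal is finding activators *outside* the
training chemical space, each candidate also carries its nearest training
neighbor and a novelty flag (nearest-neighbor similarity below a cutoff,
0.7 by default — the conventional close-structural-relationship threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chemprep import LabeledDataset, StandardizationError, standardize
from .featurize import (
    SIMILARITY_FP_BITS,
    SIMILARITY_FP_RADIUS,
    FeatureMatrix,
    build_matrix,
    fingerprint_matrix,
    tanimoto_matrix,
)
from .selection import ModelArtifact, predict

DEFAULT_NOVELTY_CUTOFF = 0.7


def rank_library(
    guiding: ModelArtifact,
    X: np.ndarray,
    ids: Sequence[str],
    chunk_size: int = 10000,
) -> pd.DataFrame:
    """Score the library with the guiding model and sort descending.

    Processing is chunked so arbitrarily large libraries stream through; the
    result is identical to a single pass.  Ties break lexicographically on id.
    """
    if X.shape[0] != len(ids):
        raise ValueError("ids and feature rows are misaligned")
    scores = np.empty(X.shape[0])
    for start in range(0, X.shape[0], max(1, chunk_size)):
        _, s = predict(guiding, X[start : start + chunk_size])
        scores[start : start + chunk_size] = s
    frame = pd.DataFrame({"id": [str(i) for i in ids], "score": scores})
    return frame.sort_values(
        ["score", "id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def consensus_filter(votes: pd.DataFrame) -> list[str]:
    """Keep the ids whose every model vote is active (unanimity rule).

    ``votes`` has one row per compound (index = id) and one 0/1 column per
    model; any missing vote is an error.
    """
    if votes.isna().any().any():
        raise ValueError("missing votes")
    mask = (votes.astype(int) == 1).all(axis=1)
    return [str(i) for i in votes.index[mask]]


def nearest_neighbor_report(
    candidate_fps: np.ndarray,
    candidate_ids: Sequence[str],
    train: LabeledDataset,
    train_fps: np.ndarray,
) -> pd.DataFrame:
    """Nearest training neighbor (argmax Tanimoto) per candidate.

    Ties break toward the lexicographically smallest training id, so the
    report is deterministic regardless of training-set order.
    """
    if train_fps.shape[0] == 0:
        raise ValueError("empty training set")
    sims = tanimoto_matrix(candidate_fps, train_fps)
    train_ids = np.array(train.ids)
    rows = []
    for i, cid in enumerate(candidate_ids):
        best = sims[i].max()
        tie_ids = train_ids[np.isclose(sims[i], best)]
        rows.append(
            {"id": str(cid), "nn_id": sorted(tie_ids)[0], "nn_similarity": float(best)}
        )
    return pd.DataFrame(rows)


@dataclass
class ScreeningResult:
    """Ranked screening table plus the per-record skip log."""

    table: pd.DataFrame  # id, score, vote columns, consensus, nn_id, nn_similarity, novel
    skipped: list[tuple[str, str]]  # (id, reason)


def run_screen(
    library: pd.DataFrame,
    guiding: ModelArtifact,
    models: Sequence[tuple[str, ModelArtifact, FeatureMatrix | None]],
    train: LabeledDataset,
    feature_builder=None,
    novelty_cutoff: float = DEFAULT_NOVELTY_CUTOFF,
    chunk_size: int = 10000,
    fp_radius: int = SIMILARITY_FP_RADIUS,
    fp_n_bits: int = SIMILARITY_FP_BITS,
) -> ScreeningResult:
    """End-to-end screen of a SMILES library (columns ``id``, ``smiles``).

    Library compounds failing standardization are logged and skipped, never
    silently scored.  ``models`` supplies (name, artifact, feature matrix)
    triples for the voting ensemble; pass ``feature_builder(dataset,
    artifact)`` to featurize per-model when matrices are not precomputed.
    """
    # standardize, logging failures
    records = []
    skipped: list[tuple[str, str]] = []
    for _, row in library.iterrows():
        rid = str(row["id"])
        try:
            smiles_std, inchi, mw = standardize(row["smiles"])
        except StandardizationError as exc:
            skipped.append((rid, str(exc)))
            continue
        records.append((rid, smiles_std, inchi, mw))
    from .chemprep import MoleculeRecord

    dataset = LabeledDataset(
        records=[MoleculeRecord(r[0], r[1], r[2], None, r[3]) for r in records],
        name="screening_library",
    )
    if len(dataset) == 0:
        empty = pd.DataFrame(
            columns=["id", "score", "consensus", "nn_id", "nn_similarity", "novel"]
        )
        return ScreeningResult(table=empty, skipped=skipped)

    if feature_builder is None:
        def feature_builder(ds, artifact):
            return build_matrix(ds, feature_set=artifact.feature_set).X

    ranked = rank_library(guiding, feature_builder(dataset, guiding), dataset.ids, chunk_size)

    votes = pd.DataFrame(index=[str(i) for i in dataset.ids])
    for name, artifact, matrix in models:
        X = matrix.X if matrix is not None else feature_builder(dataset, artifact)
        labels, _ = predict(artifact, X)
        votes[f"vote_{name}"] = pd.Series(labels, index=votes.index)
    consensus_ids = set(consensus_filter(votes))

    train_fps = fingerprint_matrix(train.smiles, fp_radius, fp_n_bits)
    cand_fps = fingerprint_matrix(dataset.smiles, fp_radius, fp_n_bits)
    nn = nearest_neighbor_report(cand_fps, dataset.ids, train, train_fps)

    table = ranked.merge(votes, left_on="id", right_index=True).merge(nn, on="id")
    table["consensus"] = table["id"].isin(consensus_ids)
    table["novel"] = table["nn_similarity"] < novelty_cutoff
    return ScreeningResult(table=table, skipped=skipped)
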