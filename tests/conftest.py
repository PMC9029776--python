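"""Shared fixtures: small molecule sets and a cached benchmark split."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pxrml import chemprep, featurize, synthbench


@pytest.fixture(scope="session")
def small_dataset() -> chemprep.LabeledDataset:
    """Six standardized drug-like molecules, three per class."""
    rows = [
        ("mol-1", "COc1ccc2cc(C(C)C(=O)O)ccc2c1", 1),            # naproxen
        ("mol-2", "CC(C)Cc1ccc(C(C)C(=O)O)cc1", 1),              # ibuprofen
        ("mol-3", "O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl", 1),          # diclofenac
        ("mol-4", "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O", 0),      # hydrochlorothiazide
        ("mol-5", "Clc1ccc(-c2ccccc2)cc1Cl", 0),
        ("mol-6", "CCOc1ccc2nc(S(N)(=O)=O)sc2c1", 0),            # ethoxzolamide
    ]
    records = []
    for rid, smi, label in rows:
        smiles_std, inchi, mw = chemprep.standardize(smi)
        records.append(chemprep.MoleculeRecord(rid, smiles_std, inchi, label, mw))
    return chemprep.LabeledDataset(records=records, name="small")


@pytest.fixture(scope="session")
def tiny_benchmark() -> synthbench.BenchmarkSplit:
    """A small generated benchmark reused across tests (8 scaffolds x 12)."""
    spec = synthbench.LibrarySpec(n_scaffolds=8, analogues_per_scaffold=12, seed=11)
    return synthbench.make_benchmark(spec)


@pytest.fixture(scope="session")
def tiny_library() -> pd.DataFrame:
    spec = synthbench.LibrarySpec(n_scaffolds=6, analogues_per_scaffold=10, seed=5)
    return synthbench.generate_library(spec)


def random_fingerprints(rng: np.random.Generator, n: int, bits: int = 64, density: float = 0.2):
    return (rng.random((n, bits)) < density).astype(np.uint8)
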