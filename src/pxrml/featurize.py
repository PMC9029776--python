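"""Molecular featurization: 17 physicochemical descriptors, Morgan
fingerprints, and Tanimoto similarity.

Two fingerprint configurations coexist on purpose: the model fingerprints
(radius 2, 8192 bits) that enter feature matrices, and the similarity
fingerprints (radius 2, 2048 bits) used for chemical-space coverage,
nearest-neighbor lookup, and similarity stratification.  Both are hashed
binary circular fingerprints; only the bit width differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Lipinski, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem import Descriptors as _Desc

from .chemprep import LabeledDataset, StandardizationError

#: the 17 physicochemical descriptors, in fixed column order
DESCRIPTOR_NAMES = (
    "n_heavy_atoms",
    "n_oxygen",
    "n_nitrogen",
    "n_sulfur",
    "n_hba",
    "n_hbd",
    "n_rings",
    "n_rotatable_bonds",
    "n_halogens",
    "n_sp3_carbons",
    "n_aromatic_atoms",
    "tpsa",
    "mol_weight",
    "molar_refractivity",
    "logp",
    "esol",
    "fraction_rotatable_bonds",
)

#: defaults for the model fingerprints entering feature matrices
MODEL_FP_RADIUS = 2
MODEL_FP_BITS = 8192

#: defaults for similarity fingerprints (coverage, nearest neighbor, strata)
SIMILARITY_FP_RADIUS = 2
SIMILARITY_FP_BITS = 2048

_HALOGENS = {9, 17, 35, 53}

FEATURE_SETS = ("PC", "FP", "PC+FP")


class FeaturizationError(ValueError):
    """Raised when a molecule cannot be featurized."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    return mol


def esol(logp: float, mw: float, n_rotatable: int, aromatic_proportion: float) -> float:
    """Estimated aqueous solubility (log mol/L), Delaney's linear model:

    logS = 0.16 - 0.63*clogP - 0.0062*MW + 0.066*RB - 0.74*AP
    """
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * n_rotatable - 0.74 * aromatic_proportion


def physchem_vector(mol: Chem.Mol) -> np.ndarray:
    """Compute the 17-descriptor vector in :data:`DESCRIPTOR_NAMES` order."""
    try:
        n_heavy = mol.GetNumHeavyAtoms()
        atoms = list(mol.GetAtoms())
        n_o = sum(1 for a in atoms if a.GetAtomicNum() == 8)
        n_n = sum(1 for a in atoms if a.GetAtomicNum() == 7)
        n_s = sum(1 for a in atoms if a.GetAtomicNum() == 16)
        n_hba = Lipinski.NumHAcceptors(mol)
        n_hbd = Lipinski.NumHDonors(mol)
        n_rings = rdMolDescriptors.CalcNumRings(mol)
        n_rot = Lipinski.NumRotatableBonds(mol)
        n_hal = sum(1 for a in atoms if a.GetAtomicNum() in _HALOGENS)
        n_sp3c = sum(
            1
            for a in atoms
            if a.GetAtomicNum() == 6 and a.GetHybridization() == Chem.HybridizationType.SP3
        )
        n_arom = sum(1 for a in atoms if a.GetIsAromatic())
        tpsa = rdMolDescriptors.CalcTPSA(mol)
        mw = _Desc.MolWt(mol)
        mr = Crippen.MolMR(mol)
        logp = Crippen.MolLogP(mol)
        arom_prop = n_arom / n_heavy if n_heavy else 0.0
        sol = esol(logp, mw, n_rot, arom_prop)
        # bonds between heavy atoms (implicit Hs carry no bonds)
        n_heavy_bonds = sum(
            1
            for b in mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
        )
        frac_rot = n_rot / n_heavy_bonds if n_heavy_bonds else 0.0
    except Exception as exc:
        raise FeaturizationError(f"descriptor computation failed: {exc}")
    return np.array(
        [
            n_heavy, n_o, n_n, n_s, n_hba, n_hbd, n_rings, n_rot, n_hal,
            n_sp3c, n_arom, tpsa, mw, mr, logp, sol, frac_rot,
        ],
        dtype=float,
    )


@lru_cache(maxsize=8)
def _morgan_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def fingerprint(
    mol: Chem.Mol, radius: int = MODEL_FP_RADIUS, n_bits: int = MODEL_FP_BITS
) -> np.ndarray:
    """Hashed binary circular (Morgan-type) fingerprint as a uint8 array."""
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    bv = _morgan_generator(radius, n_bits).GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    return arr


def fingerprint_matrix(
    smiles: Sequence[str], radius: int = SIMILARITY_FP_RADIUS, n_bits: int = SIMILARITY_FP_BITS
) -> np.ndarray:
    """Stack fingerprints for a list of SMILES into an (n, n_bits) array."""
    return np.vstack([fingerprint(mol_from_smiles(s), radius, n_bits) for s in smiles])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b|; two empty vectors give 0."""
    if a.shape != b.shape:
        raise ValueError("fingerprint lengths differ")
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between fingerprint rows of A and B.

    Rows with no bits set are defined to have similarity 0 to everything.
    """
    A = A.astype(np.int32)
    B = B.astype(np.int32)
    inter = A @ B.T
    pop_a = A.sum(axis=1)[:, None]
    pop_b = B.sum(axis=1)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim


@dataclass
class FeatureMatrix:
    """Per-molecule numeric representation aligned to a dataset."""

    X: np.ndarray
    column_names: list[str]
    feature_set: str  # "PC" | "FP" | "PC+FP"
    fp_radius: Optional[int] = None
    fp_n_bits: Optional[int] = None

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def manifest(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "n_features": self.n_features,
            "fp_radius": self.fp_radius,
            "fp_n_bits": self.fp_n_bits,
            "descriptor_names": list(DESCRIPTOR_NAMES) if "PC" in self.feature_set else [],
        }


def build_matrix(
    dataset: LabeledDataset,
    feature_set: str = "PC+FP",
    fp_radius: int = MODEL_FP_RADIUS,
    fp_n_bits: int = MODEL_FP_BITS,
) -> FeatureMatrix:
    """Featurize a dataset: PC (17 cols), FP (fp_n_bits cols), or PC+FP with
    the descriptor block first.  Row order matches dataset order."""
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")

    mols = [mol_from_smiles(s) for s in dataset.smiles]
    blocks = []
    names: list[str] = []
    if "PC" in feature_set:
        blocks.append(np.vstack([physchem_vector(m) for m in mols]))
        names += list(DESCRIPTOR_NAMES)
    if "FP" in feature_set:
        blocks.append(
            np.vstack([fingerprint(m, fp_radius, fp_n_bits) for m in mols]).astype(float)
        )
        width = len(str(fp_n_bits - 1))
        names += [f"fp_{i:0{width}d}" for i in range(fp_n_bits)]
    X = blocks[0] if len(blocks) == 1 else np.hstack(blocks)
    return FeatureMatrix(
        X=X,
        column_names=names,
        feature_set=feature_set,
        fp_radius=fp_radius if "FP" in feature_set else None,
        fp_n_bits=fp_n_bits if "FP" in feature_set else None,
    )
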