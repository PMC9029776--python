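"""Compound standardization and the filter cascade producing clean labeled datasets.

The preprocessing protocol mirrors common QSAR curation practice for nuclear
receptor assay data: strip salts/solvents down to the largest organic fragment,
canonicalize the tautomer, then discard molecules that are too small to be
drug-like (< 200 Da by default), contain elements outside the typical organic
set, carry contradictory activity labels, or duplicate another structure
(identity keyed on the standard InChI of the standardized parent).  Every
removal is attributed to exactly one step so that the report conserves counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: elements permitted in a standardized parent structure
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "Si", "P", "S", "Se", "F", "Cl", "Br", "I"]
)

#: filter cascade step names, in application order
FILTER_STEPS = (
    "missing_identifier_or_smiles",
    "inconclusive_activity",
    "unparseable_smiles",
    "below_min_mw",
    "disallowed_element",
    "contradicting_labels",
    "duplicates",
)

ACTIVATOR = 1
NON_ACTIVATOR = 0

_TAUTOMER = rdMolStandardize.TautomerEnumerator()


class StandardizationError(ValueError):
    """Raised when a SMILES cannot be parsed or standardized."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with provenance and (optionally) a binary label."""

    source_id: str
    smiles_std: str
    inchi: str
    label: Optional[int]  # 1 activator, 0 non-activator, None for reference sets
    mw: float


@dataclass
class LabeledDataset:
    """Ordered collection of standardized molecules."""

    records: list[MoleculeRecord]
    name: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles_std for r in self.records]

    @property
    def inchis(self) -> list[str]:
        return [r.inchi for r in self.records]

    @property
    def labels(self) -> list[Optional[int]]:
        return [r.label for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.source_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "smiles_std": self.smiles,
                "inchi": self.inchis,
                "label": self.labels,
                "mw": [r.mw for r in self.records],
            }
        )


@dataclass
class FilterReport:
    """Per-step removal counts for one preprocessing run.

    Invariant: ``n_initial - sum(n for _, n in steps) == n_final``.
    """

    steps: list[tuple[str, int]] = field(default_factory=list)
    n_initial: int = 0
    n_final: int = 0
    n_activators: int = 0
    n_non_activators: int = 0

    @property
    def n_removed(self) -> int:
        return sum(n for _, n in self.steps)

    def validate(self) -> None:
        if self.n_initial - self.n_removed != self.n_final:
            raise AssertionError(
                f"count conservation violated: {self.n_initial} - "
                f"{self.n_removed} != {self.n_final}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_initial": self.n_initial,
                "removed": dict(self.steps),
                "n_final": self.n_final,
                "n_activators": self.n_activators,
                "n_non_activators": self.n_non_activators,
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"initial: {self.n_initial}"]
        lines += [f"  - {name}: {n}" for name, n in self.steps]
        lines.append(
            f"final: {self.n_final} "
            f"(A: {self.n_activators}, N: {self.n_non_activators})"
        )
        return "\n".join(lines)


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Pick the parent fragment: organic (carbon-containing) fragments are
    preferred; among candidates the one with most heavy atoms wins, with ties
    broken by molecular weight and then canonical-SMILES order."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0]

    def has_carbon(m: Chem.Mol) -> bool:
        return any(a.GetAtomicNum() == 6 for a in m.GetAtoms())

    organic = [f for f in frags if has_carbon(f)]
    candidates = organic if organic else list(frags)
    candidates.sort(
        key=lambda m: (-m.GetNumHeavyAtoms(), -Descriptors.MolWt(m), Chem.MolToSmiles(m))
    )
    return candidates[0]


def standardize(smiles: str) -> tuple[str, str, float]:
    """Standardize a SMILES to its canonical-tautomer parent structure.

    Returns ``(smiles_std, inchi, mw)``.  The parent is the largest organic
    fragment (salts and solvents stripped); the tautomer is canonicalized so
    that alternative drawings of the same compound collapse to one identity.

    Raises
    ------
    StandardizationError
        If the SMILES does not parse or InChI generation fails.
    """
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        raise StandardizationError(f"unparseable SMILES: {smiles!r}")
    try:
        parent = _largest_organic_fragment(mol)
        parent = _TAUTOMER.Canonicalize(parent)
        smiles_std = Chem.MolToSmiles(parent)
        inchi = Chem.MolToInchi(parent)
    except Exception as exc:  # RDKit raises a zoo of exception types
        raise StandardizationError(f"standardization failed for {smiles!r}: {exc}")
    if not inchi:
        raise StandardizationError(f"empty InChI for {smiles!r}")
    return smiles_std, inchi, Descriptors.MolWt(parent)


def toxcast_label(hitc_cis_up, hitc_trans_up) -> Optional[int]:
    """Merge the two ToxCast PXR assay hit calls into one binary label.

    A compound is an activator only when both the cis and trans reporter
    assays called a hit (1, 1), a non-activator only when both called no hit
    (0, 0); disagreement is inconclusive and returns ``None``.
    """
    pair = (int(hitc_cis_up), int(hitc_trans_up))
    if pair == (1, 1):
        return ACTIVATOR
    if pair == (0, 0):
        return NON_ACTIVATOR
    return None


def apply_filters(
    records: Sequence[MoleculeRecord],
    min_mw: float = 200.0,
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
) -> tuple[list[MoleculeRecord], list[tuple[str, int]]]:
    """Apply the weight and element filters; counts attribute each removal to
    the first filter that fires (weight before element)."""
    kept: list[MoleculeRecord] = []
    n_light = 0
    n_element = 0
    for rec in records:
        if rec.mw < min_mw:
            n_light += 1
            continue
        mol = Chem.MolFromSmiles(rec.smiles_std)
        symbols = {a.GetSymbol() for a in mol.GetAtoms()}
        if not symbols <= allowed_elements:
            n_element += 1
            continue
        kept.append(rec)
    return kept, [("below_min_mw", n_light), ("disallowed_element", n_element)]


def resolve_duplicates(
    records: Sequence[MoleculeRecord],
) -> tuple[list[MoleculeRecord], int, int]:
    """Collapse records sharing an InChI.

    Concordant groups keep one representative (first occurrence); groups with
    conflicting labels are removed entirely.  Returns
    ``(kept, n_contradicting, n_duplicates)``.
    """
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        groups.setdefault(rec.inchi, []).append(rec)
    kept: list[MoleculeRecord] = []
    seen: set[str] = set()
    n_contra = 0
    n_dup = 0
    for rec in records:
        if rec.inchi in seen:
            continue
        seen.add(rec.inchi)
        group = groups[rec.inchi]
        labels = {g.label for g in group}
        if len(labels) > 1:
            n_contra += len(group)
        else:
            kept.append(group[0])
            n_dup += len(group) - 1
    return kept, n_contra, n_dup


def remove_train_overlap(test: LabeledDataset, train: LabeledDataset) -> LabeledDataset:
    """Drop test records whose InChI occurs in the training set (order kept)."""
    train_inchis = set(train.inchis)
    return LabeledDataset(
        records=[r for r in test.records if r.inchi not in train_inchis],
        name=test.name,
    )


# ---------------------------------------------------------------------------
# raw-table dialects

_MISSING = "missing"
_INCONCLUSIVE = "inconclusive"

_TEXT_LABELS = {
    "active": ACTIVATOR,
    "activator": ACTIVATOR,
    "a": ACTIVATOR,
    "1": ACTIVATOR,
    "inactive": NON_ACTIVATOR,
    "non_activator": NON_ACTIVATOR,
    "non-activator": NON_ACTIVATOR,
    "n": NON_ACTIVATOR,
    "0": NON_ACTIVATOR,
}

DIALECTS = ("pubchem", "toxcast", "literature", "user", "reference")


def _extract_label(row: pd.Series, dialect: str):
    """Return 1/0, ``_INCONCLUSIVE``, ``_MISSING``, or None (reference sets)."""
    if dialect == "reference":
        return None
    if dialect == "toxcast":
        cis, trans = row.get("hitc_cis_up"), row.get("hitc_trans_up")
        if pd.isna(cis) or pd.isna(trans):
            return _MISSING
        label = toxcast_label(cis, trans)
        return _INCONCLUSIVE if label is None else label
    # pubchem / literature / user: one activity column
    col = "activity" if dialect == "pubchem" else "label"
    raw = row.get(col)
    if pd.isna(raw):
        return _MISSING
    text = str(raw).strip().lower()
    if text == "inconclusive":
        return _INCONCLUSIVE
    if text in _TEXT_LABELS:
        return _TEXT_LABELS[text]
    return _MISSING


def run_preprocessing(
    raw: pd.DataFrame,
    dialect: str = "user",
    min_mw: float = 200.0,
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
    name: str = "",
) -> tuple[LabeledDataset, FilterReport]:
    """Run the full filter cascade on a raw compound table.

    Expected columns: ``id``, ``smiles``, plus dialect-specific label columns
    (``activity`` for pubchem; ``hitc_cis_up``/``hitc_trans_up`` for toxcast;
    ``label`` for literature/user; none for reference).  Reference sets skip
    the weight and element filters.

    Returns the clean :class:`LabeledDataset` and a :class:`FilterReport`
    whose per-step counts conserve the initial record count.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")

    report = FilterReport(n_initial=len(raw))

    # 1. missing identifier / SMILES / label fields; 2. inconclusive labels
    n_missing = 0
    n_inconclusive = 0
    rows: list[tuple[str, str, Optional[int]]] = []
    for _, row in raw.iterrows():
        rid = row.get("id")
        smi = row.get("smiles")
        if pd.isna(rid) or str(rid).strip() == "" or pd.isna(smi) or str(smi).strip() == "":
            n_missing += 1
            continue
        label = _extract_label(row, dialect)
        if label == _MISSING:
            n_missing += 1
            continue
        if label == _INCONCLUSIVE:
            n_inconclusive += 1
            continue
        rows.append((str(rid), str(smi), label))
    report.steps.append(("missing_identifier_or_smiles", n_missing))
    report.steps.append(("inconclusive_activity", n_inconclusive))

    # 3. standardize; unparseable records get their own accounting row
    n_bad = 0
    records: list[MoleculeRecord] = []
    for rid, smi, label in rows:
        try:
            smiles_std, inchi, mw = standardize(smi)
        except StandardizationError:
            n_bad += 1
            continue
        records.append(MoleculeRecord(rid, smiles_std, inchi, label, mw))
    report.steps.append(("unparseable_smiles", n_bad))

    # 4./5. weight and element filters (skipped for reference sets)
    if dialect == "reference":
        report.steps.append(("below_min_mw", 0))
        report.steps.append(("disallowed_element", 0))
    else:
        records, filter_rows = apply_filters(records, min_mw, allowed_elements)
        report.steps.extend(filter_rows)

    # 6./7. contradicting labels, then duplicates
    records, n_contra, n_dup = resolve_duplicates(records)
    report.steps.append(("contradicting_labels", n_contra))
    report.steps.append(("duplicates", n_dup))

    dataset = LabeledDataset(records=records, name=name)
    report.n_final = len(dataset)
    report.n_activators = sum(1 for r in records if r.label == ACTIVATOR)
    report.n_non_activators = sum(1 for r in records if r.label == NON_ACTIVATOR)
    report.validate()
    return dataset, report


def dataset_from_frame(frame: pd.DataFrame, name: str = "") -> LabeledDataset:
    """Rebuild a :class:`LabeledDataset` from a frame written by
    :meth:`LabeledDataset.to_frame` (no re-standardization)."""
    records = [
        MoleculeRecord(
            str(row["id"]),
            row["smiles_std"],
            row["inchi"],
            None if pd.isna(row.get("label")) else int(row["label"]),
            float(row.get("mw", 0.0)),
        )
        for _, row in frame.iterrows()
    ]
    return LabeledDataset(records=records, name=name)
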