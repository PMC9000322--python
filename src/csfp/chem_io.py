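"""Molecule and activity-record I/O, standardization, and curation.

Covers reading/writing SMILES collections and ChEMBL-style activity tables,
structure standardization (largest organic fragment, neutralization, canonical
aromatic SMILES), and the high-confidence activity-data curation filters used
to assemble benchmark compound sets.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "ActivityRecord",
    "SmilesParseError",
    "ValidationError",
    "standardize",
    "canonical_smiles",
    "curate_activity_records",
    "read_smiles",
    "write_smiles",
    "read_molecule_table",
    "read_activity_table",
    "write_activity_table",
    "generate_fixture_series",
]

#: activity annotations that disqualify a record
EXCLUDED_FLAGS = frozenset(
    {"inactive", "not active", "inconclusive", "potential transcription error"}
)

#: accepted potency measurement types
ACCEPTED_STANDARD_TYPES = frozenset({"Ki", "IC50", "Kd"})


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


class ValidationError(ValueError):
    """Raised when a record is missing or violates a required field."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule with stable identifier and optional class label."""

    id: str
    smiles: str
    mol: Chem.Mol = field(compare=False, repr=False)
    activity_class: str | None = None


@dataclass(frozen=True)
class ActivityRecord:
    """One ChEMBL-style compound-target activity measurement (potency in nM)."""

    compound_id: str
    smiles: str
    target_id: str
    standard_type: str
    standard_relation: str
    standard_value_nM: float | None
    confidence_score: int
    flags: frozenset[str] = frozenset()
    mol_weight_Da: float | None = None

    def __post_init__(self):
        if self.standard_value_nM is not None and self.standard_value_nM <= 0:
            raise ValidationError(
                f"record {self.compound_id}: standard_value_nM must be positive"
            )
        if not 0 <= self.confidence_score <= 9:
            raise ValidationError(
                f"record {self.compound_id}: confidence_score must be in [0, 9]"
            )


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(smiles: str, mol_id: str = "", activity_class: str | None = None) -> MoleculeRecord:
    """Parse and standardize a SMILES string into a :class:`MoleculeRecord`.

    Standardization keeps the largest organic fragment (salt/solvent
    stripping), neutralizes charges where toolkit-standard, and perceives
    aromaticity; the stored SMILES is canonical and idempotent under
    re-standardization.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    mol = _LARGEST_FRAGMENT.choose(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    canon = Chem.MolToSmiles(mol)
    return MoleculeRecord(id=mol_id or canon, smiles=canon, mol=mol, activity_class=activity_class)


def canonical_smiles(smiles: str) -> str:
    """Canonical SMILES of the standardized structure."""
    return standardize(smiles).smiles


def curate_activity_records(
    records: Sequence[ActivityRecord],
    potency_cutoff_nM: float = 10_000.0,
    mw_cutoff_Da: float = 1_000.0,
    confidence_required: int = 9,
    keep_at_most_cutoff: bool = True,
    anti_target_ids: Iterable[str] = (),
    interference_filter: Callable[[ActivityRecord], bool] | None = None,
) -> list[ActivityRecord]:
    """Apply high-confidence curation filters to activity records.

    Keeps records with molecular weight below ``mw_cutoff_Da``, a direct
    target annotation (``confidence_score == confidence_required``), an exact
    potency (relation ``"="``) of type Ki/IC50/Kd at or below
    ``potency_cutoff_nM`` (set ``keep_at_most_cutoff=False`` to invert the
    potency direction), and none of the disqualifying activity flags.
    Anti-target removal and assay-interference filtering are pluggable:
    ``anti_target_ids`` is an id blacklist, ``interference_filter`` a predicate
    returning True for records to drop. Duplicates are collapsed per
    (compound, target), keeping the most potent measurement.
    """
    if potency_cutoff_nM <= 0 or mw_cutoff_Da <= 0:
        raise ValueError("cutoffs must be positive")
    anti_targets = frozenset(anti_target_ids)

    kept: dict[tuple[str, str], ActivityRecord] = {}
    for rec in records:
        for fname in ("compound_id", "smiles", "target_id", "standard_type", "standard_relation"):
            if not getattr(rec, fname):
                raise ValidationError(
                    f"record {rec.compound_id or '<missing id>'}: missing field {fname}"
                )
        if rec.mol_weight_Da is None or rec.standard_value_nM is None:
            raise ValidationError(f"record {rec.compound_id}: missing weight or potency")
        if rec.mol_weight_Da >= mw_cutoff_Da:
            continue
        if rec.confidence_score != confidence_required:
            continue
        if rec.standard_relation != "=":
            continue
        if rec.standard_type not in ACCEPTED_STANDARD_TYPES:
            continue
        potent_enough = rec.standard_value_nM <= potency_cutoff_nM
        if keep_at_most_cutoff != potent_enough:
            continue
        if {f.lower() for f in rec.flags} & EXCLUDED_FLAGS:
            continue
        if rec.target_id in anti_targets:
            continue
        if interference_filter is not None and interference_filter(rec):
            continue
        key = (rec.compound_id, rec.target_id)
        prev = kept.get(key)
        if prev is None or rec.standard_value_nM < prev.standard_value_nM:
            kept[key] = rec
    return list(kept.values())


# ---------------------------------------------------------------------------
# file I/O (gzip-transparent)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_smiles(path: str | Path, standardize_mols: bool = True) -> list[MoleculeRecord]:
    """Read a .smi file (one ``SMILES [id]`` per line; '#' comments allowed)."""
    records = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{i}"
            if standardize_mols:
                records.append(standardize(smi, mol_id=mol_id))
            else:
                mol = Chem.MolFromSmiles(smi)
                if mol is None:
                    raise SmilesParseError(smi)
                records.append(MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol), mol=mol))
    return records


def write_smiles(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")


def read_molecule_table(path: str | Path, sep: str | None = None) -> list[MoleculeRecord]:
    """Read a CSV/TSV with columns ``id``, ``smiles`` [, ``activity_class``]."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = {"id", "smiles"} - set(df.columns)
    if missing:
        raise ValidationError(f"molecule table missing columns: {sorted(missing)}")
    has_class = "activity_class" in df.columns
    return [
        standardize(
            row.smiles,
            mol_id=str(row.id),
            activity_class=str(row.activity_class) if has_class and pd.notna(row.activity_class) else None,
        )
        for row in df.itertuples()
    ]


_ACTIVITY_COLUMNS = [
    "compound_id",
    "smiles",
    "target_id",
    "standard_type",
    "standard_relation",
    "standard_value_nM",
    "confidence_score",
    "flags",
    "mol_weight_Da",
]


def read_activity_table(path: str | Path, sep: str | None = None) -> list[ActivityRecord]:
    """Read an activity table (CSV/TSV); ``flags`` is a semicolon-joined list."""
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = set(_ACTIVITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"activity table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        flags = frozenset(
            f.strip() for f in str(row.flags).split(";") if f.strip()
        ) if pd.notna(row.flags) and str(row.flags) else frozenset()
        records.append(
            ActivityRecord(
                compound_id=str(row.compound_id),
                smiles=str(row.smiles),
                target_id=str(row.target_id),
                standard_type=str(row.standard_type),
                standard_relation=str(row.standard_relation),
                standard_value_nM=float(row.standard_value_nM) if pd.notna(row.standard_value_nM) else None,
                confidence_score=int(row.confidence_score),
                flags=flags,
                mol_weight_Da=float(row.mol_weight_Da) if pd.notna(row.mol_weight_Da) else None,
            )
        )
    return records


def write_activity_table(records: Iterable[ActivityRecord], path: str | Path, sep: str = "\t") -> None:
    rows = []
    for rec in records:
        row = {c: getattr(rec, c) for c in _ACTIVITY_COLUMNS}
        row["flags"] = ";".join(sorted(rec.flags))
        rows.append(row)
    pd.DataFrame(rows, columns=_ACTIVITY_COLUMNS).to_csv(path, sep=sep, index=False)


# fixture generation lives in csfp.fixtures; re-exported here as part of the
# I/O surface so every pipeline stage is testable without external data
from .fixtures import generate_fixture_series  # noqa: E402
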