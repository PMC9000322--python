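"""Analogue-series extraction by systematic exocyclic-bond fragmentation.

Compounds are fragmented at every combination of 1-5 exocyclic single bonds
(acyclic single bonds between heavy atoms). A cut is admitted when it splits
the molecule into one ring-containing core plus substituents with a single
attachment point each, and the core is at least twice the combined substituent
size (heavy atoms). Cores are generalized by hydrogen-capping their
substitution sites; compounds sharing a generalized core form an analogue
series.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from rdkit import Chem

from .chem_io import MoleculeRecord

__all__ = [
    "FragmentationCut",
    "CoreStructure",
    "CapacityError",
    "exocyclic_single_bonds",
    "enumerate_cuts",
    "generalize_core",
    "recombine",
    "build_analogue_series",
]


class CapacityError(RuntimeError):
    """Raised when a molecule has too many cuttable bonds to enumerate."""


@dataclass(frozen=True)
class FragmentationCut:
    """One admitted fragmentation: a core plus single-attachment substituents.

    ``core_smiles`` keeps isotope-labeled attachment dummies so the cut can be
    recombined; ``core_generalized`` is the hydrogen-capped canonical core.
    """

    bond_indices: frozenset[int]
    core_smiles: str
    substituent_smiles: tuple[str, ...]
    core_generalized: str


@dataclass(frozen=True)
class CoreStructure:
    """A generalized core shared by one or more compounds."""

    smiles: str
    member_ids: tuple[str, ...]
    contains_ring: bool

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def _as_mol(mol: MoleculeRecord | Chem.Mol) -> Chem.Mol:
    return mol.mol if isinstance(mol, MoleculeRecord) else mol


def exocyclic_single_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of acyclic single bonds between heavy atoms (never bonds to H)."""
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if not b.IsInRing()
        and b.GetBondType() == Chem.BondType.SINGLE
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]


def _heavy_atoms(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _n_dummies(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def generalize_core(core_smiles: str) -> str:
    """Hydrogen-cap the attachment dummies of a core and canonicalize."""
    mol = Chem.MolFromSmiles(core_smiles)
    if mol is None:
        raise ValueError(f"invalid core SMILES: {core_smiles!r}")
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
            atom.SetAtomMapNum(0)
    capped = Chem.RemoveHs(rw.GetMol())
    Chem.SanitizeMol(capped)
    return Chem.MolToSmiles(capped)


def enumerate_cuts(
    mol: MoleculeRecord | Chem.Mol,
    max_cuts: int = 5,
    ratio: float = 2.0,
    max_exocyclic_bonds: int = 25,
) -> list[FragmentationCut]:
    """Enumerate all admitted fragmentations of up to ``max_cuts`` bonds.

    A combination of cut bonds is admitted when exactly one fragment — the
    core — contains a ring and every other fragment keeps a single attachment
    point, with core heavy atoms >= ``ratio`` x combined substituent heavy
    atoms. Molecules without rings yield no cuts. Raises
    :class:`CapacityError` when the number of cuttable bonds exceeds
    ``max_exocyclic_bonds`` (combinatorial guard).
    """
    m = _as_mol(mol)
    if m.GetRingInfo().NumRings() == 0:
        return []
    bonds = exocyclic_single_bonds(m)
    if len(bonds) > max_exocyclic_bonds:
        raise CapacityError(
            f"{len(bonds)} exocyclic bonds exceeds cap of {max_exocyclic_bonds}"
        )
    cuts: list[FragmentationCut] = []
    for k in range(1, min(max_cuts, len(bonds)) + 1):
        for combo in combinations(bonds, k):
            labels = [(i + 1, i + 1) for i in range(k)]
            fragmented = Chem.FragmentOnBonds(
                m, list(combo), addDummies=True, dummyLabels=labels
            )
            pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=False)
            for piece in pieces:
                piece.UpdatePropertyCache(strict=False)
                Chem.FastFindRings(piece)
            # core candidates: ring-containing fragments whose removal leaves
            # only single-attachment substituents
            for core_idx, core in enumerate(pieces):
                if core.GetRingInfo().NumRings() == 0:
                    continue
                others = [p for i, p in enumerate(pieces) if i != core_idx]
                if any(_n_dummies(p) != 1 for p in others):
                    continue
                core_heavy = _heavy_atoms(core)
                sub_heavy = sum(_heavy_atoms(p) for p in others)
                if core_heavy < ratio * sub_heavy:
                    continue
                cuts.append(
                    FragmentationCut(
                        bond_indices=frozenset(combo),
                        core_smiles=Chem.MolToSmiles(core),
                        substituent_smiles=tuple(
                            sorted(Chem.MolToSmiles(p) for p in others)
                        ),
                        core_generalized=generalize_core(Chem.MolToSmiles(core)),
                    )
                )
    return cuts


def recombine(cut: FragmentationCut) -> str:
    """Rejoin a cut's core and substituents; canonical SMILES of the parent.

    Round-trip oracle: for any admitted cut of molecule M,
    ``recombine(cut) == canonical(M)``.
    """
    combined = Chem.MolFromSmiles(cut.core_smiles)
    for sub in cut.substituent_smiles:
        combined = Chem.CombineMols(combined, Chem.MolFromSmiles(sub))
    params = Chem.MolzipParams()
    params.label = Chem.MolzipLabel.Isotope
    rejoined = Chem.molzip(combined, params)
    Chem.SanitizeMol(rejoined)
    return Chem.MolToSmiles(rejoined)


def compound_cores(
    mol: MoleculeRecord | Chem.Mol,
    max_cuts: int = 5,
    ratio: float = 2.0,
    largest_only: bool = False,
    max_exocyclic_bonds: int = 25,
) -> list[str]:
    """Unique generalized cores of one compound (optionally only the largest).

    A compound whose scaffold needs no cutting (no exocyclic bonds) is its own
    core.
    """
    m = _as_mol(mol)
    if m.GetRingInfo().NumRings() == 0:
        return []
    cores = {
        c.core_generalized
        for c in enumerate_cuts(m, max_cuts=max_cuts, ratio=ratio,
                                max_exocyclic_bonds=max_exocyclic_bonds)
    }
    if not exocyclic_single_bonds(m):
        cores.add(Chem.MolToSmiles(m))
    if largest_only and cores:
        best = max(
            sorted(cores),
            key=lambda s: _heavy_atoms(Chem.MolFromSmiles(s)),
        )
        return [best]
    return sorted(cores)


def build_analogue_series(
    mols: Sequence[MoleculeRecord],
    max_cuts: int = 5,
    ratio: float = 2.0,
    min_members: int = 2,
    largest_only: bool = False,
    max_exocyclic_bonds: int = 25,
) -> list[CoreStructure]:
    """Group compounds by shared generalized core into analogue series.

    Returns ring-containing cores with at least ``min_members`` distinct
    member compounds, sorted by descending membership then core SMILES.
    Membership is invariant under input order.
    """
    members: dict[str, set[str]] = defaultdict(set)
    for rec in mols:
        for core in compound_cores(
            rec, max_cuts=max_cuts, ratio=ratio, largest_only=largest_only,
            max_exocyclic_bonds=max_exocyclic_bonds,
        ):
            members[core].add(rec.id)
    series = [
        CoreStructure(smiles=core, member_ids=tuple(sorted(ids)), contains_ring=True)
        for core, ids in members.items()
        if len(ids) >= min_members
    ]
    series.sort(key=lambda c: (-c.n_members, c.smiles))
    return series
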