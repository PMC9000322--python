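"""Core-substituent fingerprint assembly, computation, and similarity.

The fingerprint is keyed: each bit position corresponds 1:1 to one fragment —
by default the 250 most frequent single rings, 250 most frequent fused rings,
and 500 most frequent substituents (1000 bits; rings in the first half,
substituents in the second). Substructure relationships between recorded
fragments are precomputed as a closure map: a matched fused ring also sets the
bits of its recorded decomposition rings, and a matched substituent sets the
bits of recorded substituents contained within it. This guarantees a minimum
bit density for meaningful Tanimoto comparison despite the deliberately small
feature count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord
from .core_extraction import enumerate_cuts, exocyclic_single_bonds
from .ring_fragmentation import (
    RingFragment,
    decompose_fused,
    extract_ring_systems,
    merge_fragments,
)
from .substituent_library import (
    SubstituentFragment,
    harvest_substituents,
    select_top,
)

__all__ = [
    "FragmentLibrary",
    "CSFPBitvector",
    "assemble_library",
    "build_library_from_molecules",
    "compute_csfp",
    "compute_matrix",
    "tanimoto",
    "feature_count",
    "bit_density",
]


@dataclass
class CSFPBitvector:
    """A computed fingerprint with per-bit provenance.

    ``provenance`` maps each set bit to ``(fragment_pattern, how)`` where
    ``how`` is ``"direct"`` (fragment matched the molecule) or ``"closure"``
    (set through a matched ancestor fragment).
    """

    bits: np.ndarray
    provenance: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bits)


class FragmentLibrary:
    """Ordered fragment catalog defining the fingerprint's bit positions."""

    def __init__(
        self,
        single_rings: Sequence[RingFragment],
        fused_rings: Sequence[RingFragment],
        substituents: Sequence[SubstituentFragment],
        closure: dict[str, frozenset[str]] | None = None,
        metadata: dict | None = None,
    ):
        self.single_rings = list(single_rings)
        self.fused_rings = list(fused_rings)
        self.substituents = list(substituents)
        self.fragments = self.single_rings + self.fused_rings + list(self.substituents)
        patterns = [f.pattern for f in self.fragments]
        if len(set(patterns)) != len(patterns):
            raise ValueError("duplicate fragment patterns in library")
        self.bit_index: dict[str, int] = {p: i for i, p in enumerate(patterns)}
        self.closure: dict[str, frozenset[str]] = closure if closure is not None else {}
        self.metadata = metadata or {}
        self._queries = None

    @property
    def n_bits(self) -> int:
        return len(self.fragments)

    def _compiled(self):
        if self._queries is None:
            self._queries = [
                (i, frag.query, frag.pattern) for i, frag in enumerate(self.fragments)
            ]
        return self._queries

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "single_rings": [
                {
                    "pattern": f.pattern,
                    "kind": f.kind,
                    "is_model_fragment": f.is_model_fragment,
                    "frequency": f.frequency,
                    "exemplar": f.exemplar,
                }
                for f in self.single_rings
            ],
            "fused_rings": [
                {
                    "pattern": f.pattern,
                    "kind": f.kind,
                    "is_model_fragment": f.is_model_fragment,
                    "frequency": f.frequency,
                    "exemplar": f.exemplar,
                }
                for f in self.fused_rings
            ],
            "substituents": [
                {"pattern": f.pattern, "frequency": f.frequency, "source": f.source}
                for f in self.substituents
            ],
            "closure": {k: sorted(v) for k, v in self.closure.items()},
            "metadata": self.metadata,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "FragmentLibrary":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        singles = [RingFragment(**d) for d in payload["single_rings"]]
        fused = [RingFragment(**d) for d in payload["fused_rings"]]
        subs = [SubstituentFragment(**d) for d in payload["substituents"]]
        closure = {k: frozenset(v) for k, v in payload["closure"].items()}
        return cls(singles, fused, subs, closure=closure, metadata=payload.get("metadata", {}))


def _heavy(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _substituent_closure(subs: Sequence[SubstituentFragment]) -> dict[str, set[str]]:
    """Containment edges among substituents (strictly smaller ⊂ larger)."""
    exemplars = [(f.pattern, f.exemplar, f.query) for f in subs]
    sizes = {p: _heavy(ex) for p, ex, _ in exemplars}
    edges: dict[str, set[str]] = {p: set() for p, _, _ in exemplars}
    for pat_a, ex_a, _ in exemplars:
        for pat_b, _, q_b in exemplars:
            if sizes[pat_b] >= sizes[pat_a]:
                continue
            if ex_a.HasSubstructMatch(q_b):
                edges[pat_a].add(pat_b)
    # transitive closure, propagating small-to-large
    for pat in sorted(edges, key=lambda p: sizes[p]):
        expanded = set(edges[pat])
        for child in edges[pat]:
            expanded |= edges[child]
        edges[pat] = expanded
    return edges


def _ring_closure(
    singles: Sequence[RingFragment],
    fused: Sequence[RingFragment],
    fused_to_fused: bool = False,
) -> dict[str, set[str]]:
    """Decomposition edges from fused systems to recorded single rings.

    With ``fused_to_fused`` also links a fused system to smaller recorded
    fused systems it contains (off by default).
    """
    single_patterns = {f.pattern for f in singles}
    edges: dict[str, set[str]] = {}
    for frag in fused:
        products = {p.pattern for p in decompose_fused(frag)}
        edges[frag.pattern] = products & single_patterns
    if fused_to_fused:
        by_size = {f.pattern: _heavy(f.mol) for f in fused}
        for frag in fused:
            target = frag.mol
            for other in fused:
                if other.pattern == frag.pattern or by_size[other.pattern] >= by_size[frag.pattern]:
                    continue
                if target.HasSubstructMatch(other.query):
                    edges[frag.pattern].add(other.pattern)
                    edges[frag.pattern] |= edges.get(other.pattern, set())
    return edges


def assemble_library(
    rings_single: Sequence[RingFragment],
    rings_fused: Sequence[RingFragment],
    substituents: Sequence[SubstituentFragment],
    n_single: int = 250,
    n_fused: int = 250,
    n_subs: int = 500,
    fused_to_fused_closure: bool = False,
    metadata: dict | None = None,
) -> FragmentLibrary:
    """Select top fragments per category and precompute the closure map.

    Bit positions are assigned in catalog order: single rings, fused rings,
    then substituents, frequency-ranked within each category. Raises on an
    empty category.
    """
    if not rings_single or not rings_fused or not substituents:
        raise ValueError("every fragment category must be non-empty")
    singles = select_top(merge_fragments(rings_single), n_single)
    fused = select_top(merge_fragments(rings_fused), n_fused)
    sub_merged: dict[str, SubstituentFragment] = {}
    for f in substituents:
        prev = sub_merged.get(f.pattern)
        sub_merged[f.pattern] = (
            f if prev is None else replace(prev, frequency=prev.frequency + f.frequency)
        )
    subs = select_top(list(sub_merged.values()), n_subs)

    closure: dict[str, frozenset[str]] = {}
    for pattern, targets in _ring_closure(singles, fused, fused_to_fused_closure).items():
        if targets:
            closure[pattern] = frozenset(targets)
    for pattern, targets in _substituent_closure(subs).items():
        if targets:
            closure[pattern] = frozenset(targets)

    meta = {
        "quotas": {"single": n_single, "fused": n_fused, "substituents": n_subs},
        "selected": {"single": len(singles), "fused": len(fused), "substituents": len(subs)},
    }
    if metadata:
        meta.update(metadata)
    return FragmentLibrary(singles, fused, subs, closure=closure, metadata=meta)


def build_library_from_molecules(
    mols: Sequence[MoleculeRecord],
    n_single: int = 250,
    n_fused: int = 250,
    n_subs: int = 500,
    max_cuts: int = 5,
    ratio: float = 2.0,
    min_members: int = 2,
    retro_cutter="default",
    max_exocyclic_bonds: int = 25,
) -> FragmentLibrary:
    """Run the full library pipeline on a compound collection.

    Analogue-series cores are extracted by systematic fragmentation, their
    ring systems decomposed into fused and single (model) ring fragments with
    frequencies weighted by series membership, and substituents harvested from
    the same cuts plus the retrosynthetic cutter.
    """
    from .substituent_library import brics_substituents

    cuts_per_mol = [
        enumerate_cuts(rec.mol, max_cuts=max_cuts, ratio=ratio,
                       max_exocyclic_bonds=max_exocyclic_bonds)
        for rec in mols
    ]
    members: dict[str, set[str]] = {}
    for rec, cuts in zip(mols, cuts_per_mol):
        cores = {c.core_generalized for c in cuts}
        if rec.mol.GetRingInfo().NumRings() > 0 and not exocyclic_single_bonds(rec.mol):
            cores.add(rec.smiles)
        for core in cores:
            members.setdefault(core, set()).add(rec.id)

    singles: list[RingFragment] = []
    fused: list[RingFragment] = []
    for core, ids in sorted(members.items()):
        if len(ids) < min_members:
            continue
        weight = len(ids)
        for frag in extract_ring_systems(core):
            frag = replace(frag, frequency=weight)
            if frag.kind == "fused":
                fused.append(frag)
                singles.extend(decompose_fused(frag))
            else:
                singles.append(frag)

    cutter = brics_substituents if retro_cutter == "default" else retro_cutter
    subs = harvest_substituents(mols, cuts_per_mol, retro_cutter=cutter)

    return assemble_library(
        singles, fused, subs, n_single=n_single, n_fused=n_fused, n_subs=n_subs,
        metadata={"n_compounds": len(mols), "n_series_cores": sum(
            1 for ids in members.values() if len(ids) >= min_members)},
    )


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, MoleculeRecord):
        return mol.mol
    if isinstance(mol, Chem.Mol):
        return mol
    parsed = Chem.MolFromSmiles(mol)
    if parsed is None:
        raise ValueError(f"unparseable SMILES: {mol!r}")
    return parsed


def compute_csfp(mol, lib: FragmentLibrary) -> CSFPBitvector:
    """Compute the fingerprint of one molecule against a library.

    Every library fragment matching the molecule as a substructure sets its
    bit; all closure descendants of matched fragments are set as well. Bits
    are binary. A molecule matching nothing yields the all-zero vector.
    """
    target = _as_mol(mol)
    bits = np.zeros(lib.n_bits, dtype=np.uint8)
    provenance: dict[int, tuple[str, str]] = {}
    closure_hits: list[str] = []
    for i, query, pattern in lib._compiled():
        if target.HasSubstructMatch(query):
            bits[i] = 1
            provenance[i] = (pattern, "direct")
            closure_hits.extend(lib.closure.get(pattern, ()))
    for pattern in closure_hits:
        i = lib.bit_index[pattern]
        if not bits[i]:
            bits[i] = 1
            provenance[i] = (pattern, "closure")
    return CSFPBitvector(bits=bits, provenance=provenance)


def compute_matrix(mols: Iterable, lib: FragmentLibrary) -> np.ndarray:
    """Fingerprint matrix (n_molecules x n_bits, uint8)."""
    rows = [compute_csfp(m, lib).bits for m in mols]
    if not rows:
        return np.zeros((0, lib.n_bits), dtype=np.uint8)
    return np.vstack(rows)


def _bits_of(v) -> np.ndarray:
    return v.bits if isinstance(v, CSFPBitvector) else np.asarray(v)


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a ∧ b| / |a ∨ b|; 0 when both vectors are zero."""
    va, vb = _bits_of(a).astype(bool), _bits_of(b).astype(bool)
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: {va.shape} vs {vb.shape}")
    union = np.logical_or(va, vb).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(va, vb).sum() / union)


def feature_count(v) -> int:
    """Number of bits set on."""
    return int(_bits_of(v).astype(bool).sum())


def bit_density(v) -> float:
    """Percentage of bits set on."""
    bits = _bits_of(v)
    return 100.0 * feature_count(v) / len(bits)
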