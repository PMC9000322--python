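"""Ring-system decomposition with retained hybridization states.

Cores are split into ring systems by deleting every acyclic bond and atom:
connected components of the remaining ring skeleton are emitted as fused
systems (>= 2 rings sharing a bond or atom) or single rings. Fused systems are
further decomposed into their smallest-set-of-smallest-rings members. A single
ring cut from a fused system keeps the aromaticity and bond orders its atoms
had in the fused context, so its pattern re-matches that ring inside larger
ring systems — even when the combination of states could not exist as an
isolated molecule ("model fragments", e.g. the partially aromatic five-ring of
indane).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from rdkit import Chem

from ._patterns import compile_query, fragment_smarts, mol_from_flagged_smiles

__all__ = [
    "RingFragment",
    "extract_ring_systems",
    "decompose_fused",
    "merge_fragments",
]


@dataclass(frozen=True)
class RingFragment:
    """A single or fused ring pattern with state-preserving SMARTS.

    ``pattern`` is the substructure query; ``exemplar`` a (possibly
    non-sanitizable) SMILES snapshot of the fragment used to rebuild a concrete
    molecule for decomposition and closure computation. ``is_model_fragment``
    marks decomposition products whose retained electronic state (aromaticity
    or multiple bonds) differs from the perception of their bare sigma
    skeleton, i.e. rings that could not exist in isolation with these states.
    """

    pattern: str
    kind: str  # "single" | "fused"
    is_model_fragment: bool
    frequency: int = 0
    exemplar: str = ""

    def __post_init__(self):
        if self.kind not in ("single", "fused"):
            raise ValueError(f"kind must be 'single' or 'fused', got {self.kind!r}")

    @property
    def query(self) -> Chem.Mol:
        return compile_query(self.pattern)

    @property
    def mol(self) -> Chem.Mol:
        if not self.exemplar:
            raise ValueError("fragment has no exemplar")
        return mol_from_flagged_smiles(self.exemplar)


def _subfragment(parent: Chem.Mol, atoms: Sequence[int], bonds: Sequence[int]) -> Chem.Mol:
    """Copy a subgraph of ``parent`` keeping atom states; no sanitization."""
    rw = Chem.RWMol()
    amap: dict[int, int] = {}
    for idx in atoms:
        src = parent.GetAtomWithIdx(idx)
        atom = Chem.Atom(src.GetAtomicNum())
        atom.SetIsAromatic(src.GetIsAromatic())
        atom.SetFormalCharge(src.GetFormalCharge())
        amap[idx] = rw.AddAtom(atom)
    for bidx in bonds:
        bond = parent.GetBondWithIdx(bidx)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        rw.AddBond(amap[i], amap[j], bond.GetBondType())
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def _fragment_from_subgraph(
    parent: Chem.Mol,
    atoms: Sequence[int],
    bonds: Sequence[int],
    kind: str,
    is_model: bool,
    frequency: int = 1,
) -> RingFragment:
    sub = _subfragment(parent, atoms, bonds)
    return RingFragment(
        pattern=fragment_smarts(sub),
        kind=kind,
        is_model_fragment=is_model,
        frequency=frequency,
        exemplar=Chem.MolToSmiles(sub, canonical=True),
    )


def _resolve_core(core) -> Chem.Mol:
    # accepts CoreStructure, SMILES, or Mol
    if isinstance(core, Chem.Mol):
        return core
    smiles = getattr(core, "smiles", core)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid core SMILES: {smiles!r}")
    return mol


def extract_ring_systems(core, spiro_is_fused: bool = True) -> list[RingFragment]:
    """Split a core into its ring systems (fused and single ring fragments).

    Deleting all acyclic bonds and atoms leaves connected components of the
    ring skeleton; components spanning >= 2 rings are fused, the rest single.
    With ``spiro_is_fused=False``, components connected only through a shared
    spiro atom are split into their individual rings. Raises on ring-free
    cores.
    """
    mol = _resolve_core(core)
    ring_info = mol.GetRingInfo()
    if ring_info.NumRings() == 0:
        raise ValueError("core contains no rings; filter ring-free cores upstream")

    ring_bond_ids = [b.GetIdx() for b in mol.GetBonds() if b.IsInRing()]
    # connected components over ring bonds
    parent_of: dict[int, int] = {}

    def find(x: int) -> int:
        while parent_of.get(x, x) != x:
            parent_of[x] = parent_of.get(parent_of[x], parent_of[x])
            x = parent_of[x]
        return x

    def union(a: int, b: int) -> None:
        parent_of.setdefault(a, a)
        parent_of.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_of[rb] = ra

    if spiro_is_fused:
        for bidx in ring_bond_ids:
            bond = mol.GetBondWithIdx(bidx)
            union(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        components: dict[int, set[int]] = {}
        for bidx in ring_bond_ids:
            bond = mol.GetBondWithIdx(bidx)
            root = find(bond.GetBeginAtomIdx())
            components.setdefault(root, set()).add(bidx)
        bond_groups = list(components.values())
    else:
        # union rings, joining two rings only when they share a bond
        ring_bonds = [set(r) for r in ring_info.BondRings()]
        n = len(ring_bonds)
        for i in range(n):
            parent_of.setdefault(i, i)
            for j in range(i + 1, n):
                if ring_bonds[i] & ring_bonds[j]:
                    union(i, j)
        grouped: dict[int, set[int]] = {}
        for i in range(n):
            grouped.setdefault(find(i), set()).update(ring_bonds[i])
        bond_groups = list(grouped.values())

    fragments = []
    for bonds in bond_groups:
        atoms = sorted(
            {
                a
                for bidx in bonds
                for a in (
                    mol.GetBondWithIdx(bidx).GetBeginAtomIdx(),
                    mol.GetBondWithIdx(bidx).GetEndAtomIdx(),
                )
            }
        )
        n_rings = sum(1 for ring in ring_info.BondRings() if set(ring) <= set(bonds))
        kind = "fused" if n_rings >= 2 else "single"
        fragments.append(
            _fragment_from_subgraph(mol, atoms, sorted(bonds), kind, is_model=False)
        )
    fragments.sort(key=lambda f: f.pattern)
    return fragments


def _skeleton_differs(fragment_mol: Chem.Mol) -> bool:
    """True when retained states differ from the bare sigma-skeleton perception.

    The sigma skeleton of a ring (same atoms, all bonds single, no aromaticity)
    perceives as a saturated ring; any retained aromatic atom or multiple bond
    therefore marks the fragment as a model fragment.
    """
    if any(a.GetIsAromatic() for a in fragment_mol.GetAtoms()):
        return True
    return any(
        b.GetBondType() != Chem.BondType.SINGLE for b in fragment_mol.GetBonds()
    )


def decompose_fused(fused: RingFragment) -> list[RingFragment]:
    """Decompose a fused system into its SSSR single-ring fragments.

    Each product keeps the aromaticity/bond orders of its atoms as they were
    in the fused context, so its pattern matches that ring inside the parent
    system. Exactly one fragment per SSSR ring is returned.
    """
    if fused.kind != "fused":
        raise ValueError("decompose_fused expects a fused ring fragment")
    mol = fused.mol
    ring_info = mol.GetRingInfo()
    fragments = []
    for atom_ring, bond_ring in zip(ring_info.AtomRings(), ring_info.BondRings()):
        sub = _subfragment(mol, sorted(atom_ring), sorted(bond_ring))
        fragments.append(
            RingFragment(
                pattern=fragment_smarts(sub),
                kind="single",
                is_model_fragment=_skeleton_differs(sub),
                frequency=fused.frequency,
                exemplar=Chem.MolToSmiles(sub, canonical=True),
            )
        )
    fragments.sort(key=lambda f: f.pattern)
    return fragments


def merge_fragments(fragments: Iterable[RingFragment]) -> list[RingFragment]:
    """Merge fragments with identical patterns, summing frequencies.

    A pattern that ever occurs as a chemically intact ring is not flagged as a
    model fragment in the merged catalog.
    """
    merged: dict[str, RingFragment] = {}
    for frag in fragments:
        prev = merged.get(frag.pattern)
        if prev is None:
            merged[frag.pattern] = frag
        else:
            merged[frag.pattern] = replace(
                prev,
                frequency=prev.frequency + frag.frequency,
                is_model_fragment=prev.is_model_fragment and frag.is_model_fragment,
            )
    return sorted(merged.values(), key=lambda f: (-f.frequency, f.pattern))
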