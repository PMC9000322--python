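"""Frequency-ranked substituent catalog built from fragmentation products.

Substituents are single-attachment fragments harvested from two sources:
systematic exocyclic-bond cuts (the same cuts that define analogue-series
cores) and a pluggable retrosynthetic cutter (BRICS bond rules by default).
Hydrogen and the unsubstituted benzene ring are excluded — benzene is only
permitted as a ring fragment, which avoids ambiguous ring/substituent
assignments. Duplicates are merged by canonical pattern with frequencies
summed across sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import BRICS

from ._patterns import compile_query, fragment_smarts

__all__ = [
    "SubstituentFragment",
    "harvest_substituents",
    "select_top",
    "brics_substituents",
    "is_excluded_substituent",
    "normalize_substituent",
    "substituent_smarts",
]

_BENZENE_CANON = Chem.MolToSmiles(Chem.MolFromSmiles("c1ccccc1"))


@dataclass(frozen=True)
class SubstituentFragment:
    """An R-group pattern with exactly one attachment point.

    ``pattern`` is canonical SMILES with a ``*`` attachment atom; the matching
    query encodes per-atom H counts so interior atoms only match positions
    with the same substitution state.
    """

    pattern: str
    frequency: int = 0
    source: str = "random_cut"  # "random_cut" | "retrosynthetic"

    @property
    def smarts(self) -> str:
        return substituent_smarts(self.pattern)

    @property
    def query(self) -> Chem.Mol:
        return compile_query(self.smarts)

    @property
    def exemplar(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.pattern)


def normalize_substituent(smiles: str) -> str:
    """Canonical pattern with an unlabeled attachment dummy, or None-equivalent.

    Raises when the fragment does not have exactly one attachment point.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid substituent SMILES: {smiles!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(f"substituent must have exactly one attachment point: {smiles!r}")
    for atom in dummies:
        atom.SetIsotope(0)
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def is_excluded_substituent(pattern: str) -> bool:
    """True for bare hydrogen or the unsubstituted benzene ring."""
    mol = Chem.MolFromSmiles(pattern)
    if mol is None:
        return True
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() > 1 and a.GetAtomicNum() != 0]
    if not heavy:  # [*][H] or bare dummy
        return True
    if len(heavy) == 1 and heavy[0].GetAtomicNum() == 1:
        return True
    # benzene check: hydrogen-cap the attachment and compare
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
    try:
        capped = Chem.RemoveHs(rw.GetMol())
        Chem.SanitizeMol(capped)
    except Exception:
        return False
    return Chem.MolToSmiles(capped) == _BENZENE_CANON


def substituent_smarts(pattern: str) -> str:
    """State- and H-count-preserving SMARTS for a substituent pattern.

    The attachment dummy becomes a heavy-atom wildcard, so matching a
    substituent in a whole molecule requires an anchor atom outside the
    fragment (ring atoms may anchor).
    """
    mol = Chem.MolFromSmiles(pattern)
    if mol is None:
        raise ValueError(f"invalid substituent pattern: {pattern!r}")
    return fragment_smarts(mol, with_h_count=True)


def brics_substituents(mol: Chem.Mol) -> list[str]:
    """Substituent candidates from single cuts at BRICS retrosynthetic bonds."""
    out = []
    for (i, j), _labels in BRICS.FindBRICSBonds(mol):
        bond = mol.GetBondBetweenAtoms(i, j)
        if bond is None or bond.IsInRing():
            continue
        pieces = Chem.GetMolFrags(
            Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True,
                                 dummyLabels=[(0, 0)]),
            asMols=True,
            sanitizeFrags=True,
        )
        for piece in pieces:
            out.append(normalize_substituent(Chem.MolToSmiles(piece)))
    return out


def harvest_substituents(
    mols: Sequence,
    cuts_per_mol: Sequence[Sequence] | None = None,
    retro_cutter: Callable[[Chem.Mol], list[str]] | None = brics_substituents,
) -> list[SubstituentFragment]:
    """Collect substituent fragments with per-occurrence frequency counts.

    ``cuts_per_mol`` holds each molecule's admitted
    :class:`~csfp.core_extraction.FragmentationCut` list (the "random cut"
    source); only single-bond cuts contribute, so each substituent is counted
    once per occurrence rather than once per cut combination. ``retro_cutter``
    (default: BRICS rules) supplies the retrosynthetic source; pass ``None``
    to disable. Hydrogen and benzene are excluded; duplicates merge with
    frequencies summed across sources.
    """
    counts: dict[str, dict[str, int]] = {}

    def add(pattern: str, source: str) -> None:
        if is_excluded_substituent(pattern):
            return
        by_source = counts.setdefault(pattern, {})
        by_source[source] = by_source.get(source, 0) + 1

    if cuts_per_mol is not None:
        for cuts in cuts_per_mol:
            for cut in cuts:
                if len(cut.bond_indices) != 1:
                    continue
                for sub in cut.substituent_smiles:
                    add(normalize_substituent(sub), "random_cut")
    if retro_cutter is not None:
        for rec in mols:
            mol = rec.mol if hasattr(rec, "mol") else rec
            for sub in retro_cutter(mol):
                add(sub, "retrosynthetic")

    fragments = []
    for pattern, by_source in counts.items():
        source = "+".join(sorted(by_source)) if len(by_source) > 1 else next(iter(by_source))
        fragments.append(
            SubstituentFragment(
                pattern=pattern,
                frequency=sum(by_source.values()),
                source=source,
            )
        )
    return sorted(fragments, key=lambda f: (-f.frequency, f.pattern))


def select_top(fragments: Sequence, n: int) -> list:
    """Top-``n`` fragments by frequency; ties broken by pattern order.

    Works for ring and substituent fragments alike. When fewer than ``n``
    fragments are available, all are returned with a warning (the library is
    then smaller; callers record this in metadata).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(fragments, key=lambda f: (-f.frequency, f.pattern))
    if len(ordered) < n:
        warnings.warn(
            f"only {len(ordered)} fragments available, {n} requested; "
            "library will be smaller",
            stacklevel=2,
        )
        return ordered
    return ordered[:n]
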