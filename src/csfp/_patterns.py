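"""Internal helpers for writing state-preserving substructure patterns.

Fragment patterns must encode the electronic state atoms had in their parent
structure (aromatic vs aliphatic, bond orders), so that a ring cut out of a
fused system still matches that system even when the fragment could not exist
as an isolated molecule. We therefore emit SMARTS with explicit per-atom
element/aromaticity/charge primitives and explicit bond symbols instead of
plain SMILES.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from rdkit import Chem

_BOND_SYMBOL = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}

ATTACHMENT_QUERY = "[!#1]"  # attachment wildcard: any heavy atom


def atom_query(atom: Chem.Atom, with_h_count: bool = False) -> str:
    """SMARTS primitive for one atom, preserving its current state.

    Dummy atoms (attachment points) become a heavy-atom wildcard. H counts are
    encoded only for substituent fragments, where the fragment is a complete
    R-group and interior positions must not match further-substituted atoms.
    """
    if atom.GetAtomicNum() == 0:
        return ATTACHMENT_QUERY
    parts = [f"#{atom.GetAtomicNum()}", "a" if atom.GetIsAromatic() else "A"]
    if with_h_count:
        parts.append(f"H{atom.GetTotalNumHs()}")
    charge = atom.GetFormalCharge()
    if charge:
        parts.append(("+" if charge > 0 else "-") + str(abs(charge)))
    return "[" + ";".join(parts) + "]"


def fragment_smarts(
    mol: Chem.Mol,
    atoms: Sequence[int] | None = None,
    bonds: Iterable[int] | None = None,
    with_h_count: bool = False,
) -> str:
    """Canonical state-preserving SMARTS for a fragment of ``mol``.

    ``atoms``/``bonds`` restrict the pattern to a subgraph (defaults: whole
    molecule). Canonical output makes the string usable as a dictionary key.
    """
    if atoms is None:
        atoms = list(range(mol.GetNumAtoms()))
    atom_symbols = [atom_query(a, with_h_count=with_h_count) for a in mol.GetAtoms()]
    bond_symbols = [_BOND_SYMBOL[b.GetBondType()] for b in mol.GetBonds()]
    kwargs = {}
    if bonds is not None:
        kwargs["bondsToUse"] = list(bonds)
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=list(atoms),
        atomSymbols=atom_symbols,
        bondSymbols=bond_symbols,
        canonical=True,
        **kwargs,
    )


def compile_query(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ValueError(f"invalid fragment pattern: {pattern!r}")
    return query


def mol_from_flagged_smiles(smiles: str) -> Chem.Mol:
    """Rebuild a (possibly non-sanitizable) fragment exemplar from SMILES.

    Model ring fragments carry aromatic flags that are invalid for an isolated
    molecule, so sanitization is skipped and ring perception done directly.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ValueError(f"unparseable exemplar SMILES: {smiles!r}")
    mol.UpdatePropertyCache(strict=False)
    Chem.GetSSSR(mol)  # smallest-set-of-smallest-rings perception
    return mol
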