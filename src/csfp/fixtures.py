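"""Deterministic synthetic chemistry fixtures.

Every pipeline stage must be exercisable without external compound databases,
so this module generates:

* analogue series — sets of molecules sharing one ring-containing scaffold and
  differing only in R-groups drawn from a small pool, emulating the
  medicinal-chemistry series from which cores are sampled;
* background/decoy molecules built on a disjoint scaffold pool, emulating a
  random screening database;
* a combinatorial fragment catalog (single rings, fused rings, substituents)
  with synthetic frequency counts, large enough to assemble the full
  default-size fingerprint (250 + 250 + 500 fragments).

All generators are pure functions of their seed.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from ._patterns import fragment_smarts

__all__ = [
    "generate_fixture_series",
    "generate_background",
    "generate_fragment_catalog",
    "attach_rgroups",
]

# Scaffolds carry two numbered attachment points. The active pool seeds
# analogue series; the background pool uses different ring systems so decoys
# are structurally distinct from any fixture series.
ACTIVE_SCAFFOLDS = [
    "[*:1]c1ccc2nc([*:2])ccc2c1",
    "[*:1]c1ccc2[nH]c([*:2])cc2c1",
    "[*:1]c1ccc2nc([*:2])sc2c1",
    "[*:1]c1ccc2nc([*:2])oc2c1",
    "[*:1]c1ccc2ncnc([*:2])c2c1",
    "[*:1]c1cnc2ccccc2c1[*:2]",
    "[*:1]c1cc2c(cc1[*:2])OCO2",
    "[*:1]c1ccc2c(c1)CCN2C(=O)[*:2]",
    "[*:1]c1ccc2c(c1)nc([*:2])n2C",
    "[*:1]c1ccc2c(c1)CCC2[*:2]",
    "[*:1]c1ccc2c(c1)OCC(=O)N2[*:2]",
    "[*:1]C1Cc2ccccc2CN1C(=O)[*:2]",
    "[*:1]c1ccc(-c2nc([*:2])no2)cc1",
    "[*:1]c1ccc(N2CCN([*:2])CC2)cc1",
    "[*:1]c1ccc(S(=O)(=O)N2CCC([*:2])CC2)cc1",
    "[*:1]c1ccc(C(=O)N2CCN([*:2])CC2)cc1",
    "[*:1]c1cnc(N2CCOC([*:2])C2)nc1",
    "[*:1]c1nc2ccccc2n1CC(=O)N[*:2]",
    "[*:1]c1ccc(CNC(=O)c2ccc([*:2])nc2)cc1",
    "[*:1]c1nc([*:2])c2ccccc2n1",
    "[*:1]c1ccc2c(c1)oc1ccc([*:2])cc12",
    "[*:1]C1CCc2nc([*:2])sc2C1",
    "[*:1]c1ccc2c(c1)CCN(C(=O)C[*:2])C2",
    "[*:1]c1cc2ncncc2cc1[*:2]",
]

BACKGROUND_SCAFFOLDS = [
    "[*:1]c1ccco1",
    "[*:1]c1cccs1",
    "[*:1]c1cc[nH]c1",
    "[*:1]C1CCCO1",
    "[*:1]C1CCCCC1[*:2]",
    "[*:1]C1CCOC([*:2])C1",
    "[*:1]c1cc2ccccc2cc1[*:2]",
    "[*:1]N1CCOC([*:2])C1",
    "[*:1]c1nc2ccccc2s1",
    "[*:1]c1cnn([*:2])c1",
    "[*:1]c1ncc([*:2])o1",
    "[*:1]C1CC([*:2])C1",
    "[*:1]C1CCCN1[*:2]",
    "[*:1]c1cscc1[*:2]",
    "[*:1]C1COC([*:2])CN1",
    "[*:1]c1cc2c(cc1[*:2])OCCO2",
    "[*:1]C1CCCCCC1",
    "[*:1]c1cnc([*:2])nc1N",
]

RGROUP_POOL = [
    "C", "CC", "CCC", "C(C)C", "CO", "OC", "N", "NC", "O", "F", "Cl", "Br",
    "C#N", "C(=O)C", "C(=O)OC", "C(F)(F)F", "N(C)C", "OCC", "CCN", "CC#N",
    "S(C)(=O)(=O)", "OC(F)F",
]

# decoys carry their own R-group chemistry, disjoint from the series pool, so
# a random background is structurally distinct from any analogue series
BACKGROUND_RGROUPS = [
    "CCCC", "CCl", "CBr", "OCCC", "NCCC", "C(C)CC", "CCF", "COC", "CCCO",
    "NC(C)C", "SC", "CF", "C(C)O", "CC(C)C", "OCC(C)C", "C(=O)NC", "CCOC",
    "N(CC)CC", "CC(F)F", "SCC",
]


def attach_rgroups(scaffold: str, rgroups: dict[int, str]) -> str:
    """Attach R-group bodies to the numbered attachment points of a scaffold.

    ``rgroups`` maps attachment-map numbers to SMILES bodies (written from the
    attachment atom outward, e.g. ``"OC"`` for methoxy). Unfilled attachment
    points are hydrogen-capped. Returns canonical SMILES.
    """
    mol = Chem.MolFromSmiles(scaffold)
    if mol is None:
        raise ValueError(f"invalid scaffold: {scaffold!r}")
    combined = mol
    for mapno, body in rgroups.items():
        rg = Chem.MolFromSmiles(f"[*:{mapno}]{body}")
        if rg is None:
            raise ValueError(f"invalid R-group body: {body!r}")
        combined = Chem.CombineMols(combined, rg)
    zipped = Chem.RWMol(Chem.molzip(combined))
    # hydrogen-cap any attachment point left open
    for atom in zipped.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetAtomMapNum(0)
    product = Chem.RemoveHs(zipped.GetMol())
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def _heavy_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _sample_series(
    scaffold: str,
    size: int,
    rng: np.random.Generator,
    used: set[str],
    ratio: float = 2.0,
    max_attempts_per_mol: int = 500,
) -> list[str]:
    # keep the scaffold at least `ratio` x the combined R-group size, so the
    # shared core is recoverable by size-ratio-constrained fragmentation
    scaffold_heavy = _heavy_count(scaffold)
    r_heavy = {r: _heavy_count(r) for r in RGROUP_POOL}
    out: list[str] = []
    attempts = 0
    while len(out) < size:
        attempts += 1
        if attempts > max_attempts_per_mol * size:
            raise RuntimeError(
                f"could not generate {size} unique analogues on scaffold {scaffold!r}"
            )
        r1, r2 = rng.choice(RGROUP_POOL, size=2, replace=True)
        if scaffold_heavy < ratio * (r_heavy[str(r1)] + r_heavy[str(r2)]):
            continue
        smi = attach_rgroups(scaffold, {1: str(r1), 2: str(r2)})
        if smi not in used:
            used.add(smi)
            out.append(smi)
    return out


def generate_fixture_series(n_series: int, series_size: int, seed: int):
    """Generate analogue series: ``n_series`` scaffolds × ``series_size`` analogues.

    Each returned :class:`~csfp.chem_io.MoleculeRecord` is labeled with its
    series id (``activity_class="series-<i>"``). All molecules are unique;
    output is deterministic for a fixed seed.
    """
    from .chem_io import standardize

    if n_series < 1 or series_size < 2:
        raise ValueError("need n_series >= 1 and series_size >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ACTIVE_SCAFFOLDS))
    used: set[str] = set()
    records = []
    for i in range(n_series):
        scaffold = ACTIVE_SCAFFOLDS[order[i % len(ACTIVE_SCAFFOLDS)]]
        for j, smi in enumerate(_sample_series(scaffold, series_size, rng, used)):
            records.append(
                standardize(smi, mol_id=f"S{i}_{j}", activity_class=f"series-{i}")
            )
    return records


def generate_background(n: int, seed: int, exclude: Iterable[str] = ()):
    """Generate ``n`` unique decoy molecules on the background scaffold pool.

    ``exclude`` lists canonical SMILES (e.g. of an active set) that must not
    appear among the decoys.
    """
    from .chem_io import standardize

    rng = np.random.default_rng(seed)
    used = set(exclude)
    records = []
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 500 * max(n, 1):
            raise RuntimeError("could not generate enough unique background molecules")
        scaffold = BACKGROUND_SCAFFOLDS[int(rng.integers(len(BACKGROUND_SCAFFOLDS)))]
        r1, r2 = rng.choice(BACKGROUND_RGROUPS, size=2, replace=True)
        smi = attach_rgroups(scaffold, {1: str(r1), 2: str(r2)})
        if smi in used:
            continue
        used.add(smi)
        records.append(standardize(smi, mol_id=f"BG{len(records)}"))
    return records


# ---------------------------------------------------------------------------
# combinatorial fragment catalog


def _valid_unique_mols(smiles_iter: Iterable[str]) -> list[Chem.Mol]:
    seen: set[str] = set()
    mols = []
    for smi in smiles_iter:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        mols.append(mol)
    return mols


def _enumerate_single_rings() -> list[Chem.Mol]:
    candidates: list[str] = []
    # aromatic six-membered rings: C/N combinations, up to 3 N
    for combo in itertools.product("cn", repeat=6):
        if combo.count("n") <= 3:
            candidates.append(f"{combo[0]}1{''.join(combo[1:])}1")
    # aromatic five-membered rings: one pivot heteroatom (o/s/[nH]) + up to 2 n
    for pivot in ("o", "s", "[nH]"):
        for rest in itertools.product("cn", repeat=4):
            if rest.count("n") <= 2:
                candidates.append(f"{pivot}1{''.join(rest)}1")
    # saturated rings of size 3-8 with up to 3 heteroatoms
    for size in range(3, 9):
        max_het = 2 if size < 5 else 3
        for k in range(0, max_het + 1):
            for positions in itertools.combinations(range(size), k):
                for elements in itertools.product("NOS", repeat=k):
                    atoms = ["C"] * size
                    for p, e in zip(positions, elements):
                        atoms[p] = e
                    candidates.append(f"{atoms[0]}1{''.join(atoms[1:])}1")
                    # one-double-bond variant between the first two carbons
                    cc = [i for i in range(size - 1) if atoms[i] == atoms[i + 1] == "C"]
                    if cc:
                        i = cc[0]
                        body = "".join(
                            a + ("=" if idx == i else "") for idx, a in enumerate(atoms)
                        )
                        candidates.append(f"{body[0]}1{body[1:]}1")
    return _valid_unique_mols(candidates)


_FUSED_SKELETONS = [
    "c1ccc2ccccc2c1",        # naphthalene
    "C1CCC2CCCCC2C1",        # decalin
    "c1ccc2c(c1)CCCC2",      # tetralin
    "c1ccc2[nH]ccc2c1",      # indole skeleton
    "c1ccc2occc2c1",         # benzofuran
    "c1ccc2sccc2c1",         # benzothiophene
    "c1ccc2c(c1)CCC2",       # indane
    "c1ccc2c(c1)OCO2",       # benzodioxole
    "C1CCC2CCCC2C1",         # hydrindane
    "C1CCC2(CC1)CCCC2",      # spiro[5.5]undecane
    "c1ccc2c(c1)CCN2",       # indoline
    "c1ccc2c(c1)OCCO2",      # benzodioxine
]


def _enumerate_fused_rings() -> list[Chem.Mol]:
    mols: dict[str, Chem.Mol] = {}
    for skeleton in _FUSED_SKELETONS:
        base = Chem.MolFromSmiles(skeleton)
        n = base.GetNumAtoms()
        position_sets = [()] + [(i,) for i in range(n)] + list(
            itertools.combinations(range(n), 2)
        )
        for positions in position_sets:
            element_choices = []
            for p in positions:
                if base.GetAtomWithIdx(p).GetIsAromatic():
                    element_choices.append((7,))
                else:
                    element_choices.append((7, 8, 16))
            for elements in itertools.product(*element_choices):
                rw = Chem.RWMol(base)
                for p, z in zip(positions, elements):
                    atom = rw.GetAtomWithIdx(p)
                    atom.SetAtomicNum(z)
                    atom.SetNumExplicitHs(0)
                    atom.SetNoImplicit(False)
                mol = rw.GetMol()
                try:
                    Chem.SanitizeMol(mol)
                except Exception:
                    continue
                canon = Chem.MolToSmiles(mol)
                if canon not in mols and mol.GetRingInfo().NumRings() >= 2:
                    mols[canon] = mol
    return list(mols.values())


_SUB_TERMINALS = [
    "F", "Cl", "Br", "I", "C#N", "C(F)(F)F", "C(=O)C", "C(=O)O", "C(=O)OC",
    "C(=O)N", "S(C)(=O)(=O)", "[N+](=O)[O-]", "C=C", "C#C", "O", "N", "S",
]

_SUB_RINGS = [
    "c1ccncc1", "c1ccoc1", "c1ccsc1", "C1CCCCC1", "C1CCNCC1", "C1CCOCC1",
    "c1ccc(F)cc1", "c1ccc(C)cc1", "c1ccc(O)cc1", "c1ccc(N)cc1", "C1CC1",
    "c1cnncc1", "C1CCNC1",
]


def _enumerate_substituents() -> list[str]:
    bodies: list[str] = []
    for length in range(1, 5):
        for chain in itertools.product("CNO", repeat=length):
            bodies.append("".join(chain))
    prefixes = [""] + ["".join(p) for ln in (1, 2, 3) for p in itertools.product("CNO", repeat=ln)]
    for prefix in prefixes:
        for terminal in _SUB_TERMINALS:
            bodies.append(prefix + terminal)
    for x, y in itertools.product("CNOF", repeat=2):
        bodies.append(f"C({x}){y}")
    bodies.extend(f"C(C)(C){x}" for x in "CNOF")
    bodies.extend(_SUB_RINGS)
    bodies.extend("C" + r for r in _SUB_RINGS)
    seen: set[str] = set()
    out: list[str] = []
    for body in bodies:
        mol = Chem.MolFromSmiles("[*]" + body)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append(canon)
    return out


@lru_cache(maxsize=4)
def generate_fragment_catalog(seed: int = 0):
    """Build a synthetic fragment catalog with frequency counts.

    Returns ``(single_rings, fused_rings, substituents)`` — lists of
    :class:`~csfp.ring_fragmentation.RingFragment` and
    :class:`~csfp.substituent_library.SubstituentFragment` large enough for a
    default 250/250/500 fingerprint assembly. Frequencies follow a Zipf-like
    profile with rank order shuffled deterministically by ``seed``.
    """
    from .ring_fragmentation import RingFragment
    from .substituent_library import SubstituentFragment, is_excluded_substituent

    rng = np.random.default_rng(seed)

    def frequencies(n: int) -> np.ndarray:
        ranks = rng.permutation(n) + 1
        return np.maximum(1, (5000.0 / ranks**1.05)).astype(int)

    singles_mols = _enumerate_single_rings()
    fused_mols = _enumerate_fused_rings()
    sub_patterns = [p for p in _enumerate_substituents() if not is_excluded_substituent(p)]

    single_freq = frequencies(len(singles_mols))
    fused_freq = frequencies(len(fused_mols))
    sub_freq = frequencies(len(sub_patterns))

    singles = [
        RingFragment(
            pattern=fragment_smarts(m),
            kind="single",
            is_model_fragment=False,
            frequency=int(f),
            exemplar=Chem.MolToSmiles(m),
        )
        for m, f in zip(singles_mols, single_freq)
    ]
    fused = [
        RingFragment(
            pattern=fragment_smarts(m),
            kind="fused",
            is_model_fragment=False,
            frequency=int(f),
            exemplar=Chem.MolToSmiles(m),
        )
        for m, f in zip(fused_mols, fused_freq)
    ]
    subs = [
        SubstituentFragment(pattern=p, frequency=int(f), source="random_cut")
        for p, f in zip(sub_patterns, sub_freq)
    ]
    return singles, fused, subs
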