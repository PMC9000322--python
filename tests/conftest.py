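"""Shared fixtures: synthetic compound sets and small fragment libraries.

Expensive fixtures (library fits, large molecule sets) are session-scoped so
the cost is paid once per run.
"""

from __future__ import annotations

import warnings

import pytest

from csfp.chem_io import MoleculeRecord
from csfp.fingerprint import FragmentLibrary, assemble_library
from csfp.fixtures import (
    generate_background,
    generate_fixture_series,
    generate_fragment_catalog,
)
from csfp.substituent_library import SubstituentFragment
from csfp.vectorizers import CSFPVectorizer


@pytest.fixture(scope="session")
def small_series() -> list[MoleculeRecord]:
    """3 analogue series x 4 compounds."""
    return generate_fixture_series(3, 4, seed=7)


@pytest.fixture(scope="session")
def catalog():
    """Full combinatorial fragment catalog (singles, fused, substituents)."""
    return generate_fragment_catalog(0)


@pytest.fixture(scope="session")
def toy_library(catalog) -> FragmentLibrary:
    """A <= 30-fragment library for brute-force comparisons."""
    singles, fused, subs = catalog
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return assemble_library(singles, fused, subs, n_single=10, n_fused=5, n_subs=15)


@pytest.fixture(scope="session")
def closure_library() -> FragmentLibrary:
    """Tiny library where one substituent contains two recorded substituents."""
    from csfp.ring_fragmentation import RingFragment

    singles = [
        RingFragment(
            pattern="[#6;A]1-[#6;A]-[#6;A]-[#6;A]-[#6;A]-[#6;A]-1",
            kind="single", is_model_fragment=False, frequency=5,
            exemplar="C1CCCCC1",
        )
    ]
    fused = [
        RingFragment(
            pattern="[#6;a]1:[#6;a]:[#6;a]:[#6;a]:[#6;a]:[#6;a]:[#6;a]:[#6;a]:[#6;a]:[#6;a]:1",
            kind="fused", is_model_fragment=False, frequency=5,
            exemplar="c1ccc2ccccc2c1",
        )
    ]
    subs = [
        SubstituentFragment("*NCC", 5),
        SubstituentFragment("*CC", 3),
        SubstituentFragment("*C", 2),
        SubstituentFragment("*F", 1),
    ]
    return assemble_library(singles, fused, subs, n_single=1, n_fused=1, n_subs=4)


@pytest.fixture(scope="session")
def thousand_molecules() -> list[MoleculeRecord]:
    """1000 fixture molecules: 500 from analogue series + 500 background."""
    actives = generate_fixture_series(25, 20, seed=101)
    background = generate_background(500, seed=102, exclude={a.smiles for a in actives})
    return actives + background


@pytest.fixture(scope="session")
def benchmark_data():
    """Benchmark class (4 series x 30 actives), 1000 decoys, fitted vectorizer."""
    actives = generate_fixture_series(4, 30, seed=3)
    background = generate_background(1000, seed=4, exclude={a.smiles for a in actives})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vec = CSFPVectorizer().fit(actives + background)
    return actives, background, vec
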