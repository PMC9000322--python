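"""Library assembly, closure bit setting, and Tanimoto similarity."""

import warnings

import numpy as np
import pytest
from rdkit import Chem

from csfp.fingerprint import (
    CSFPBitvector,
    FragmentLibrary,
    assemble_library,
    bit_density,
    build_library_from_molecules,
    compute_csfp,
    compute_matrix,
    feature_count,
    tanimoto,
)
from csfp.ring_fragmentation import RingFragment
from csfp.substituent_library import SubstituentFragment


class TestAssembly:
    def test_additive_bit_count(self, catalog):
        singles, fused, subs = catalog
        lib = assemble_library(singles, fused, subs, n_single=2, n_fused=2, n_subs=4)
        assert lib.n_bits == 8
        assert len(lib.single_rings) == 2 and len(lib.substituents) == 4

    def test_bit_index_is_bijection(self, toy_library):
        indices = sorted(toy_library.bit_index.values())
        assert indices == list(range(toy_library.n_bits))

    def test_bit_order_singles_fused_substituents(self, toy_library):
        n_s = len(toy_library.single_rings)
        n_f = len(toy_library.fused_rings)
        for i, frag in enumerate(toy_library.fragments):
            if i < n_s:
                assert frag.kind == "single"
            elif i < n_s + n_f:
                assert frag.kind == "fused"
            else:
                assert isinstance(frag, SubstituentFragment)

    def test_empty_category_raises(self, catalog):
        singles, fused, subs = catalog
        with pytest.raises(ValueError):
            assemble_library([], fused, subs)

    def test_closure_is_transitive_and_acyclic(self, catalog):
        singles, fused, subs = catalog
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lib = assemble_library(singles, fused, subs, n_single=20, n_fused=20, n_subs=60)
        for parent, children in lib.closure.items():
            assert parent not in children
            for child in children:
                assert children >= lib.closure.get(child, frozenset())

    def test_json_round_trip(self, toy_library, tmp_path):
        path = tmp_path / "lib.json"
        toy_library.to_json(path)
        back = FragmentLibrary.from_json(path)
        assert back.bit_index == toy_library.bit_index
        assert back.closure == toy_library.closure
        mol = "CCNc1ccc2ccccc2c1"
        assert np.array_equal(compute_csfp(mol, back).bits, compute_csfp(mol, toy_library).bits)


class TestCompute:
    def test_substituent_with_two_substructures_sets_three_bits(self, closure_library):
        """An N-ethylamino substituent containing recorded ethyl and methyl
        sets three substituent bits (itself plus both substructures)."""
        v = compute_csfp("CCNC1CCCCC1", closure_library)
        substituent_bits = [b for b in np.flatnonzero(v.bits) if b >= 2]
        assert len(substituent_bits) == 3
        assert closure_library.closure["*NCC"] == frozenset({"*CC", "*C"})

    def test_fused_ring_closure_sets_decomposition_bits(self):
        (fused,) = __import__("csfp").extract_ring_systems("c1ccc2ccccc2c1")
        from csfp.ring_fragmentation import decompose_fused

        six = decompose_fused(fused)[0]
        lib = assemble_library([six], [fused], [SubstituentFragment("*F", 1)],
                               n_single=1, n_fused=1, n_subs=1)
        v = compute_csfp("c1ccc2ccccc2c1", lib)  # naphthalene itself
        ring_bits = np.flatnonzero(v.bits[:2])
        assert len(ring_bits) == 2
        assert lib.closure[fused.pattern] == frozenset({six.pattern})

    def test_unmatched_molecule_gives_zero_vector(self, closure_library):
        v = compute_csfp("O=S=O", closure_library)
        assert feature_count(v) == 0 and v.provenance == {}

    def test_popcount_equals_provenance(self, toy_library, small_series):
        for rec in small_series:
            v = compute_csfp(rec, toy_library)
            assert feature_count(v) == len(v.provenance)

    def test_every_closure_bit_has_direct_ancestor(self, benchmark_data):
        actives, _, vec = benchmark_data
        lib = vec.library_
        for rec in actives[:40]:
            v = compute_csfp(rec, lib)
            direct = {p for p, how in v.provenance.values() if how == "direct"}
            for bit, (pattern, how) in v.provenance.items():
                if how == "closure":
                    assert any(pattern in lib.closure.get(d, ()) for d in direct)

    def test_closure_monotonicity(self, closure_library, small_series):
        """Bits with closure are a superset of bits without."""
        bare = FragmentLibrary(
            closure_library.single_rings,
            closure_library.fused_rings,
            closure_library.substituents,
            closure={},
        )
        for rec in small_series:
            with_closure = compute_csfp(rec, closure_library).bits
            without = compute_csfp(rec, bare).bits
            assert np.all(with_closure >= without)


def _brute_force_bits(mol, lib: FragmentLibrary) -> np.ndarray:
    """Independent matcher: test every fragment and every closure pair."""
    from csfp._patterns import mol_from_flagged_smiles

    target = mol.mol if hasattr(mol, "mol") else Chem.MolFromSmiles(mol)
    bits = np.zeros(lib.n_bits, dtype=np.uint8)
    matched = []
    for frag in lib.fragments:
        if target.HasSubstructMatch(frag.query):
            bits[lib.bit_index[frag.pattern]] = 1
            matched.append(frag)
    # closure expansion recomputed from scratch, pair by pair
    for frag in matched:
        if isinstance(frag, RingFragment) and frag.kind == "fused":
            exemplar = mol_from_flagged_smiles(frag.exemplar)
            for other in lib.single_rings:
                if exemplar.HasSubstructMatch(other.query):
                    bits[lib.bit_index[other.pattern]] = 1
        elif isinstance(frag, SubstituentFragment):
            exemplar = Chem.MolFromSmiles(frag.pattern)
            for other in lib.substituents:
                if other.pattern != frag.pattern and exemplar.HasSubstructMatch(other.query):
                    bits[lib.bit_index[other.pattern]] = 1
    return bits


class TestOracleEquivalence:
    def test_matches_brute_force_on_toy_library(self, toy_library, small_series):
        for rec in small_series:
            assert np.array_equal(
                compute_csfp(rec, toy_library).bits, _brute_force_bits(rec, toy_library)
            )

    def test_feature_count_equals_enumerated_matches(self, closure_library):
        mol = "CCNC1CCCCC1"
        assert feature_count(compute_csfp(mol, closure_library)) == int(
            _brute_force_bits(mol, closure_library).sum()
        )


class TestTanimoto:
    def test_identical_nonzero_is_one(self):
        v = np.array([1, 0, 1, 1], dtype=np.uint8)
        assert tanimoto(v, v) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(np.array([1, 1, 0, 0]), np.array([0, 0, 1, 1])) == 0.0

    def test_formula_case(self):
        a = np.zeros(10); a[[1, 2, 3]] = 1
        b = np.zeros(10); b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == pytest.approx(0.5)

    def test_zero_vector_convention(self):
        z = np.zeros(8)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4), np.zeros(5))

    def test_symmetry_and_metric_property(self):
        rng = np.random.default_rng(5)
        vs = (rng.random((12, 32)) < 0.3).astype(np.uint8)
        for a in vs[:6]:
            for b in vs[6:]:
                assert tanimoto(a, b) == pytest.approx(tanimoto(b, a))
        # 1 - Tc obeys the triangle inequality (soergel distance, spot check)
        for i in range(4):
            a, b, c = vs[3 * i], vs[3 * i + 1], vs[3 * i + 2]
            dab, dbc, dac = 1 - tanimoto(a, b), 1 - tanimoto(b, c), 1 - tanimoto(a, c)
            assert dac <= dab + dbc + 1e-12


class TestCounts:
    def test_zero_vector(self):
        v = CSFPBitvector(bits=np.zeros(1000, dtype=np.uint8))
        assert feature_count(v) == 0 and bit_density(v) == 0.0

    def test_density_percentage(self):
        bits = np.zeros(1000, dtype=np.uint8)
        bits[:28] = 1
        assert bit_density(CSFPBitvector(bits=bits)) == pytest.approx(2.8)

    def test_matrix_agrees_with_per_molecule(self, toy_library, small_series):
        X = compute_matrix(small_series, toy_library)
        assert X.shape == (len(small_series), toy_library.n_bits)
        for row, rec in zip(X, small_series):
            assert np.array_equal(row, compute_csfp(rec, toy_library).bits)


def test_duplicate_patterns_rejected():
    s = RingFragment("[#6;A]1-[#6;A]-[#6;A]-1", "single", False, exemplar="C1CC1")
    with pytest.raises(ValueError, match="duplicate"):
        FragmentLibrary([s, s], [], [])


def test_pipeline_library_from_molecules(small_series):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lib = build_library_from_molecules(small_series, n_single=10, n_fused=10, n_subs=30)
    assert lib.n_bits > 0
    assert lib.metadata["n_series_cores"] >= 3
    # fingerprints of the source molecules are non-empty
    X = compute_matrix(small_series, lib)
    assert (X.sum(axis=1) > 0).all()
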