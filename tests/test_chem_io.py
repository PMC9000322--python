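"""Standardization, curation filters, and molecule/activity I/O."""

import gzip

import pytest
from rdkit import Chem

from csfp.chem_io import (
    ActivityRecord,
    SmilesParseError,
    ValidationError,
    canonical_smiles,
    curate_activity_records,
    read_activity_table,
    read_molecule_table,
    read_smiles,
    standardize,
    write_activity_table,
    write_smiles,
)
from csfp.fixtures import generate_fixture_series


class TestStandardize:
    def test_canonicalization_idempotent(self):
        rec = standardize("c1ccccc1")
        assert standardize(rec.smiles).smiles == rec.smiles

    def test_kekulized_and_aromatic_agree(self):
        assert standardize("C1=CC=CC=C1").smiles == standardize("c1ccccc1").smiles

    def test_salt_stripping_keeps_largest_organic(self):
        rec = standardize("CCO.[Na+].[Cl-]")
        assert rec.mol.GetNumAtoms() == 3
        assert rec.smiles == "CCO"

    def test_charge_neutralization(self):
        assert standardize("CC(=O)[O-]").smiles == "CC(=O)O"

    @pytest.mark.parametrize("bad", ["", "   ", "notasmiles(("])
    def test_unparseable_raises_with_offender(self, bad):
        with pytest.raises(SmilesParseError):
            standardize(bad)

    def test_idempotence_over_fixture_set(self, thousand_molecules):
        for rec in thousand_molecules:
            assert canonical_smiles(rec.smiles) == rec.smiles


def _record(**overrides) -> ActivityRecord:
    base = dict(
        compound_id="C1",
        smiles="c1ccccc1",
        target_id="T1",
        standard_type="Ki",
        standard_relation="=",
        standard_value_nM=100.0,
        confidence_score=9,
        flags=frozenset(),
        mol_weight_Da=300.0,
    )
    base.update(overrides)
    return ActivityRecord(**base)


class TestCuration:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"standard_relation": ">"},
            {"flags": frozenset({"inconclusive"})},
            {"flags": frozenset({"inactive"})},
            {"flags": frozenset({"not active"})},
            {"flags": frozenset({"potential transcription error"})},
            {"confidence_score": 8},
            {"mol_weight_Da": 1000.0},
            {"standard_value_nM": 20_000.0},
            {"standard_type": "EC50"},
        ],
        ids=[
            "inexact-relation", "flag-inconclusive", "flag-inactive",
            "flag-not-active", "flag-transcription", "low-confidence",
            "overweight", "weak-potency", "wrong-type",
        ],
    )
    def test_each_filter_individually_excludes(self, overrides):
        """A record failing exactly one filter is dropped; the base record passes."""
        assert curate_activity_records([_record()]) == [_record()]
        assert curate_activity_records([_record(**overrides)]) == []

    def test_six_record_fixture_keeps_two(self):
        records = [
            _record(compound_id="A"),                                # keeps
            _record(compound_id="B", standard_value_nM=5000.0),      # keeps
            _record(compound_id="C", standard_relation=">"),
            _record(compound_id="D", confidence_score=5),
            _record(compound_id="E", flags=frozenset({"inactive"})),
            _record(compound_id="F", mol_weight_Da=1500.0),
        ]
        kept = curate_activity_records(records)
        assert sorted(r.compound_id for r in kept) == ["A", "B"]

    def test_output_subset_and_idempotent(self):
        records = [_record(compound_id=f"C{i}", standard_value_nM=v)
                   for i, v in enumerate([1.0, 50.0, 20000.0, 9999.0])]
        once = curate_activity_records(records)
        assert set(r.compound_id for r in once) <= set(r.compound_id for r in records)
        assert curate_activity_records(once) == once

    def test_duplicates_collapse_to_most_potent(self):
        records = [
            _record(standard_value_nM=500.0),
            _record(standard_value_nM=50.0),
            _record(standard_value_nM=5000.0),
        ]
        kept = curate_activity_records(records)
        assert len(kept) == 1 and kept[0].standard_value_nM == 50.0

    def test_anti_target_hook(self):
        records = [_record(target_id="hERG"), _record(compound_id="C2")]
        kept = curate_activity_records(records, anti_target_ids={"hERG"})
        assert [r.compound_id for r in kept] == ["C2"]

    def test_interference_hook(self):
        kept = curate_activity_records(
            [_record()], interference_filter=lambda r: "c1ccccc1" in r.smiles
        )
        assert kept == []

    def test_missing_field_names_record(self):
        with pytest.raises(ValidationError, match="C1"):
            curate_activity_records([_record(mol_weight_Da=None)])

    def test_potency_direction_configurable(self):
        weak = _record(standard_value_nM=50_000.0)
        assert curate_activity_records([weak]) == []
        assert curate_activity_records([weak], keep_at_most_cutoff=False) == [weak]

    def test_invalid_record_fields_rejected(self):
        with pytest.raises(ValidationError):
            _record(standard_value_nM=-1.0)
        with pytest.raises(ValidationError):
            _record(confidence_score=12)


class TestFixtureGenerator:
    def test_single_series_shares_core_distinct_rgroups(self):
        recs = generate_fixture_series(1, 3, seed=7)
        assert len(recs) == 3
        assert len({r.smiles for r in recs}) == 3
        assert all(r.activity_class == "series-0" for r in recs)

    def test_deterministic(self):
        a = [r.smiles for r in generate_fixture_series(2, 5, seed=13)]
        b = [r.smiles for r in generate_fixture_series(2, 5, seed=13)]
        assert a == b

    def test_all_unique(self):
        recs = generate_fixture_series(5, 4, seed=1)
        assert len({r.smiles for r in recs}) == 20

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            generate_fixture_series(0, 3, seed=1)
        with pytest.raises(ValueError):
            generate_fixture_series(1, 1, seed=1)


class TestIO:
    def test_smiles_round_trip(self, tmp_path, small_series):
        path = tmp_path / "mols.smi"
        write_smiles(small_series, path)
        back = read_smiles(path)
        assert [(r.id, r.smiles) for r in back] == [
            (r.id, r.smiles) for r in small_series
        ]

    def test_gzip_transparent(self, tmp_path, small_series):
        path = tmp_path / "mols.smi.gz"
        write_smiles(small_series, path)
        with gzip.open(path, "rt") as fh:
            assert len(fh.readlines()) == len(small_series)
        assert len(read_smiles(path)) == len(small_series)

    def test_molecule_table(self, tmp_path):
        path = tmp_path / "mols.csv"
        path.write_text("id,smiles,activity_class\nm1,c1ccccc1,easy\nm2,CCO,\n")
        recs = read_molecule_table(path)
        assert recs[0].activity_class == "easy" and recs[1].activity_class is None

    def test_activity_table_round_trip(self, tmp_path):
        records = [_record(), _record(compound_id="C2", flags=frozenset({"inactive"}))]
        path = tmp_path / "act.tsv"
        write_activity_table(records, path)
        back = read_activity_table(path)
        assert back == records

    def test_missing_columns_raise(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,name\n1,x\n")
        with pytest.raises(ValidationError, match="smiles"):
            read_molecule_table(path)
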