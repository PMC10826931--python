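"""Cohort data model, I/O round-trips, summaries, and splitting."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emsflags.metrics import RocAnalysis
from emsflags.records import (
    Cohort,
    EncounterRecord,
    TEXT_FIELDS,
    parse_label,
    read_encounters,
    read_report,
    split_train_test,
    summarize_cohort,
    write_encounters,
    write_report,
)

text_strategy = st.text(
    alphabet=st.characters(blacklist_categories=("Cs", "Cc")), max_size=40
)

record_strategy = st.builds(
    EncounterRecord,
    record_id=st.uuids().map(str),
    county=st.sampled_from(["Travis", "El Paso", "Williamson", ""]),
    call_nature=text_strategy,
    primary_impression=text_strategy,
    chief_complaint=text_strategy,
    chief_narrative=text_strategy,
    medication_list=text_strategy,
    medical_history=text_strategy,
    ethnicity=st.sampled_from(["White", "Hispanic or Latino", "unknown"]),
    gender=st.sampled_from(["male", "female", "unknown"]),
    age=st.one_of(st.none(), st.integers(0, 130).map(float)),
    label=st.one_of(st.none(), st.integers(0, 1)),
    phase=st.one_of(st.none(), st.sampled_from(["one", "two"])),
)


class TestReadWrite:
    @pytest.mark.parametrize("fmt", ["csv", "jsonl"])
    def test_round_trip_identity(self, small_cohort, tmp_path, fmt):
        path = tmp_path / f"cohort.{fmt}"
        write_encounters(small_cohort, path, format=fmt)
        back = read_encounters(path, format=fmt)
        assert back.record_ids == small_cohort.record_ids
        for a, b in zip(small_cohort, back):
            for f in TEXT_FIELDS:
                assert getattr(a, f) == getattr(b, f)
            assert (a.label, a.age, a.ethnicity, a.gender, a.county) == (
                b.label, b.age, b.ethnicity, b.gender, b.county
            )

    @settings(max_examples=25, deadline=None)
    @given(records=st.lists(record_strategy, min_size=1, max_size=8,
                            unique_by=lambda r: r.record_id))
    def test_round_trip_property(self, tmp_path_factory, records):
        # csv round-trip normalizes newlines inside quoted fields; the
        # jsonl path must be exactly lossless for arbitrary text
        cohort = Cohort(records)
        path = tmp_path_factory.mktemp("rt") / "cohort.jsonl"
        write_encounters(cohort, path, format="jsonl")
        back = read_encounters(path, format="jsonl")
        assert back.record_ids == cohort.record_ids
        for a, b in zip(cohort, back):
            for f in TEXT_FIELDS:
                assert getattr(a, f) == getattr(b, f)
            assert a.label == b.label and a.age == b.age

    def test_missing_text_column_becomes_empty_string(self, tmp_path):
        path = tmp_path / "partial.csv"
        path.write_text("record_id,county,label\nR1,Travis,1\n")
        cohort = read_encounters(path)
        assert cohort[0].chief_narrative == ""
        assert cohort[0].label == 1

    def test_duplicate_record_id_is_hard_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("record_id,chief_narrative\nA1,x\nA1,y\n")
        with pytest.raises(ValueError, match="A1"):
            read_encounters(path)

    def test_label_dialects(self):
        assert parse_label("OOD") == 1
        assert parse_label("Non-OOD") == 0
        assert parse_label("true") == 1
        assert parse_label(0) == 0
        assert parse_label("") is None
        with pytest.raises(ValueError, match="row 7"):
            parse_label("maybe", row=7)

    def test_unknown_columns_pass_through(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text("record_id,dispatch_code,label\nR1,E-17,0\n")
        cohort = read_encounters(path)
        assert cohort[0].extras["dispatch_code"] == "E-17"
        out = tmp_path / "out.csv"
        write_encounters(cohort, out)
        assert read_encounters(out)[0].extras["dispatch_code"] == "E-17"


class TestValidation:
    def test_age_bounds(self):
        with pytest.raises(ValueError, match="age"):
            EncounterRecord(record_id="X", age=140)

    def test_duplicate_ids_in_constructor(self):
        with pytest.raises(ValueError, match="B2"):
            Cohort([EncounterRecord(record_id="B2"),
                    EncounterRecord(record_id="B2")])


class TestSummaries:
    def test_empty_cohort_is_all_zeros(self):
        s = summarize_cohort(Cohort([]))
        assert s.n_total == 0 and s.n_positive == 0
        assert s.n_by_county == {}
        assert s.positive_share_by_ethnicity == {}

    def test_county_counts_permutation_invariant(self, rng):
        records = [
            EncounterRecord(record_id=f"r{i}",
                            county=["Travis", "El Paso"][i % 2],
                            label=i % 3 == 0)
            for i in range(30)
        ]
        s1 = summarize_cohort(Cohort(records))
        perm = list(rng.permutation(30))
        s2 = summarize_cohort(Cohort([records[i] for i in perm]))
        assert s1.n_by_county == s2.n_by_county
        assert s1.n_positive == s2.n_positive

    def test_shares_over_labeled_positives_only(self):
        records = [
            EncounterRecord(record_id="p1", label=1, ethnicity="White"),
            EncounterRecord(record_id="p2", label=1, ethnicity="Asian"),
            EncounterRecord(record_id="n1", label=0, ethnicity="White"),
            EncounterRecord(record_id="u1", label=None, ethnicity="White"),
        ]
        s = summarize_cohort(Cohort(records))
        assert s.positive_share_by_ethnicity["White"] == (1, 50.0)
        assert s.n_unlabeled == 1


class TestSplitting:
    def test_exact_sizes_unstratified(self):
        cohort = Cohort([EncounterRecord(record_id=str(i)) for i in range(10)])
        train, test = split_train_test(cohort, 0.2, seed=0,
                                       stratify_on_label=False)
        assert len(test) == 2 and len(train) == 8

    def test_deterministic(self, default_benchmark_cohort):
        cohort, _ = default_benchmark_cohort
        a = split_train_test(cohort, 0.2, seed=3)
        b = split_train_test(cohort, 0.2, seed=3)
        assert a[1].record_ids == b[1].record_ids

    @pytest.mark.parametrize("fraction,seed", [(0.2, 0), (0.33, 5), (0.5, 9)])
    def test_partition_property(self, default_benchmark_cohort, fraction, seed):
        cohort, _ = default_benchmark_cohort
        train, test = split_train_test(cohort, fraction, seed=seed)
        tr, te = set(train.record_ids), set(test.record_ids)
        assert not tr & te
        assert tr | te == set(cohort.record_ids)

    def test_stratified_rounding_study_sized(self):
        # a 438/2520 labeled split at 20% gives round(87.6)+round(504)=592
        records = [
            EncounterRecord(record_id=f"p{i}", label=1) for i in range(438)
        ] + [
            EncounterRecord(record_id=f"n{i}", label=0) for i in range(2520)
        ]
        _, test = split_train_test(Cohort(records), 0.2, seed=1)
        assert len(test) == 592
        assert sum(r.label for r in test) == 88

    def test_stratified_requires_labels(self):
        cohort = Cohort([EncounterRecord(record_id=str(i)) for i in range(10)])
        with pytest.raises(ValueError, match="unlabeled"):
            split_train_test(cohort, 0.2, seed=0, stratify_on_label=True)


class TestReports:
    def test_summary_round_trip(self, small_cohort, tmp_path):
        summary = summarize_cohort(small_cohort)
        path = tmp_path / "summary.json"
        write_report(summary, path)
        back = read_report(path)
        assert back["n_total"] == len(small_cohort)
        assert back["n_by_county"]["Travis"] == 2

    def test_roc_ci_serializes_as_pair(self, tmp_path):
        roc = RocAnalysis(auc=0.9, variance=1e-4, ci_level=0.95,
                          ci=(0.88, 0.92), n_pos=50, n_neg=50)
        path = tmp_path / "roc.json"
        write_report(roc, path)
        assert read_report(path)["ci"] == [0.88, 0.92]

    def test_nan_serializes_as_null(self, tmp_path):
        path = tmp_path / "nan.json"
        write_report({"mean_age": float("nan")}, path)
        assert json.loads(path.read_text())["mean_age"] is None
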