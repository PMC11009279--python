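import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from narrascreen.corpus import (
    CUTOFF,
    NarrativeRecord,
    Pcl5Response,
    balance_downsample,
    check_unique_ids,
    default_train_per_class,
    filter_min_words,
    label_case,
    load_corpus,
    make_split,
    score_pcl5,
    word_count,
    write_corpus_csv,
    write_split_manifest,
)
from narrascreen.errors import ValidationError

item_values = st.one_of(st.none(), st.integers(min_value=0, max_value=4))
responses = st.lists(item_values, min_size=20, max_size=20).map(
    lambda items: Pcl5Response(tuple(items))
)


class TestScorePcl5:
    def test_all_zero(self):
        assert score_pcl5(Pcl5Response((0,) * 20)) == 0

    def test_all_max(self):
        assert score_pcl5(Pcl5Response((4,) * 20)) == 80

    def test_missing_items_contribute_zero(self):
        response = Pcl5Response(tuple([3] * 10 + [None] * 10))
        assert score_pcl5(response) == 30

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValidationError, match="20 items"):
            Pcl5Response((0,) * 19)

    @pytest.mark.parametrize("bad", [-1, 5, 17])
    def test_out_of_range_value_names_slot(self, bad):
        items = [0] * 20
        items[6] = bad
        with pytest.raises(ValidationError, match="item 7"):
            Pcl5Response(tuple(items))

    def test_from_raw_normalizes_missing_markers(self):
        raw = ["", "NA", "nan", None, "null"] + ["2"] * 15
        response = Pcl5Response.from_raw(raw)
        assert response.n_missing == 5
        assert score_pcl5(response) == 30

    def test_from_raw_rejects_garbage(self):
        raw = ["x"] + [0] * 19
        with pytest.raises(ValidationError, match="item 1"):
            Pcl5Response.from_raw(raw)

    @given(responses, st.integers(min_value=0, max_value=19))
    def test_monotone_in_item_severity(self, response, slot):
        before = score_pcl5(response)
        items = list(response.items)
        current = items[slot] if items[slot] is not None else 0
        if current >= 4:
            return
        items[slot] = current + 1
        assert score_pcl5(Pcl5Response(tuple(items))) >= before


class TestLabelCase:
    @pytest.mark.parametrize(
        "total,expected", [(31, 1), (30, 0), (80, 1), (0, 0), (32, 1)]
    )
    def test_cutoff_boundary(self, total, expected):
        assert label_case(total) == expected

    @pytest.mark.parametrize("bad", [-1, 81, 1000])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            label_case(bad)

    @given(responses)
    def test_consistent_with_score(self, response):
        total = score_pcl5(response)
        assert label_case(total) == (1 if total >= CUTOFF else 0)


class TestFilterMinWords:
    def test_word_boundary(self, record_factory):
        records = [
            record_factory("a", 0, n_words=29),
            record_factory("b", 0, n_words=30),
        ]
        assert [r.subject_id for r in filter_min_words(records)] == ["b"]

    def test_empty_narrative_excluded(self, record_factory):
        assert filter_min_words([record_factory("a", 0, n_words=0)]) == []

    def test_passthrough_when_all_long(self, record_factory):
        records = [record_factory(f"s{i}", 0, n_words=30 + i) for i in range(5)]
        assert filter_min_words(records) == records

    def test_word_count_is_whitespace_tokens(self):
        assert word_count("one two  three\nfour\tfive ") == 5
        assert word_count("") == 0
        assert word_count("punctuation, stays attached!") == 3


class TestBalanceDownsample:
    def test_paper_scale_counts(self, record_factory):
        records = [record_factory(f"p{i}", 1) for i in range(190)]
        records += [record_factory(f"n{i}", 0) for i in range(1105)]
        balanced = balance_downsample(records, seed=0)
        labels = [r.label for r in balanced]
        assert labels.count(1) == 190
        assert labels.count(0) == 190

    def test_already_balanced_unchanged_membership(self, record_factory):
        records = [record_factory(f"s{i}", i % 2) for i in range(10)]
        balanced = balance_downsample(records, seed=3)
        assert {r.subject_id for r in balanced} == {r.subject_id for r in records}

    def test_deterministic_given_seed(self, record_factory):
        records = [record_factory(f"p{i}", 1) for i in range(3)]
        records += [record_factory(f"n{i}", 0) for i in range(10)]
        first = [r.subject_id for r in balance_downsample(records, seed=11)]
        second = [r.subject_id for r in balance_downsample(records, seed=11)]
        assert first == second

    def test_empty_class_rejected(self, record_factory):
        records = [record_factory(f"s{i}", 0) for i in range(4)]
        with pytest.raises(ValidationError, match="class 1"):
            balance_downsample(records, seed=0)

    def test_minority_kept_in_full(self, record_factory):
        minority = [record_factory(f"p{i}", 1) for i in range(3)]
        majority = [record_factory(f"n{i}", 0) for i in range(9)]
        balanced = balance_downsample(minority + majority, seed=5)
        kept = {r.subject_id for r in balanced}
        assert {r.subject_id for r in minority} <= kept

    @given(st.integers(min_value=0, max_value=2**31), st.integers(2, 9),
           st.integers(2, 9))
    @settings(max_examples=25, deadline=None)
    def test_equal_counts_for_any_seed(self, seed, n1, n0):
        records = [make_for_label(i, 1) for i in range(n1)]
        records += [make_for_label(100 + i, 0) for i in range(n0)]
        balanced = balance_downsample(records, seed=seed)
        labels = [r.label for r in balanced]
        assert labels.count(0) == labels.count(1) == min(n1, n0)


def make_for_label(i, label):
    from conftest import make_record

    return make_record(f"h{i}", label)


class TestMakeSplit:
    def _balanced(self, record_factory, per_class):
        records = [record_factory(f"p{i}", 1) for i in range(per_class)]
        records += [record_factory(f"n{i}", 0) for i in range(per_class)]
        return records

    def test_paper_arithmetic(self, record_factory):
        split = make_split(self._balanced(record_factory, 190),
                           train_per_class=170, seed=0)
        assert all(len(v) == 170 for v in split.train_ids.values())
        assert all(len(v) == 20 for v in split.test_ids.values())

    def test_default_train_fraction(self):
        assert default_train_per_class(190) == 170
        assert default_train_per_class(19) == 17

    def test_two_per_class(self, record_factory):
        split = make_split(self._balanced(record_factory, 2),
                           train_per_class=1, seed=0)
        assert all(len(v) == 1 for v in split.train_ids.values())
        assert all(len(v) == 1 for v in split.test_ids.values())

    def test_same_seed_identical(self, record_factory):
        records = self._balanced(record_factory, 12)
        a = make_split(records, train_per_class=9, seed=42)
        b = make_split(records, train_per_class=9, seed=42)
        assert a == b

    def test_train_per_class_too_large(self, record_factory):
        with pytest.raises(ValidationError):
            make_split(self._balanced(record_factory, 5), train_per_class=5,
                       seed=0)

    def test_unbalanced_input_rejected(self, record_factory):
        records = [record_factory("p0", 1)] + [
            record_factory(f"n{i}", 0) for i in range(3)
        ]
        with pytest.raises(ValidationError, match="not balanced"):
            make_split(records, train_per_class=1, seed=0)

    @given(st.integers(min_value=0, max_value=2**31))
    @settings(max_examples=20, deadline=None)
    def test_partition_property(self, seed):
        records = [make_for_label(i, 1) for i in range(7)]
        records += [make_for_label(50 + i, 0) for i in range(7)]
        split = make_split(records, train_per_class=5, seed=seed)
        for cls_label in (0, 1):
            ids = {
                r.subject_id for r in records if r.label == cls_label
            }
            train = set(split.train_ids[cls_label])
            test = set(split.test_ids[cls_label])
            assert train | test == ids
            assert not train & test


class TestComposition:
    def test_filter_balance_split_preserve_records(self, record_factory):
        records = [
            record_factory(f"p{i}", 1, n_words=25 + i) for i in range(8)
        ] + [record_factory(f"n{i}", 0, n_words=25 + i) for i in range(12)]
        by_id = {r.subject_id: r for r in records}
        filtered = filter_min_words(records, min_words=30)
        balanced = balance_downsample(filtered, seed=2)
        for rec in balanced:
            original = by_id[rec.subject_id]
            assert rec.label == original.label
            assert rec.narrative == original.narrative


class TestIO:
    def _corpus(self, record_factory, n=6):
        records = [record_factory(f"s{i}", i % 2) for i in range(n)]
        # one record with missing items, label still well-defined
        records.append(
            NarrativeRecord.build(
                "s-missing",
                "some words " * 20,
                Pcl5Response(tuple([4] * 9 + [None] * 11)),
            )
        )
        return records

    def test_csv_round_trip(self, tmp_path, record_factory):
        records = self._corpus(record_factory)
        path = tmp_path / "corpus.csv"
        write_corpus_csv(records, path)
        loaded = load_corpus(path)
        assert [r.subject_id for r in loaded] == [r.subject_id for r in records]
        assert [r.pcl5_total for r in loaded] == [r.pcl5_total for r in records]
        assert [r.label for r in loaded] == [r.label for r in records]
        assert loaded[-1].pcl5.n_missing == 11

    def test_jsonl_round_trip(self, tmp_path, record_factory):
        records = self._corpus(record_factory)
        path = tmp_path / "corpus.jsonl"
        with path.open("w") as handle:
            for rec in records:
                row = {"subject_id": rec.subject_id, "narrative": rec.narrative}
                for i, v in enumerate(rec.pcl5.items, start=1):
                    row[f"pcl5_{i:02d}"] = v
                handle.write(json.dumps(row) + "\n")
        loaded = load_corpus(path)
        assert [r.pcl5_total for r in loaded] == [r.pcl5_total for r in records]

    def test_duplicate_subject_ids_rejected(self, tmp_path, record_factory):
        records = [record_factory("dup", 0), record_factory("dup", 1)]
        path = tmp_path / "corpus.csv"
        write_corpus_csv(records, path)
        with pytest.raises(ValidationError, match="duplicate"):
            load_corpus(path)
        with pytest.raises(ValidationError, match="duplicate"):
            check_unique_ids(records)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("subject_id,narrative\na,hello world\n")
        with pytest.raises(ValidationError, match="pcl5_01"):
            load_corpus(path)

    def test_split_manifest(self, tmp_path, record_factory):
        records = [record_factory(f"p{i}", 1) for i in range(4)]
        records += [record_factory(f"n{i}", 0) for i in range(4)]
        split = make_split(records, train_per_class=3, seed=0)
        path = tmp_path / "split.jsonl"
        write_split_manifest(split, path)
        rows = [json.loads(line) for line in path.read_text().splitlines()]
        assert len(rows) == 8
        assert sum(r["split"] == "train" for r in rows) == 6
        assert {r["label"] for r in rows} == {0, 1}
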