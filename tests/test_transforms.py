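"""Transformation unit tests, including a brute-force oracle that
re-derives each transformation by independent exhaustive enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triagekit import (
    MultiLabelDataset,
    SingleLabelDataset,
    binary_views,
    dm_transform,
    integrated_transform,
    lp_transform,
    split_dataset,
    subset_accuracy,
    tp_transform,
)
from triagekit.scheme import PriorityClass, PriorityScheme


# --------------------------------------------------------------------------
# independent oracles (naive re-derivations, kept free of the implementation)
# --------------------------------------------------------------------------

def oracle_dm(rows):
    return [(t, lab, p) for t, labs, p in rows for lab in sorted(labs)]


def oracle_lp(rows):
    seen = []
    out = []
    for t, labs, p in rows:
        if labs not in seen:
            seen.append(labs)
        out.append((t, seen.index(labs) + 1, p))
    return out


def oracle_tp(rows, rank_of_label):
    return [(t, min(rank_of_label[l] for l in labs), p) for t, labs, p in rows]


def tiny_datasets():
    labels = st.frozensets(st.integers(1, 4), min_size=1, max_size=4)
    return st.lists(labels, min_size=1, max_size=8).map(
        lambda sets: MultiLabelDataset(
            [(f"t{i}", s, f"r{i}") for i, s in enumerate(sets)],
            {i: f"label{i}" for i in range(1, 5)},
        )
    )


# --------------------------------------------------------------------------
# worked examples
# --------------------------------------------------------------------------

class TestWorkedExamples:
    def test_dm_expands_to_the_eight_rows(self, toy_multilabel):
        out = dm_transform(toy_multilabel)
        expected = [
            ("text1", 1), ("text1", 3), ("text1", 5),
            ("text2", 1), ("text2", 2),
            ("text3", 1),
            ("text4", 2),
            ("text5", 3),
        ]
        assert [(t, c) for t, c, _ in out.rows] == expected
        assert out.class_vocab == toy_multilabel.label_vocab

    def test_lp_assigns_first_appearance_ids(self, toy_multilabel):
        out = lp_transform(toy_multilabel)
        assert [c for _, c, _ in out.rows] == [1, 2, 3, 4, 5]
        assert out.rows[4] == ("text5", 5, "r5")

    def test_tp_keeps_the_most_urgent_rank(self, toy_multilabel, rank_scheme):
        out = tp_transform(toy_multilabel, rank_scheme)
        assert [c for _, c, _ in out.rows] == [1, 1, 1, 2, 3]
        assert out.rows[3] == ("text4", 2, "r4")

    def test_lp_descriptor_joins_sorted_member_names(self, toy_multilabel):
        out = lp_transform(toy_multilabel)
        assert out.class_vocab[2] == "label1+label2"

    def test_lp_reuses_class_for_repeated_combo(self):
        data = MultiLabelDataset(
            [("a", frozenset({1}), "r1"), ("b", frozenset({2}), "r2"),
             ("c", frozenset({1}), "r3")],
            {1: "A", 2: "B"},
        )
        out = lp_transform(data)
        assert [c for _, c, _ in out.rows] == [1, 2, 1]
        assert out.n_classes == 2

    def test_all_single_label_dm_is_identity_expansion(self):
        data = MultiLabelDataset(
            [("a", frozenset({2}), "r1"), ("b", frozenset({1}), "r2")],
            {1: "A", 2: "B"},
        )
        assert len(dm_transform(data)) == len(data)


class TestIntegrated:
    @pytest.fixture
    def trauma_scheme(self):
        return PriorityScheme([
            PriorityClass(1, "trauma", frozenset({"Head trauma", "Scalp laceration"})),
            PriorityClass(2, "hemorrhage", frozenset({"Subarachnoid hemorrhage"})),
        ])

    def test_integration_dm_collapses_same_class_pairs(self, trauma_scheme):
        data = MultiLabelDataset(
            [("fall", frozenset({1, 2}), "r1")],
            {1: "Head trauma", 2: "Scalp laceration"},
        )
        out = integrated_transform(data, trauma_scheme, "DM")
        assert [(t, c) for t, c, _ in out.rows] == [("fall", 1)]

    def test_integration_lp_makes_cross_class_combo(self, trauma_scheme):
        data = MultiLabelDataset(
            [("fall", frozenset({1, 2}), "r1")],
            {1: "Head trauma", 2: "Subarachnoid hemorrhage"},
        )
        out = integrated_transform(data, trauma_scheme, "LP")
        assert out.rows[0][1] == 1
        assert out.class_vocab[1] == "hemorrhage+trauma"

    def test_integration_lp_equals_tp_when_rank_sets_are_singletons(
        self, trauma_scheme
    ):
        data = MultiLabelDataset(
            [("a", frozenset({1}), "r1"), ("b", frozenset({2}), "r2"),
             ("c", frozenset({1, 3}), "r3")],
            {1: "Head trauma", 2: "Subarachnoid hemorrhage", 3: "Scalp laceration"},
        )
        lp_out = integrated_transform(data, trauma_scheme, "LP")
        tp_out = tp_transform(data, trauma_scheme)
        # every coarsened set is a singleton rank, so the two agree row-wise
        lp_ranks = [lp_out.class_vocab[c] for _, c, _ in lp_out.rows]
        tp_ranks = [tp_out.class_vocab[c] for _, c, _ in tp_out.rows]
        assert lp_ranks == tp_ranks

    def test_unknown_only_records_dropped_and_logged(self, trauma_scheme):
        data = MultiLabelDataset(
            [("a", frozenset({1}), "r1"), ("b", frozenset({2}), "r2")],
            {1: "Head trauma", 2: "gout"},
        )
        out = tp_transform(data, trauma_scheme)
        assert len(out) == 1
        assert out.dropped == ["r2"]


class TestBruteForceOracle:
    @settings(max_examples=100, deadline=None)
    @given(tiny_datasets())
    def test_dm_matches_oracle(self, data):
        assert dm_transform(data).rows == oracle_dm(data.rows)

    @settings(max_examples=100, deadline=None)
    @given(tiny_datasets())
    def test_lp_matches_oracle(self, data):
        out = lp_transform(data)
        assert out.rows == oracle_lp(data.rows)
        assert out.n_classes == len({labs for _, labs, _ in data.rows})

    @settings(max_examples=100, deadline=None)
    @given(tiny_datasets())
    def test_tp_matches_oracle(self, data):
        scheme = PriorityScheme(
            [PriorityClass(i, f"label{i}", frozenset({f"label{i}"})) for i in range(1, 5)]
        )
        out = tp_transform(data, scheme)
        assert [(t, c, p) for t, c, p in out.rows] == oracle_tp(
            data.rows, {i: i for i in range(1, 5)}
        )

    @settings(max_examples=100, deadline=None)
    @given(tiny_datasets())
    def test_row_count_contracts(self, data):
        assert len(dm_transform(data)) == sum(len(l) for _, l, _ in data.rows)
        assert len(lp_transform(data)) == len(data)


class TestBinaryViews:
    def test_br_targets_are_membership_flags(self, toy_multilabel):
        tasks = binary_views(toy_multilabel, mode="BR")
        assert len(tasks) == 6
        task1 = next(t for t in tasks if t.label_id == 1)
        assert [target for _, _, target, _ in task1.rows] == [1, 1, 1, 0, 0]
        assert all(t.chain_prior == () for t in tasks)

    def test_cc_task_reads_earlier_gold_labels(self):
        # label B duplicates label A; the B-task sees A's gold value
        data = MultiLabelDataset(
            [("x", frozenset({1, 2}), "r1"), ("y", frozenset({1, 2}), "r2"),
             ("z", frozenset({2}), "r3")],
            {1: "A", 2: "B"},
        )
        tasks = binary_views(data, mode="CC", chain_order=[2, 1])
        task_a = next(t for t in tasks if t.label_id == 1)
        assert task_a.chain_prior == (2,)
        assert [vals for _, vals, _, _ in task_a.rows] == [(1,), (1,), (1,)]

    def test_invalid_chain_order_rejected(self, toy_multilabel):
        with pytest.raises(ValueError):
            binary_views(toy_multilabel, mode="CC", chain_order=[1, 2])

    def test_subset_accuracy(self):
        true = [frozenset({1}), frozenset({1, 2}), frozenset()]
        pred = [frozenset({1}), frozenset({1}), frozenset()]
        assert subset_accuracy(true, pred) == pytest.approx(2 / 3)

    def test_empty_prediction_only_matches_empty_truth(self):
        assert subset_accuracy([frozenset({1})], [frozenset()]) == 0.0
        assert subset_accuracy([frozenset()], [frozenset()]) == 1.0


class TestSplit:
    def _dataset(self, sizes):
        rows = []
        for cid, n in enumerate(sizes, start=1):
            rows += [(f"t{cid}_{i}", cid, f"r{cid}_{i}") for i in range(n)]
        vocab = {cid: f"c{cid}" for cid in range(1, len(sizes) + 1)}
        return SingleLabelDataset(rows, vocab, method="LP")

    def test_same_seed_identical_splits(self):
        data = self._dataset([10, 10])
        a = split_dataset(data, 0.3, seed=7)
        b = split_dataset(data, 0.3, seed=7)
        assert a[0].rows == b[0].rows and a[1].rows == b[1].rows

    def test_stratification_arithmetic(self):
        data = self._dataset([25, 25, 25, 25])
        train, test = split_dataset(data, 0.2, seed=0)
        counts = np.bincount(test.class_ids(), minlength=5)[1:]
        assert list(counts) == [5, 5, 5, 5]
        assert len(train) + len(test) == 100

    def test_singleton_class_goes_to_train(self):
        data = self._dataset([1, 10])
        train, test = split_dataset(data, 0.5, seed=0)
        assert all(cid != 1 for _, cid, _ in test.rows)
        assert any(cid == 1 for _, cid, _ in train.rows)

    def test_disjoint_and_exhaustive(self):
        data = self._dataset([7, 13])
        train, test = split_dataset(data, 0.25, seed=3)
        train_ids = {p for _, _, p in train.rows}
        test_ids = {p for _, _, p in test.rows}
        assert not train_ids & test_ids
        assert len(train_ids | test_ids) == 20

    def test_empty_dataset_rejected(self):
        data = SingleLabelDataset([], {}, method="LP")
        with pytest.raises(ValueError):
            split_dataset(data, 0.2, seed=0)


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path, toy_multilabel):
        out = lp_transform(toy_multilabel)
        path = tmp_path / "lp.tsv"
        out.write(path)
        back = SingleLabelDataset.read(path)
        assert back.rows == out.rows
        assert back.class_vocab == out.class_vocab
        assert back.method == "LP"
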