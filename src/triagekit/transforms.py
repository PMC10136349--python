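"""Multilabel -> single-label problem transformations.

A record with several diagnoses is a multilabel example; an ordinary
softmax classifier needs a single class per example.  Five strategies are
implemented:

* **DM** (dictionary mapping) — duplicate the record into one row per
  label.  Simple, but every multi-label record becomes several identical
  texts under different classes, amplifying class overlap.
* **LP** (label powerset) — each distinct label *combination* becomes one
  class; one row per record.
* **TP** (triage priority) — map each label to an expert urgency rank and
  keep only the most urgent rank present; one row per record.  This is
  the label-coarsening transformation that collapses overlapping
  combinations into a common class.
* **integration-DM / integration-LP** — first coarsen each record's label
  set to its set of priority ranks, then apply DM or LP to the coarsened
  sets.
* **BR / CC** (binary relevance / classifier chain) — multilabel views:
  one binary task per label; CC additionally feeds each task the 0/1
  values of all earlier labels in the chain.

All transformations are pure dataset -> dataset functions; training lives
in :mod:`triagekit.classifier`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records_io import Corpus
from .scheme import PriorityScheme

__all__ = [
    "MultiLabelDataset",
    "SingleLabelDataset",
    "BinaryTask",
    "dm_transform",
    "lp_transform",
    "tp_transform",
    "integrated_transform",
    "binary_views",
    "split_dataset",
    "subset_accuracy",
]


@dataclass
class MultiLabelDataset:
    """Rows of (text, label-id set, provenance) plus the label vocabulary.

    Label ids are dense 1..K; ``label_vocab`` maps each id to its name.
    """

    rows: list[tuple[str, frozenset[int], str]]
    label_vocab: dict[int, str]

    def __post_init__(self) -> None:
        k = len(self.label_vocab)
        if sorted(self.label_vocab) != list(range(1, k + 1)):
            raise ValueError("label ids must be dense 1..K")
        for text, labels, prov in self.rows:
            if not labels:
                raise ValueError(f"record {prov!r} has an empty label set")
            if not labels <= set(self.label_vocab):
                raise ValueError(f"record {prov!r} has labels outside the vocabulary")

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_corpus(cls, corpus: Corpus) -> "MultiLabelDataset":
        """Build a multilabel dataset over diagnosis names (ids by sorted name)."""
        names = sorted({d for r in corpus for d in r.diagnoses})
        ids = {name: i + 1 for i, name in enumerate(names)}
        rows = [
            (r.complaint, frozenset(ids[d] for d in r.diagnoses), r.record_id)
            for r in corpus
        ]
        return cls(rows, {i: n for n, i in ids.items()})

    def label_names(self, labels: frozenset[int]) -> frozenset[str]:
        return frozenset(self.label_vocab[i] for i in labels)


@dataclass
class SingleLabelDataset:
    """Rows of (text, class-id, provenance) produced by a transformation."""

    rows: list[tuple[str, int, str]]
    class_vocab: dict[int, str]
    method: str
    dropped: list[str] = field(default_factory=list)  # provenance of omitted records

    def __post_init__(self) -> None:
        k = len(self.class_vocab)
        if sorted(self.class_vocab) != list(range(1, k + 1)):
            raise ValueError("class ids must be dense 1..K")
        for text, cid, prov in self.rows:
            if cid not in self.class_vocab:
                raise ValueError(f"row {prov!r} has class id {cid} outside the vocabulary")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_classes(self) -> int:
        return len(self.class_vocab)

    def texts(self) -> list[str]:
        return [t for t, _, _ in self.rows]

    def class_ids(self) -> np.ndarray:
        return np.array([c for _, c, _ in self.rows], dtype=np.int64)

    # -- serialization ----------------------------------------------------

    def write(self, path: str | Path) -> None:
        """Write rows as TSV (text, class_id, provenance) + JSON vocab sidecar."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write("text\tclass_id\tprovenance\n")
            for text, cid, prov in self.rows:
                fh.write(f"{text}\t{cid}\t{prov}\n")
        sidecar = path.with_suffix(path.suffix + ".vocab.json")
        sidecar.write_text(
            json.dumps(
                {"method": self.method,
                 "class_vocab": {str(k): v for k, v in self.class_vocab.items()}},
                ensure_ascii=False, indent=2,
            ),
            encoding="utf-8",
        )

    @classmethod
    def read(cls, path: str | Path) -> "SingleLabelDataset":
        path = Path(path)
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".vocab.json").read_text(encoding="utf-8")
        )
        rows = []
        with path.open(encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                text, cid, prov = line.rstrip("\n").split("\t")
                rows.append((text, int(cid), prov))
        vocab = {int(k): v for k, v in sidecar["class_vocab"].items()}
        return cls(rows, vocab, sidecar["method"])


# --------------------------------------------------------------------------
# DM / LP / TP
# --------------------------------------------------------------------------

def dm_transform(data: MultiLabelDataset) -> SingleLabelDataset:
    """Dictionary mapping: one (text, label) row per (record, label) pair.

    Rows preserve record order, then label-index order within a record, so
    a record labelled {1, 3, 5} contributes three consecutive rows.
    """
    rows = [
        (text, label, prov)
        for text, labels, prov in data.rows
        for label in sorted(labels)
    ]
    return SingleLabelDataset(rows, dict(data.label_vocab), method="DM")


def lp_transform(data: MultiLabelDataset) -> SingleLabelDataset:
    """Label powerset: each distinct label combination is one class.

    Class ids are assigned 1-based in order of first appearance; the class
    descriptor joins the member label names, sorted, with ``+``.
    """
    combo_ids: dict[frozenset[int], int] = {}
    rows: list[tuple[str, int, str]] = []
    for text, labels, prov in data.rows:
        if labels not in combo_ids:
            combo_ids[labels] = len(combo_ids) + 1
        rows.append((text, combo_ids[labels], prov))
    vocab = {
        cid: "+".join(sorted(data.label_vocab[i] for i in combo))
        for combo, cid in combo_ids.items()
    }
    return SingleLabelDataset(rows, vocab, method="LP")


def tp_transform(
    data: MultiLabelDataset, scheme: PriorityScheme
) -> SingleLabelDataset:
    """Triage priority: coarsen labels to ranks, keep the most urgent.

    Each record's label names are mapped through the scheme and the
    minimum (most urgent) rank becomes its single class.  Records whose
    integrated rank set is empty (all labels unknown under the
    ``drop_record`` policy) are omitted and listed in ``dropped``.
    """
    rows: list[tuple[str, int, str]] = []
    dropped: list[str] = []
    uses_other = False
    for text, labels, prov in data.rows:
        ranks = scheme.integrate_labels(data.label_names(labels))
        if not ranks:
            dropped.append(prov)
            continue
        cid = min(ranks)
        uses_other = uses_other or cid == scheme.other_rank
        rows.append((text, cid, prov))
    vocab = _rank_vocab(scheme, include_other=uses_other)
    return SingleLabelDataset(rows, vocab, method="TP", dropped=dropped)


def _rank_vocab(scheme: PriorityScheme, include_other: bool = False) -> dict[int, str]:
    vocab = {c.rank: c.name for c in scheme.classes}
    if include_other:
        vocab[scheme.other_rank] = "other"
    return vocab


def coarsen(
    data: MultiLabelDataset, scheme: PriorityScheme
) -> tuple[MultiLabelDataset, list[str]]:
    """Replace each record's label set by its set of priority ranks."""
    rows: list[tuple[str, frozenset[int], str]] = []
    dropped: list[str] = []
    uses_other = False
    for text, labels, prov in data.rows:
        ranks = scheme.integrate_labels(data.label_names(labels))
        if not ranks:
            dropped.append(prov)
            continue
        uses_other = uses_other or scheme.other_rank in ranks
        rows.append((text, ranks, prov))
    vocab = _rank_vocab(scheme, include_other=uses_other)
    return MultiLabelDataset(rows, vocab), dropped


def integrated_transform(
    data: MultiLabelDataset, scheme: PriorityScheme, inner: str
) -> SingleLabelDataset:
    """integration-DM / integration-LP: coarsen to rank sets, then DM or LP."""
    if inner not in {"DM", "LP"}:
        raise ValueError(f"inner must be 'DM' or 'LP', got {inner!r}")
    coarse, dropped = coarsen(data, scheme)
    out = dm_transform(coarse) if inner == "DM" else lp_transform(coarse)
    out.method = f"integration-{inner}"
    out.dropped = dropped
    return out


# --------------------------------------------------------------------------
# BR / CC multilabel views
# --------------------------------------------------------------------------

@dataclass
class BinaryTask:
    """One binary task: is ``label_id`` present?

    ``rows`` are (text, prior-label values, 0/1 target, provenance); for
    binary relevance ``prior`` is empty, for a classifier chain it holds
    the gold 0/1 values of every earlier label in the chain (at inference
    the chain substitutes its own predictions).
    """

    label_id: int
    label_name: str
    chain_prior: tuple[int, ...]  # label ids whose values this task consumes
    rows: list[tuple[str, tuple[int, ...], int, str]]


def binary_views(
    data: MultiLabelDataset,
    mode: str = "BR",
    chain_order: list[int] | str = "vocab",
) -> list[BinaryTask]:
    """Per-label binary training tasks (binary relevance or classifier chain).

    ``chain_order`` is a permutation of label ids (CC only); ``"vocab"``
    uses vocabulary order.  Prediction convention: a label is predicted
    present iff its task probability exceeds 0.5; the headline multilabel
    metric is subset (exact-match) accuracy.
    """
    if mode not in {"BR", "CC"}:
        raise ValueError(f"mode must be 'BR' or 'CC', got {mode!r}")
    label_ids = sorted(data.label_vocab)
    if mode == "BR":
        order = label_ids
    else:
        order = label_ids if chain_order == "vocab" else list(chain_order)
        if sorted(order) != label_ids:
            raise ValueError("chain_order must be a permutation of the label ids")

    tasks: list[BinaryTask] = []
    for pos, label in enumerate(order):
        prior = tuple(order[:pos]) if mode == "CC" else ()
        rows = [
            (
                text,
                tuple(int(p in labels) for p in prior),
                int(label in labels),
                prov,
            )
            for text, labels, prov in data.rows
        ]
        tasks.append(BinaryTask(label, data.label_vocab[label], prior, rows))
    return tasks


def subset_accuracy(
    true_sets: list[frozenset[int]], pred_sets: list[frozenset[int]]
) -> float:
    """Exact-match accuracy: the predicted label set equals the true set."""
    if len(true_sets) != len(pred_sets):
        raise ValueError("length mismatch")
    if not true_sets:
        raise ValueError("empty evaluation")
    return sum(t == p for t, p in zip(true_sets, pred_sets)) / len(true_sets)


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def split_dataset(
    data: SingleLabelDataset, test_fraction: float, seed: int
) -> tuple[SingleLabelDataset, SingleLabelDataset]:
    """Deterministic stratified train/test split.

    Each class with >= 2 rows contributes ``round(n * test_fraction)``
    rows to the test set (at least keeping one row in train); classes
    with a single row go entirely to train.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if not data.rows:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for idx, (_, cid, _) in enumerate(data.rows):
        by_class.setdefault(cid, []).append(idx)

    test_idx: set[int] = set()
    for cid in sorted(by_class):
        idxs = by_class[cid]
        if len(idxs) < 2:
            continue
        n_test = int(round(len(idxs) * test_fraction))
        n_test = min(max(n_test, 0), len(idxs) - 1)
        chosen = rng.choice(len(idxs), size=n_test, replace=False)
        test_idx.update(idxs[i] for i in chosen)

    train_rows = [r for i, r in enumerate(data.rows) if i not in test_idx]
    test_rows = [r for i, r in enumerate(data.rows) if i in test_idx]
    train = SingleLabelDataset(train_rows, dict(data.class_vocab), data.method)
    test = SingleLabelDataset(test_rows, dict(data.class_vocab), data.method)
    return train, test
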