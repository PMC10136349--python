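"""Synthetic multilabel corpus generator.

Emulates the statistical shape of a neurosurgery chief-complaint dump
without any real patient data: diagnoses drawn from a triage scheme with
Zipf (power-law) imbalance, a mean of ~1.27 labels per record, extra
labels biased toward the primary diagnosis's own priority class (the
head-trauma + scalp-laceration style of combination), and a controllable
fraction of records that repeat an earlier complaint verbatim under a
different label set — the "class overlapping" phenomenon.

Complaints are synthetic token strings ("sym3x12 dur4 u57"), not natural
language: every downstream operation treats text as an opaque string or
n-gram source, so token identity is all that matters.  Each non-overlap
record carries a uniqueness token, making text collisions occur exactly
where they were injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records_io import Corpus, Record
from .scheme import PriorityScheme, builtin_scheme

__all__ = ["GeneratorConfig", "GroundTruth", "generate_corpus"]


@dataclass
class GeneratorConfig:
    """Knobs of the generator; defaults emulate the study corpus shape."""

    n_records: int = 1000
    scheme: PriorityScheme = field(default_factory=builtin_scheme)
    zipf_s: float = 1.2           # Zipf exponent of diagnosis frequencies
    mean_labels: float = 1.27     # target mean labels per record
    overlap_rate: float = 0.1     # fraction of records reusing an earlier text
    companion_bias: float = 0.7   # extra labels drawn from the primary's class
    vocab_per_class: int = 30     # symptom tokens per priority class
    shared_vocab: int = 10        # duration/shared tokens across classes
    shared_token_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be > 0")
        if not 0.0 <= self.overlap_rate < 1.0:
            raise ValueError("overlap_rate must be in [0, 1)")
        if self.mean_labels < 1.0:
            raise ValueError("mean_labels must be >= 1")
        if self.zipf_s < 0:
            raise ValueError("zipf_s must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually did, for audits and tests."""

    diagnosis_order: list[str]          # Zipf rank order (rank 1 first)
    diagnosis_counts: dict[str, int]    # records containing each diagnosis
    priority_counts: dict[int, int]     # records whose triage label is each rank
    injected_overlap_ids: list[str]     # record_ids that copied an earlier text
    mean_labels_empirical: float

    def as_dict(self) -> dict:
        return {
            "diagnosis_order": self.diagnosis_order,
            "diagnosis_counts": self.diagnosis_counts,
            "priority_counts": {str(k): v for k, v in self.priority_counts.items()},
            "injected_overlap_ids": self.injected_overlap_ids,
            "mean_labels_empirical": self.mean_labels_empirical,
        }


def _diagnosis_table(scheme: PriorityScheme) -> tuple[list[str], dict[str, int]]:
    """Diagnoses in Zipf-rank order (priority rank, then name) + rank lookup."""
    order: list[str] = []
    rank_of: dict[str, int] = {}
    for cls in scheme.classes:
        for name in sorted(cls.members):
            order.append(name)
            rank_of[name] = cls.rank
    return order, rank_of


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus; deterministic given ``config.seed``.

    Per record: a primary diagnosis is drawn Zipf(``zipf_s``) over the
    scheme's diagnoses; ``1 + min(Poisson(mean_labels − 1), M − 1)``
    labels in total, extras preferring the primary's priority class with
    probability ``companion_bias``; the complaint is a symptom token from
    the primary class's vocabulary plus a shared duration token.  With
    probability ``overlap_rate`` the record instead copies the complaint
    of an earlier record with a different label set, verbatim; all other
    records get a uniqueness token so no accidental duplicates occur.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    order, rank_of = _diagnosis_table(scheme)
    m = len(order)
    zipf_w = np.arange(1, m + 1, dtype=np.float64) ** (-config.zipf_s)
    zipf_p = zipf_w / zipf_w.sum()
    by_class: dict[int, list[int]] = {}
    for idx, name in enumerate(order):
        by_class.setdefault(rank_of[name], []).append(idx)

    records: list[Record] = []
    label_sets: list[frozenset[str]] = []
    injected: list[str] = []
    diag_counts: dict[str, int] = {name: 0 for name in order}
    prio_counts: dict[int, int] = {c.rank: 0 for c in scheme.classes}
    total_labels = 0

    for i in range(config.n_records):
        # ---- label set -------------------------------------------------
        primary = int(rng.choice(m, p=zipf_p))
        chosen = {primary}
        n_extra = min(int(rng.poisson(config.mean_labels - 1.0)), m - 1)
        for _ in range(n_extra):
            same_class = [j for j in by_class[rank_of[order[primary]]] if j not in chosen]
            if same_class and rng.random() < config.companion_bias:
                chosen.add(int(rng.choice(same_class)))
            else:
                remaining = [j for j in range(m) if j not in chosen]
                w = zipf_p[remaining] / zipf_p[remaining].sum()
                chosen.add(int(rng.choice(remaining, p=w)))
        labels = frozenset(order[j] for j in chosen)

        # ---- complaint -------------------------------------------------
        rank = rank_of[order[primary]]
        is_overlap = False
        if i > 0 and rng.random() < config.overlap_rate:
            donors = [k for k in range(len(records)) if label_sets[k] != labels]
            if donors:
                donor = int(rng.choice(donors))
                complaint = records[donor].complaint
                is_overlap = True
        if not is_overlap:
            sym = f"sym{rank}x{int(rng.integers(config.vocab_per_class))}"
            dur = f"dur{int(rng.integers(config.shared_vocab))}"
            parts = [sym, dur]
            if rng.random() < config.shared_token_prob:
                parts.append(f"shared{int(rng.integers(config.shared_vocab))}")
            parts.append(f"u{i}")  # uniqueness token: no accidental duplicates
            complaint = " ".join(parts)

        rid = str(i)
        records.append(Record(rid, complaint, labels))
        label_sets.append(labels)
        if is_overlap:
            injected.append(rid)
        for name in labels:
            diag_counts[name] += 1
        prio_counts[min(rank_of[n] for n in labels)] += 1
        total_labels += len(labels)

    truth = GroundTruth(
        diagnosis_order=order,
        diagnosis_counts=diag_counts,
        priority_counts=prio_counts,
        injected_overlap_ids=injected,
        mean_labels_empirical=total_labels / config.n_records,
    )
    return Corpus(records, source_tag=f"synthetic(seed={config.seed})"), truth
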