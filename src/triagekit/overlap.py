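"""Class-overlap diagnostics.

Two rows "overlap" when they carry the *same* text under *different*
class ids — the situation in which no classifier, however good, can be
right on both.  The statistic reported is the number (and percentage) of
overlapping rows; merging classes (label coarsening, e.g. the triage-
priority transformation) can only reduce it, which is exactly why
coarsening helps on overlap-heavy corpora.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .transforms import SingleLabelDataset

__all__ = [
    "OverlapReport",
    "compute_overlap",
    "proportion_from_counts",
    "relative_change",
]


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (matching printed report precision)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OverlapReport:
    """Row-level overlap statistic for one transformed dataset."""

    method: str
    total_rows: int
    overlapping_rows: int
    overlapping_texts: int  # distinct texts involved (secondary counter)
    proportion_pct: float   # 100 * overlapping_rows / total_rows, 2 decimals

    def __str__(self) -> str:
        return (
            f"{self.method}\t{self.total_rows}\t{self.overlapping_rows}\t"
            f"{self.proportion_pct:.2f}%"
        )


def proportion_from_counts(overlapping: int, total: int) -> float:
    """Percentage of overlapping rows, rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= overlapping <= total:
        raise ValueError("need 0 <= overlapping <= total")
    return _round2(100.0 * overlapping / total)


def relative_change(before: float, after: float) -> float:
    """Signed percent change from ``before`` to ``after``, 2 decimals.

    Positive means the overlap proportion grew (e.g. after row-duplicating
    transformations), negative that it shrank (after coarsening).
    """
    if before <= 0:
        raise ValueError("before must be > 0")
    return _round2(100.0 * (after - before) / before)


def compute_overlap(data: SingleLabelDataset) -> OverlapReport:
    """Count rows whose text also occurs under a different class id.

    A row is overlapping iff its (already normalised) text appears in at
    least one other row with a different ``class_id``.  Rows are counted,
    not distinct texts; the distinct-text count is reported alongside.
    """
    if not data.rows:
        raise ValueError("cannot compute overlap of an empty dataset")
    classes_by_text: dict[str, set[int]] = {}
    for text, cid, _ in data.rows:
        classes_by_text.setdefault(text, set()).add(cid)
    overlapping_texts = {t for t, cids in classes_by_text.items() if len(cids) > 1}
    overlapping_rows = sum(1 for text, _, _ in data.rows if text in overlapping_texts)
    return OverlapReport(
        method=data.method,
        total_rows=len(data.rows),
        overlapping_rows=overlapping_rows,
        overlapping_texts=len(overlapping_texts),
        proportion_pct=proportion_from_counts(overlapping_rows, len(data.rows)),
    )
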