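"""Corpus data model, readers/writers and preprocessing.

A corpus is an ordered collection of medical records, each carrying a
free-text chief complaint and a set of diagnosis names.  Preprocessing
mirrors the usual hygiene steps for hospital record dumps: Unicode
normalisation, punctuation-noise removal, dropping records that lack
either a complaint or a diagnosis, and frequency screening of rare
diagnoses.

Only the complaint and diagnosis fields are ever read; any other columns
or keys in the input (names, identifiers, demographics) are ignored, so
de-identification is by field selection.
"""

from __future__ import annotations

import io
import json
import re
import unicodedata
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "Record",
    "Corpus",
    "CleanLog",
    "ScreenLog",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "clean_corpus",
    "screen_diagnoses",
    "normalize_text",
]

#: Separator for multi-diagnosis cells in CSV/TSV files.
DIAGNOSIS_SEP = ";"

#: Default screening threshold: keep diagnoses occurring in >= 101 records,
#: i.e. strictly more than 100.
DEFAULT_MIN_COUNT = 101


class CorpusFormatError(ValueError):
    """Raised when an input file lacks required columns/keys or is malformed."""


@dataclass(frozen=True)
class Record:
    """One medical record: id, chief-complaint text and diagnosis names."""

    record_id: str
    complaint: str
    diagnoses: frozenset[str]

    def __post_init__(self) -> None:
        if not isinstance(self.diagnoses, frozenset):
            object.__setattr__(self, "diagnoses", frozenset(self.diagnoses))


@dataclass
class Corpus:
    """Ordered collection of records with unique ids."""

    records: list[Record] = field(default_factory=list)
    source_tag: str = ""

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = [k for k, v in Counter(ids).items() if v > 1]
            raise ValueError(f"duplicate record_ids in corpus: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.records == other.records


@dataclass
class CleanLog:
    """Counts of records dropped per reason during cleaning."""

    dropped_no_complaint: int = 0
    dropped_no_diagnosis: int = 0

    @property
    def total_dropped(self) -> int:
        return self.dropped_no_complaint + self.dropped_no_diagnosis


@dataclass
class ScreenLog:
    """Diagnoses removed by frequency screening, with their corpus counts."""

    removed: dict[str, int] = field(default_factory=dict)
    dropped_records: int = 0


# --------------------------------------------------------------------------
# text normalisation
# --------------------------------------------------------------------------

_WS_RE = re.compile(r"\s+")


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith(("P", "S"))


def _strip_edges(text: str) -> str:
    # strip punctuation/symbol runs (any length) and whitespace at both ends
    start, end = 0, len(text)
    while start < end and (_is_punct(text[start]) or text[start].isspace()):
        start += 1
    while end > start and (_is_punct(text[end - 1]) or text[end - 1].isspace()):
        end -= 1
    return text[start:end]


def _collapse_internal_runs(text: str) -> str:
    # internal punctuation runs of length >= 2 are noise; replace by a space
    out: list[str] = []
    i, n = 0, len(text)
    while i < n:
        if _is_punct(text[i]):
            j = i
            while j < n and _is_punct(text[j]):
                j += 1
            run = text[i:j]
            out.append(run if len(run) == 1 else " ")
            i = j
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


def normalize_text(text: str) -> str:
    """NFKC-normalise, drop punctuation noise, collapse whitespace.

    Edge punctuation runs of any length are removed; internal runs of two
    or more punctuation/symbol characters are replaced by a single space
    (single internal marks, e.g. a comma between clauses, are kept).
    Idempotent: applying twice equals applying once.
    """
    text = unicodedata.normalize("NFKC", text)
    text = _collapse_internal_runs(text)
    text = _strip_edges(text)
    text = _WS_RE.sub(" ", text)
    return text


def normalize_diagnosis(name: str) -> str:
    """Whitespace/Unicode normalisation for diagnosis names (no punctuation strip)."""
    return _WS_RE.sub(" ", unicodedata.normalize("NFKC", name)).strip()


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def _split_diagnoses(cell: str) -> frozenset[str]:
    parts = (p.strip() for p in str(cell).split(DIAGNOSIS_SEP))
    return frozenset(p for p in parts if p)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "tsv", "jsonl"}:
        return suffix
    raise CorpusFormatError(f"cannot infer corpus format from {path.name!r}; pass format=")


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a corpus from CSV, TSV or JSONL.

    CSV/TSV need columns ``complaint`` and ``diagnoses`` (``;``-separated);
    JSONL needs keys ``complaint`` and ``diagnoses`` (a list).  ``record_id``
    is optional — the 0-based row index is assigned when absent.  All other
    columns/keys are ignored (field-selection de-identification).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in {"csv", "tsv", "jsonl"}:
        raise CorpusFormatError(f"unknown corpus format {fmt!r}")
    try:
        raw = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise IOError(f"{path} is not valid UTF-8: {exc}") from exc

    records: list[Record] = []
    if fmt == "jsonl":
        for i, line in enumerate(raw.splitlines()):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{i + 1}: invalid JSON: {exc}") from exc
            if "complaint" not in obj:
                raise CorpusFormatError(f"{path}:{i + 1}: missing 'complaint' key")
            diagnoses = obj.get("diagnoses", [])
            if isinstance(diagnoses, str):
                diagnoses = [diagnoses]
            records.append(
                Record(
                    record_id=str(obj.get("record_id", i)),
                    complaint=str(obj["complaint"]),
                    diagnoses=frozenset(str(d).strip() for d in diagnoses if str(d).strip()),
                )
            )
    else:
        sep = "," if fmt == "csv" else "\t"
        if not raw.strip():
            return Corpus([], source_tag=str(path))
        df = pd.read_csv(io.StringIO(raw), sep=sep, dtype=str, keep_default_na=False)
        if "complaint" not in df.columns:
            raise CorpusFormatError(f"{path}: missing 'complaint' column")
        if "diagnoses" not in df.columns:
            raise CorpusFormatError(f"{path}: missing 'diagnoses' column")
        has_id = "record_id" in df.columns
        for i, row in enumerate(df.itertuples(index=False)):
            rid = str(getattr(row, "record_id")) if has_id else str(i)
            records.append(
                Record(
                    record_id=rid,
                    complaint=str(getattr(row, "complaint")),
                    diagnoses=_split_diagnoses(getattr(row, "diagnoses")),
                )
            )
    return Corpus(records, source_tag=str(path))


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus to CSV, TSV or JSONL (inverse of :func:`read_corpus`)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in corpus:
                fh.write(
                    json.dumps(
                        {
                            "record_id": r.record_id,
                            "complaint": r.complaint,
                            "diagnoses": sorted(r.diagnoses),
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(
            {
                "record_id": [r.record_id for r in corpus],
                "complaint": [r.complaint for r in corpus],
                "diagnoses": [DIAGNOSIS_SEP.join(sorted(r.diagnoses)) for r in corpus],
            }
        )
        df.to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# cleaning and screening
# --------------------------------------------------------------------------

def clean_corpus(corpus: Corpus) -> tuple[Corpus, CleanLog]:
    """Normalise texts and keep only records with both a complaint and a diagnosis.

    Complaints are NFKC-normalised with punctuation noise removed and
    whitespace collapsed; diagnosis names are whitespace-normalised.
    Records whose complaint normalises to the empty string, or whose
    diagnosis set is (or becomes) empty, are dropped and counted.
    """
    log = CleanLog()
    kept: list[Record] = []
    for r in corpus:
        complaint = normalize_text(r.complaint)
        diagnoses = frozenset(
            d for d in (normalize_diagnosis(x) for x in r.diagnoses) if d
        )
        if not complaint:
            log.dropped_no_complaint += 1
            continue
        if not diagnoses:
            log.dropped_no_diagnosis += 1
            continue
        kept.append(Record(r.record_id, complaint, diagnoses))
    return Corpus(kept, source_tag=corpus.source_tag), log


def diagnosis_counts(corpus: Corpus) -> Counter:
    """Number of records containing each diagnosis (set semantics, not multiplicity)."""
    counts: Counter = Counter()
    for r in corpus:
        counts.update(r.diagnoses)
    return counts


def screen_diagnoses(
    corpus: Corpus, min_count: int = DEFAULT_MIN_COUNT
) -> tuple[Corpus, ScreenLog]:
    """Remove diagnoses occurring in fewer than ``min_count`` records.

    A diagnosis is kept iff its record count is >= ``min_count``; records
    whose diagnosis set becomes empty are dropped.  The default threshold
    of 101 keeps diagnoses with strictly more than 100 occurrences.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = diagnosis_counts(corpus)
    removed = {d: c for d, c in counts.items() if c < min_count}
    log = ScreenLog(removed=dict(sorted(removed.items())))
    kept: list[Record] = []
    for r in corpus:
        diagnoses = frozenset(d for d in r.diagnoses if d not in removed)
        if diagnoses:
            kept.append(Record(r.record_id, r.complaint, diagnoses))
        else:
            log.dropped_records += 1
    return Corpus(kept, source_tag=corpus.source_tag), log
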