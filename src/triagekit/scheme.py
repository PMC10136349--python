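"""Triage-priority scheme: expert-ranked urgency classes over diagnoses.

A scheme is an ordered list of priority classes (rank 1 = most urgent),
each owning a set of diagnosis names.  Mapping a record's diagnosis set
through the scheme coarsens it to a set of ranks; taking the minimum rank
yields the triage-priority single label (a head-trauma + subarachnoid-
hemorrhage record is a trauma case, because trauma outranks cerebral
hemorrhage).

The built-in scheme encodes the 10-class neurosurgery scheme covering the
28 frequent diagnoses: trauma first, then cerebral hemorrhage, epilepsy,
space-occupying lesions, aneurysm/vascular malformation, post-tumor-surgery
follow-up, chronic subdural hematoma, hydrocephalus, headache and
dizziness.  "Subarachnoid hemorrhage" is a member of the cerebral-
hemorrhage class (rank 2); the traumatic variant, "Traumatic subarachnoid
hemorrhage", sits with the other traumatic hemorrhages in the trauma class
(rank 1).
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

__all__ = [
    "UnknownPolicy",
    "PriorityClass",
    "PriorityScheme",
    "SchemeValidationError",
    "UnknownDiagnosisError",
    "load_scheme",
    "builtin_scheme",
]


class SchemeValidationError(ValueError):
    """Raised when a scheme definition is inconsistent."""


class UnknownDiagnosisError(KeyError):
    """Raised for a diagnosis outside the scheme under the ``error`` policy."""


class UnknownPolicy(str, Enum):
    """What to do with a diagnosis the scheme does not cover."""

    ERROR = "error"
    DROP_RECORD = "drop_record"
    OTHER_CLASS = "other_class"


def _norm(name: str) -> str:
    return " ".join(unicodedata.normalize("NFKC", name).split()).casefold()


@dataclass(frozen=True)
class PriorityClass:
    """One urgency class: rank (1 = most urgent), display name, member diagnoses."""

    rank: int
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise SchemeValidationError(f"rank must be >= 1, got {self.rank}")
        if not self.members:
            raise SchemeValidationError(f"class {self.name!r} has no members")
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class PriorityScheme:
    """Validated ordered set of priority classes plus an unknown-diagnosis policy."""

    classes: list[PriorityClass]
    unknown_policy: UnknownPolicy = UnknownPolicy.DROP_RECORD
    _lookup: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.unknown_policy = UnknownPolicy(self.unknown_policy)
        self.classes = sorted(self.classes, key=lambda c: c.rank)
        ranks = [c.rank for c in self.classes]
        if ranks != list(range(1, len(ranks) + 1)):
            raise SchemeValidationError(f"ranks must be consecutive 1..K, got {ranks}")
        lookup: dict[str, int] = {}
        for cls in self.classes:
            for member in cls.members:
                key = _norm(member)
                if key in lookup and lookup[key] != cls.rank:
                    raise SchemeValidationError(
                        f"diagnosis {member!r} belongs to ranks "
                        f"{lookup[key]} and {cls.rank}; add an explicit resolution"
                    )
                lookup[key] = cls.rank
        self._lookup = lookup

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def other_rank(self) -> int:
        """Rank used for unknown diagnoses under the ``other_class`` policy."""
        return self.n_classes + 1

    def class_name(self, rank: int) -> str:
        if rank == self.other_rank:
            return "other"
        return self.classes[rank - 1].name

    def map_diagnosis(self, diagnosis: str) -> int | None:
        """Rank of one diagnosis.

        Lookup is exact after NFKC + casefold + whitespace normalisation.
        Unknowns: raise under ``error``, return ``None`` under
        ``drop_record``, return :attr:`other_rank` under ``other_class``.
        """
        rank = self._lookup.get(_norm(diagnosis))
        if rank is not None:
            return rank
        if self.unknown_policy is UnknownPolicy.ERROR:
            raise UnknownDiagnosisError(diagnosis)
        if self.unknown_policy is UnknownPolicy.OTHER_CLASS:
            return self.other_rank
        return None

    def integrate_labels(self, diagnoses: frozenset[str] | set[str]) -> frozenset[int]:
        """Coarsen a diagnosis set to its set of priority ranks.

        Deduplicates ranks; under ``drop_record`` unknown diagnoses are
        silently skipped, so an all-unknown set yields the empty set (the
        caller drops the record).
        """
        if not diagnoses:
            raise ValueError("diagnosis set must be non-empty")
        ranks = set()
        for d in diagnoses:
            rank = self.map_diagnosis(d)
            if rank is not None:
                ranks.add(rank)
        return frozenset(ranks)

    def triage_label(self, diagnoses: frozenset[str] | set[str]) -> int | None:
        """The single triage label: the most urgent (minimum) rank present."""
        ranks = self.integrate_labels(diagnoses)
        return min(ranks) if ranks else None


# --------------------------------------------------------------------------
# built-in scheme
# --------------------------------------------------------------------------

_BUILTIN = [
    (1, "trauma", [
        "Head trauma",
        "Scalp laceration",
        "Traumatic brain injury syndrome",
        "Scalp hematoma",
        "Skull fracture",
        "Scalp contusion",
        "Traumatic subarachnoid hemorrhage",
        "Multiple cerebral contusion",
        "Traumatic epidural hematoma",
        "Traumatic subdural hematoma",
        "Traumatic cerebral hemorrhage",
        "Cerebral edema",
        "Traumatic intracranial hemorrhage",
    ]),
    (2, "cerebral hemorrhage", [
        "Subarachnoid hemorrhage",
        "Cerebral hemorrhage",
    ]),
    (3, "epilepsy", ["Epilepsy"]),
    (4, "intracranial space-occupying lesion", [
        "Intracranial space occupying lesions",
    ]),
    (5, "aneurysm / vascular malformation", [
        "Intracranial aneurysm",
        "Cerebrovascular malformation",
        "Aneurysm",
    ]),
    (6, "post tumor surgery", [
        "After the brain tumor surgery",
        "After the pituitary tumor surgery",
    ]),
    (7, "chronic subdural hematoma", ["Chronic subdural hematoma"]),
    (8, "hydrocephalus", ["Hydrocephalus"]),
    (9, "headache", ["Headache"]),
    (10, "dizziness", ["Dizzy"]),
]


def builtin_scheme(
    unknown_policy: UnknownPolicy | str = UnknownPolicy.DROP_RECORD,
) -> PriorityScheme:
    """The built-in 10-class neurosurgery triage scheme."""
    classes = [
        PriorityClass(rank, name, frozenset(members))
        for rank, name, members in _BUILTIN
    ]
    return PriorityScheme(classes, unknown_policy=UnknownPolicy(unknown_policy))


# --------------------------------------------------------------------------
# config files
# --------------------------------------------------------------------------

def load_scheme(
    source: str | Path = "builtin",
    unknown_policy: UnknownPolicy | str | None = None,
) -> PriorityScheme:
    """Load a scheme: ``"builtin"`` or a YAML/JSON config path.

    A config file is a mapping with ``classes``: a list of
    ``{rank, name, members: [...]}``, optional ``unknown_policy`` and an
    optional ``resolve: {diagnosis: rank}`` mapping that must cover every
    diagnosis listed under more than one class.
    """
    if source == "builtin":
        return builtin_scheme(unknown_policy or UnknownPolicy.DROP_RECORD)
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if isinstance(cfg, list):  # bare list of classes
        cfg = {"classes": cfg}
    if not isinstance(cfg, dict) or "classes" not in cfg:
        raise SchemeValidationError(f"{path}: expected a 'classes' list")

    resolve = {_norm(k): int(v) for k, v in (cfg.get("resolve") or {}).items()}
    classes: list[PriorityClass] = []
    for entry in cfg["classes"]:
        rank = int(entry["rank"])
        members = []
        for m in entry.get("members", []):
            key = _norm(str(m))
            if key in resolve and resolve[key] != rank:
                continue  # resolved to another class
            members.append(str(m))
        classes.append(
            PriorityClass(rank, str(entry.get("name", f"class {rank}")), frozenset(members))
        )

    policy = unknown_policy or cfg.get("unknown_policy", UnknownPolicy.DROP_RECORD)
    # PriorityScheme.__post_init__ raises on any duplicate left unresolved
    return PriorityScheme(classes, unknown_policy=UnknownPolicy(policy))
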