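"""Core record types for the pipeline.

A dataset flows through three shapes: raw :class:`ProteinRecord` sequences,
a :class:`MeasurementTable` of per-id pH observations (point values or
lo/hi ranges, optionally tagged with the source organism), and a
:class:`CuratedDataset` mapping each surviving id to a single optimal-pH
label after the curation rules have been applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .errors import ValidationError

PH_MIN = 0.0
PH_MAX = 14.0

#: Canonical amino-acid alphabet in fixed (alphabetical) order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Tolerated noncanonical symbols (ambiguity codes and rare residues).
NONCANONICAL_AA = "BJOUXZ*"

_ALLOWED = set(CANONICAL_AA) | set(NONCANONICAL_AA)
_GAPS = {"-", "."}


def check_ph(value: float, context: str = "pH") -> float:
    """Validate a single pH value against the physically meaningful range."""
    v = float(value)
    if not (PH_MIN <= v <= PH_MAX):
        raise ValidationError(f"{context} value {v} outside [{PH_MIN}, {PH_MAX}]")
    return v


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with optional annotations.

    Parameters
    ----------
    id : str
        Accession identifier; nonempty and unique within a dataset.
    sequence : str
        Amino-acid string, uppercased at construction. The 20 canonical
        letters plus tolerated noncanonical symbols (X, B, Z, J, U, O, *)
        are accepted; whitespace and gap characters are rejected.
    pfam_ids, ec_numbers, superkingdom : optional annotations
    """

    id: str
    sequence: str
    pfam_ids: Optional[tuple[str, ...]] = None
    ec_numbers: Optional[tuple[str, ...]] = None
    superkingdom: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record id must be nonempty")
        seq = self.sequence.upper()
        if not seq:
            raise ValidationError(f"record {self.id!r}: sequence must be nonempty")
        bad = set(seq) - _ALLOWED
        if bad & _GAPS or any(c.isspace() for c in seq):
            raise ValidationError(
                f"record {self.id!r}: sequence contains gap or whitespace characters"
            )
        if bad:
            raise ValidationError(
                f"record {self.id!r}: unknown sequence symbols {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Observation:
    """One pH observation: a point value or a (lo, hi) range."""

    id: str
    lo: float
    hi: float
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        check_ph(self.lo, f"observation for {self.id!r}: lo")
        check_ph(self.hi, f"observation for {self.id!r}: hi")
        if self.lo > self.hi:
            raise ValidationError(
                f"observation for {self.id!r}: lo {self.lo} > hi {self.hi}"
            )

    @property
    def is_range(self) -> bool:
        return self.lo != self.hi

    @property
    def value(self) -> float:
        """Point value, or the midpoint for a range observation."""
        return (self.lo + self.hi) / 2.0

    @classmethod
    def point(cls, id: str, ph: float, organism: Optional[str] = None) -> "Observation":
        return cls(id=id, lo=ph, hi=ph, organism=organism)


@dataclass
class MeasurementTable:
    """Raw per-id pH observations before curation."""

    observations: list[Observation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.observations)

    def add(self, obs: Observation) -> None:
        self.observations.append(obs)

    def ids(self) -> list[str]:
        """Distinct ids in first-appearance order."""
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(obs.id, None)
        return list(seen)

    def by_id(self) -> dict[str, list[Observation]]:
        out: dict[str, list[Observation]] = {}
        for obs in self.observations:
            out.setdefault(obs.id, []).append(obs)
        return out


@dataclass
class CuratedDataset:
    """Labeled dataset: one optimal-pH value per protein record."""

    records: list[ProteinRecord]
    labels: dict[str, float]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids in dataset: {dupes}")
        missing = [i for i in ids if i not in self.labels]
        extra = [i for i in self.labels if i not in set(ids)]
        if missing or extra:
            raise ValidationError(
                f"records and labels disagree (missing labels: {missing[:5]}, "
                f"labels without records: {extra[:5]})"
            )
        for i, v in self.labels.items():
            check_ph(v, f"label for {i!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[ProteinRecord, float]]:
        for rec in self.records:
            yield rec, self.labels[rec.id]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_values(self) -> list[float]:
        return [self.labels[r.id] for r in self.records]

    def record(self, id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == id:
                return r
        raise KeyError(id)

    def subset(self, ids: Sequence[str]) -> "CuratedDataset":
        keep = set(ids)
        recs = [r for r in self.records if r.id in keep]
        return CuratedDataset(recs, {r.id: self.labels[r.id] for r in recs})
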