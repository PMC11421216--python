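"""Two-step k-mer baseline predictor.

Step one (once per training set): every length-k subsequence of every
training sequence is associated with that sequence's pH label; per k-mer the
mean, minimum and maximum of its label list are tabulated. Step two (per
query): the query's pH is the occurrence-weighted average of the tabulated
mean values over its k-mers,

    pH = (sum_i P_i * T_i) / N

where P_i counts occurrences of k-mer i in the query, T_i is its tabulated
mean (0 when the k-mer is absent from the table) and N is the number of
k-mer positions in the query (len - k + 1). Absent k-mers therefore drag the
literal prediction toward 0; the ``present_only`` mode divides by the number
of matched occurrences instead, which keeps predictions inside the training
label range and is the recommended setting in practice. Replacing the mean
column by the min / max columns yields an optimal-pH *range* estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterator, Literal

import numpy as np

from .data import CuratedDataset
from .errors import ParseError, ValidationError

Mode = Literal["literal", "present_only"]


@dataclass(frozen=True)
class KmerStats:
    mean_ph: float
    min_ph: float
    max_ph: float
    count: int

    def __post_init__(self) -> None:
        if not (self.min_ph <= self.mean_ph <= self.max_ph):
            raise ValidationError("k-mer stats must satisfy min <= mean <= max")
        if self.count < 1:
            raise ValidationError("k-mer count must be >= 1")


@dataclass
class KmerTable:
    """Sparse k-mer -> pH summary table plus the training-median fallback."""

    k: int
    entries: dict[str, KmerStats]
    train_median: float
    n_skipped_short: int = 0

    def __post_init__(self) -> None:
        bad = [m for m in self.entries if len(m) != self.k]
        if bad:
            raise ValidationError(f"k-mer keys of wrong length: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.entries)


def iter_kmers(sequence: str, k: int) -> Iterator[str]:
    for i in range(len(sequence) - k + 1):
        yield sequence[i : i + k]


def build_kmer_table(
    train: CuratedDataset, k: int = 3, multiset: bool = True
) -> KmerTable:
    """Aggregate training k-mer occurrences into (mean, min, max, count).

    With ``multiset`` (default) every occurrence of a k-mer in a sequence
    contributes one copy of that sequence's label, mirroring the
    occurrence-count weighting used at prediction time; with ``multiset=False``
    each sequence contributes its label once per distinct k-mer. Sequences
    shorter than k are skipped and counted in ``n_skipped_short``.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(train) == 0:
        raise ValidationError("build_kmer_table: empty training set")
    sums: dict[str, float] = {}
    mins: dict[str, float] = {}
    maxs: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_short = 0
    for rec, label in train:
        if len(rec.sequence) < k:
            n_short += 1
            continue
        kmers = iter_kmers(rec.sequence, k) if multiset else set(
            iter_kmers(rec.sequence, k)
        )
        for m in kmers:
            sums[m] = sums.get(m, 0.0) + label
            counts[m] = counts.get(m, 0) + 1
            mins[m] = min(mins.get(m, label), label)
            maxs[m] = max(maxs.get(m, label), label)
    entries = {
        m: KmerStats(
            # clamp: summed means can drift a ulp past the bounds
            mean_ph=min(max(sums[m] / counts[m], mins[m]), maxs[m]),
            min_ph=mins[m],
            max_ph=maxs[m],
            count=counts[m],
        )
        for m in sums
    }
    return KmerTable(
        k=k,
        entries=entries,
        train_median=float(median(train.label_values())),
        n_skipped_short=n_short,
    )


def _averaged(
    table: KmerTable, sequence: str, column: str, mode: Mode
) -> tuple[float, bool]:
    """Occurrence-weighted average of one stats column; bool flags the fallback."""
    if mode not in ("literal", "present_only"):
        raise ValidationError(f"unknown prediction mode {mode!r}")
    k = table.k
    if len(sequence) < k:
        raise ValidationError(
            f"sequence of length {len(sequence)} shorter than k={k}"
        )
    total = 0.0
    n_hits = 0
    n_positions = len(sequence) - k + 1
    for m in iter_kmers(sequence.upper(), k):
        stats = table.entries.get(m)
        if stats is not None:
            total += getattr(stats, column)
            n_hits += 1
    if mode == "literal":
        return total / n_positions, False
    if n_hits == 0:
        return table.train_median, True
    return total / n_hits, False


def predict_kmer_ph(table: KmerTable, sequence: str, mode: Mode = "literal") -> float:
    """Point optimal-pH prediction for one sequence (see module docstring)."""
    return _averaged(table, sequence, "mean_ph", mode)[0]


def predict_kmer_ph_flagged(
    table: KmerTable, sequence: str, mode: Mode = "literal"
) -> tuple[float, bool]:
    """As :func:`predict_kmer_ph`, also flagging the train-median fallback."""
    return _averaged(table, sequence, "mean_ph", mode)


def predict_kmer_range(
    table: KmerTable, sequence: str, mode: Mode = "literal"
) -> tuple[float, float]:
    """Optimal-pH range estimate: the same averaging over min / max columns."""
    lo, _ = _averaged(table, sequence, "min_ph", mode)
    hi, _ = _averaged(table, sequence, "max_ph", mode)
    return lo, hi


def write_kmer_table(table: KmerTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# k={table.k} train_median={table.train_median!r}\n")
        fh.write("kmer,mean,min,max,count\n")
        for m in sorted(table.entries):
            s = table.entries[m]
            fh.write(f"{m},{s.mean_ph!r},{s.min_ph!r},{s.max_ph!r},{s.count}\n")


def read_kmer_table(path: str) -> KmerTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# k="):
            raise ParseError(f"{path}: missing k-mer table header line")
        fields = dict(tok.split("=", 1) for tok in header[2:].split())
        k = int(fields["k"])
        train_median = float(fields["train_median"])
        colnames = fh.readline().strip().split(",")
        if colnames != ["kmer", "mean", "min", "max", "count"]:
            raise ParseError(f"{path}: unexpected k-mer table columns {colnames}")
        entries = {}
        for line in fh:
            m, mean, lo, hi, count = line.strip().split(",")
            entries[m] = KmerStats(float(mean), float(lo), float(hi), int(count))
    return KmerTable(k=k, entries=entries, train_median=train_median)
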