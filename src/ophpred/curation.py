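"""Curation rules turning raw pH measurements into one label per sequence.

Two aggregation paths exist. Optimal-pH curation pools all observations for
an id (ranges first replaced by their midpoints), discards the id when the
pooled values scatter too widely (population standard deviation above a
threshold, 1.0 by default), and otherwise labels it with the pooled mean.
Mean-growth-pH aggregation instead averages per organism first and then takes
the unweighted mean over organisms, so organisms with many measurements do
not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import CuratedDataset, MeasurementTable, ProteinRecord, check_ph
from .errors import ValidationError


def range_midpoint(lo: float, hi: float) -> float:
    """Midpoint of an optimal-pH range: (lo + hi) / 2."""
    check_ph(lo, "lo")
    check_ph(hi, "hi")
    if lo > hi:
        raise ValidationError(f"range lo {lo} > hi {hi}")
    return (lo + hi) / 2.0


@dataclass
class CurationLog:
    """Counts and ids recorded while curating, for pipeline reporting."""

    n_input_ids: int = 0
    n_kept: int = 0
    dropped_high_std: list[str] = field(default_factory=list)


def curate_optimal_ph(
    table: MeasurementTable,
    records: Sequence[ProteinRecord],
    std_threshold: float = 1.0,
) -> tuple[CuratedDataset, CurationLog]:
    """Apply the optimal-pH curation rules.

    Per id: range observations are replaced by midpoints and pooled with point
    values; if the pooled values have population standard deviation strictly
    greater than ``std_threshold`` the id is dropped, otherwise the label is
    the arithmetic mean of the pooled values. Ids with no measurements are
    absent from the output. Raises if a measurement id has no sequence record.
    """
    by_record = {r.id: r for r in records}
    grouped = table.by_id()
    missing = sorted(set(grouped) - set(by_record))
    if missing:
        raise ValidationError(f"measurement ids missing from records: {missing}")
    log = CurationLog(n_input_ids=len(grouped))
    kept_records: list[ProteinRecord] = []
    labels: dict[str, float] = {}
    for rid, observations in grouped.items():
        values = np.array([obs.value for obs in observations], dtype=float)
        if np.std(values) > std_threshold:  # population std, strict comparison
            log.dropped_high_std.append(rid)
            continue
        kept_records.append(by_record[rid])
        # clamp: the float mean can drift a ulp past the pooled extremes
        labels[rid] = float(min(max(np.mean(values), values.min()), values.max()))
    log.n_kept = len(kept_records)
    return CuratedDataset(kept_records, labels), log


def aggregate_growth_ph(observations: Mapping[str, Sequence[float]]) -> float:
    """Mean growth pH of one protein across organisms.

    The value is the unweighted mean over the K organisms of each organism's
    per-measurement mean, so every organism contributes equally regardless of
    how many times it was measured. The caller applies the std > 1.0 discard
    over the per-organism means, mirroring the optimal-pH rule.
    """
    if not observations:
        raise ValidationError("aggregate_growth_ph: no organisms supplied")
    means = []
    for organism, values in observations.items():
        if len(values) == 0:
            raise ValidationError(
                f"aggregate_growth_ph: organism {organism!r} has no measurements"
            )
        means.append(float(np.mean(np.asarray(values, dtype=float))))
    return float(np.mean(means))


def growth_ph_std(observations: Mapping[str, Sequence[float]]) -> float:
    """Population std of the per-organism means, for the caller's discard rule."""
    if not observations:
        raise ValidationError("growth_ph_std: no organisms supplied")
    means = [float(np.mean(np.asarray(v, dtype=float))) for v in observations.values()]
    return float(np.std(means))
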