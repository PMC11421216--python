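"""Performance metrics and the δ-vicinity filtered evaluation protocol.

Headline metrics are mean absolute error and Spearman's rank correlation
(average-rank transform followed by product-moment correlation of the ranks;
this equals the classical 1 - 6 Σ d_i² / (n(n²-1)) form exactly when there
are no ties). Because most curated labels sit near neutral pH, a constant
median predictor already looks respectable on MAE; the δ protocol therefore
removes test points whose true label lies within δ pH units of the training
median and re-scores, probing performance away from the neutral bulk.
Metrics can additionally be stratified by a group label (e.g. superkingdom).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

DEFAULT_DELTAS = (0.0, 0.5, 1.0, 1.5)


def mae(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean absolute error."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValidationError("mae: length mismatch")
    if yt.size == 0:
        raise ValidationError("mae: empty input")
    return float(np.mean(np.abs(yt - yp)))


def spearman(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Spearman rank correlation; NaN when either vector is constant.

    A constant vector has no rank ordering, so the correlation is undefined —
    this is exactly the naive median predictor's situation, reported as
    "absent" rather than 0.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValidationError("spearman: length mismatch")
    if yt.size < 2:
        raise ValidationError("spearman: need at least 2 points")
    if np.all(yt == yt[0]) or np.all(yp == yp[0]):
        return float("nan")
    return float(stats.spearmanr(yt, yp).statistic)


def delta_filter(
    y_true: Sequence[float],
    center: float,
    delta: float,
    closed: bool = False,
) -> np.ndarray:
    """Indices of test points retained at vicinity width δ.

    A point is removed when its true label falls inside the open interval
    (center - δ, center + δ); δ = 0 retains everything. ``closed`` switches
    to removing the closed interval (|y - center| <= δ) for users who prefer
    the boundary excluded.
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    yt = np.asarray(y_true, dtype=float)
    dev = np.abs(yt - center)
    keep = dev > delta if closed else dev >= delta
    return np.nonzero(keep)[0]


@dataclass
class MetricRow:
    n: int
    mae: Optional[float]
    spearman: Optional[float]  # None when undefined (constant vector or n < 2)


@dataclass
class EvalReport:
    n: int
    mae: float
    spearman: Optional[float]
    delta_table: dict[float, MetricRow] = field(default_factory=dict)
    group_table: dict[str, MetricRow] = field(default_factory=dict)

    def to_lines(self) -> list[str]:
        def fmt(x: Optional[float]) -> str:
            return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.4f}"

        lines = ["scope,delta,n,mae,spearman"]
        lines.append(f"overall,,{self.n},{fmt(self.mae)},{fmt(self.spearman)}")
        for d in sorted(self.delta_table):
            row = self.delta_table[d]
            lines.append(f"delta,{d},{row.n},{fmt(row.mae)},{fmt(row.spearman)}")
        for g in sorted(self.group_table):
            row = self.group_table[g]
            lines.append(f"group:{g},,{row.n},{fmt(row.mae)},{fmt(row.spearman)}")
        return lines

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.to_lines()) + "\n")


def _row(yt: np.ndarray, yp: np.ndarray) -> MetricRow:
    if yt.size == 0:
        return MetricRow(n=0, mae=None, spearman=None)
    m = mae(yt, yp)
    if yt.size < 2:
        return MetricRow(n=int(yt.size), mae=m, spearman=None)
    s = spearman(yt, yp)
    return MetricRow(n=int(yt.size), mae=m, spearman=None if math.isnan(s) else s)


def evaluate(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    train_median: float,
    deltas: Sequence[float] = DEFAULT_DELTAS,
    groups: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Full evaluation: overall, per-δ filtered, and optional per-group metrics.

    The δ filter is centered on the *training*-label median, so the protocol
    never consults test labels beyond the filtering itself.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape:
        raise ValidationError("evaluate: length mismatch")
    if yt.size == 0:
        raise ValidationError("evaluate: empty input")
    if groups is not None and len(groups) != yt.size:
        raise ValidationError("evaluate: groups length mismatch")
    overall = _row(yt, yp)
    report = EvalReport(
        n=overall.n, mae=overall.mae if overall.mae is not None else 0.0,
        spearman=overall.spearman,
    )
    for d in deltas:
        idx = delta_filter(yt, train_median, d)
        report.delta_table[float(d)] = _row(yt[idx], yp[idx])
    if groups is not None:
        garr = np.asarray(groups)
        for g in np.unique(garr):
            idx = np.nonzero(garr == g)[0]
            report.group_table[str(g)] = _row(yt[idx], yp[idx])
    return report
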