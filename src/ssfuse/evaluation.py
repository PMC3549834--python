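"""Performance metrics for predicted disulfide topologies.

A prediction is judged over the universe of candidate cysteine pairs:
true positives are known bonds predicted, true negatives are non-bonded
pairs left unpredicted.  Accuracy Q2, sensitivity Qc, specificity Qnc and
Matthews correlation are reported both *micro* (counts pooled across
proteins) and *macro* (per-protein metrics averaged), since aggregate
tables in the literature are usually macro averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import BondHypothesis, Topology


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def p(self) -> int:
        """Number of true bonds."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Number of true non-bonded pairs."""
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp, fp=self.fp + other.fp,
            tn=self.tn + other.tn, fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Q2 (accuracy), Qc (sensitivity), Qnc (specificity), MCC.

    Metrics with a zero denominator are NaN ("undefined"), not errors.
    """

    q2: float
    qc: float
    qnc: float
    mcc: float


def confusion(
    pred: Topology | Iterable[BondHypothesis],
    truth: Topology | Iterable[BondHypothesis],
    all_pairs: Iterable[BondHypothesis],
) -> ConfusionCounts:
    """Count the four outcomes over a pair universe.

    Truth must be contained in the universe; a predicted bond outside it
    is an error (it cannot be scored).
    """
    universe = set(all_pairs)
    pred_set = set(pred)
    truth_set = set(truth)
    if not truth_set <= universe:
        raise ValueError(f"truth bonds outside the pair universe: {truth_set - universe}")
    if not pred_set <= universe:
        raise ValueError(
            f"predicted bonds outside the pair universe: {pred_set - universe}"
        )
    tp = len(pred_set & truth_set)
    fp = len(pred_set - truth_set)
    fn = len(truth_set - pred_set)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: ConfusionCounts) -> MetricSet:
    """Q2, Qc, Qnc and MCC from the counts; NaN where undefined."""
    q2 = _ratio(c.tp + c.tn, c.p + c.n)
    qc = _ratio(c.tp, c.p)
    qnc = _ratio(c.tn, c.n)
    denom = (
        (c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, math.sqrt(denom)) if denom > 0 else math.nan
    return MetricSet(q2=q2, qc=qc, qnc=qnc, mcc=mcc)


def sensitivity(tp: int, p: int) -> float:
    """Qc = TP / P directly from counts (for bond-list-only fixtures)."""
    return _ratio(tp, p)


def macro_metrics(per_protein: Sequence[MetricSet]) -> MetricSet:
    """Arithmetic mean of each metric over proteins, skipping NaNs."""
    if not per_protein:
        raise ValueError("at least one protein is required")

    def mean_of(values: list[float]) -> float:
        vals = [v for v in values if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else math.nan

    return MetricSet(
        q2=mean_of([m.q2 for m in per_protein]),
        qc=mean_of([m.qc for m in per_protein]),
        qnc=mean_of([m.qnc for m in per_protein]),
        mcc=mean_of([m.mcc for m in per_protein]),
    )


def micro_metrics(per_protein: Sequence[ConfusionCounts]) -> MetricSet:
    """Metrics from pooled counts across proteins."""
    if not per_protein:
        raise ValueError("at least one protein is required")
    total = per_protein[0]
    for c in per_protein[1:]:
        total = total + c
    return metrics(total)
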