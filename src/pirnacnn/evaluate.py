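"""Binary-classification measures: ACC, Pre, Sn, Sp and MCC.

piRNA is the positive class.  A metric whose denominator is zero is
reported as ``None`` (an explicit "undefined" marker) rather than 0 or
an exception — silent zeros would corrupt fold averages.  Aggregation
over cross-validation folds reports the per-metric arithmetic mean and
sample (n-1) standard deviation, formatted "0.95 ± 0.003" style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from pirnacnn.errors import DataError
from pirnacnn.seqio import PredictionRecord

METRIC_NAMES = ("acc", "pre", "sn", "sp", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally with piRNA as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    """The five measures; ``None`` marks an undefined (0/0) value."""

    acc: Optional[float]
    pre: Optional[float]
    sn: Optional[float]
    sp: Optional[float]
    mcc: Optional[float]

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class AggregateReport:
    """Mean ± sd of each metric over folds, plus pooled-count metrics."""

    mean: MetricsReport
    sd: MetricsReport
    pooled: MetricsReport
    n_folds: int

    def formatted(self) -> str:
        """Table-style block: mean to 2 decimals, sd to 3."""
        header = "Metric\tMean ± SD\tPooled"
        rows = [header]
        labels = {"acc": "ACC", "pre": "Pre", "sn": "Sn", "sp": "Sp", "mcc": "MCC"}
        for name in METRIC_NAMES:
            m = getattr(self.mean, name)
            s = getattr(self.sd, name)
            p = getattr(self.pooled, name)
            cell = "undefined" if m is None else f"{m:.2f} ± {s:.3f}"
            pooled = "undefined" if p is None else f"{p:.4f}"
            rows.append(f"{labels[name]}\t{cell}\t{pooled}")
        return "\n".join(rows)


def confusion(preds: Sequence[PredictionRecord], truths: Sequence[str]) -> ConfusionCounts:
    """Tally predictions against truth labels ("piRNA"/"non-piRNA").

    ``truths`` may be a list of labels aligned with ``preds`` or a
    mapping id -> label; with a mapping, every prediction id must be
    present.
    """
    if isinstance(truths, dict):
        missing = [p.id for p in preds if p.id not in truths]
        if missing:
            raise DataError(f"no truth label for ids {missing[:5]}")
        pairs = [(p.call, truths[p.id]) for p in preds]
    else:
        if len(preds) != len(truths):
            raise DataError("predictions and truths differ in length")
        pairs = [(p.call, t) for p, t in zip(preds, truths)]
    tp = fp = tn = fn = 0
    for call, truth in pairs:
        if truth == "piRNA":
            if call == "piRNA":
                tp += 1
            else:
                fn += 1
        else:
            if call == "piRNA":
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Compute ACC, Pre, Sn, Sp, MCC from a confusion tally.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any
    zero factor makes it undefined (None), as for the ratio metrics.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = _ratio(tp + tn, c.total)
    pre = _ratio(tp, tp + fp)
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(acc, pre, sn, sp, mcc)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2 or max(values) == min(values):
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def aggregate(fold_reports: Sequence[MetricsReport],
              fold_counts: Sequence[ConfusionCounts] | None = None) -> AggregateReport:
    """Mean ± sample sd per metric over folds (macro aggregation).

    When the per-fold confusion counts are supplied, pooled-count
    (micro) metrics are computed as well; macro is the headline number.
    A metric undefined in any fold is aggregated over the defined folds
    only; if undefined everywhere, the aggregate is undefined too.
    """
    if len(fold_reports) < 2:
        raise ValueError("need at least two fold reports to aggregate")
    means: dict = {}
    sds: dict = {}
    for name in METRIC_NAMES:
        defined = [getattr(r, name) for r in fold_reports if getattr(r, name) is not None]
        if defined:
            means[name], sds[name] = _mean_sd(defined)
        else:
            means[name] = sds[name] = None
    if fold_counts:
        pooled_counts = fold_counts[0]
        for c in fold_counts[1:]:
            pooled_counts = pooled_counts + c
        pooled = metrics(pooled_counts)
    else:
        pooled = MetricsReport(None, None, None, None, None)
    return AggregateReport(MetricsReport(**means), MetricsReport(**sds), pooled,
                           n_folds=len(fold_reports))
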