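"""Agreement metrics of a test against a label set, with bootstrap CIs.

The label set may be the ground truth or a noisy comparator; following the
regulatory naming convention, ratio metrics computed against an uncertain
comparator are reported as positive/negative percent agreement (PPA/NPA)
rather than sensitivity/specificity — the arithmetic is identical, the name
signals that the reference may be wrong.

AUC is the Mann-Whitney rank statistic (probability a random positive
outranks a random negative, ties credited 0.5), computed in O(n log n) via
midranks.  Metrics with an empty denominator are undefined and surface as
``None`` / NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .cohort import Cohort, SeedLike, as_rng

__all__ = [
    "MetricSet",
    "ConfidenceInterval",
    "METRIC_NAMES",
    "auc",
    "confusion_metrics",
    "compute_metrics",
    "bootstrap_ci",
]

METRIC_NAMES = ("auc", "ppa", "npa", "ppv", "npv")


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts plus derived agreement metrics.

    ``tp/fp/tn/fn`` are counts of the test call against the label set
    (labels play the role of the reference).  Ratio metrics are ``None``
    when their denominator is empty.  ``auc`` is carried when scores were
    available, else ``None``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: Optional[float] = None

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    @property
    def ppa(self) -> Optional[float]:
        """Positive percent agreement (= sensitivity vs a perfect reference)."""
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def npa(self) -> Optional[float]:
        """Negative percent agreement (= specificity vs a perfect reference)."""
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    def value(self, metric: str) -> Optional[float]:
        if metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
        return getattr(self, metric)

    def as_dict(self) -> dict:
        d = {m: self.value(m) for m in METRIC_NAMES}
        d.update(tp=self.tp, fp=self.fp, tn=self.tn, fn=self.fn)
        return d


@dataclass(frozen=True)
class ConfidenceInterval:
    """Percentile interval; ``unstable`` flags >50% undefined resamples."""

    lower: float
    upper: float
    level: float = 0.95
    method: str = "bootstrap"
    n_undefined: int = 0
    unstable: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def auc(scores: Sequence[float], labels: Sequence) -> float:
    """Mann-Whitney AUC of scores against binary labels, ties credited 0.5.

    Equals the mean over all positive-negative pairs of
    1[score_pos > score_neg] + 0.5 * 1[tie].  Raises ``ValueError`` when a
    class is empty; batch callers should pre-check and record the metric as
    missing instead.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative label")
    ranks = stats.rankdata(s)  # midranks handle ties -> 0.5 pair credit
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_metrics(calls: Sequence, labels: Sequence) -> MetricSet:
    """2x2 confusion counts and agreement metrics of calls vs labels."""
    c = np.asarray(calls, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if c.shape != y.shape:
        raise ValueError("calls and labels must have equal length")
    if c.size == 0:
        raise ValueError("calls and labels must be nonempty")
    tp = int(np.sum(c & y))
    fp = int(np.sum(c & ~y))
    tn = int(np.sum(~c & ~y))
    fn = int(np.sum(~c & y))
    return MetricSet(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(cohort: Cohort, labels: Sequence) -> MetricSet:
    """All metrics of a cohort's test (scores + calls) against a label set.

    AUC is None (missing) when the label set is single-class.
    """
    y = np.asarray(labels, dtype=bool)
    base = confusion_metrics(cohort.calls, y)
    a: Optional[float] = None
    if 0 < y.sum() < y.size:
        a = auc(cohort.score, y)
    return MetricSet(tp=base.tp, fp=base.fp, tn=base.tn, fn=base.fn, auc=a)


def bootstrap_ci(
    cohort: Cohort,
    labels: Sequence,
    metric: str,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: SeedLike = None,
) -> ConfidenceInterval:
    """Patient-level bootstrap percentile interval for one metric.

    Patients are resampled with replacement ``n_boot`` times; the interval
    is the (alpha/2, 1 - alpha/2) percentile of the resampled metric.
    Resamples where the metric is undefined (empty denominator or
    single-class labels for AUC) are dropped and counted; the interval is
    flagged unstable when more than half are undefined.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    y = np.asarray(labels, dtype=bool)
    if y.size != cohort.n:
        raise ValueError("labels must match cohort length")
    rng = as_rng(seed)
    scores = cohort.score
    calls = cohort.calls
    values = np.empty(n_boot)
    n_undef = 0
    for b in range(n_boot):
        idx = rng.integers(0, cohort.n, size=cohort.n)
        yb = y[idx]
        if metric == "auc":
            k = int(yb.sum())
            if k == 0 or k == yb.size:
                values[b] = np.nan
                n_undef += 1
                continue
            values[b] = auc(scores[idx], yb)
        else:
            v = confusion_metrics(calls[idx], yb).value(metric)
            if v is None:
                values[b] = np.nan
                n_undef += 1
            else:
                values[b] = v
    good = values[~np.isnan(values)]
    if good.size == 0:
        raise ValueError(f"metric {metric!r} undefined in every bootstrap resample")
    alpha = 1.0 - level
    lo, hi = np.quantile(good, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ConfidenceInterval(
        lower=float(lo),
        upper=float(hi),
        level=level,
        method="bootstrap",
        n_undefined=n_undef,
        unstable=n_undef > n_boot / 2,
    )
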