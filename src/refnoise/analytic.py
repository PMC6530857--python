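"""Closed-form expectations for apparent performance under comparator noise.

These are the deterministic counterparts of the Monte-Carlo engine: given a
test's true sensitivity/specificity (or true AUC) and the comparator's
false-positive/false-negative rates, they return the expected *apparent*
metrics when the test is scored against the noisy comparator instead of the
ground truth.  They double as an independent oracle for the simulator — the
two are cross-checked in the test suite — and give the "AUC ceiling": the
maximum apparent AUC any test, even a perfect one, can achieve against a
comparator with a given error rate.

Derivation sketch (mixture identities over the 2x2 table): flipping is
independent of the test result, so each comparator class is a mixture of
truly-positive and truly-negative patients.  For apparent PPA, the
comparator-positive group contains (1 - fn) * n_pos true positives (test
positive with probability se) and fp * n_neg true negatives (test positive
with probability 1 - sp):

    PPA' = [(1-fn) n_pos se + fp n_neg (1-sp)] / [(1-fn) n_pos + fp n_neg]

and analogously for NPA, PPV, NPV.  For AUC, with a = contaminated fraction
of comparator positives and b = of comparator negatives, a random
comparator-positive vs comparator-negative pair is (clean, clean) with
probability (1-a)(1-b) (ordered correctly with probability A), mixed with
probability (1-a)b + a(1-b) (within-class exchangeability gives 0.5), and
doubly contaminated with probability ab (ordered correctly with
probability 1 - A):

    AUC' = (1-a)(1-b) A + [(1-a)b + a(1-b)] / 2 + a b (1 - A)

A perfect balanced test at overall flip rate e gives the ceiling 1 - e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

__all__ = [
    "ExpectedMetrics",
    "PerformanceRequirement",
    "expected_apparent_metrics",
    "expected_apparent_auc",
    "expected_overall_misclassification",
    "rejection_probability",
    "relative_error",
]


@dataclass(frozen=True)
class ExpectedMetrics:
    """Expected apparent agreement metrics; None where the denominator is empty."""

    ppa: Optional[float]
    npa: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]

    def as_dict(self) -> dict:
        return {"ppa": self.ppa, "npa": self.npa, "ppv": self.ppv, "npv": self.npv}


def _check_prop(name: str, x: float) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {x}")


def expected_apparent_metrics(
    se: float,
    sp: float,
    n_neg: int,
    n_pos: int,
    fp_rate: float,
    fn_rate: float,
) -> ExpectedMetrics:
    """Expected apparent PPA/NPA/PPV/NPV under class-specific comparator noise.

    Exact at the expectation level for exact-count flipping with per-class
    rates; with fp_rate = fn_rate it is also the expectation under pooled
    uniform flipping on a balanced cohort.
    """
    for name, x in (("se", se), ("sp", sp), ("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        _check_prop(name, x)
    if n_neg < 0 or n_pos < 0 or n_neg + n_pos == 0:
        raise ValueError("need nonnegative class sizes with at least one patient")
    fp, fn = fp_rate, fn_rate

    def ratio(num: float, den: float) -> Optional[float]:
        return num / den if den > 0 else None

    # comparator-positive group: surviving true positives + flipped negatives
    ppa = ratio((1 - fn) * n_pos * se + fp * n_neg * (1 - sp),
                (1 - fn) * n_pos + fp * n_neg)
    npa = ratio((1 - fp) * n_neg * sp + fn * n_pos * (1 - se),
                (1 - fp) * n_neg + fn * n_pos)
    # test-positive group: true positives called positive + false-positive calls
    ppv = ratio(n_pos * se * (1 - fn) + n_neg * (1 - sp) * fp,
                n_pos * se + n_neg * (1 - sp))
    npv = ratio(n_neg * sp * (1 - fp) + n_pos * (1 - se) * fn,
                n_neg * sp + n_pos * (1 - se))
    return ExpectedMetrics(ppa=ppa, npa=npa, ppv=ppv, npv=npv)


def expected_apparent_auc(
    true_auc: float,
    n_neg: int,
    n_pos: int,
    fp_rate: float,
    fn_rate: float,
) -> float:
    """Expected apparent AUC under comparator noise (three-way pair mixture).

    With ``true_auc = 1`` and balanced classes at overall rate e this is the
    AUC ceiling 1 - e.  Assumes flip selection is independent of score
    (within-class exchangeability), which holds for all injection schemes
    whose weights do not depend on the test score.
    """
    if not (0.5 <= true_auc <= 1.0):
        raise ValueError("true_auc must lie in [0.5, 1]")
    _check_prop("fp_rate", fp_rate)
    _check_prop("fn_rate", fn_rate)
    n_cpos = (1 - fn_rate) * n_pos + fp_rate * n_neg
    n_cneg = (1 - fp_rate) * n_neg + fn_rate * n_pos
    if n_cpos <= 0 or n_cneg <= 0:
        raise ValueError("comparator class is empty; apparent AUC undefined")
    a = fp_rate * n_neg / n_cpos   # contaminated fraction of comparator positives
    b = fn_rate * n_pos / n_cneg   # contaminated fraction of comparator negatives
    A = true_auc
    return (1 - a) * (1 - b) * A + ((1 - a) * b + a * (1 - b)) * 0.5 + a * b * (1 - A)


def expected_overall_misclassification(
    fp_rate: float, fn_rate: float, n_neg: int, n_pos: int
) -> float:
    """Overall comparator error rate: class-size-weighted mean of FP and FN rates."""
    _check_prop("fp_rate", fp_rate)
    _check_prop("fn_rate", fn_rate)
    if n_neg < 0 or n_pos < 0 or n_neg + n_pos == 0:
        raise ValueError("need at least one patient")
    return (fp_rate * n_neg + fn_rate * n_pos) / (n_neg + n_pos)


@dataclass(frozen=True)
class PerformanceRequirement:
    """A pass/fail bar for a trial: e.g. "PPA must reach 0.99".

    ``n_labelled`` is the number of comparator-positive (for PPA) or
    comparator-negative (for NPA) patients; ``per_label_accuracy`` the
    probability each such comparator label is actually correct.
    """

    metric: str
    required_level: float
    n_labelled: int
    per_label_accuracy: float

    def __post_init__(self) -> None:
        if self.metric not in ("ppa", "npa"):
            raise ValueError("requirement metric must be 'ppa' or 'npa'")
        _check_prop("required_level", self.required_level)
        _check_prop("per_label_accuracy", self.per_label_accuracy)
        if self.n_labelled < 1:
            raise ValueError("n_labelled must be >= 1")


def rejection_probability(req: PerformanceRequirement) -> float:
    """Probability a *perfect* test fails the requirement due to comparator noise.

    A perfect test agrees with a comparator label exactly when that label is
    correct, so the observed agreement count is Binomial(n, p) with
    p = per_label_accuracy.  The test is rejected when the count falls below
    ceil(required_level * n); the exact binomial tail gives the probability.
    Point-estimate thresholding is used (the bar applies to the observed
    proportion itself, not a confidence bound).
    """
    n = req.n_labelled
    k = math.ceil(req.required_level * n)
    if k <= 0:
        return 0.0
    # P(X >= k) via the exact survival function; rejection is its complement
    p_pass = float(stats.binom.sf(k - 1, n, req.per_label_accuracy))
    return 1.0 - p_pass


def relative_error(auc: float, auc0: float) -> float:
    """Apparent error rate relative to the noise-free error: (1-AUC)/(1-AUC0).

    ``auc0`` is the AUC at zero comparator misclassification; values above 1
    quantify how much comparator noise inflates the apparent error.
    """
    if auc0 >= 1.0:
        raise ZeroDivisionError(
            "relative error is undefined when the noise-free AUC is exactly 1"
        )
    return (1.0 - auc) / (1.0 - auc0)
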