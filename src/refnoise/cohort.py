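"""Cohort data model and synthetic cohort generators.

A cohort is the unit of every simulation here: a set of patients, each with a
binary ground-truth disease state, a continuous test score (higher = more
positive) and optionally a binary test call obtained by thresholding the
score.  Three generators cover the canonical study designs:

* :func:`make_perfect_cohort` — a test with no score overlap between classes
  (true AUC exactly 1), used to isolate the effect of comparator noise.
* :func:`make_binormal_cohort` — equal-variance binormal scores tuned to a
  target population AUC, the standard overlap model in ROC analysis.
* :func:`make_called_cohort` — binary calls with exact sensitivity and
  specificity counts, for reproducing worked 2x2-table examples bit-for-bit.

All generators take an explicit seed; the same seed yields the same cohort.
The call convention throughout the package is ``score >= threshold`` =>
positive call (ties at the threshold are positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "Patient",
    "Cohort",
    "ScenarioSpec",
    "make_perfect_cohort",
    "make_binormal_cohort",
    "make_called_cohort",
    "binormal_separation",
]

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def as_rng(seed: SeedLike) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding.

    Used for every count-from-proportion conversion so that fixtures such as
    round(0.850 * 100) = 85 are platform-stable.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


class Patient(NamedTuple):
    """One subject: id, true state, test score, optional binary call."""

    id: str
    truth: bool
    score: float
    call: Optional[bool] = None


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of patients with an optional call threshold.

    Parameters
    ----------
    ids : array of str
        Unique patient identifiers.
    truth : boolean array
        Ground-truth state (True = positive).
    score : float array
        Continuous test output, higher = more positive; must be finite.
    call : boolean array, optional
        Binary test call.  If absent and ``threshold`` is set, calls are
        derived as ``score >= threshold``.
    threshold : float, optional
        Score cutoff mapping scores to calls.
    """

    ids: np.ndarray
    truth: np.ndarray
    score: np.ndarray
    call: Optional[np.ndarray] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=object)
        truth = np.asarray(self.truth, dtype=bool)
        score = np.asarray(self.score, dtype=float)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "score", score)
        if len(truth) < 1:
            raise ValueError("a cohort needs at least one patient")
        if not (len(ids) == len(truth) == len(score)):
            raise ValueError("ids, truth and score must have equal length")
        if len(set(ids.tolist())) != len(ids):
            raise ValueError("patient ids must be unique")
        if not np.all(np.isfinite(score)):
            raise ValueError("scores must be finite")
        if self.call is not None:
            call = np.asarray(self.call, dtype=bool)
            if len(call) != len(truth):
                raise ValueError("call must match cohort length")
            object.__setattr__(self, "call", call)
            if self.threshold is not None and not np.array_equal(
                call, score >= self.threshold
            ):
                raise ValueError(
                    "calls are inconsistent with the threshold convention "
                    "call == (score >= threshold)"
                )

    @property
    def n(self) -> int:
        return len(self.truth)

    @property
    def n_pos(self) -> int:
        return int(self.truth.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.truth).sum())

    @property
    def calls(self) -> np.ndarray:
        """Binary calls, derived from the threshold when not stored."""
        if self.call is not None:
            return self.call
        if self.threshold is None:
            raise ValueError("cohort has neither calls nor a threshold")
        return self.score >= self.threshold

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[Patient]:
        call = self.call
        for i in range(self.n):
            yield Patient(
                id=str(self.ids[i]),
                truth=bool(self.truth[i]),
                score=float(self.score[i]),
                call=None if call is None else bool(call[i]),
            )

    def with_calls_from_threshold(self) -> "Cohort":
        return replace(self, call=self.calls)


def make_perfect_cohort(n_neg: int, n_pos: int, seed: SeedLike = None) -> Cohort:
    """Cohort for a perfect test: positive scores strictly above negatives.

    Negative scores are uniform on [0, 0.4] and positives on [0.6, 1], two
    disjoint bands; the threshold sits at 0.5 between them, so calls equal
    truth and the AUC against ground truth is exactly 1 for every seed.
    """
    if n_neg < 1 or n_pos < 1:
        raise ValueError("n_neg and n_pos must each be >= 1")
    rng = as_rng(seed)
    neg_scores = rng.uniform(0.0, 0.4, size=n_neg)
    pos_scores = rng.uniform(0.6, 1.0, size=n_pos)
    ids = np.array(
        [f"neg{i:04d}" for i in range(n_neg)] + [f"pos{i:04d}" for i in range(n_pos)],
        dtype=object,
    )
    truth = np.concatenate([np.zeros(n_neg, bool), np.ones(n_pos, bool)])
    score = np.concatenate([neg_scores, pos_scores])
    return Cohort(ids=ids, truth=truth, score=score, call=truth.copy(), threshold=0.5)


def binormal_separation(target_auc: float) -> float:
    """Mean separation d = sqrt(2) * Phi^-1(AUC) of the equal-variance binormal model.

    Inverts AUC = Phi(d / sqrt(2)) for two unit-variance Gaussians whose
    means differ by d.
    """
    return math.sqrt(2.0) * float(stats.norm.ppf(target_auc))


def make_binormal_cohort(
    n_neg: int, n_pos: int, target_auc: float, seed: SeedLike = None
) -> Cohort:
    """Cohort with overlapping Gaussian scores at a target population AUC.

    Negatives ~ N(0, 1), positives ~ N(d, 1) with d = sqrt(2) * Phi^-1(AUC),
    so the population AUC equals ``target_auc``; the sample AUC fluctuates
    around it.  The default threshold is the midpoint d/2 of the two means
    and calls are derived from it.
    """
    if n_neg < 1 or n_pos < 1:
        raise ValueError("n_neg and n_pos must each be >= 1")
    if not (0.5 <= target_auc < 1.0):
        raise ValueError("target_auc must lie in [0.5, 1)")
    rng = as_rng(seed)
    delta = binormal_separation(target_auc)
    neg_scores = rng.normal(0.0, 1.0, size=n_neg)
    pos_scores = rng.normal(delta, 1.0, size=n_pos)
    ids = np.array(
        [f"neg{i:04d}" for i in range(n_neg)] + [f"pos{i:04d}" for i in range(n_pos)],
        dtype=object,
    )
    truth = np.concatenate([np.zeros(n_neg, bool), np.ones(n_pos, bool)])
    score = np.concatenate([neg_scores, pos_scores])
    threshold = delta / 2.0
    return Cohort(
        ids=ids,
        truth=truth,
        score=score,
        call=score >= threshold,
        threshold=threshold,
    )


def make_called_cohort(
    n_neg: int, n_pos: int, se: float, sp: float, seed: SeedLike = None
) -> Cohort:
    """Cohort with exact sensitivity/specificity counts of binary calls.

    Exactly ``round(se * n_pos)`` positives carry a positive call and
    ``round(sp * n_neg)`` negatives a negative call (rounding half away from
    zero); which patients is chosen at random.  Scores are placed in the
    band consistent with each call ([0.6, 1] for positive calls, [0, 0.4]
    for negative) around the fixed threshold 0.5.
    """
    if n_neg < 1 or n_pos < 1:
        raise ValueError("n_neg and n_pos must each be >= 1")
    if not (0.0 <= se <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("se and sp must lie in [0, 1]")
    rng = as_rng(seed)
    n_tp = round_half_away(se * n_pos)
    n_tn = round_half_away(sp * n_neg)

    pos_call = np.zeros(n_pos, bool)
    pos_call[rng.choice(n_pos, size=n_tp, replace=False)] = True
    neg_call = np.ones(n_neg, bool)  # True here means "called positive"
    neg_call[:] = False
    fp_idx = rng.choice(n_neg, size=n_neg - n_tn, replace=False)
    neg_call[fp_idx] = True

    call = np.concatenate([neg_call, pos_call])
    score = np.where(
        call,
        rng.uniform(0.6, 1.0, size=n_neg + n_pos),
        rng.uniform(0.0, 0.4, size=n_neg + n_pos),
    )
    ids = np.array(
        [f"neg{i:04d}" for i in range(n_neg)] + [f"pos{i:04d}" for i in range(n_pos)],
        dtype=object,
    )
    truth = np.concatenate([np.zeros(n_neg, bool), np.ones(n_pos, bool)])
    return Cohort(ids=ids, truth=truth, score=score, call=call, threshold=0.5)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parametric description of a synthetic cohort, buildable on demand.

    ``shape`` is one of ``"perfect"``, ``"binormal"`` (requires
    ``target_auc``) or ``"fixed_counts"`` (requires ``se`` and ``sp``).
    Used by the engine's trial-size sweeps, where the same scenario is
    re-instantiated at several cohort sizes.
    """

    n_neg: int
    n_pos: int
    shape: str = "perfect"
    target_auc: Optional[float] = None
    se: Optional[float] = None
    sp: Optional[float] = None
    seed: SeedLike = None

    def __post_init__(self) -> None:
        if self.n_neg < 0 or self.n_pos < 0 or self.n_neg + self.n_pos < 2:
            raise ValueError("need n_neg >= 0, n_pos >= 0, n_neg + n_pos >= 2")
        if self.shape not in ("perfect", "binormal", "fixed_counts"):
            raise ValueError(f"unknown cohort shape {self.shape!r}")
        if self.shape == "binormal":
            if self.target_auc is None or not (0.5 <= self.target_auc < 1.0):
                raise ValueError("binormal shape requires target_auc in [0.5, 1)")
        if self.shape == "fixed_counts":
            if self.se is None or self.sp is None:
                raise ValueError("fixed_counts shape requires se and sp")

    def build(self, seed: SeedLike = None) -> Cohort:
        """Instantiate the cohort; an explicit seed overrides the stored one."""
        use = seed if seed is not None else self.seed
        if self.shape == "perfect":
            return make_perfect_cohort(self.n_neg, self.n_pos, use)
        if self.shape == "binormal":
            return make_binormal_cohort(self.n_neg, self.n_pos, self.target_auc, use)
        return make_called_cohort(self.n_neg, self.n_pos, self.se, self.sp, use)

    def resized(self, n_neg: int, n_pos: int) -> "ScenarioSpec":
        return replace(self, n_neg=n_neg, n_pos=n_pos)
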