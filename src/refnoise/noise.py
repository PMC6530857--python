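"""Comparator misclassification (noise) injection.

The comparator — the imperfect reference a new test is judged against — is
modelled as the ground-truth labels with a controlled number of flips.
Three schemes are provided:

* :func:`inject_uniform` — a fixed overall fraction of patients, drawn from
  the pooled cohort, has its label flipped (positives and negatives equally
  likely to be misclassified).
* :func:`inject_class_rates` — separate false-positive and false-negative
  rates: a fixed fraction of true negatives is flipped to positive and of
  true positives to negative.
* :func:`inject_weighted` — flips drawn without replacement with probability
  proportional to a per-patient weight, for noise that follows an observed
  uncertainty distribution (e.g. expert-panel residual uncertainty).

All schemes flip an exact count, ``round(rate * N)`` (half away from zero),
rather than per-patient Bernoulli trials: the realized noise level on the
x-axis of a sweep is then exact, and only the identity of the flipped
patients is random.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .cohort import SeedLike, as_rng, round_half_away

__all__ = [
    "NoiseSpec",
    "ComparatorLabels",
    "InfeasibleSelectionError",
    "inject_uniform",
    "inject_class_rates",
    "inject_weighted",
]


class InfeasibleSelectionError(ValueError):
    """Raised when a weighted draw cannot produce the requested flip count."""


@dataclass(frozen=True)
class ComparatorLabels:
    """Comparator labels for a cohort, with flip provenance.

    ``labels[i]`` is the comparator's classification of patient *i*;
    ``flipped[i]`` is True iff it diverges from ground truth.  ``fp_count``
    counts true negatives labelled positive, ``fn_count`` true positives
    labelled negative.
    """

    labels: np.ndarray
    flipped: np.ndarray
    fp_count: int
    fn_count: int

    @property
    def n_flipped(self) -> int:
        return self.fp_count + self.fn_count


def _finish(truth: np.ndarray, flip_idx: np.ndarray) -> ComparatorLabels:
    labels = truth.copy()
    labels[flip_idx] = ~labels[flip_idx]
    flipped = np.zeros_like(truth)
    flipped[flip_idx] = True
    fp_count = int(np.sum(flipped & ~truth))  # true negative -> labelled positive
    fn_count = int(np.sum(flipped & truth))
    return ComparatorLabels(labels=labels, flipped=flipped, fp_count=fp_count, fn_count=fn_count)


def _check_truth(truth: Sequence) -> np.ndarray:
    arr = np.asarray(truth, dtype=bool)
    if arr.size == 0:
        raise ValueError("label sequence must be nonempty")
    return arr


def inject_uniform(truth: Sequence, rate: float, seed: SeedLike = None) -> ComparatorLabels:
    """Flip exactly ``round(rate * N)`` labels chosen uniformly from the cohort.

    Both classes are equally likely to be misclassified, so the realized
    FP/FN split is hypergeometric — a deliberate source of iteration-to-
    iteration spread in the sweeps.
    """
    arr = _check_truth(truth)
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = as_rng(seed)
    n_flip = round_half_away(rate * arr.size)
    flip_idx = rng.choice(arr.size, size=n_flip, replace=False)
    return _finish(arr, flip_idx)


def inject_class_rates(
    truth: Sequence, fp_rate: float, fn_rate: float, seed: SeedLike = None
) -> ComparatorLabels:
    """Flip exact per-class counts: FP rate on true negatives, FN rate on positives."""
    arr = _check_truth(truth)
    if not (0.0 <= fp_rate <= 1.0 and 0.0 <= fn_rate <= 1.0):
        raise ValueError("fp_rate and fn_rate must lie in [0, 1]")
    rng = as_rng(seed)
    neg_idx = np.flatnonzero(~arr)
    pos_idx = np.flatnonzero(arr)
    if fp_rate > 0 and neg_idx.size == 0:
        raise ValueError("nonzero fp_rate with no true negatives in the cohort")
    if fn_rate > 0 and pos_idx.size == 0:
        raise ValueError("nonzero fn_rate with no true positives in the cohort")
    n_fp = round_half_away(fp_rate * neg_idx.size)
    n_fn = round_half_away(fn_rate * pos_idx.size)
    flips = [
        rng.choice(neg_idx, size=n_fp, replace=False) if n_fp else np.empty(0, int),
        rng.choice(pos_idx, size=n_fn, replace=False) if n_fn else np.empty(0, int),
    ]
    return _finish(arr, np.concatenate(flips))


def weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k distinct indices, sequentially, with renormalized weights.

    Each draw selects index i with probability w_i / sum(remaining w), then
    zeroes w_i.  Sequential renormalized draws are used (rather than e.g.
    Gumbel tricks) so that results are seed-stable and easy to reason about.
    """
    w = np.asarray(weights, dtype=float).copy()
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and nonnegative")
    if k > np.count_nonzero(w):
        raise InfeasibleSelectionError(
            f"cannot draw {k} patients: only {np.count_nonzero(w)} have positive weight"
        )
    chosen = np.empty(k, dtype=int)
    for j in range(k):
        total = w.sum()
        i = rng.choice(w.size, p=w / total)
        chosen[j] = i
        w[i] = 0.0
    return chosen


def inject_weighted(
    truth: Sequence,
    weights: Sequence[float],
    total_rate: float,
    seed: SeedLike = None,
) -> ComparatorLabels:
    """Flip ``round(total_rate * N)`` labels drawn proportionally to weights.

    A patient with weight zero is never flipped; a patient with twice the
    weight of another is (approximately) twice as likely to be selected.
    Sampling is without replacement — each patient has a single label.
    """
    arr = _check_truth(truth)
    w = np.asarray(weights, dtype=float)
    if w.size != arr.size:
        raise ValueError("weights must have one entry per patient")
    if not 0.0 <= total_rate <= 1.0:
        raise ValueError("total_rate must lie in [0, 1]")
    rng = as_rng(seed)
    n_flip = round_half_away(total_rate * arr.size)
    if n_flip == 0:
        return _finish(arr, np.empty(0, int))
    flip_idx = weighted_sample_without_replacement(w, n_flip, rng)
    return _finish(arr, flip_idx)


@dataclass(frozen=True)
class NoiseSpec:
    """Declarative description of one noise-injection scheme.

    Construct via :meth:`uniform`, :meth:`class_rates` or :meth:`weighted`;
    apply to a truth vector with :meth:`apply`.  ``level`` is the nominal
    overall misclassification rate used to label sweep axes.
    """

    mode: str
    rate: Optional[float] = None
    fp_rate: Optional[float] = None
    fn_rate: Optional[float] = None
    weights: Optional[tuple] = None
    total_rate: Optional[float] = None

    @classmethod
    def uniform(cls, rate: float) -> "NoiseSpec":
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")
        return cls(mode="uniform", rate=rate)

    @classmethod
    def class_rates(cls, fp_rate: float, fn_rate: float) -> "NoiseSpec":
        if not (0.0 <= fp_rate <= 1.0 and 0.0 <= fn_rate <= 1.0):
            raise ValueError("fp_rate and fn_rate must lie in [0, 1]")
        return cls(mode="class_rates", fp_rate=fp_rate, fn_rate=fn_rate)

    @classmethod
    def weighted(cls, weights: Sequence[float], total_rate: float) -> "NoiseSpec":
        w = tuple(float(x) for x in weights)
        if total_rate > 0 and not any(x > 0 for x in w):
            raise InfeasibleSelectionError(
                "weighted noise with positive rate needs at least one positive weight"
            )
        return cls(mode="weighted", weights=w, total_rate=total_rate)

    def apply(self, truth: Sequence, seed: SeedLike = None) -> ComparatorLabels:
        if self.mode == "uniform":
            return inject_uniform(truth, self.rate, seed)
        if self.mode == "class_rates":
            return inject_class_rates(truth, self.fp_rate, self.fn_rate, seed)
        if self.mode == "weighted":
            return inject_weighted(truth, np.asarray(self.weights), self.total_rate, seed)
        raise ValueError(f"unknown noise mode {self.mode!r}")

    @property
    def level(self) -> float:
        """Nominal overall rate for sweep axes (class-rate mode: unweighted mean)."""
        if self.mode == "uniform":
            return float(self.rate)
        if self.mode == "weighted":
            return float(self.total_rate)
        return 0.5 * (self.fp_rate + self.fn_rate)
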