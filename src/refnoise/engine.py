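"""Monte-Carlo engine: repeated noise injection and median/CI aggregation.

Each iteration draws fresh comparator labels from a noise specification and
scores the cohort's test against them; distributions over iterations are
summarised by the median and the empirical 95% interval (2.5th-97.5th
percentile across iterations).  Two sweep axes are provided: noise level
(:func:`sweep`) and trial size at fixed noise (:func:`size_sweep`).

Seeding is counter-based: iteration (level i, cycle j) uses
``SeedSequence(master_seed, spawn_key=(i, j))``, so results are bit-stable
and adding levels or iterations never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, ScenarioSpec
from .metrics import METRIC_NAMES, compute_metrics
from .noise import NoiseSpec

__all__ = ["IterationResult", "SweepResult", "run_iterations", "sweep", "size_sweep"]

DEFAULT_N_ITER = 100  # simulation cycles per noise level


def _child_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


@dataclass(frozen=True)
class IterationResult:
    """Per-metric value distributions from repeated injection at one setting.

    ``values`` has one row per iteration and one column per metric; NaN
    marks iterations where a metric was undefined.
    """

    values: pd.DataFrame
    n_iter: int
    level: float = 0.0

    def median(self, metric: str) -> float:
        return float(np.nanmedian(self.values[metric].to_numpy()))

    def ci(self, metric: str, level: float = 0.95) -> tuple:
        v = self.values[metric].to_numpy()
        good = v[~np.isnan(v)]
        if good.size == 0:
            return (np.nan, np.nan)
        alpha = 1.0 - level
        lo, hi = np.quantile(good, [alpha / 2.0, 1.0 - alpha / 2.0])
        return (float(lo), float(hi))

    def n_missing(self, metric: str) -> int:
        return int(np.isnan(self.values[metric].to_numpy()).sum())

    def unstable(self, metric: str) -> bool:
        return self.n_missing(metric) > self.n_iter / 2

    def summary(self, ci_level: float = 0.95) -> pd.DataFrame:
        rows = []
        for m in METRIC_NAMES:
            lo, hi = self.ci(m, ci_level)
            rows.append(
                {
                    "level": self.level,
                    "metric": m,
                    "median": self.median(m) if self.n_missing(m) < self.n_iter else np.nan,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "n_missing": self.n_missing(m),
                    "unstable": self.unstable(m),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepResult:
    """Aggregated sweep: one row per (level, metric) with median and empirical CI."""

    table: pd.DataFrame
    levels: tuple
    n_iter: int
    seed: int
    axis: str = "noise"  # or "size"
    iterations: Optional[tuple] = None  # per-level IterationResult, if retained

    def metric_series(self, metric: str) -> pd.DataFrame:
        sub = self.table[self.table["metric"] == metric]
        return sub.sort_values("level").reset_index(drop=True)


def run_iterations(
    cohort: Cohort,
    spec: NoiseSpec,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    level_index: int = 0,
) -> IterationResult:
    """Inject noise ``n_iter`` times and score the test against each draw.

    Each iteration gets an independent child RNG derived from the master
    seed and (level_index, iteration) counters.  Undefined metrics are
    recorded as NaN, never dropped silently.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rows = np.empty((n_iter, len(METRIC_NAMES)))
    for j in range(n_iter):
        rng = _child_rng(seed, level_index, j)
        comp = spec.apply(cohort.truth, rng)
        ms = compute_metrics(cohort, comp.labels)
        rows[j] = [
            np.nan if ms.value(m) is None else ms.value(m) for m in METRIC_NAMES
        ]
    values = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    return IterationResult(values=values, n_iter=n_iter, level=spec.level)


def sweep(
    cohort: Cohort,
    specs: Sequence[NoiseSpec],
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    levels: Optional[Sequence[float]] = None,
    keep_iterations: bool = False,
) -> SweepResult:
    """Run the engine at each noise level and assemble the sweep table.

    ``levels`` labels the x-axis; it defaults to each spec's nominal rate.
    """
    if len(specs) == 0:
        raise ValueError("need at least one noise specification")
    if levels is None:
        levels = [s.level for s in specs]
    if len(levels) != len(specs):
        raise ValueError("levels must match specs one-to-one")
    frames = []
    kept = []
    for i, (lvl, spec) in enumerate(zip(levels, specs)):
        res = run_iterations(cohort, spec, n_iter=n_iter, seed=seed, level_index=i)
        res = IterationResult(values=res.values, n_iter=res.n_iter, level=float(lvl))
        frames.append(res.summary())
        if keep_iterations:
            kept.append(res)
    table = pd.concat(frames, ignore_index=True)
    return SweepResult(
        table=table,
        levels=tuple(float(x) for x in levels),
        n_iter=n_iter,
        seed=seed,
        axis="noise",
        iterations=tuple(kept) if keep_iterations else None,
    )


def size_sweep(
    scenario: ScenarioSpec,
    sizes: Sequence[tuple],
    spec: NoiseSpec,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
    keep_iterations: bool = False,
) -> SweepResult:
    """Sweep over trial size at a fixed noise level.

    ``sizes`` is a sequence of (n_neg, n_pos) pairs; each cohort is built
    from the scenario resized to that pair, with a deterministic child seed,
    and the sweep table is indexed by total cohort size.  Confidence
    intervals shrink roughly as 1/sqrt(n) — the motivation for this sweep.
    """
    if len(sizes) == 0:
        raise ValueError("need at least one size")
    frames = []
    kept = []
    levels = []
    for i, (n_neg, n_pos) in enumerate(sizes):
        if n_neg + n_pos < 2 or min(n_neg, n_pos) < 1:
            raise ValueError("each size needs at least one patient per class")
        cohort = scenario.resized(n_neg, n_pos).build(_child_rng(seed, 1_000_000 + i))
        res = run_iterations(cohort, spec, n_iter=n_iter, seed=seed, level_index=i)
        total = float(n_neg + n_pos)
        res = IterationResult(values=res.values, n_iter=res.n_iter, level=total)
        levels.append(total)
        frames.append(res.summary())
        if keep_iterations:
            kept.append(res)
    table = pd.concat(frames, ignore_index=True)
    return SweepResult(
        table=table,
        levels=tuple(levels),
        n_iter=n_iter,
        seed=seed,
        axis="size",
        iterations=tuple(kept) if keep_iterations else None,
    )
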