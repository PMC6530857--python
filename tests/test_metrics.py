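"""AUC rank statistic, confusion metrics, bootstrap intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refnoise import (
    Cohort,
    auc,
    bootstrap_ci,
    compute_metrics,
    confusion_metrics,
    make_called_cohort,
)
from conftest import auc_pairwise


class TestAuc:
    def test_tied_scores_worked_example(self):
        # pairs: (2,1)=1, (3,1)=1, (2,2)=0.5, (3,2)=1 -> 3.5/4
        assert auc([1, 2, 2, 3], [0, 0, 1, 1]) == pytest.approx(0.875)

    def test_perfect_separation_is_one(self):
        assert auc([1, 2, 10, 11], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    @given(
        n=st.integers(2, 50),
        data=st.data(),
    )
    @settings(max_examples=80, deadline=None)
    def test_rank_auc_equals_pairwise_oracle(self, n, data):
        # integer scores force ties; labels constrained to contain both classes
        scores = data.draw(st.lists(st.integers(0, 8), min_size=n, max_size=n))
        n_pos = data.draw(st.integers(1, n - 1))
        labels = np.zeros(n, bool)
        labels[:n_pos] = True
        perm = np.array(data.draw(st.permutations(range(n))))
        labels = labels[perm]
        assert auc(scores, labels) == pytest.approx(
            auc_pairwise(scores, labels), abs=1e-12
        )

    @given(n=st.integers(2, 30), seed=st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None)
    def test_score_negation_symmetry_without_ties(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(n).astype(float)  # distinct
        labels = np.zeros(n, bool)
        labels[: max(1, n // 2)] = True
        labels = rng.permutation(labels)
        if 0 < labels.sum() < n:
            assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestConfusionMetrics:
    def test_worked_example_table(self, worked_example_cohort):
        ms = confusion_metrics(worked_example_cohort.calls, worked_example_cohort.truth)
        assert ms.ppa == pytest.approx(0.970)
        assert ms.npa == pytest.approx(0.850)
        assert round(ms.ppv, 3) == 0.866
        assert round(ms.npv, 3) == 0.966

    def test_identity_calls_all_ones(self):
        y = np.array([0, 1, 0, 1], bool)
        ms = confusion_metrics(y, y)
        assert (ms.ppa, ms.npa, ms.ppv, ms.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_small_table_direct_arithmetic(self):
        # TP=2, FP=1, FN=0, TN=1
        calls = [1, 1, 1, 0]
        labels = [1, 1, 0, 0]
        ms = confusion_metrics(calls, labels)
        assert ms.ppa == 1.0 and ms.npa == 0.5
        assert ms.ppv == pytest.approx(2 / 3) and ms.npv == 1.0

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 2, 50).astype(bool)
        labels = rng.integers(0, 2, 50).astype(bool)
        perm = rng.permutation(50)
        assert confusion_metrics(calls, labels) == confusion_metrics(
            calls[perm], labels[perm]
        )

    def test_swapping_roles_swaps_agreement_and_predictive_values(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, 80).astype(bool)
        labels = rng.integers(0, 2, 80).astype(bool)
        a = confusion_metrics(calls, labels)
        b = confusion_metrics(labels, calls)
        assert a.ppa == b.ppv and a.ppv == b.ppa
        assert a.npa == b.npv and a.npv == b.npa

    def test_undefined_ratios_are_none_not_zero(self):
        ms = confusion_metrics([1, 1], [1, 0])  # no test negatives
        assert ms.npa == 0.0  # tn=0, fp=1 -> defined
        assert ms.npv is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])


class TestComputeMetrics:
    def test_auc_missing_for_single_class_labels(self, worked_example_cohort):
        ms = compute_metrics(worked_example_cohort, np.ones(200, bool))
        assert ms.auc is None
        assert ms.ppa is not None

    def test_includes_auc_for_two_class_labels(self, perfect_cohort):
        ms = compute_metrics(perfect_cohort, perfect_cohort.truth)
        assert ms.auc == 1.0


class TestBootstrap:
    def test_constant_metric_gives_zero_width_at_one(self):
        c = make_called_cohort(20, 20, se=1.0, sp=1.0, seed=0)
        ci = bootstrap_ci(c, c.truth, "ppa", n_boot=200, seed=1)
        assert (ci.lower, ci.upper) == (1.0, 1.0)
        assert ci.width == 0.0 and not ci.unstable

    def test_coverage_of_true_proportion(self):
        # PPA of Bernoulli(0.8) calls on an all-positive label set is a
        # plain proportion; percentile-bootstrap coverage should be near 95%
        rng = np.random.default_rng(7)
        n, hits, reps = 100, 0, 300
        for r in range(reps):
            call = rng.random(n) < 0.8
            score = np.where(call, 0.9, 0.1)
            c = Cohort(
                ids=[f"p{i}" for i in range(n)],
                truth=np.ones(n, bool),
                score=score,
                call=call,
            )
            ci = bootstrap_ci(c, c.truth, "ppa", n_boot=400, seed=1000 + r)
            hits += ci.contains(0.8)
        assert 0.88 <= hits / reps <= 0.99

    def test_undefined_resamples_counted(self, worked_example_cohort):
        # AUC against an extremely unbalanced label set: some resamples
        # lose the minority class entirely and must be dropped, not zeroed
        labels = np.zeros(200, bool)
        labels[:1] = True
        ci = bootstrap_ci(worked_example_cohort, labels, "auc", n_boot=500, seed=3)
        assert ci.n_undefined > 0
        assert ci.lower <= ci.upper

    def test_too_few_resamples_rejected(self, worked_example_cohort):
        with pytest.raises(ValueError):
            bootstrap_ci(
                worked_example_cohort, worked_example_cohort.truth, "ppa", n_boot=50
            )
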