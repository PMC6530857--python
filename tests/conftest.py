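import numpy as np
import pytest
from hypothesis import settings

from refnoise import make_called_cohort, make_perfect_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def perfect_cohort():
    """Balanced perfect-test cohort: 100 negatives, 100 positives, AUC 1."""
    return make_perfect_cohort(100, 100, seed=20240501)


@pytest.fixture(scope="session")
def worked_example_cohort():
    """Binary-call fixture with TP=97, FN=3, TN=85, FP=15 against truth."""
    return make_called_cohort(100, 100, se=0.970, sp=0.850, seed=20240502)


def auc_pairwise(scores, labels):
    """O(n^2) pairwise oracle for the rank AUC (ties credited 0.5)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
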