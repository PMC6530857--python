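"""Expert-panel comparator model: confidence, strata, misclassification rates.

In adjudicated trials (e.g. sepsis vs sterile inflammation), the comparator
is a retrospective physician diagnosis: several blinded panelists each call
a patient positive, negative or indeterminate.  Mapping the calls to
probabilities (positive -> 1, negative -> 0, indeterminate -> 1/2), the
per-patient confidence of infection is their simple average; with three
panelists it takes values in {0, 1/6, 1/3, 1/2, 2/3, 5/6, 1}.

Patients stratify by agreement level, nested as
super-unanimous ⊆ unanimous ⊆ consensus ⊆ forced:

* unanimous — all three panelists agree on a non-indeterminate call;
* super-unanimous — unanimous, and the enrolling site's diagnosis matches;
* consensus — a majority (>= 2) agree on a non-indeterminate call;
* indeterminate — no such majority; the forced label resolves these.

The residual uncertainty p_wrong = 1 - max(c, 1 - c) is the probability
the assigned label is wrong; averaged over assigned negatives/positives it
yields the comparator's FP/FN misclassification rates, which feed the
weighted noise-injection scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .analytic import expected_overall_misclassification
from .cohort import SeedLike, as_rng

__all__ = [
    "POS",
    "NEG",
    "IND",
    "STRATA",
    "PanelAssessment",
    "PanelData",
    "MisclassificationRates",
    "panel_confidence",
    "classify_patient",
    "misclassification_rates",
    "generate_panel_data",
]

POS = "pos"
NEG = "neg"
IND = "ind"

CALL_PROB = {POS: 1.0, NEG: 0.0, IND: 0.5}
# accepted spellings in input files
_ALIASES = {
    "pos": POS, "positive": POS, "yes": POS, "y": POS, "1": POS,
    "neg": NEG, "negative": NEG, "no": NEG, "n": NEG, "0": NEG,
    "ind": IND, "indeterminate": IND,
}

STRATA = ("super_unanimous", "unanimous", "consensus", "forced_only", "indeterminate")


def normalize_call(call: str) -> str:
    """Map an input token to the canonical {pos, neg, ind}; raise on junk."""
    key = str(call).strip().lower()
    if key not in _ALIASES:
        raise ValueError(f"invalid panelist call {call!r}")
    return _ALIASES[key]


def panel_confidence(calls: Sequence[str]) -> float:
    """Simple average of the three mapped calls (pos=1, neg=0, ind=1/2)."""
    if len(calls) != 3:
        raise ValueError("exactly three panelist calls are required")
    return sum(CALL_PROB[normalize_call(c)] for c in calls) / 3.0


def classify_patient(
    calls: Sequence[str], site_dx: Optional[str] = None
) -> Tuple[str, str]:
    """Assign a label and an agreement stratum to one patient.

    The assigned label follows confidence (> 1/2 positive, < 1/2 negative,
    = 1/2 indeterminate).  Strata: unanimous when all three calls agree on a
    non-indeterminate value, super-unanimous when additionally the site
    diagnosis matches, consensus when a majority agrees, indeterminate when
    no majority exists.  The forced label (used when every patient must get
    a binary call) is positive at confidence >= 1/2 — the tie is broken
    toward positive, the cautious direction for a treatable infection.
    """
    norm = [normalize_call(c) for c in calls]
    if len(norm) != 3:
        raise ValueError("exactly three panelist calls are required")
    conf = panel_confidence(norm)
    if conf > 0.5:
        assigned = POS
    elif conf < 0.5:
        assigned = NEG
    else:
        assigned = IND

    non_ind = [c for c in norm if c != IND]
    unanimous = len(non_ind) == 3 and len(set(non_ind)) == 1
    majority = any(non_ind.count(v) >= 2 for v in (POS, NEG))
    if unanimous and site_dx is not None and normalize_call(site_dx) == norm[0]:
        stratum = "super_unanimous"
    elif unanimous:
        stratum = "unanimous"
    elif majority:
        stratum = "consensus"
    else:
        stratum = "indeterminate"
    return assigned, stratum


@dataclass(frozen=True)
class PanelAssessment:
    """One patient's panel adjudication with derived quantities."""

    patient_id: str
    calls: Tuple[str, str, str]
    site_dx: Optional[str] = None

    @property
    def confidence(self) -> float:
        return panel_confidence(self.calls)

    @property
    def assigned(self) -> str:
        return classify_patient(self.calls, self.site_dx)[0]

    @property
    def stratum(self) -> str:
        return classify_patient(self.calls, self.site_dx)[1]

    @property
    def forced_label(self) -> str:
        """Binary label for every patient; ties (confidence 1/2) go positive."""
        return POS if self.confidence >= 0.5 else NEG

    @property
    def p_wrong(self) -> float:
        """Residual uncertainty: probability the assigned label is wrong."""
        c = self.confidence
        return 1.0 - max(c, 1.0 - c)


@dataclass(frozen=True)
class MisclassificationRates:
    fp_rate: float  # mean p_wrong over assigned negatives
    fn_rate: float  # mean p_wrong over assigned positives
    overall: float


def misclassification_rates(
    assessments: Iterable[PanelAssessment],
) -> MisclassificationRates:
    """Comparator FP/FN/overall rates from panel residual uncertainty.

    A patient assigned positive with confidence c has probability 1 - c of
    truly being negative, i.e. of being a comparator false positive — hence
    the FN rate of the comparator is the mean residual uncertainty over
    assigned positives, and symmetrically for the FP rate.  Indeterminate
    patients enter through their forced label.
    """
    items = list(assessments)
    pos_p = [a.p_wrong for a in items if a.forced_label == POS]
    neg_p = [a.p_wrong for a in items if a.forced_label == NEG]
    if not pos_p or not neg_p:
        raise ValueError(
            "misclassification rates need at least one assigned positive and one negative"
        )
    fn_rate = float(np.mean(pos_p))
    fp_rate = float(np.mean(neg_p))
    overall = expected_overall_misclassification(
        fp_rate, fn_rate, n_neg=len(neg_p), n_pos=len(pos_p)
    )
    return MisclassificationRates(fp_rate=fp_rate, fn_rate=fn_rate, overall=overall)


@dataclass(frozen=True)
class PanelData:
    """Synthetic panel assessments plus the hidden truth used to generate them."""

    assessments: Tuple[PanelAssessment, ...]
    truth: np.ndarray  # bool, True = truly positive

    def __len__(self) -> int:
        return len(self.assessments)

    @property
    def flip_weights(self) -> np.ndarray:
        """Per-patient residual uncertainty, for weighted noise injection."""
        return np.array([a.p_wrong for a in self.assessments])

    def strata_counts(self) -> dict:
        counts = {s: 0 for s in STRATA if s != "forced_only"}
        for a in self.assessments:
            counts[a.stratum] += 1
        return counts


def generate_panel_data(
    n_neg: int,
    n_pos: int,
    panelist_error: float,
    indeterminate_rate: float,
    seed: SeedLike = None,
    site_error: Optional[float] = None,
) -> PanelData:
    """Synthetic three-panelist adjudication with known generative truth.

    Each panelist independently calls a patient indeterminate with the
    given rate; otherwise they emit the true label with probability
    1 - panelist_error.  The site diagnosis is always binary and wrong with
    probability ``site_error`` (defaults to ``panelist_error``).  The
    hidden truth is retained so the recovered misclassification rates can
    be validated against the generative process.
    """
    if not (0.0 <= panelist_error <= 1.0 and 0.0 <= indeterminate_rate <= 1.0):
        raise ValueError("panelist_error and indeterminate_rate must lie in [0, 1]")
    if site_error is None:
        site_error = panelist_error
    rng = as_rng(seed)
    n = n_neg + n_pos
    truth = np.concatenate([np.zeros(n_neg, bool), np.ones(n_pos, bool)])
    assessments: List[PanelAssessment] = []
    for i in range(n):
        true_call = POS if truth[i] else NEG
        wrong_call = NEG if truth[i] else POS
        calls = []
        for _ in range(3):
            if rng.random() < indeterminate_rate:
                calls.append(IND)
            elif rng.random() < panelist_error:
                calls.append(wrong_call)
            else:
                calls.append(true_call)
        site = wrong_call if rng.random() < site_error else true_call
        assessments.append(
            PanelAssessment(
                patient_id=f"pt{i:05d}", calls=tuple(calls), site_dx=site
            )
        )
    return PanelData(assessments=tuple(assessments), truth=truth)
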