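"""Expert-panel model: confidence mapping, strata, rate recovery."""

import itertools

import numpy as np
import pytest

from refnoise import (
    PanelAssessment,
    classify_patient,
    generate_panel_data,
    misclassification_rates,
    panel_confidence,
)
from refnoise.panel import IND, NEG, POS

ALL_TRIPLES = list(itertools.product([POS, NEG, IND], repeat=3))


def classify_oracle(calls, site_dx=None):
    """Independent enumeration of the stated rules for one call triple."""
    conf = sum({POS: 1.0, NEG: 0.0, IND: 0.5}[c] for c in calls) / 3
    label = POS if conf > 0.5 else NEG if conf < 0.5 else IND
    unanimous = calls[0] == calls[1] == calls[2] != IND
    majority = any(
        sum(c == v for c in calls) >= 2 for v in (POS, NEG)
    )
    if unanimous and site_dx == calls[0]:
        stratum = "super_unanimous"
    elif unanimous:
        stratum = "unanimous"
    elif majority:
        stratum = "consensus"
    else:
        stratum = "indeterminate"
    return label, stratum


class TestConfidence:
    def test_unanimous_extremes(self):
        assert panel_confidence([POS, POS, POS]) == 1.0
        assert panel_confidence([NEG, NEG, NEG]) == 0.0

    def test_mixed_call_arithmetic(self):
        assert panel_confidence([POS, POS, IND]) == pytest.approx(5 / 6)
        assert panel_confidence([POS, IND, NEG]) == pytest.approx(0.5)

    def test_confidence_lattice(self):
        values = {round(panel_confidence(t), 9) for t in ALL_TRIPLES}
        assert values == {round(v, 9) for v in (0, 1 / 6, 1 / 3, 1 / 2, 2 / 3, 5 / 6, 1)}

    def test_swap_symmetry(self):
        swap = {POS: NEG, NEG: POS, IND: IND}
        for t in ALL_TRIPLES:
            swapped = tuple(swap[c] for c in t)
            assert panel_confidence(swapped) == pytest.approx(1 - panel_confidence(t))

    def test_invalid_call_rejected(self):
        with pytest.raises(ValueError):
            panel_confidence([POS, "maybe", NEG])
        with pytest.raises(ValueError):
            panel_confidence([POS, NEG])


class TestClassification:
    def test_super_unanimous_requires_matching_site(self):
        assert classify_patient([POS, POS, POS], site_dx=POS) == (POS, "super_unanimous")
        assert classify_patient([POS, POS, POS], site_dx=NEG) == (POS, "unanimous")
        assert classify_patient([POS, POS, POS]) == (POS, "unanimous")

    def test_majority_rule(self):
        assert classify_patient([POS, POS, NEG]) == (POS, "consensus")
        assert classify_patient([NEG, NEG, IND]) == (NEG, "consensus")

    def test_tied_confidence_is_indeterminate(self):
        label, stratum = classify_patient([POS, IND, NEG])
        assert (label, stratum) == (IND, "indeterminate")
        a = PanelAssessment("x", (POS, IND, NEG))
        assert a.forced_label == POS  # tie broken toward positive
        assert a.p_wrong == 0.5

    @pytest.mark.parametrize("site", [None, POS, NEG])
    def test_all_27_triples_match_enumeration_oracle(self, site):
        for t in ALL_TRIPLES:
            assert classify_patient(t, site) == classify_oracle(t, site)

    def test_accepts_spelled_out_tokens(self):
        assert classify_patient(["positive", "Yes", "Indeterminate"])[0] == POS


class TestMisclassificationRates:
    def test_certain_panel_has_zero_rates(self):
        items = [
            PanelAssessment("a", (POS, POS, POS)),
            PanelAssessment("b", (NEG, NEG, NEG)),
        ]
        r = misclassification_rates(items)
        assert (r.fp_rate, r.fn_rate, r.overall) == (0.0, 0.0, 0.0)

    def test_direct_arithmetic_example(self):
        # confidences (1, 2/3) for the positives and 1/6 for the negative
        items = [
            PanelAssessment("a", (POS, POS, POS)),      # conf 1
            PanelAssessment("b", (POS, POS, NEG)),      # conf 2/3, p_wrong 1/3
            PanelAssessment("c", (NEG, NEG, IND)),      # conf 1/6, p_wrong 1/6
        ]
        r = misclassification_rates(items)
        assert r.fn_rate == pytest.approx(1 / 6)
        assert r.fp_rate == pytest.approx(1 / 6)
        assert r.overall == pytest.approx(1 / 6)

    def test_overall_between_class_rates(self):
        rng = np.random.default_rng(5)
        items = []
        for i in range(50):
            calls = tuple(rng.choice([POS, NEG, IND], 3))
            items.append(PanelAssessment(f"p{i}", calls))
        r = misclassification_rates(items)
        assert min(r.fp_rate, r.fn_rate) - 1e-12 <= r.overall <= max(r.fp_rate, r.fn_rate) + 1e-12

    def test_single_class_panel_rejected(self):
        with pytest.raises(ValueError):
            misclassification_rates([PanelAssessment("a", (POS, POS, POS))])

    def test_residual_uncertainty_bounded_by_half(self):
        for t in ALL_TRIPLES:
            a = PanelAssessment("x", t)
            assert 0.0 <= a.p_wrong <= 0.5
            if a.confidence == 0.5:
                assert a.p_wrong == 0.5


class TestGenerator:
    def test_error_free_panel_all_super_unanimous(self):
        data = generate_panel_data(20, 20, panelist_error=0.0, indeterminate_rate=0.0, seed=1)
        assert all(a.stratum == "super_unanimous" for a in data.assessments)
        assert all(a.confidence in (0.0, 1.0) for a in data.assessments)

    def test_indeterminate_call_frequency(self):
        q = 0.15
        data = generate_panel_data(2000, 2000, panelist_error=0.0, indeterminate_rate=q, seed=2)
        calls = [c for a in data.assessments for c in a.calls]
        frac = sum(c == IND for c in calls) / len(calls)
        se = np.sqrt(q * (1 - q) / len(calls))
        assert abs(frac - q) < 4 * se

    def test_strata_partition_cohort(self):
        data = generate_panel_data(300, 300, 0.15, 0.15, seed=3)
        counts = data.strata_counts()
        assert sum(counts.values()) == 600

    def test_rate_recovery_against_triple_enumeration(self):
        # exact oracle: enumerate the 27 call-triple probabilities and
        # compute the expected wrong-forced-label rate of the generator
        e, q = 0.1, 0.1
        p_call = {IND: q, "right": (1 - q) * (1 - e), "wrong": (1 - q) * e}

        def triple_prob(t, true_label):
            prob = 1.0
            for c in t:
                if c == IND:
                    prob *= p_call[IND]
                elif c == true_label:
                    prob *= p_call["right"]
                else:
                    prob *= p_call["wrong"]
            return prob

        # expected probability the forced label disagrees with the truth,
        # for a truly positive patient (negative is symmetric up to the tie
        # rule, which favours the positive label)
        wrong_pos = sum(
            triple_prob(t, POS)
            for t in ALL_TRIPLES
            if PanelAssessment("x", t).forced_label != POS
        )
        wrong_neg = sum(
            triple_prob(t, NEG)
            for t in ALL_TRIPLES
            if PanelAssessment("x", t).forced_label != NEG
        )

        data = generate_panel_data(2500, 2500, e, q, seed=4)
        forced = np.array([a.forced_label == POS for a in data.assessments])
        obs_wrong_pos = np.mean(forced[data.truth] == False)  # noqa: E712
        obs_wrong_neg = np.mean(forced[~data.truth] == True)  # noqa: E712
        se_pos = np.sqrt(wrong_pos * (1 - wrong_pos) / 2500)
        se_neg = np.sqrt(wrong_neg * (1 - wrong_neg) / 2500)
        assert abs(obs_wrong_pos - wrong_pos) < 3 * se_pos
        assert abs(obs_wrong_neg - wrong_neg) < 3 * se_neg

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            generate_panel_data(10, 10, panelist_error=1.5, indeterminate_rate=0.0, seed=0)
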