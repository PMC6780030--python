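"""TdP scoring, classification and prediction metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import emwtrials as e
from emwtrials.drugs import ConditionSummary, TrialResult


def make_trial(summaries, n_tot=107, drug="x"):
    return TrialResult(drug, tuple(summaries), pd.DataFrame(), {
        m: ConditionSummary(n_tot=n_tot, n_ra=ra, n_da=0, n_emw=nemw,
                            n_valid_emw=n_tot - ra, median_dEMw=med,
                            median_dAPD90=0.0, median_dCTD90=0.0,
                            frac_ra=ra / n_tot,
                            frac_emw_short=nemw / max(n_tot - ra, 1),
                            frac_apd_long=0.0)
        for m, (ra, nemw, med) in summaries.items()}, n_tot)


class TestTdPScore:
    def test_worked_example(self):
        si = e.ScoreInputs((1.0, 10.0), (0, 2), (1, 2), 4)
        assert e.tdp_score(si) == pytest.approx(0.3182, abs=2e-4)

    def test_extremes(self):
        clean = e.ScoreInputs((1.0, 10.0, 100.0), (0, 0, 0), (0, 0, 0), 10)
        assert e.tdp_score(clean) == 0.0
        worst = e.ScoreInputs((1.0, 10.0, 100.0), (4, 10, 0), (6, 0, 10), 10)
        assert e.tdp_score(worst) == pytest.approx(1.0)

    def test_original_score_is_ra_only(self):
        si = e.ScoreInputs((1.0, 10.0), (2, 4), (3, 3), 10)
        ra_only = e.tdp_score(si, include_emw=False)
        manual = (1.0 * 2 + 0.1 * 4) / (10 * 1.1)
        assert ra_only == pytest.approx(manual)
        assert e.tdp_score(si) >= ra_only

    def test_double_counting_rejected(self):
        with pytest.raises(ValueError):
            e.ScoreInputs((1.0,), (6,), (5,), 10)

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_monotone_and_bounded(self, data):
        n_tot = data.draw(st.integers(2, 50))
        k = data.draw(st.integers(1, 4))
        mults = sorted(data.draw(st.lists(
            st.floats(0.1, 100), min_size=k, max_size=k)))
        nra = [data.draw(st.integers(0, n_tot // 2)) for _ in range(k)]
        nemw = [data.draw(st.integers(0, n_tot // 2)) for _ in range(k)]
        si = e.ScoreInputs(tuple(mults), tuple(nra), tuple(nemw), n_tot)
        s = e.tdp_score(si)
        assert 0.0 <= s <= 1.0
        # bumping any count can only raise the score
        j = data.draw(st.integers(0, k - 1))
        if nra[j] + nemw[j] < n_tot:
            nra2 = list(nra)
            nra2[j] += 1
            s2 = e.tdp_score(e.ScoreInputs(tuple(mults), tuple(nra2),
                                           tuple(nemw), n_tot))
            assert s2 >= s

    def test_weight_scale_invariance(self):
        """Rescaling all tested concentrations by a constant leaves the
        score unchanged (weights are relative)."""
        si1 = e.ScoreInputs((1.0, 10.0), (1, 3), (2, 2), 10)
        si2 = e.ScoreInputs((7.0, 70.0), (1, 3), (2, 2), 10)
        assert e.tdp_score(si1) == pytest.approx(e.tdp_score(si2))


class TestClassify:
    def test_inert_safe_everywhere(self):
        trial = make_trial({1.0: (0, 0, 0.0), 10.0: (0, 0, 0.0)})
        for crit in ("RA_only", "RA_plus_EMw"):
            for mult in (1.0, 10.0):
                assert not e.classify(trial, crit, mult).risky

    def test_threshold_is_strict(self):
        trial = make_trial({10.0: (0, 40, -10.0)})
        assert not e.classify(trial, "RA_plus_EMw", 10.0).risky
        trial2 = make_trial({10.0: (0, 41, -10.000001)})
        assert e.classify(trial2, "RA_plus_EMw", 10.0).risky

    def test_disjunction_with_single_ra_model(self):
        trial = make_trial({10.0: (1, 0, -5.0)})
        assert e.classify(trial, "RA_only", 10.0).risky
        assert e.classify(trial, "RA_plus_EMw", 10.0).risky
        assert not e.classify(trial, "EMw_only", 10.0).risky

    def test_high_ra_fraction_risky_by_construction(self):
        trial = make_trial({10.0: (105, 0, math.nan)})
        assert e.classify(trial, "RA_plus_EMw", 10.0).risky

    def test_degenerate_trial_raises(self):
        t = TrialResult("x", (10.0,), pd.DataFrame(), {10.0: ConditionSummary(
            n_tot=107, n_ra=0, n_da=107, n_emw=0, n_valid_emw=0,
            median_dEMw=math.nan, median_dAPD90=math.nan,
            median_dCTD90=math.nan, frac_ra=0.0, frac_emw_short=math.nan,
            frac_apd_long=math.nan)}, 107)
        with pytest.raises(ValueError, match="degenerate"):
            e.classify(t, "RA_plus_EMw", 10.0)

    def test_unknown_requests_rejected(self):
        trial = make_trial({10.0: (0, 0, 0.0)})
        with pytest.raises(KeyError):
            e.classify(trial, "RA_only", 30.0)
        with pytest.raises(ValueError):
            e.classify(trial, "nonsense", 10.0)


class TestMetrics:
    def test_printed_confusion_counts(self):
        """27/30 risky drugs and 9/10 safe drugs correct -> 90% accuracy,
        90% sensitivity and specificity."""
        cm = e.ConfusionSummary(TP=27, TN=9, FP=1, FN=3)
        assert cm.accuracy == pytest.approx(0.90)
        assert cm.sensitivity == pytest.approx(0.90)
        assert cm.specificity == pytest.approx(0.90)
        assert cm.ppv == pytest.approx(27 / 28)
        assert cm.npv == pytest.approx(9 / 12)

    def test_exact_count_identity(self):
        cm = e.ConfusionSummary(TP=13, TN=7, FP=2, FN=5)
        n = cm.TP + cm.TN + cm.FP + cm.FN
        assert cm.accuracy * n == cm.TP + cm.TN

    def test_perfect_classifier(self):
        cm = e.ConfusionSummary(TP=5, TN=5, FP=0, FN=0)
        for v in (cm.sensitivity, cm.specificity, cm.accuracy, cm.ppv,
                  cm.npv):
            assert v == 1.0

    def test_metrics_from_calls(self):
        calls = [
            e.RiskCall("a", "RA_plus_EMw", 10.0, True, -20.0, 0.1),
            e.RiskCall("b", "RA_plus_EMw", 10.0, False, 5.0, 0.0),
            e.RiskCall("c", "RA_plus_EMw", 10.0, True, -30.0, 0.5),
        ]
        truth = {"a": True, "b": False, "c": False}
        cm = e.prediction_metrics(calls, truth)
        assert (cm.TP, cm.TN, cm.FP, cm.FN) == (1, 1, 1, 0)
        with pytest.raises(KeyError):
            e.prediction_metrics(
                [e.RiskCall("zzz", "RA_only", 1.0, True, 0.0, 0.0)], truth)

    def test_truth_mapping(self):
        assert e.truth_label("known")
        assert e.truth_label("possible")
        assert e.truth_label("conditional")
        assert not e.truth_label("NC")
        assert not e.truth_label("unlisted")
        with pytest.raises(ValueError):
            e.truth_label("maybe")


class TestLogModulus:
    def test_zero(self):
        assert e.log_modulus(0.0) == 0.0

    def test_base10_anchor(self):
        assert e.log_modulus(99.0) == pytest.approx(2.0)

    @settings(deadline=None, max_examples=100)
    @given(x=st.floats(-1e6, 1e6))
    def test_odd_symmetry(self, x):
        assert e.log_modulus(-x) == pytest.approx(-e.log_modulus(x))

    def test_vectorised(self):
        out = e.log_modulus(np.array([-99.0, 0.0, 9.0]))
        np.testing.assert_allclose(out, [-2.0, 0.0, 1.0])
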