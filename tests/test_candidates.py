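"""Candidate-track statistics: adjusted logistic regression, backward
stepwise selection, the compound score, ROC/AUC, LRT and meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from radsig.candidates import (
    _fit_logit,
    backward_stepwise,
    compound_score,
    likelihood_ratio_test,
    meta_analyse,
    roc_auc,
    univariable_adjusted,
    StepwiseModel,
)
from conftest import make_samples


class TestUnivariable:
    def test_binary_score_matches_2x2_closed_form(self):
        """Counts (exposed/unexposed x case/control) a,b,c,d = 20,80,5,95:
        OR = (20*95)/(80*5) = 4.75."""
        y = [1] * 20 + [0] * 80 + [1] * 5 + [0] * 95
        score = [1] * 100 + [0] * 100
        ids = [f"s{i}" for i in range(200)]
        samples = make_samples(ids, y)
        res = univariable_adjusted(pd.Series(score, index=ids, name="x"), samples)
        assert res.odds_ratio == pytest.approx(4.75, abs=1e-6)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_independent_score_log_or_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        ids = [f"s{i}" for i in range(n)]
        y = rng.binomial(1, 0.25, n)
        score = rng.normal(size=n)
        samples = make_samples(ids, y)
        res = univariable_adjusted(pd.Series(score, index=ids, name="x"), samples)
        assert abs(res.beta) < 0.15

    def test_constant_score_rejected(self):
        ids = ["a", "b", "c", "d"]
        samples = make_samples(ids, [0, 1, 0, 1])
        with pytest.raises(ValueError, match="constant"):
            univariable_adjusted(pd.Series(1.0, index=ids, name="flat"), samples)

    def test_perfect_separation_flagged_not_penalized(self):
        n = 40
        ids = [f"s{i}" for i in range(n)]
        y = [0] * 20 + [1] * 20
        score = [0.0] * 20 + [1.0] * 20
        samples = make_samples(ids, y)
        res = univariable_adjusted(pd.Series(score, index=ids, name="sep"), samples)
        assert res.separation_flag
        assert res.odds_ratio == float("inf")

    def test_parameter_recovery_on_synthetic_logistic(self):
        """Mean estimated log-OR over reps within 2*mean(SE) of truth."""
        rng = np.random.default_rng(42)
        beta_true, n, reps = 0.8, 400, 30
        betas, ses = [], []
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + beta_true * x))))
            ids = [f"s{i}" for i in range(n)]
            res = univariable_adjusted(pd.Series(x, index=ids, name="x"),
                                       make_samples(ids, y))
            betas.append(res.beta)
            ses.append(res.se)
        assert abs(np.mean(betas) - beta_true) < 2 * np.mean(ses)


class TestRocAuc:
    def test_all_pairs_enumeration_example(self):
        roc = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_and_flipped(self):
        roc = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert roc.auc == 1.0
        flipped = roc_auc([1, 2, 3, 10, 11], [1, 1, 1, 0, 0])
        assert flipped.auc == pytest.approx(1.0 - roc.auc)

    def test_constant_score_is_half_by_tie_convention(self):
        assert roc_auc([1.0] * 6, [0, 1, 0, 1, 0, 1]).auc == pytest.approx(0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_equals_brute_force_pair_concordance(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(labels) in (0, n):
            labels[0] = 1 - labels[0]
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        brute = np.mean([[1.0 if p > q else 0.5 if p == q else 0.0 for q in neg]
                         for p in pos])
        assert roc_auc(scores, labels).auc == pytest.approx(brute, abs=1e-12)


class TestLikelihoodRatio:
    def _fits(self, with_feature):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-1.2 * x)))
        X_null = pd.DataFrame({"z": rng.normal(size=n)})
        X_full = X_null.assign(x=x) if with_feature else X_null
        null_res, _ = _fit_logit(y, X_null)
        full_res, _ = _fit_logit(y, X_full)
        return null_res, full_res

    def test_identical_models_statistic_zero_p_one(self):
        null_res, _ = self._fits(False)
        stat, df, p = likelihood_ratio_test(null_res, null_res)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_tail_closed_form(self):
        """An ll gain of 5.0 with one extra parameter: stat 10, p =
        chi2_sf(10,1) ~ 1.565e-3."""
        null_res, full_res = self._fits(True)
        stat, df, p = likelihood_ratio_test(null_res, full_res)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(stat, 1), rel=1e-12)
        assert stats.chi2.sf(10.0, 1) == pytest.approx(1.565402e-3, rel=1e-4)

    def test_non_nested_rejected(self):
        _, full_res = self._fits(True)
        null_res, _ = self._fits(False)
        null2 = _fit_logit(
            np.array([0, 1] * 100),
            pd.DataFrame({"other": np.arange(200, dtype=float)}),
        )[0]
        with pytest.raises(ValueError):
            likelihood_ratio_test(null2, full_res)


def _signal_scores(rng, n=500, n_signal=3, n_noise=1, beta=1.0):
    ids = [f"s{i}" for i in range(n)]
    X = rng.normal(size=(n, n_signal + n_noise))
    eta = -1.0 + beta * X[:, :n_signal].sum(axis=1)
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    cols = [f"sig{i}" for i in range(n_signal)] + [f"noise{i}" for i in range(n_noise)]
    return pd.DataFrame(X, index=ids, columns=cols), make_samples(ids, y)


class TestStepwise:
    def test_noise_eliminated_signal_retained(self):
        rng = np.random.default_rng(7)
        frame, samples = _signal_scores(rng)
        model = backward_stepwise(frame, samples, alpha_remove=0.05)
        assert set(model.retained) == {"sig0", "sig1", "sig2"}
        assert model.trace[0][0] == "noise0"

    def test_alpha_one_removes_nothing(self):
        rng = np.random.default_rng(8)
        frame, samples = _signal_scores(rng)
        model = backward_stepwise(frame, samples, alpha_remove=1.0)
        assert set(model.retained) == set(frame.columns)
        assert model.trace == []

    def test_single_strong_feature_retained_empty_trace(self):
        rng = np.random.default_rng(9)
        frame, samples = _signal_scores(rng, n_signal=1, n_noise=0)
        model = backward_stepwise(frame, samples)
        assert model.retained == ["sig0"]
        assert model.trace == []

    def test_pure_noise_can_empty_the_model(self):
        rng = np.random.default_rng(10)
        n = 300
        ids = [f"s{i}" for i in range(n)]
        frame = pd.DataFrame(rng.normal(size=(n, 2)), index=ids, columns=["a", "b"])
        samples = make_samples(ids, rng.binomial(1, 0.3, n))
        model = backward_stepwise(frame, samples, alpha_remove=1e-6)
        assert model.retained == []


class TestCompoundScore:
    def test_single_feature_linear(self):
        model = StepwiseModel(["f"], {"f": 2.0}, 0.0, -10.0, [])
        frame = pd.DataFrame({"f": [1.0, 2.0, -3.0]}, index=["a", "b", "c"])
        comp = compound_score(model, frame)
        assert np.allclose(comp.to_numpy(), [2.0, 4.0, -6.0])

    def test_two_feature_dot_product_oracle(self):
        model = StepwiseModel(["f", "g"], {"f": 1.5, "g": -0.5}, 0.25, -1.0, [])
        frame = pd.DataFrame({"f": [1.0, 0.0, 2.0], "g": [2.0, 4.0, -1.0]},
                             index=["a", "b", "c"])
        comp = compound_score(model, frame)
        expected = 0.25 + frame.to_numpy() @ np.array([1.5, -0.5])
        assert np.allclose(comp.to_numpy(), expected, atol=1e-12)

    def test_all_zero_coefficients_constant_auc_half(self):
        model = StepwiseModel(["f"], {"f": 0.0}, 1.0, -1.0, [])
        frame = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        comp = compound_score(model, frame)
        assert roc_auc(comp.to_numpy(), [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_missing_feature_errors(self):
        model = StepwiseModel(["zz"], {"zz": 1.0}, 0.0, -1.0, [])
        with pytest.raises(ValueError, match="zz"):
            compound_score(model, pd.DataFrame({"f": [1.0]}))


class TestMetaAnalysis:
    def test_inverse_variance_closed_form_fixture(self):
        res = meta_analyse([1.0, 3.0], [0.5, 0.5])
        assert res.pooled_beta == pytest.approx(2.0)
        assert res.pooled_se == pytest.approx(0.353553, abs=1e-6)
        assert res.q == pytest.approx(8.0)
        assert res.i2 == pytest.approx(87.5)

    def test_identical_cohorts_no_heterogeneity(self):
        res = meta_analyse([0.7, 0.7, 0.7], [0.2, 0.2, 0.2])
        assert res.pooled_beta == pytest.approx(0.7)
        assert res.q == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == 0.0
        assert res.re_pooled_beta == pytest.approx(0.7)

    def test_single_cohort_passthrough(self):
        res = meta_analyse([1.5], [0.4])
        assert res.pooled_beta == 1.5
        assert res.pooled_se == pytest.approx(0.4)
        assert res.q == 0.0 and res.i2 == 0.0

    def test_empty_or_bad_se_rejected(self):
        with pytest.raises(ValueError):
            meta_analyse([], [])
        with pytest.raises(ValueError):
            meta_analyse([1.0], [0.0])
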