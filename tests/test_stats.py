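from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ranovol import (
    TwoByTwo,
    ValidationError,
    dichotomize,
    fisher_exact,
    logistic_univariate,
    multivariate_screen_and_fit,
    wilcoxon_rank_sum,
)

from oracles import oracle_fisher_p


def table_vectors(a, b, c, d):
    """Outcome and exposure vectors realizing the 2x2 (a, b; c, d)."""
    outcome = [1] * a + [0] * b + [1] * c + [0] * d
    exposure = [1] * (a + b) + [0] * (c + d)
    return np.array(outcome), np.array(exposure)


class TestFisherExact:
    def test_fractionation_table_odds_ratio_and_p(self):
        res = fisher_exact(TwoByTwo(3, 9, 1, 56))
        assert res.odds_ratio == pytest.approx(18.67, abs=0.005)
        assert res.p_value == pytest.approx(0.0151, abs=5e-4)

    def test_balanced_table(self):
        res = fisher_exact(TwoByTwo(5, 5, 5, 5))
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0

    def test_zero_cell_gives_infinite_odds_ratio(self):
        assert fisher_exact(TwoByTwo(4, 6, 0, 10)).odds_ratio == math.inf

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            TwoByTwo(-1, 2, 3, 4)

    def test_agrees_with_scipy(self):
        from scipy.stats import fisher_exact as scipy_fisher

        rng = np.random.default_rng(7)
        for _ in range(50):
            cells = rng.integers(0, 25, size=4)
            if cells.sum() == 0:
                continue
            res = fisher_exact(TwoByTwo(*map(int, cells)))
            _, p_ref = scipy_fisher(np.array(cells).reshape(2, 2))
            assert res.p_value == pytest.approx(p_ref, abs=1e-7)


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        # complete separation of {1,2,3} vs {4,5,6}: 2/C(6,3) = 0.10
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.10)

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_singletons(self):
        assert wilcoxon_rank_sum([-0.41], [-0.19]) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        x=st.lists(st.integers(-100, 100), min_size=2, max_size=10, unique=True),
        y=st.lists(st.integers(-100, 100), min_size=2, max_size=10, unique=True),
    )
    def test_invariant_under_monotone_transform(self, x, y):
        # x**3 is strictly monotone and exact in float64 on this range, so
        # the rank (and tie) structure is preserved exactly
        p1 = wilcoxon_rank_sum(x, y)
        p2 = wilcoxon_rank_sum(np.array(x, float) ** 3, np.array(y, float) ** 3)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestDichotomize:
    def test_cutpoint_is_inclusive(self):
        assert dichotomize([4.7, 4.69], 4.7).tolist() == [1, 0]

    def test_degenerate_cutpoints(self):
        values = [1.0, 2.0, 3.0]
        assert dichotomize(values, 10.0).tolist() == [0, 0, 0]
        assert dichotomize(values, min(values)).tolist() == [1, 1, 1]


class TestLogisticRegression:
    def test_binary_predictor_matches_cross_product_ratio(self):
        outcome, exposure = table_vectors(3, 9, 1, 56)
        res = logistic_univariate(outcome, exposure, name="fractionation")
        assert res.odds_ratio == pytest.approx(56 / 3, rel=1e-4)
        assert res.p_value == pytest.approx(0.016, abs=2e-3)
        assert res.included_in_multivariate
        assert not res.separation_flag

    def test_separation_reported_not_hidden(self):
        outcome, exposure = table_vectors(0, 5, 4, 60)
        res = logistic_univariate(outcome, exposure, name="preceding_surgery")
        assert res.separation_flag
        assert res.odds_ratio < 1e-4
        assert res.p_value > 0.9
        assert not res.included_in_multivariate

    def test_independent_predictor_has_unit_odds_ratio(self):
        # identical outcome rates in both exposure groups
        outcome, exposure = table_vectors(4, 16, 4, 16)
        res = logistic_univariate(outcome, exposure)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValidationError):
            logistic_univariate(np.zeros(10), np.arange(10))


class TestScreenedMultivariate:
    @staticmethod
    def _cohort(seed=5, n=120):
        rng = np.random.default_rng(seed)
        strong = rng.integers(0, 2, n)
        noise = rng.integers(0, 2, n)
        logit = -2.0 + 2.2 * strong
        outcome = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
        return outcome, pd.DataFrame({"strong": strong, "noise": noise})

    def test_only_screened_predictors_enter(self):
        outcome, predictors = self._cohort()
        model = multivariate_screen_and_fit(outcome, predictors)
        included = {r.predictor for r in model.multivariate}
        assert "strong" in included
        by_name = {r.predictor: r for r in model.univariate}
        for name, res in by_name.items():
            assert res.included_in_multivariate == (res.p_value < 0.300)
            assert (name in included) == res.included_in_multivariate

    def test_screen_p_one_admits_everything(self):
        outcome, predictors = self._cohort()
        model = multivariate_screen_and_fit(outcome, predictors, screen_p=1.0)
        assert {r.predictor for r in model.multivariate} == set(predictors.columns)

    def test_single_screened_predictor_equals_univariate(self):
        outcome, exposure = table_vectors(8, 22, 4, 46)
        model = multivariate_screen_and_fit(
            outcome, pd.DataFrame({"only": exposure}), screen_p=1.0
        )
        (multi,) = model.multivariate
        (uni,) = model.univariate
        assert multi.odds_ratio == pytest.approx(uni.odds_ratio, rel=1e-8)

    def test_nothing_passes_returns_univariate_only(self):
        outcome, exposure = table_vectors(5, 15, 5, 15)
        model = multivariate_screen_and_fit(
            outcome, pd.DataFrame({"flat": exposure}), screen_p=0.001
        )
        assert model.multivariate == ()
        assert len(model.univariate) == 1


class TestFisherEnumerationProperty:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.integers(0, 30),
        b=st.integers(0, 30),
        c=st.integers(0, 30),
        d=st.integers(0, 30),
    )
    def test_p_in_unit_interval_and_matches_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact(TwoByTwo(a, b, c, d)).p_value
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(oracle_fisher_p(a, b, c, d), abs=1e-12)
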