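"""Weighted rank correlation, validation summaries, paired tests, exact power."""

import numpy as np
import pytest
from scipy import stats as sps

from fitkit.core import Dimension
from fitkit.errors import DegenerateDataError, NoSolutionError, ValidationError
from fitkit.stats import (
    PowerQuery,
    correlation_power,
    paired_comparison,
    rank_correlation_test,
    required_sample_size,
    skewness,
    validate_scores,
    weighted_rank_correlation,
)


class TestWeightedRankCorrelation:
    def test_perfect_concordance(self, rng):
        x = rng.normal(size=10)
        assert weighted_rank_correlation(x, x, rng.uniform(0.5, 2, 10)) == pytest.approx(1.0)

    def test_reversal(self):
        x = np.arange(8.0)
        assert weighted_rank_correlation(x, -x, np.ones(8)) == pytest.approx(-1.0)

    def test_equal_weights_reduce_to_spearman(self, rng):
        for _ in range(200):
            n = rng.integers(3, 40)
            x, y = rng.normal(size=n), rng.normal(size=n)
            ours = weighted_rank_correlation(x, y, np.full(n, 3.7))
            ref = sps.spearmanr(x, y)[0]
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x, y, w = rng.normal(size=15), rng.normal(size=15), rng.uniform(1, 9, 15)
        base = weighted_rank_correlation(x, y, w)
        assert weighted_rank_correlation(np.exp(x), y, w) == pytest.approx(base, abs=1e-12)
        assert weighted_rank_correlation(x, 5 * y + 2, w) == pytest.approx(base, abs=1e-12)

    def test_weights_matter(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 3.0])
        light = weighted_rank_correlation(x, y, [1, 1, 1, 1])
        heavy_disagreement = weighted_rank_correlation(x, y, [1, 1, 10, 10])
        assert heavy_disagreement < light

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            weighted_rank_correlation([1, 1, 1], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValidationError):
            weighted_rank_correlation([1, 2, 3], [1, 2, 3], [1, 0, 1])
        with pytest.raises(ValidationError):
            weighted_rank_correlation([1, 2], [1, 2], [1, 1])


class TestValidateScores:
    @staticmethod
    def _tables(n_questions=5, n_solutions=12, noise=0.0, seed=0):
        import pandas as pd

        from fitkit.elo import EloConfig, RatingTable

        rng = np.random.default_rng(seed)
        score_rows, rating_rows = [], []
        for dim in Dimension:
            for q in range(1, n_questions + 1):
                latent = rng.normal(size=n_solutions)
                for i in range(n_solutions):
                    sid = f"Q{q}S{i}"
                    score_rows.append({
                        "dimension": dim.value, "qid": q, "sid": sid,
                        "score_mean": 50 + 10 * latent[i] + noise * rng.normal(),
                        "n_repeats": 3,
                    })
                    rating_rows.append({
                        "dimension": dim.value, "qid": q, "sid": sid,
                        "rating": 1600 + 100 * latent[i], "match_count": 10 + i % 3,
                        "provisional": False,
                    })
        return pd.DataFrame(score_rows), RatingTable.from_frame(pd.DataFrame(rating_rows))

    def test_monotone_scores_give_unit_correlations(self):
        scores, ratings = self._tables(noise=0.0)
        for summary in validate_scores(scores, ratings).values():
            assert summary.n_questions == 5
            assert summary.mean == pytest.approx(1.0)
            assert summary.sd == pytest.approx(0.0, abs=1e-12)

    def test_independent_scores_give_near_zero_mean(self):
        import pandas as pd

        scores, ratings = self._tables(n_questions=50, n_solutions=20, seed=11)
        rng = np.random.default_rng(5)
        scores["score_mean"] = rng.normal(50, 10, size=len(scores))
        summaries = validate_scores(scores, ratings)
        for summary in summaries.values():
            assert abs(summary.mean) < 0.1

    def test_small_questions_excluded_and_reported(self):
        scores, ratings = self._tables(n_questions=3)
        scores = scores[~((scores["qid"] == 2) & (scores["sid"] != "Q2S0"))]
        summaries = validate_scores(scores, ratings)
        for summary in summaries.values():
            assert summary.n_questions == 2
            assert summary.excluded and summary.excluded[0][0] == 2


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([1, 2, 3]) == pytest.approx(0.0)

    def test_right_tail_positive_and_antisymmetry(self, rng):
        assert skewness([0, 0, 0, 1]) > 0
        x = rng.gamma(2, size=200)
        assert skewness(-x) == pytest.approx(-skewness(x))

    def test_matches_biased_moment_definition(self, rng):
        x = rng.normal(size=60)
        m = x - x.mean()
        expected = np.mean(m**3) / np.mean(m**2) ** 1.5
        assert skewness(x) == pytest.approx(expected, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            skewness([2, 2, 2])


class TestRankCorrelationTest:
    def test_concordant_and_reversed(self):
        x = np.arange(10.0)
        assert rank_correlation_test(x, x**3)[0] == pytest.approx(1.0)
        assert rank_correlation_test(x, -x)[0] == pytest.approx(-1.0)

    def test_against_brute_force_rank_pearson(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=25), rng.normal(size=25)
            rho, _ = rank_correlation_test(x, y)
            rx = sps.rankdata(x)
            ry = sps.rankdata(y)
            brute = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(brute, abs=1e-12)

    def test_constant_input(self):
        with pytest.raises(DegenerateDataError):
            rank_correlation_test([1, 1, 1, 1], [1, 2, 3, 4])


class TestPairedComparison:
    def test_identical_vectors_degenerate(self, rng):
        r = rng.uniform(size=20)
        with pytest.raises(DegenerateDataError):
            paired_comparison(r, r)

    def test_constant_shift_detected(self, rng):
        r1 = rng.uniform(0.3, 0.7, size=30)
        r2 = r1 - 0.2 + rng.normal(0, 0.01, size=30)
        p, d, bf10 = paired_comparison(r1, r2)
        assert p < 1e-6
        assert d > 2
        assert bf10 > 100

    def test_null_pairs_favor_null_in_majority_of_seeds(self):
        favors_null = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r1 = rng.normal(0.5, 0.1, size=50)
            r2 = rng.normal(0.5, 0.1, size=50)
            _, _, bf10 = paired_comparison(r1, r2)
            favors_null += bf10 < 1
        assert favors_null > 10

    def test_agrees_with_scipy_p_and_cohens_d_definition(self, rng):
        r1, r2 = rng.uniform(size=15), rng.uniform(size=15)
        p, d, _ = paired_comparison(r1, r2)
        assert p == pytest.approx(sps.ttest_rel(r1, r2).pvalue)
        diff = r1 - r2
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1))


class TestExactPower:
    def test_planning_query_returns_112(self):
        assert required_sample_size(PowerQuery(rho=0.3, alpha=0.05, power=0.9)) == 112

    def test_minimality_contract(self):
        n = required_sample_size(0.3, 0.05, 0.9)
        assert correlation_power(n, 0.3, 0.05) >= 0.9
        assert correlation_power(n - 1, 0.3, 0.05) < 0.9

    def test_monotone_in_effect_size_and_power(self):
        assert required_sample_size(0.5, 0.05, 0.9) < required_sample_size(0.3, 0.05, 0.9)
        assert required_sample_size(0.3, 0.05, 0.95) > required_sample_size(0.3, 0.05, 0.9)
        assert required_sample_size(-0.3, 0.05, 0.9) == required_sample_size(0.3, 0.05, 0.9)

    def test_power_matches_monte_carlo(self, rng):
        """Exact power at n=60, rho=0.35 against a simulation oracle."""
        n, rho, reps = 60, 0.35, 30000
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=(reps, n))
        x = xy[:, :, 0] - xy[:, :, 0].mean(axis=1, keepdims=True)
        y = xy[:, :, 1] - xy[:, :, 1].mean(axis=1, keepdims=True)
        r = (x * y).sum(1) / np.sqrt((x**2).sum(1) * (y**2).sum(1))
        tcrit = sps.t.ppf(0.975, n - 2)
        rcrit = tcrit / np.sqrt(n - 2 + tcrit**2)
        mc = np.mean(np.abs(r) > rcrit)
        se = np.sqrt(mc * (1 - mc) / reps)
        assert abs(correlation_power(n, rho) - mc) < 3 * se

    def test_invalid_queries(self):
        with pytest.raises(ValidationError):
            PowerQuery(rho=0.0)
        with pytest.raises(ValidationError):
            PowerQuery(rho=0.3, alpha=1.5)
        with pytest.raises(NoSolutionError):
            required_sample_size(0.01, 0.05, 0.9, max_n=100)
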