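"""Synthetic generator: latent structure, rater model, end-to-end recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fitkit.core import Dimension
from fitkit.errors import ValidationError
from fitkit.synth import (
    SimConfig,
    bradley_terry_strengths,
    low_noise_config,
    run_experiment,
    simulate_llm_scores,
    simulate_rater,
    simulate_solutions,
)

CN, CF, GAL = (Dimension.COMBINATION_NOVELTY, Dimension.COMBINATION_FEASIBILITY,
               Dimension.GOAL_ATTAINMENT)


class TestSimulateSolutions:
    def test_sign_structure_at_default_targets(self):
        config = SimConfig(n_questions=10, n_solutions_per_question=100, seed=4)
        truth, _, _ = simulate_solutions(config)
        lat = truth.latents
        r_gal_cn = sps.spearmanr(lat[GAL.value], lat[CN.value])[0]
        r_gal_cf = sps.spearmanr(lat[GAL.value], lat[CF.value])[0]
        r_cn_cf = sps.spearmanr(lat[CN.value], lat[CF.value])[0]
        assert r_gal_cn > 0.1 and r_gal_cf > 0.1 and r_cn_cf < -0.3

    def test_left_skewed_marginals_for_cf_and_gal(self):
        config = SimConfig(n_questions=10, n_solutions_per_question=200, seed=2)
        truth, _, _ = simulate_solutions(config)
        assert sps.skew(truth.latents[CF.value]) < -0.2
        assert sps.skew(truth.latents[GAL.value]) < -0.2
        assert abs(sps.skew(truth.latents[CN.value])) < 0.2

    def test_zero_correlation_config(self):
        config = SimConfig(n_questions=10, n_solutions_per_question=100,
                           corr_gal_cn=0.0, corr_gal_cf=0.0, corr_cn_cf=0.0, seed=6)
        truth, _, _ = simulate_solutions(config)
        lat = truth.latents
        for a, b in [(GAL, CN), (GAL, CF), (CN, CF)]:
            assert abs(sps.spearmanr(lat[a.value], lat[b.value])[0]) < 0.1

    def test_deterministic_given_seed(self):
        config = low_noise_config(seed=9)
        t1, s1, p1 = simulate_solutions(config)
        t2, s2, p2 = simulate_solutions(config)
        pd.testing.assert_frame_equal(t1.latents, t2.latents)
        assert s1 == s2 and p1 == p2

    def test_infeasible_correlation_targets_rejected(self):
        with pytest.raises(ValidationError, match="positive semidefinite"):
            SimConfig(corr_gal_cn=0.9, corr_gal_cf=0.9, corr_cn_cf=-0.9)

    def test_sanity_pool_covers_every_dimension_question(self):
        config = low_noise_config()
        _, _, pool = simulate_solutions(config)
        assert len(pool) == 3 * config.n_questions
        assert len({(p.dimension, p.qid) for p in pool}) == len(pool)


class TestSimulateRater:
    def test_zero_noise_higher_latent_always_wins(self, rng):
        config = dataclasses.replace(SimConfig(), rater_noise_sd=0.0, lapse_rate=0.0)
        assert all(simulate_rater(1.0, 0.0, config, rng) == 1 for _ in range(100))
        assert all(simulate_rater(-1.0, 0.0, config, rng) == 0 for _ in range(100))

    def test_full_lapse_is_a_coin(self, rng):
        config = dataclasses.replace(SimConfig(), lapse_rate=1.0)
        wins = np.mean([simulate_rater(5.0, -5.0, config, rng) for _ in range(10000)])
        assert abs(wins - 0.5) < 0.02

    def test_equal_latents_symmetric(self, rng):
        config = dataclasses.replace(SimConfig(), lapse_rate=0.0)
        wins = np.mean([simulate_rater(0.3, 0.3, config, rng) for _ in range(10000)])
        assert abs(wins - 0.5) < 0.02

    def test_win_rate_matches_thurstone_probability(self, rng):
        config = dataclasses.replace(SimConfig(), rater_noise_sd=0.5, lapse_rate=0.0)
        p = sps.norm.cdf(1.0 / (np.sqrt(2) * 0.5))
        wins = np.mean([simulate_rater(1.0, 0.0, config, rng) for _ in range(10000)])
        assert abs(wins - p) < 0.02


class TestSimulateLlmScores:
    def test_zero_noise_is_monotone_in_latents(self):
        config = dataclasses.replace(low_noise_config(seed=3), llm_noise_sd=0.0)
        truth, _, _ = simulate_solutions(config)
        scores = simulate_llm_scores(truth, config, rng=1)
        for (dim, qid), grp in scores.groupby(["dimension", "qid"]):
            lats = [truth.latent(Dimension(dim), sid) for sid in grp["sid"]]
            interior = grp["score_mean"].between(1.001, 99.999)
            if interior.sum() >= 3:  # clipping can tie extremes
                sub = grp[interior]
                rho = sps.spearmanr([truth.latent(Dimension(dim), s) for s in sub["sid"]],
                                    sub["score_mean"])[0]
                assert rho == pytest.approx(1.0)

    def test_scores_clipped_to_scale(self):
        config = dataclasses.replace(low_noise_config(seed=5), llm_noise_sd=80.0)
        truth, _, _ = simulate_solutions(config)
        scores = simulate_llm_scores(truth, config, rng=2)
        assert scores["score_mean"].between(1, 100).all()

    def test_rank_agreement_decreases_with_noise(self):
        base = low_noise_config(seed=7)
        truth, _, _ = simulate_solutions(base)
        agreement = []
        for noise in (0.0, 10.0, 40.0):
            config = dataclasses.replace(base, llm_noise_sd=noise)
            scores = simulate_llm_scores(truth, config, rng=3)
            rhos = []
            for (dim, qid), grp in scores.groupby(["dimension", "qid"]):
                lats = [truth.latent(Dimension(dim), s) for s in grp["sid"]]
                rhos.append(sps.spearmanr(lats, grp["score_mean"])[0])
            agreement.append(np.mean(rhos))
        assert agreement[0] > agreement[1] > agreement[2]


class TestRunExperiment:
    def test_full_sanity_failure_leaves_ratings_untouched(self):
        config = dataclasses.replace(low_noise_config(seed=2, n_raters=2),
                                     sanity_failure_rate=1.0)
        result = run_experiment(config)
        assert result.n_rating_bearing() == 0
        frame = result.rating_table.to_frame()
        assert (frame["rating"] == 1600.0).all()
        assert (frame["match_count"] == 0).all()

    def test_zero_sanity_failure_keeps_all_real_matches(self):
        result = run_experiment(low_noise_config(seed=2, n_raters=2))
        real = [m for m in result.judgments if not m.is_sanity]
        assert all(m.qc_passed for m in real)
        assert result.n_rating_bearing() == len(real)

    def test_lapse_raters_with_sanity_failures_reduce_evidence(self):
        base = low_noise_config(seed=3, n_raters=3)
        noisy = dataclasses.replace(base, lapse_rate=1.0, sanity_failure_rate=0.5)
        clean, degraded = run_experiment(base), run_experiment(noisy)
        assert degraded.n_rating_bearing() < clean.n_rating_bearing()

    def test_elo_ranking_agrees_with_bradley_terry_oracle(self):
        """Two independent routes from the same match log to a ranking."""
        result = run_experiment(low_noise_config(seed=8, n_raters=6))
        qid = 1
        sids = [s.sid for s in result.solutions if s.qid == qid]
        ms = [m for m in result.judgments
              if m.qid == qid and m.dimension is CN and not m.is_sanity]
        bt = bradley_terry_strengths(ms, sids)
        elo_ratings = [result.rating_table.rating(CN, s) for s in sids]
        rho = sps.spearmanr(elo_ratings, [bt[s] for s in sids])[0]
        assert rho > 0.9

    def test_determinism_end_to_end(self):
        r1 = run_experiment(low_noise_config(seed=5, n_raters=2))
        r2 = run_experiment(low_noise_config(seed=5, n_raters=2))
        assert r1.judgments == r2.judgments
        pd.testing.assert_frame_equal(r1.rating_table.to_frame(), r2.rating_table.to_frame())
        assert r1.recovery == r2.recovery
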