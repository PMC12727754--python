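"""Synthetic-data generator for end-to-end testing of the FIT pipeline.

The generator reproduces the statistical structure the evaluation machinery
assumes, so every stage can be exercised and checked against a known ground
truth without any external data:

* latent solution quality on the three dimensions is drawn from a Gaussian
  copula whose correlation targets carry the observed sign structure (goal
  attainment positively related to both novelty and feasibility, novelty
  negatively related to feasibility), with left-skewed (skew-normal)
  marginals for feasibility and goal attainment;
* human 2AFC raters follow a Thurstone choice model - the higher-latent
  solution wins with probability Phi((q_A - q_B) / (sqrt(2) * noise_sd)) -
  with an optional lapse rate (pure guessing) and a sanity-check failure
  rate;
* automated scores are a noisy affine map of the latents onto the 1-100
  scale.

Defaults mirror the study conditions: 50 questions, 42 solutions per
question, 122 raters, latent correlation targets +0.23 / +0.28 / -0.49.
A desk-scale ``low_noise_config`` preset (6 questions x 20 solutions,
near-noiseless raters, 6 raters = 12 matches per solution) is provided for
parameter-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Dimension, FeedbackFlags, Solution, Validity
from .elo import EloConfig, MatchRecord, RatingTable, compute_ratings
from .errors import ValidationError
from .scheduler import SanityPair, SchedulerState, build_rater_plan, qc_filter
from .stats import ValidationSummary, validate_scores

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "low_noise_config",
    "simulate_solutions",
    "simulate_rater",
    "simulate_llm_scores",
    "run_experiment",
    "bradley_terry_strengths",
]

_DIMS = (Dimension.COMBINATION_NOVELTY, Dimension.COMBINATION_FEASIBILITY, Dimension.GOAL_ATTAINMENT)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator; defaults follow the experiment
    scale (50 questions, ~42 valid solutions per question, 122 raters)."""

    n_questions: int = 50
    n_solutions_per_question: int = 42
    n_participants: int = 144
    n_raters: int = 122
    # latent Spearman-sign targets between (CN, CF), (GAL, CN), (GAL, CF)
    corr_gal_cn: float = 0.23
    corr_gal_cf: float = 0.28
    corr_cn_cf: float = -0.49
    cf_skew: float = -4.0  # skew-normal shape; negative = left-skewed
    gal_skew: float = -3.0
    rater_noise_sd: float = 0.5  # Thurstone discriminal dispersion, latent sd units
    lapse_rate: float = 0.02
    sanity_failure_rate: float = 0.05
    llm_center: float = 55.0  # affine map of latents onto the 1-100 scale
    llm_slope: float = 18.0
    llm_noise_sd: float = 12.0
    llm_bias: float = 0.0
    question_distortion_sd: float = 0.0  # per-question offset of the LLM map
    temperature: float = 100.0  # pair-selection closeness temperature
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lapse_rate", "sanity_failure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("rater_noise_sd", "llm_noise_sd", "question_distortion_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if np.linalg.eigvalsh(self.correlation_matrix()).min() < -1e-10:
            raise ValidationError("correlation targets are not positive semidefinite")

    def correlation_matrix(self) -> np.ndarray:
        """Latent correlation over (CN, CF, GAL)."""
        return np.array(
            [
                [1.0, self.corr_cn_cf, self.corr_gal_cn],
                [self.corr_cn_cf, 1.0, self.corr_gal_cf],
                [self.corr_gal_cn, self.corr_gal_cf, 1.0],
            ]
        )


def low_noise_config(seed: int = 0, n_raters: int = 6) -> SimConfig:
    """Desk-scale preset for parameter recovery: near-noiseless raters, no
    lapses or sanity failures; 6 raters give ~12 matches per solution with
    20 solutions per question."""
    return SimConfig(
        n_questions=6,
        n_solutions_per_question=20,
        n_participants=20,
        n_raters=n_raters,
        rater_noise_sd=0.1,
        lapse_rate=0.0,
        sanity_failure_rate=0.0,
        llm_noise_sd=2.0,
        seed=seed,
    )


@dataclass
class SimTruth:
    """Latent per-solution qualities (standardized per dimension) and the
    designed sanity solutions."""

    latents: pd.DataFrame  # sid, qid, participant, one column per dimension
    sanity_latents: pd.DataFrame

    def latent(self, dimension: Dimension, sid: str) -> float:
        row = self.latents.loc[self.latents["sid"] == sid]
        return float(row[Dimension(dimension).value].iloc[0])


def simulate_solutions(
    config: SimConfig, rng: np.random.Generator | int | None = None
) -> tuple[SimTruth, list[Solution], list[SanityPair]]:
    """Draw latent qualities, templated solution rows, and a sanity pool.

    Sanity pairs use two dedicated designed solutions per (dimension,
    question) with extreme latent separation; they are not part of the rated
    solution set.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n_questions * config.n_solutions_per_question
    z = rng.multivariate_normal(np.zeros(3), config.correlation_matrix(), size=n)
    u = sps.norm.cdf(z)
    cn = z[:, 0]
    cf = sps.skewnorm.ppf(u[:, 1], a=config.cf_skew)
    gal = sps.skewnorm.ppf(u[:, 2], a=config.gal_skew)
    lat = np.column_stack([cn, cf, gal])
    lat = (lat - lat.mean(axis=0)) / lat.std(axis=0)  # common standardized scale

    rows, solutions = [], []
    i = 0
    for q in range(1, config.n_questions + 1):
        for k in range(config.n_solutions_per_question):
            sid = f"Q{q:02d}S{k:02d}"
            participant = f"P{(i % config.n_participants) + 1:03d}"
            rows.append(
                {
                    "sid": sid,
                    "qid": q,
                    "participant": participant,
                    Dimension.COMBINATION_NOVELTY.value: lat[i, 0],
                    Dimension.COMBINATION_FEASIBILITY.value: lat[i, 1],
                    Dimension.GOAL_ATTAINMENT.value: lat[i, 2],
                }
            )
            solutions.append(
                Solution(
                    sid=sid,
                    participant=participant,
                    qid=q,
                    text=f"Synthetic solution {sid}: combine the two elements of question {q}.",
                    order_index=k,
                    feedback=FeedbackFlags(True, True, True),
                    validity=Validity.VALID,
                )
            )
            i += 1

    sanity_rows, sanity_pool = [], []
    for dim in _DIMS:
        for q in range(1, config.n_questions + 1):
            hi, lo = f"Q{q:02d}-SANHI-{dim.value}", f"Q{q:02d}-SANLO-{dim.value}"
            sanity_pool.append(SanityPair(dimension=dim, qid=q, sid_high=hi, sid_low=lo))
            sanity_rows.append({"sid": hi, "qid": q, "dimension": dim.value, "latent": 2.5})
            sanity_rows.append({"sid": lo, "qid": q, "dimension": dim.value, "latent": -2.5})

    truth = SimTruth(
        latents=pd.DataFrame(rows), sanity_latents=pd.DataFrame(sanity_rows)
    )
    return truth, solutions, sanity_pool


def simulate_rater(
    q_a: float, q_b: float, config: SimConfig, rng: np.random.Generator
) -> int:
    """One 2AFC judgment under the Thurstone model; returns outcome for A.

    With probability ``lapse_rate`` the rater guesses uniformly; otherwise A
    wins with probability Phi((q_A - q_B) / (sqrt(2) * noise_sd)).  At zero
    noise the higher latent always wins (exact ties fall back to a coin).
    """
    if config.lapse_rate and rng.random() < config.lapse_rate:
        return int(rng.integers(2))
    if config.rater_noise_sd == 0.0:
        if q_a == q_b:
            return int(rng.integers(2))
        return int(q_a > q_b)
    p_a = sps.norm.cdf((q_a - q_b) / (math.sqrt(2.0) * config.rater_noise_sd))
    return int(rng.random() < p_a)


def simulate_llm_scores(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator | int = 0
) -> pd.DataFrame:
    """Noisy affine map of the latents onto the 1-100 rating scale."""
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    rows = []
    distortion: dict[int, float] = {}
    for dim in _DIMS:
        for _, rec in truth.latents.iterrows():
            qid = int(rec["qid"])
            if config.question_distortion_sd and qid not in distortion:
                distortion[qid] = rng.normal(0.0, config.question_distortion_sd)
            raw = (
                config.llm_center
                + config.llm_slope * rec[dim.value]
                + config.llm_bias
                + distortion.get(qid, 0.0)
                + (rng.normal(0.0, config.llm_noise_sd) if config.llm_noise_sd else 0.0)
            )
            rows.append(
                {
                    "dimension": dim.value,
                    "qid": qid,
                    "sid": rec["sid"],
                    "score_mean": float(np.clip(raw, 1.0, 100.0)),
                    "n_repeats": 1,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SimResult:
    config: SimConfig
    truth: SimTruth
    solutions: list[Solution]
    sanity_pool: list[SanityPair]
    judgments: list[MatchRecord]
    rating_table: RatingTable
    llm_scores: pd.DataFrame
    validation: dict[Dimension, ValidationSummary]
    recovery: dict[Dimension, float]  # mean per-question Spearman(latent, Elo)
    recovery_per_question: dict[Dimension, dict[int, float]]

    @property
    def mean_recovery(self) -> float:
        return float(np.mean(list(self.recovery.values())))

    def n_rating_bearing(self) -> int:
        return sum(1 for m in self.judgments if m.qc_passed and not m.is_sanity)


def run_experiment(
    config: SimConfig, seed: int | None = None, elo_config: EloConfig = EloConfig()
) -> SimResult:
    """Full pipeline: schedule raters, simulate judgments, QC-filter, replay
    Elo, simulate automated scores, and validate them against the Elo ground
    truth.

    The scheduler reads an epochal ratings snapshot refreshed after each
    completed rater (the batch-update stand-in), so pair selection adapts as
    evidence accumulates.
    """
    master = np.random.default_rng(config.seed if seed is None else seed)
    truth, solutions, sanity_pool = simulate_solutions(config, master)
    by_question = {
        q: [s.sid for s in solutions if s.qid == q]
        for q in range(1, config.n_questions + 1)
    }
    latent = {
        (dim, rec["sid"]): float(rec[dim.value])
        for _, rec in truth.latents.iterrows()
        for dim in _DIMS
    }
    roster = [
        (dim, s.sid, s.qid) for dim in _DIMS for s in solutions
    ]

    judgments: list[MatchRecord] = []
    table = compute_ratings([], elo_config, roster=roster)
    ts = 0
    for r in range(config.n_raters):
        state = SchedulerState(solutions_by_question=by_question, ratings=table)
        plan = build_rater_plan(
            rater=f"R{r + 1:03d}",
            state=state,
            sanity_pool=sanity_pool,
            seed=master,
            temperature=config.temperature,
        )
        for pm in plan.matches:
            if pm.is_sanity:
                correct = master.random() >= config.sanity_failure_rate
                outcome_a = int(correct)  # sid_a is the designed winner
            else:
                outcome_a = simulate_rater(
                    latent[(pm.dimension, pm.sid_a)],
                    latent[(pm.dimension, pm.sid_b)],
                    config,
                    master,
                )
            judgments.append(
                MatchRecord(
                    dimension=pm.dimension,
                    qid=pm.qid,
                    sid_a=pm.sid_a,
                    sid_b=pm.sid_b,
                    outcome_a=outcome_a,
                    rater=plan.rater,
                    block_position=pm.slot,
                    is_sanity=pm.is_sanity,
                    timestamp=ts,
                )
            )
            ts += 1
        # epochal snapshot refresh once this rater's blocks are complete
        filtered = qc_filter(judgments, sanity_pool)
        table = compute_ratings(filtered, elo_config, roster=roster)

    filtered = qc_filter(judgments, sanity_pool) if judgments else []
    table = compute_ratings(filtered, elo_config, roster=roster)
    llm_scores = simulate_llm_scores(truth, config, master)
    validation = validate_scores(llm_scores, table)

    recovery: dict[Dimension, float] = {}
    recovery_pq: dict[Dimension, dict[int, float]] = {}
    for dim in _DIMS:
        per_q = {}
        for q, sids in by_question.items():
            lats = np.array([latent[(dim, sid)] for sid in sids])
            ratings = np.array([table.rating(dim, sid) for sid in sids])
            if np.var(ratings) == 0:
                continue
            per_q[q] = float(sps.spearmanr(lats, ratings)[0])
        recovery_pq[dim] = per_q
        recovery[dim] = float(np.mean(list(per_q.values()))) if per_q else float("nan")

    return SimResult(
        config=config,
        truth=truth,
        solutions=solutions,
        sanity_pool=sanity_pool,
        judgments=[replace_qc(m, filtered_map(filtered)) for m in judgments]
        if judgments
        else [],
        rating_table=table,
        llm_scores=llm_scores,
        validation=validation,
        recovery=recovery,
        recovery_per_question=recovery_pq,
    )


def filtered_map(filtered: Sequence[MatchRecord]) -> dict[int, bool]:
    return {m.timestamp: m.qc_passed for m in filtered}


def replace_qc(m: MatchRecord, qc: dict[int, bool]) -> MatchRecord:
    return replace(m, qc_passed=qc.get(m.timestamp, m.qc_passed))


def bradley_terry_strengths(
    matches: Sequence[MatchRecord], sids: Sequence[str], n_iter: int = 500, tol: float = 1e-10
) -> dict[str, float]:
    """Independent Bradley-Terry MLE (minorization-maximization) from the
    same match log; a cross-check oracle for the Elo ranking on small
    instances, never the rating implementation."""
    idx = {s: i for i, s in enumerate(sids)}
    n = len(sids)
    wins = np.zeros(n)
    games = np.zeros((n, n))
    for m in matches:
        if m.is_sanity or not m.qc_passed:
            continue
        a, b = idx[m.sid_a], idx[m.sid_b]
        games[a, b] += 1
        games[b, a] += 1
        wins[a if m.outcome_a else b] += 1
    pi = np.ones(n)
    for _ in range(n_iter):
        denom = (games / (pi[:, None] + pi[None, :])).sum(axis=1)
        new = np.where(denom > 0, np.maximum(wins, 1e-12) / np.maximum(denom, 1e-12), pi)
        new /= np.exp(np.mean(np.log(new)))
        if np.max(np.abs(new - pi)) < tol:
            pi = new
            break
        pi = new
    return {s: float(np.log(pi[idx[s]])) for s in sids}
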