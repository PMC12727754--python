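"""Validation and analysis statistics.

Validation of the automated ratings against the human Elo ground truth uses a
weighted rank correlation per question: both score vectors are converted to
average ranks and a weighted Pearson correlation of the rank vectors is
taken, with Elo match counts as weights, so solutions whose Elo rating rests
on more comparisons count more.  With equal weights this reduces exactly to
Spearman's rank correlation.

Sample-size planning uses the exact sampling distribution of the Pearson
correlation coefficient under a bivariate normal model (the hypergeometric
density, not the Fisher-z approximation), matching the behavior of standard
exact power software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

from .core import Dimension
from .errors import DegenerateDataError, NoSolutionError, ValidationError

__all__ = [
    "PowerQuery",
    "ValidationSummary",
    "weighted_rank_correlation",
    "validate_scores",
    "skewness",
    "rank_correlation_test",
    "paired_comparison",
    "correlation_power",
    "required_sample_size",
]


@dataclass(frozen=True)
class PowerQuery:
    rho: float
    alpha: float = 0.05
    power: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < abs(self.rho) < 1:
            raise ValidationError("rho must satisfy 0 < |rho| < 1")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValidationError("alpha and power must be in (0, 1)")


@dataclass
class ValidationSummary:
    dimension: Dimension
    per_question: dict[int, float] = field(default_factory=dict)
    excluded: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_questions(self) -> int:
        return len(self.per_question)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_question.values())))

    @property
    def sd(self) -> float:
        vals = list(self.per_question.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = w @ x, w @ y
    cov = w @ ((x - mx) * (y - my))
    vx, vy = w @ (x - mx) ** 2, w @ (y - my) ** 2
    if vx <= 0 or vy <= 0:
        raise DegenerateDataError("zero variance in a rank vector")
    return float(cov / math.sqrt(vx * vy))


def weighted_rank_correlation(x, y, w) -> float:
    """Weighted Pearson correlation of the (average-tie) rank vectors of x, y."""
    x, y, w = (np.asarray(v, dtype=float) for v in (x, y, w))
    if not (len(x) == len(y) == len(w)):
        raise ValidationError("x, y, w must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    return _weighted_pearson(sps.rankdata(x), sps.rankdata(y), w)


def validate_scores(
    score_table: pd.DataFrame,
    rating_table,
    min_solutions: int = 3,
) -> dict[Dimension, ValidationSummary]:
    """Per-question weighted rank correlation of automated vs Elo scores.

    ``score_table`` needs columns dimension/qid/sid/score_mean (an
    ``AutomatedScoreTable.scores`` frame works directly); weights are the Elo
    match counts.  Questions with fewer than ``min_solutions`` overlapping,
    positively weighted solutions are excluded and reported.
    """
    if hasattr(score_table, "scores"):
        score_table = score_table.scores
    ratings = rating_table.to_frame() if hasattr(rating_table, "to_frame") else rating_table
    merged = score_table.merge(
        ratings[["dimension", "sid", "rating", "match_count"]],
        on=["dimension", "sid"],
        how="inner",
    )
    merged = merged[merged["match_count"] > 0]
    out: dict[Dimension, ValidationSummary] = {}
    for dim in Dimension:
        summary = ValidationSummary(dimension=dim)
        sub = merged[merged["dimension"] == dim.value]
        for qid, grp in sub.groupby("qid"):
            if len(grp) < min_solutions:
                summary.excluded.append((int(qid), f"only {len(grp)} scored solutions"))
                continue
            try:
                r = weighted_rank_correlation(
                    grp["score_mean"].to_numpy(),
                    grp["rating"].to_numpy(),
                    grp["match_count"].to_numpy(),
                )
            except DegenerateDataError as exc:
                summary.excluded.append((int(qid), str(exc)))
                continue
            summary.per_question[int(qid)] = r
        out[dim] = summary
    return out


def skewness(x) -> float:
    """Third standardized central moment, no bias correction."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise DegenerateDataError("skewness needs n >= 3")
    if np.var(x) == 0:
        raise DegenerateDataError("skewness undefined for zero variance")
    return float(sps.skew(x, bias=True))


def rank_correlation_test(x, y) -> tuple[float, float]:
    """Spearman's rank correlation with a two-sided p-value."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValidationError("need paired samples with n >= 4")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateDataError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def paired_comparison(r1, r2) -> tuple[float, float, float]:
    """Paired two-sided t-test p-value, paired Cohen's d, and JZS BF10.

    Used e.g. to compare per-question validation coefficients between two
    rating protocols (such as two prompt languages).  Cohen's d is
    mean(diff)/sd(diff); the Bayes factor is the default JZS paired-sample
    Bayes factor with Cauchy scale sqrt(2)/2.
    """
    import pingouin as pg

    r1, r2 = np.asarray(r1, dtype=float), np.asarray(r2, dtype=float)
    if len(r1) != len(r2) or len(r1) < 3:
        raise ValidationError("need paired vectors with n >= 3")
    diff = r1 - r2
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            raise DegenerateDataError("identical pairs: test degenerate")
        raise DegenerateDataError("zero-variance differences")
    t, p = sps.ttest_rel(r1, r2)
    d = float(diff.mean() / sd)
    bf10 = float(pg.bayesfactor_ttest(float(t), nx=len(r1), paired=True, r=math.sqrt(2) / 2))
    return float(p), d, bf10


def _log_r_density(r: np.ndarray, rho: float, n: int) -> np.ndarray:
    """Log density of the sample correlation r for a bivariate normal sample
    of size n with population correlation rho (hypergeometric form)."""
    r = np.asarray(r, dtype=float)
    lognum = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * math.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-r * r)
    )
    logden = (
        0.5 * math.log(2 * math.pi)
        + special.gammaln(n - 0.5)
        + (n - 1.5) * np.log1p(-rho * r)
    )
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    return lognum - logden + np.log(hyp)


def correlation_power(n: int, rho: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided test of H0: rho = 0 at sample size n.

    The critical region comes from the exact null distribution (the usual t
    transform of r is exactly t with n-2 df under H0); the probability of
    rejection under the alternative integrates the exact density of r.
    """
    if n < 4:
        return 0.0
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df=n - 2)
    r_crit = t_crit / math.sqrt(n - 2 + t_crit * t_crit)
    accept, _ = integrate.quad(
        lambda r: math.exp(_log_r_density(r, rho, n)), -r_crit, r_crit, limit=200
    )
    return float(min(1.0, max(0.0, 1.0 - accept)))


def required_sample_size(
    rho: float | PowerQuery, alpha: float = 0.05, power: float = 0.9, max_n: int = 1_000_000
) -> int:
    """Smallest n whose exact two-sided correlation-test power reaches target."""
    if isinstance(rho, PowerQuery):
        query = rho
    else:
        query = PowerQuery(rho=rho, alpha=alpha, power=power)
    rho_abs = abs(query.rho)
    lo, hi = 4, 8
    while correlation_power(hi, rho_abs, query.alpha) < query.power:
        lo, hi = hi, hi * 2
        if hi > max_n:
            raise NoSolutionError(f"power {query.power} unattainable below n={max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if correlation_power(mid, rho_abs, query.alpha) >= query.power:
            hi = mid
        else:
            lo = mid + 1
    return hi
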