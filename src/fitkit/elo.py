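"""Elo rating of FIT solutions from two-alternative forced-choice matches.

Each human judgment pits two solutions of the same question against each
other on one dimension.  Ratings start at a common baseline and are updated
after every match by K times the gap between the observed outcome and the
logistic expected win probability

    E_A = 1 / (1 + 10^((R_B - R_A) / s)),

with step size K = 16, baseline 1600 and logistic scale s = 400 points by
default.  Because E_A + E_B = 1 and S_A + S_B = 1, every update conserves the
two ratings' sum; the total rating mass is always n * initial_rating.
Matches are replayed in strict timestamp order (ties broken by record index),
so the result is deterministic for a given log.  Sanity-check matches and
matches from blocks that failed quality control never bear on ratings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Dimension
from .errors import IntegrityError, ValidationError

__all__ = [
    "EloConfig",
    "MatchRecord",
    "MatchEvaluation",
    "RatingTable",
    "expected_score",
    "update_match",
    "compute_ratings",
    "match_count_summary",
    "read_matches",
    "write_matches",
]

PROVISIONAL_THRESHOLD = 9  # ratings from fewer matches are "provisional"


@dataclass(frozen=True)
class EloConfig:
    k_factor: float = 16.0
    initial_rating: float = 1600.0
    logistic_scale: float = 400.0
    provisional_threshold: int = PROVISIONAL_THRESHOLD

    def __post_init__(self) -> None:
        if min(self.k_factor, self.initial_rating, self.logistic_scale) <= 0:
            raise ValidationError("EloConfig fields must be positive")


@dataclass(frozen=True)
class MatchRecord:
    """One 2AFC judgment; outcome_a is 1 if solution A won, 0 if it lost."""

    dimension: Dimension
    qid: int
    sid_a: str
    sid_b: str
    outcome_a: int
    rater: str = ""
    block_position: int = 0
    is_sanity: bool = False
    qc_passed: bool = True
    timestamp: int = 0

    def __post_init__(self) -> None:
        if self.sid_a == self.sid_b:
            raise ValidationError("a match needs two distinct solutions")
        if self.outcome_a not in (0, 1):
            raise ValidationError("outcome_a must be 0 or 1")
        if not isinstance(self.dimension, Dimension):
            object.__setattr__(self, "dimension", Dimension(self.dimension))

    @property
    def outcome_b(self) -> int:
        return 1 - self.outcome_a

    @property
    def winner(self) -> str:
        return self.sid_a if self.outcome_a == 1 else self.sid_b


@dataclass(frozen=True)
class MatchEvaluation:
    expected_a: float
    expected_b: float
    new_rating_a: float
    new_rating_b: float


@dataclass
class RatingTable:
    """Per-(dimension, sid) ratings and match counts for valid solutions."""

    config: EloConfig = field(default_factory=EloConfig)
    _ratings: dict[tuple[Dimension, str], float] = field(default_factory=dict)
    _counts: dict[tuple[Dimension, str], int] = field(default_factory=dict)
    _qids: dict[str, int] = field(default_factory=dict)

    def rating(self, dimension: Dimension, sid: str) -> float:
        return self._ratings[(Dimension(dimension), sid)]

    def match_count(self, dimension: Dimension, sid: str) -> int:
        return self._counts[(Dimension(dimension), sid)]

    def is_provisional(self, dimension: Dimension, sid: str) -> bool:
        return self.match_count(dimension, sid) < self.config.provisional_threshold

    def sids(self, dimension: Dimension | None = None) -> list[str]:
        if dimension is None:
            return sorted({sid for (_, sid) in self._ratings})
        dimension = Dimension(dimension)
        return sorted(sid for (d, sid) in self._ratings if d == dimension)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: EloConfig | None = None) -> "RatingTable":
        table = cls(config=config or EloConfig())
        for _, row in df.iterrows():
            key = (Dimension(row["dimension"]), str(row["sid"]))
            table._ratings[key] = float(row["rating"])
            table._counts[key] = int(row["match_count"])
            table._qids[str(row["sid"])] = int(row["qid"])
        return table

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dimension": d.value,
                "qid": self._qids.get(sid, -1),
                "sid": sid,
                "rating": r,
                "match_count": self._counts[(d, sid)],
                "provisional": self._counts[(d, sid)] < self.config.provisional_threshold,
            }
            for (d, sid), r in sorted(self._ratings.items())
        ]
        return pd.DataFrame(
            rows, columns=["dimension", "qid", "sid", "rating", "match_count", "provisional"]
        )


def expected_score(rating_a: float, rating_b: float, config: EloConfig = EloConfig()) -> tuple[float, float]:
    """Expected win probabilities (E_A, E_B); they sum to one."""
    if not (math.isfinite(rating_a) and math.isfinite(rating_b)):
        raise ValueError("ratings must be finite")
    e_a = 1.0 / (1.0 + 10.0 ** ((rating_b - rating_a) / config.logistic_scale))
    return e_a, 1.0 - e_a


def update_match(
    rating_a: float, rating_b: float, outcome_a: int, config: EloConfig = EloConfig()
) -> MatchEvaluation:
    """Post-match ratings R' = R + K (S - E) for both sides."""
    if outcome_a not in (0, 1):
        raise ValueError("outcome_a must be 0 or 1")
    e_a, e_b = expected_score(rating_a, rating_b, config)
    return MatchEvaluation(
        expected_a=e_a,
        expected_b=e_b,
        new_rating_a=rating_a + config.k_factor * (outcome_a - e_a),
        new_rating_b=rating_b + config.k_factor * ((1 - outcome_a) - e_b),
    )


def compute_ratings(
    matches: Sequence[MatchRecord],
    config: EloConfig = EloConfig(),
    roster: Iterable[tuple[Dimension, str, int]] | None = None,
) -> RatingTable:
    """Replay rating-bearing matches in timestamp order.

    Sanity matches and matches with ``qc_passed=False`` are excluded from
    updates but their solutions still appear (at the initial rating, count 0)
    so that downstream joins see the full roster.  ``roster`` may add
    (dimension, sid, qid) entries with no matches at all.
    """
    table = RatingTable(config=config)

    def ensure(dim: Dimension, sid: str, qid: int) -> None:
        if sid in table._qids and table._qids[sid] != qid:
            raise IntegrityError(
                f"solution {sid} appears under qid {table._qids[sid]} and {qid}"
            )
        table._qids[sid] = qid
        table._ratings.setdefault((dim, sid), config.initial_rating)
        table._counts.setdefault((dim, sid), 0)

    if roster:
        for dim, sid, qid in roster:
            ensure(Dimension(dim), sid, qid)
    ordered = sorted(enumerate(matches), key=lambda ix: (ix[1].timestamp, ix[0]))
    for _, m in ordered:
        if m.is_sanity:
            continue  # designed sanity solutions are not rated solutions
        ensure(m.dimension, m.sid_a, m.qid)
        ensure(m.dimension, m.sid_b, m.qid)
        if not m.qc_passed:
            continue
        ka, kb = (m.dimension, m.sid_a), (m.dimension, m.sid_b)
        ev = update_match(table._ratings[ka], table._ratings[kb], m.outcome_a, config)
        table._ratings[ka] = ev.new_rating_a
        table._ratings[kb] = ev.new_rating_b
        table._counts[ka] += 1
        table._counts[kb] += 1
    return table


def match_count_summary(table: RatingTable) -> pd.DataFrame:
    """Per-dimension mean/sd/min/max of match counts and fraction provisional."""
    df = table.to_frame()
    if df.empty:
        return pd.DataFrame(
            columns=["dimension", "mean", "sd", "min", "max", "frac_provisional", "n_solutions"]
        )
    rows = []
    for dim, grp in df.groupby("dimension", sort=True):
        counts = grp["match_count"].to_numpy()
        rows.append(
            {
                "dimension": dim,
                "mean": float(np.mean(counts)),
                "sd": float(np.std(counts, ddof=1)) if len(counts) > 1 else 0.0,
                "min": int(np.min(counts)),
                "max": int(np.max(counts)),
                "frac_provisional": float(np.mean(counts < table.config.provisional_threshold)),
                "n_solutions": len(counts),
            }
        )
    return pd.DataFrame(rows)


def write_matches(path: str | Path, matches: Sequence[MatchRecord]) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for m in matches:
            fh.write(
                json.dumps(
                    {
                        "dimension": m.dimension.value,
                        "qid": m.qid,
                        "sid_a": m.sid_a,
                        "sid_b": m.sid_b,
                        "outcome_a": m.outcome_a,
                        "rater": m.rater,
                        "block_position": m.block_position,
                        "is_sanity": m.is_sanity,
                        "qc_passed": m.qc_passed,
                        "timestamp": m.timestamp,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_matches(path: str | Path) -> list[MatchRecord]:
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(MatchRecord(**json.loads(line)))
    return records
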