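"""Rater evaluation plans and block-level quality control for 2AFC judging.

Each human rater works through the three evaluation dimensions in random
order.  A dimension holds 6 questions; a question holds a block of 21
matches, and slot 11 of every block is a sanity-check pair with a designed
obvious winner, unbeknownst to the rater.  Real pairs are drawn with higher
priority for solutions with closer current ratings (weight exp(-|dR|/tau)),
never repeating a pair within a block.  A block's 20 real judgments count
toward ratings only if its sanity judgment picked the designed winner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import Dimension
from .elo import MatchRecord, RatingTable
from .errors import QCError, SchedulingError

__all__ = [
    "MATCHES_PER_BLOCK",
    "SANITY_SLOT",
    "QUESTIONS_PER_DIMENSION",
    "SanityPair",
    "PlannedMatch",
    "RaterPlan",
    "SchedulerState",
    "select_pair",
    "build_rater_plan",
    "qc_filter",
]

MATCHES_PER_BLOCK = 21
SANITY_SLOT = 11  # 1-based slot reserved for the sanity pair
QUESTIONS_PER_DIMENSION = 6
DEFAULT_TEMPERATURE = 100.0  # rating points; weight = exp(-|dR|/tau)


@dataclass(frozen=True)
class SanityPair:
    dimension: Dimension
    qid: int
    sid_high: str  # designed obvious winner
    sid_low: str

    def __post_init__(self) -> None:
        if self.sid_high == self.sid_low:
            raise SchedulingError("sanity pair needs two distinct solutions")
        if not isinstance(self.dimension, Dimension):
            object.__setattr__(self, "dimension", Dimension(self.dimension))


@dataclass(frozen=True)
class PlannedMatch:
    dimension: Dimension
    qid: int
    slot: int  # 1..21 within the block
    sid_a: str
    sid_b: str
    is_sanity: bool


@dataclass
class RaterPlan:
    rater: str
    matches: list[PlannedMatch]

    def __len__(self) -> int:
        return len(self.matches)

    def blocks(self) -> list[list[PlannedMatch]]:
        out, cur = [], []
        for m in self.matches:
            cur.append(m)
            if m.slot == MATCHES_PER_BLOCK:
                out.append(cur)
                cur = []
        return out


@dataclass
class SchedulerState:
    """Snapshot the scheduler reads: valid solutions per question plus the
    current ratings/match counts (refreshed epochally, e.g. per completed
    rater)."""

    solutions_by_question: Mapping[int, Sequence[str]]
    ratings: RatingTable

    def rating(self, dimension: Dimension, sid: str) -> float:
        try:
            return self.ratings.rating(dimension, sid)
        except KeyError:
            return self.ratings.config.initial_rating

    def count(self, dimension: Dimension, sid: str) -> int:
        try:
            return self.ratings.match_count(dimension, sid)
        except KeyError:
            return 0


def select_pair(
    sids: Sequence[str],
    ratings: Mapping[str, float],
    counts: Mapping[str, int],
    rng: np.random.Generator,
    temperature: float = DEFAULT_TEMPERATURE,
    exclude: frozenset[frozenset[str]] | set = frozenset(),
) -> tuple[str, str]:
    """Sample one unordered pair, preferring close ratings.

    Pairs are weighted exp(-|R_i - R_j| / temperature).  When the sampled
    weight is shared by several pairs, the tie is broken toward the lowest
    total match count (uniformly among remaining ties).  Pairs in ``exclude``
    are never returned (no repeats within a block).
    """
    candidates = [
        (a, b)
        for i, a in enumerate(sids)
        for b in sids[i + 1 :]
        if frozenset((a, b)) not in exclude
    ]
    if not candidates:
        raise SchedulingError("fewer than 2 available candidates for pairing")
    gaps = np.array([abs(ratings[a] - ratings[b]) for a, b in candidates])
    weights = np.exp(-gaps / temperature)
    picked = candidates[rng.choice(len(candidates), p=weights / weights.sum())]
    w0 = math.exp(-abs(ratings[picked[0]] - ratings[picked[1]]) / temperature)
    tied = [c for c, w in zip(candidates, weights) if abs(w - w0) <= 1e-12]
    min_count = min(counts[a] + counts[b] for a, b in tied)
    tied = [c for c in tied if counts[c[0]] + counts[c[1]] == min_count]
    return tied[rng.integers(len(tied))]


def build_rater_plan(
    rater: str,
    state: SchedulerState,
    sanity_pool: Sequence[SanityPair],
    seed: int | np.random.Generator,
    questions_per_dimension: int = QUESTIONS_PER_DIMENSION,
    temperature: float = DEFAULT_TEMPERATURE,
) -> RaterPlan:
    """Build one rater's full plan: 3 dimensions x 6 questions x 21 slots.

    The dimension order is randomized per rater.  Within a dimension the
    questions with the lowest cumulative match counts are scheduled (paper is
    silent on subset choice; balancing maximizes rating reliability).  Slot 11
    of every block is the block's sanity pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sanity = {(p.dimension, p.qid): p for p in sanity_pool}
    dims = list(Dimension)
    rng.shuffle(dims)
    plan: list[PlannedMatch] = []
    for dim in dims:
        eligible = [
            qid for qid, sids in state.solutions_by_question.items() if len(sids) >= 2
        ]
        if len(eligible) < questions_per_dimension:
            raise SchedulingError(
                f"need {questions_per_dimension} questions with >=2 valid solutions, "
                f"have {len(eligible)}"
            )
        load = {
            qid: sum(state.count(dim, sid) for sid in state.solutions_by_question[qid])
            for qid in eligible
        }
        chosen = sorted(eligible, key=lambda q: (load[q], q))[:questions_per_dimension]
        rng.shuffle(chosen)
        for qid in chosen:
            if (dim, qid) not in sanity:
                raise SchedulingError(f"no sanity pair for ({dim.value}, qid {qid})")
            sids = list(state.solutions_by_question[qid])
            ratings = {s: state.rating(dim, s) for s in sids}
            counts = {s: state.count(dim, s) for s in sids}
            used: set[frozenset[str]] = set()
            for slot in range(1, MATCHES_PER_BLOCK + 1):
                if slot == SANITY_SLOT:
                    p = sanity[(dim, qid)]
                    plan.append(PlannedMatch(dim, qid, slot, p.sid_high, p.sid_low, True))
                    continue
                if len(used) == len(sids) * (len(sids) - 1) // 2:
                    used.clear()  # tiny question: all pairs seen, allow a second pass
                a, b = select_pair(sids, ratings, counts, rng, temperature, exclude=used)
                used.add(frozenset((a, b)))
                counts[a] += 1
                counts[b] += 1
                if rng.integers(2):  # randomize presentation side
                    a, b = b, a
                plan.append(PlannedMatch(dim, qid, slot, a, b, False))
    return RaterPlan(rater=rater, matches=plan)


def qc_filter(
    judgments: Sequence[MatchRecord], sanity_pool: Sequence[SanityPair]
) -> list[MatchRecord]:
    """Set qc_passed per block: real matches pass iff the block's sanity
    judgment picked the designed winner; sanity matches never bear on ratings.

    Pure and idempotent: returns new records, input untouched.
    """
    sanity = {(p.dimension, p.qid): p for p in sanity_pool}
    blocks: dict[tuple[str, Dimension, int], list[MatchRecord]] = {}
    for m in judgments:
        blocks.setdefault((m.rater, m.dimension, m.qid), []).append(m)
    verdicts: dict[tuple[str, Dimension, int], bool] = {}
    for key, members in blocks.items():
        sanity_matches = [m for m in members if m.is_sanity]
        if not sanity_matches:
            raise QCError(f"block {key} has no sanity judgment")
        pair = sanity.get((key[1], key[2]))
        if pair is None:
            raise QCError(f"no sanity pair registered for block {key}")
        verdicts[key] = all(m.winner == pair.sid_high for m in sanity_matches)
    return [
        replace(
            m,
            qc_passed=False if m.is_sanity else verdicts[(m.rater, m.dimension, m.qid)],
        )
        for m in judgments
    ]
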