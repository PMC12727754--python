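"""Automated 1-100 rating of FIT solutions by an LLM judge.

The prompt protocol follows five principles: one dimension per prompt, batch
mode with at most 20 solutions of the same question per prompt, a 1-100
scale, "explain first, rate later" (three lines per solution with the numeric
rating last, as a JSON fragment), and a random shuffle of the solutions
before every input.  Each dimension is rated three times and the per-solution
scores are averaged.  Prompts are built from four building blocks -
introduction, dimension definition, FIT question, solutions - and sent in
English, with the question and solution fields left in their original
language.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Dimension, Question, Solution
from .errors import BatchingError, ParseError
from .judges import Judge, TranscriptWriter

__all__ = [
    "INTRODUCTION_BLOCK",
    "DIMENSION_BLOCKS",
    "JSON_KEYS",
    "RatingPrompt",
    "ParsedRatings",
    "AutomatedScoreTable",
    "build_rating_prompt",
    "parse_ratings",
    "rate_question",
    "MockRatingJudge",
]

MAX_BATCH = 20
SCORE_MIN, SCORE_MAX = 1.0, 100.0

INTRODUCTION_BLOCK = (
    "We aim to evaluate the creativity of solutions in the Fusion Innovation "
    "Test (FIT) based on specific criteria. In each question of FIT, people "
    "will be presented with 2 elements and 1 goal, and they are required to "
    "come up with creative solutions that combine the 2 provided elements to "
    "achieve the given goal. In a solution, the 2 given elements must be "
    "used, but they were allowed to add additional elements into their "
    "solutions whenever needed."
)

# The requested JSON fragment key per dimension.
JSON_KEYS: Mapping[Dimension, str] = {
    Dimension.COMBINATION_NOVELTY: "novelty",
    Dimension.COMBINATION_FEASIBILITY: "feasibility",
    Dimension.GOAL_ATTAINMENT: "goal attainment level",
}

DIMENSION_BLOCKS: Mapping[Dimension, str] = {
    Dimension.COMBINATION_NOVELTY: (
        "Please rate these solutions, given below, in terms of the Novelty of "
        "the combination of 2 elements in solutions, which is defined as follows:\n"
        "Rate the novelty of the combination of 2 elements in a solution on a "
        "scale of 1-100, with 1 being not novel at all and 100 being extremely "
        "novel. Consider how unique, original, or surprising the two given "
        "elements are combined in a solution, while disregarding the "
        "feasibility of the combination of 2 elements and goal attainment "
        "level in that solution. Make sure to give a rating to every solution, "
        "disregarding the quality of the sentence.\n"
        "Proceed as follows in your evaluation:\n"
        "Write 3 (three) lines for each solution in the list below. On the "
        "first line, write the solution number and briefly describe the "
        "solution in your own words. On the second line, consider other novel "
        "ways to combine the two elements, including those listed, and compare "
        "the solution to these in terms of its Novelty of the combination of 2 "
        "elements. Finally, on the third line, provide your numeric rating as "
        'a json object of the form {"novelty":x}. Evaluate each solution in '
        "the order provided, leaving one empty line between evaluations. Do "
        "evaluate each of the 20 solutions below individually and make sure to "
        "give a rating to every solution, even if there are repetitions."
    ),
    Dimension.COMBINATION_FEASIBILITY: (
        "Please rate these solutions, given below, in terms of the Feasibility "
        "of the combination of 2 elements in solutions, which is defined as follows:\n"
        "Rate the feasibility of the combination of 2 elements in a solution "
        "on a scale of 1-100, with 1 being not feasible at all and 100 being "
        "extremely feasible. Consider how practical or doable in real-life the "
        "way two elements are combined in the solution, while disregarding the "
        "novelty of the combination of 2 elements and goal attainment level in "
        "the solution. Make sure to give a rating to every solution, "
        "disregarding the quality of the sentence.\n"
        "Proceed as follows in your evaluation:\n"
        "Write 3 (three) lines for each solution in the list below. On the "
        "first line, write the solution number and briefly describe the "
        "solution in your own words. On the second line, consider other "
        "feasible ways to combine the two elements, including those listed, "
        "and compare the solution to these in terms of its Feasibility of the "
        "combination of 2 elements. Finally, on the third line, provide your "
        'numeric rating as a json object of the form {"feasibility":x}. '
        "Evaluate each solution in the order provided, leaving one empty line "
        "between evaluations. Do evaluate each of the 20 solutions below "
        "individually and make sure to give a rating to every solution, even "
        "if there are repetitions."
    ),
    Dimension.GOAL_ATTAINMENT: (
        "Please rate these solutions, given below, in terms of their Goal "
        "Attainment Level, which is defined as follows:\n"
        "Rate the goal attainment level of the solution on a scale of 1 to "
        "100, with 1 being not achieving the goal at all and 100 being "
        "achieving the goal with an extremely high level. Consider to what "
        "level the solution achieves the given goal, while disregarding the "
        "novelty and feasibility of the combination of 2 elements in the "
        "solution. Make sure to give a rating to every solution, disregarding "
        "the quality of the sentence.\n"
        "Proceed as follows in your evaluation:\n"
        "Write 3 (three) lines for each solution in the list below. On the "
        "first line, write the solution number and briefly describe the "
        "solution in your own words. On the second line, consider other "
        "solutions with a high level of goal attainment, including those "
        "listed, and compare the solution to these in terms of its Goal "
        "Attainment Level. Finally, on the third line, provide your numeric "
        'rating as a json object of the form {"goal attainment level":x}. '
        "Evaluate each solution in the order provided, leaving one empty line "
        "between evaluations. Do evaluate each of the 20 solutions below "
        "individually and make sure to give a rating to every solution, even "
        "if there are repetitions."
    ),
}


@dataclass(frozen=True)
class RatingPrompt:
    dimension: Dimension
    text: str
    sids: tuple[str, ...]  # presentation order


@dataclass
class ParsedRatings:
    scores: list[float | None]  # per presented solution; None = missing
    raw: str


@dataclass
class AutomatedScoreTable:
    """Mean 1-100 score per (dimension, sid) plus the per-repeat scores."""

    scores: pd.DataFrame  # columns dimension, qid, sid, score_mean, n_repeats
    per_repeat: dict[tuple[Dimension, str], list[float]] = field(default_factory=dict)
    unscored: list[tuple[Dimension, str]] = field(default_factory=list)


def build_rating_prompt(
    dimension: Dimension, question: Question, batch: Sequence[Solution]
) -> RatingPrompt:
    """Concatenate the four building blocks for one batch (<= 20 solutions)."""
    dimension = Dimension(dimension)
    if not 1 <= len(batch) <= MAX_BATCH:
        raise BatchingError(f"batch size {len(batch)} outside 1..{MAX_BATCH}")
    question_block = (
        "FIT question\n"
        "Elements:\n"
        f"(1) {question.element1}\n"
        f"(2) {question.element2}\n"
        f"Goal: {question.goal}"
    )
    solutions_block = "Solutions:\n" + "\n".join(
        f"({i}) {s.text}" for i, s in enumerate(batch, start=1)
    )
    text = "\n\n".join(
        [INTRODUCTION_BLOCK, DIMENSION_BLOCKS[dimension], question_block, solutions_block]
    )
    return RatingPrompt(dimension=dimension, text=text, sids=tuple(s.sid for s in batch))


def _fragment_pattern(dimension: Dimension) -> re.Pattern:
    key = re.escape(JSON_KEYS[Dimension(dimension)])
    # tolerate smart quotes and whitespace in the model's JSON fragment
    q = "[\"“”]"
    return re.compile(rf"\{{\s*{q}{key}{q}\s*:\s*(-?\d+(?:\.\d+)?)\s*\}}")


def parse_ratings(response: str, expected_n: int, dimension: Dimension) -> ParsedRatings:
    """Pull the dimension's JSON fragments out of a judge response, in order.

    Entries beyond ``expected_n`` are ignored; absent or out-of-range entries
    are marked missing.  A response with zero fragments is a parse error.
    """
    values = [float(v) for v in _fragment_pattern(dimension).findall(response)]
    if not values:
        raise ParseError(f"no {JSON_KEYS[Dimension(dimension)]!r} fragments in response")
    scores: list[float | None] = [
        v if SCORE_MIN <= v <= SCORE_MAX else None for v in values[:expected_n]
    ]
    scores += [None] * (expected_n - len(scores))
    return ParsedRatings(scores=scores, raw=response)


def rate_question(
    question: Question,
    solutions: Sequence[Solution],
    judge: Judge,
    dimensions: Sequence[Dimension] = tuple(Dimension),
    repeats: int = 3,
    batch_size: int = MAX_BATCH,
    rng: np.random.Generator | int = 0,
    max_requeries: int = 2,
    transcript: TranscriptWriter | None = None,
) -> AutomatedScoreTable:
    """Rate all solutions of one question on the given dimensions.

    Per repeat: independent shuffle, chunking into batches of at most
    ``batch_size``, one prompt per batch.  A batch whose response leaves some
    solution unscored is re-queried up to ``max_requeries`` times; after that
    the averages simply use the repeats that produced a score.
    """
    if not solutions:
        raise ValueError("need at least one valid solution")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    per_repeat: dict[tuple[Dimension, str], list[float]] = {
        (Dimension(d), s.sid): [] for d in dimensions for s in solutions
    }
    for dim in map(Dimension, dimensions):
        for repeat in range(repeats):
            order = list(rng.permutation(len(solutions)))
            shuffled = [solutions[i] for i in order]
            for b0 in range(0, len(shuffled), batch_size):
                batch = shuffled[b0 : b0 + batch_size]
                prompt = build_rating_prompt(dim, question, batch)
                scores: list[float | None] = [None] * len(batch)
                for attempt in range(1 + max_requeries):
                    response = judge(prompt.text)
                    try:
                        parsed = parse_ratings(response, len(batch), dim)
                    except ParseError:
                        parsed = ParsedRatings([None] * len(batch), response)
                    if transcript:
                        transcript.log(
                            dimension=dim.value, qid=question.qid, repeat=repeat,
                            batch_index=b0 // batch_size, attempt=attempt,
                            prompt=prompt.text, response=response, parsed=parsed.scores,
                        )
                    scores = [
                        old if old is not None else new
                        for old, new in zip(scores, parsed.scores)
                    ]
                    if all(v is not None for v in scores):
                        break
                for s, v in zip(batch, scores):
                    if v is not None:
                        per_repeat[(dim, s.sid)].append(v)
    rows, unscored = [], []
    for d in map(Dimension, dimensions):
        for s in solutions:
            vals = per_repeat[(d, s.sid)]
            if vals:
                rows.append(
                    {
                        "dimension": d.value,
                        "qid": question.qid,
                        "sid": s.sid,
                        "score_mean": float(np.mean(vals)),
                        "n_repeats": len(vals),
                    }
                )
            else:
                unscored.append((d, s.sid))
    frame = pd.DataFrame(rows, columns=["dimension", "qid", "sid", "score_mean", "n_repeats"])
    return AutomatedScoreTable(scores=frame, per_repeat=per_repeat, unscored=unscored)


class MockRatingJudge:
    """Deterministic order-blind judge for tests and simulation.

    Scores each presented solution by looking up its text in
    ``scores_by_text`` (per-dimension maps or a flat map) and emits a
    three-line evaluation with the proper JSON fragment, optionally with
    seeded Gaussian noise.
    """

    def __init__(
        self,
        scores_by_text: Mapping,
        noise_sd: float = 0.0,
        rng: np.random.Generator | int = 0,
    ):
        self.scores_by_text = scores_by_text
        self.noise_sd = noise_sd
        self.rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        self.n_calls = 0

    def _detect_dimension(self, prompt: str) -> Dimension:
        for dim, key in JSON_KEYS.items():
            if f'{{"{key}":x}}' in prompt:
                return dim
        raise ParseError("prompt requests no known rating key")

    def __call__(self, prompt: str) -> str:
        self.n_calls += 1
        dim = self._detect_dimension(prompt)
        table = self.scores_by_text.get(dim, self.scores_by_text)
        body = prompt.split("Solutions:\n", 1)[1]
        texts = [
            re.sub(r"^\(\d+\) ", "", line) for line in body.splitlines() if line.strip()
        ]
        lines = []
        for i, text in enumerate(texts, start=1):
            score = float(table[text]) + (
                self.rng.normal(0.0, self.noise_sd) if self.noise_sd else 0.0
            )
            score = int(round(min(SCORE_MAX, max(SCORE_MIN, score))))
            lines.append(
                f"({i}) Restating the solution.\nComparison with alternatives.\n"
                f'{{"{JSON_KEYS[dim]}":{score}}}\n'
            )
        return "\n".join(lines)
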