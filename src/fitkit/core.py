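"""Domain types, the bundled FIT question bank, set partitioning, balanced
session assignment, and tabular I/O.

The Fusion Innovation Test (FIT) asks participants to combine two everyday
elements (an object, a technology, a service, a data source) into a creative
solution that achieves a stated real-world goal.  Goals come in two
categories: Self Improvement Goals (SIG, personal needs and well-being) and
Sustainable Development Goals (SDG, environmental and societal challenges).
The bundled English bank holds 50 questions, 25 per category, divided into
5 sets of 5 SIG + 5 SDG questions each.
"""

from __future__ import annotations

import csv
import enum
import json
import random
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import IntegrityError, ParseError, PartitionError, SchemaError, ValidationError

__all__ = [
    "Category",
    "Dimension",
    "Validity",
    "Question",
    "QuestionBank",
    "FeedbackFlags",
    "Solution",
    "SessionAssignment",
    "load_question_bank",
    "partition_into_sets",
    "assign_sessions",
    "read_solutions",
    "write_solutions",
]


class Category(str, enum.Enum):
    """FIT goal category."""

    SIG = "SIG"
    SDG = "SDG"


class Dimension(str, enum.Enum):
    """The three per-solution FIT evaluation dimensions."""

    COMBINATION_NOVELTY = "combination_novelty"
    COMBINATION_FEASIBILITY = "combination_feasibility"
    GOAL_ATTAINMENT = "goal_attainment"


class Validity(str, enum.Enum):
    """Screening state of a solution; transitions only move forward from
    UNSCREENED."""

    UNSCREENED = "unscreened"
    FAILED_ELEMENT_CHECK = "failed_element_check"
    FAILED_FEEDBACK = "failed_feedback"
    VALID = "valid"


_BUNDLED_BANKS = {"en": "fit_questions_en.csv"}


@dataclass(frozen=True)
class Question:
    """One FIT item: two elements plus one goal."""

    qid: int
    element1: str
    element2: str
    goal: str
    category: Category
    set_id: int
    language: str = "en"

    def __post_init__(self) -> None:
        if self.element1 == self.element2:
            raise ValidationError(f"question {self.qid}: element1 equals element2")
        if not isinstance(self.category, Category):
            object.__setattr__(self, "category", Category(self.category))


@dataclass(frozen=True)
class QuestionBank:
    questions: tuple[Question, ...]
    language: str = "en"

    def __post_init__(self) -> None:
        qids = [q.qid for q in self.questions]
        if len(set(qids)) != len(qids):
            dupes = sorted({q for q in qids if qids.count(q) > 1})
            raise IntegrityError(f"duplicate qid(s): {dupes}")

    def __len__(self) -> int:
        return len(self.questions)

    def __iter__(self):
        return iter(self.questions)

    def get(self, qid: int) -> Question:
        for q in self.questions:
            if q.qid == qid:
                return q
        raise KeyError(qid)

    def filter(self, category: Category | str | None = None, set_id: int | None = None) -> "QuestionBank":
        qs = self.questions
        if category is not None:
            category = Category(category)
            qs = tuple(q for q in qs if q.category == category)
        if set_id is not None:
            qs = tuple(q for q in qs if q.set_id == set_id)
        return QuestionBank(qs, self.language)


@dataclass(frozen=True)
class FeedbackFlags:
    """Answers to the three after-question feedback items of a FIT trial:
    were both elements understood, was the goal understood, and was the last
    solution completed when time ran out."""

    elements_understood: bool
    goal_understood: bool
    last_solution_completed: bool


@dataclass(frozen=True)
class Solution:
    """A participant's free-text answer to one FIT question."""

    sid: str
    participant: str
    qid: int
    text: str
    order_index: int = 0
    feedback: FeedbackFlags = FeedbackFlags(True, True, True)
    validity: Validity = Validity.UNSCREENED

    def __post_init__(self) -> None:
        if self.order_index < 0:
            raise ValidationError(f"solution {self.sid}: negative order_index")

    def with_validity(self, validity: Validity) -> "Solution":
        """Forward-only validity transition."""
        if self.validity is not Validity.UNSCREENED and validity != self.validity:
            raise ValidationError(
                f"solution {self.sid}: cannot move from {self.validity.value} to {validity.value}"
            )
        return replace(self, validity=validity)


@dataclass(frozen=True)
class SessionAssignment:
    participant: str
    fit_set: int
    aut_set: int


_BANK_COLUMNS = ["qid", "set_id", "category", "element1", "element2", "goal", "language"]


def load_question_bank(source: str | Path = "en") -> QuestionBank:
    """Load a question bank from a bundled name ("en") or a CSV/JSON file.

    The bundled English bank is the package's transcription of the published
    50-question table.  ja/zh banks are not bundled; pass a file with the same
    columns (row-order qid correspondence with the English table is assumed).
    """
    if isinstance(source, str) and source in _BUNDLED_BANKS:
        ref = resources.files("fitkit.data").joinpath(_BUNDLED_BANKS[source])
        with ref.open("r", encoding="utf-8") as fh:
            return _bank_from_rows(csv.DictReader(fh), language=source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no bundled bank or file named {source!r}")
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        return _bank_from_rows(rows)
    with path.open("r", encoding="utf-8", newline="") as fh:
        return _bank_from_rows(csv.DictReader(fh))


def _bank_from_rows(rows: Iterable[dict], language: str | None = None) -> QuestionBank:
    questions = []
    for row in rows:
        missing = [c for c in _BANK_COLUMNS if c not in row or row[c] is None]
        if missing:
            raise SchemaError(f"question bank missing column(s): {missing}")
        questions.append(
            Question(
                qid=int(row["qid"]),
                element1=row["element1"],
                element2=row["element2"],
                goal=row["goal"],
                category=Category(row["category"]),
                set_id=int(row["set_id"]),
                language=row["language"],
            )
        )
    lang = language or (questions[0].language if questions else "en")
    return QuestionBank(tuple(questions), language=lang)


def partition_into_sets(bank: QuestionBank, n_sets: int) -> list[list[Question]]:
    """Split a bank into ``n_sets`` sets with equal SIG and SDG counts.

    Honors the bundled ``set_id`` when it already forms a valid partition;
    otherwise assigns deterministically round-robin by qid within category.
    """
    by_cat = {c: sorted((q for q in bank if q.category == c), key=lambda q: q.qid) for c in Category}
    for cat, qs in by_cat.items():
        if len(qs) % n_sets:
            raise PartitionError(
                f"{len(qs)} {cat.value} questions not divisible into {n_sets} sets"
            )
    existing = {q.set_id for q in bank}
    if existing == set(range(1, n_sets + 1)):
        sets = [[q for q in bank if q.set_id == s] for s in range(1, n_sets + 1)]
        per_cat = {len(by_cat[c]) // n_sets for c in Category}
        if all(
            sum(q.category == c for q in s) == len(by_cat[c]) // n_sets
            for s in sets
            for c in Category
        ):
            return sets
    sets = [[] for _ in range(n_sets)]
    for qs in by_cat.values():
        for i, q in enumerate(qs):
            sets[i % n_sets].append(q)
    return sets


def assign_sessions(
    n_participants: int, n_fit_sets: int = 5, n_aut_sets: int = 5, seed: int = 0
) -> list[SessionAssignment]:
    """Assign each participant a (FIT set, AUT set) combination such that the
    counts of every combination differ by at most one, in seeded shuffled order.
    """
    if min(n_participants, n_fit_sets, n_aut_sets) <= 0:
        raise ValidationError("all counts must be positive")
    rng = random.Random(seed)
    combos = [(f, a) for f in range(1, n_fit_sets + 1) for a in range(1, n_aut_sets + 1)]
    full, rem = divmod(n_participants, len(combos))
    pool = combos * full + rng.sample(combos, rem)
    rng.shuffle(pool)
    return [
        SessionAssignment(participant=f"P{i + 1:03d}", fit_set=f, aut_set=a)
        for i, (f, a) in enumerate(pool)
    ]


_SOLUTION_COLUMNS = [
    "sid",
    "participant",
    "qid",
    "order_index",
    "text",
    "elements_understood",
    "goal_understood",
    "last_solution_completed",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def read_solutions(path: str | Path) -> list[Solution]:
    """Read solutions from CSV (UTF-8, one row per solution; trial-level
    feedback flags repeated on every row of the trial)."""
    path = Path(path)
    solutions: list[Solution] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = [c for c in _SOLUTION_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing column(s): {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                if any(row[c] in (None, "") for c in _SOLUTION_COLUMNS if c != "text"):
                    raise ValueError("empty required field")
                solutions.append(
                    Solution(
                        sid=row["sid"],
                        participant=row["participant"],
                        qid=int(row["qid"]),
                        order_index=int(row["order_index"]),
                        text=row["text"],
                        feedback=FeedbackFlags(
                            _BOOL[row["elements_understood"].strip().lower()],
                            _BOOL[row["goal_understood"].strip().lower()],
                            _BOOL[row["last_solution_completed"].strip().lower()],
                        ),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(f"{path}, line {lineno}: malformed row ({exc})") from exc
    return solutions


def write_solutions(path: str | Path, solutions: Sequence[Solution]) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_SOLUTION_COLUMNS)
        for s in solutions:
            writer.writerow(
                [
                    s.sid,
                    s.participant,
                    s.qid,
                    s.order_index,
                    s.text,
                    str(s.feedback.elements_understood).lower(),
                    str(s.feedback.goal_understood).lower(),
                    str(s.feedback.last_solution_completed).lower(),
                ]
            )
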