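"""Validity screening of FIT solutions and completeness screening of AUT answers.

FIT screening is a two-step process.  Step 1 asks a binary judge whether both
question elements actually play a role in the solution; a solution advances
only on a unanimous run of "yes" votes (three by default).  Step 2 removes
every solution of any trial where the participant reported not understanding
the elements or the goal.  AUT answers go through a three-step completeness
screen: a terminal Japanese period marks an answer complete, a bare repetition
of the question item is incomplete, and everything else is referred to the
judge with a cut-off probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import Question, QuestionBank, Solution, Validity
from .errors import JudgeError, ValidationError
from .judges import Judge, TranscriptWriter, parse_verdict

__all__ = [
    "STEP1_TEMPLATE",
    "AUT_STEP3_TEMPLATE",
    "JudgeVote",
    "ScreeningReport",
    "AutScreeningReport",
    "build_step1_prompt",
    "check_element_usage",
    "apply_feedback_filter",
    "screen_fit",
    "screen_aut",
]

# Verbatim element-usage probe; placeholders are the solution text and the
# two question elements.
STEP1_TEMPLATE = (
    'In the scenario "{solution}", the two elements "{element1}" and '
    '"{element2}" both play a role: Yes/No'
)

AUT_STEP3_TEMPLATE = (
    'The string "{answer}" is a participant\'s answer to the question of '
    'alternative uses of the item "{item}". Input was cut off after a time '
    "limit. Does the answer, which may be extremely brief, appear to have "
    "been cut off? Yes/No"
)

JAPANESE_PERIOD = "。"  # 「。」


@dataclass(frozen=True)
class JudgeVote:
    verdict: str  # "yes" | "no"
    raw_response: str
    attempt_index: int  # 1-based


@dataclass
class ScreeningReport:
    """Outcome of the two-step FIT screen; dispositions partition the input."""

    n_input: int
    n_pass_step1: int
    n_valid: int
    dispositions: dict[str, Validity]
    solutions: list[Solution]

    def valid_solutions(self) -> list[Solution]:
        return [s for s in self.solutions if s.validity is Validity.VALID]


@dataclass
class AutScreeningReport:
    complete: list[tuple[str, str]] = field(default_factory=list)
    incomplete: list[tuple[str, str]] = field(default_factory=list)
    undecided: list[tuple[str, str]] = field(default_factory=list)


def build_step1_prompt(solution: Solution, question: Question) -> str:
    return STEP1_TEMPLATE.format(
        solution=solution.text, element1=question.element1, element2=question.element2
    )


def _vote(prompt: str, judge: Judge, attempt: int, transcript: TranscriptWriter | None, sid: str) -> JudgeVote:
    """One vote with a single retry on an unparseable response."""
    for retry in range(2):
        response = judge(prompt)
        verdict = parse_verdict(response)
        if transcript:
            transcript.log(sid=sid, attempt=attempt, retry=retry, prompt=prompt,
                           response=response, verdict=verdict)
        if verdict is not None:
            return JudgeVote(verdict=verdict, raw_response=response, attempt_index=attempt)
    raise JudgeError(f"no parseable yes/no verdict for solution {sid}")


def check_element_usage(
    solution: Solution,
    question: Question,
    judge: Judge,
    votes: int = 3,
    transcript: TranscriptWriter | None = None,
) -> bool:
    """True iff all ``votes`` independent judge queries answer yes."""
    if votes < 1:
        raise ValidationError("votes must be >= 1")
    prompt = build_step1_prompt(solution, question)
    return all(
        _vote(prompt, judge, attempt, transcript, solution.sid).verdict == "yes"
        for attempt in range(1, votes + 1)
    )


def apply_feedback_filter(
    solutions: Sequence[Solution], drop_incomplete_last: bool = False
) -> list[Solution]:
    """Remove every solution of any trial whose elements or goal were unclear.

    With ``drop_incomplete_last`` (off by default), additionally drop the last
    solution (highest order_index) of a trial whose final solution was cut off
    by the time limit.
    """
    kept: list[Solution] = []
    trials: dict[tuple[str, int], list[Solution]] = {}
    for s in solutions:
        if s.feedback is None:
            raise ValidationError(f"solution {s.sid}: missing feedback flags")
        trials.setdefault((s.participant, s.qid), []).append(s)
    for members in trials.values():
        # flags are trial-level and repeated per row; AND across rows keeps
        # the result well-defined (and order-independent) even on
        # inconsistent input
        elements_ok = all(m.feedback.elements_understood for m in members)
        goal_ok = all(m.feedback.goal_understood for m in members)
        completed = all(m.feedback.last_solution_completed for m in members)
        if not (elements_ok and goal_ok):
            continue
        members = sorted(members, key=lambda s: s.order_index)
        if drop_incomplete_last and not completed and members:
            members = members[:-1]
        kept.extend(members)
    order = {s.sid: i for i, s in enumerate(solutions)}
    return sorted(kept, key=lambda s: order[s.sid])


def screen_fit(
    solutions: Sequence[Solution],
    bank: QuestionBank,
    judge: Judge,
    votes: int = 3,
    drop_incomplete_last: bool = False,
    transcript: TranscriptWriter | None = None,
) -> ScreeningReport:
    """Run the full two-step screen and return updated solutions + report.

    Judge failures leave a solution UNSCREENED (not failed); such solutions do
    not advance.  The result is independent of input row order: all per-trial
    logic is keyed by (participant, qid), never by position.
    """
    step1_pass: list[Solution] = []
    dispositions: dict[str, Validity] = {}
    out: list[Solution] = []
    for s in solutions:
        question = bank.get(s.qid)
        try:
            ok = check_element_usage(s, question, judge, votes=votes, transcript=transcript)
        except JudgeError:
            dispositions[s.sid] = Validity.UNSCREENED
            out.append(s)
            continue
        if ok:
            step1_pass.append(s)
        else:
            s = s.with_validity(Validity.FAILED_ELEMENT_CHECK)
            dispositions[s.sid] = s.validity
            out.append(s)
    surviving = {s.sid for s in apply_feedback_filter(step1_pass, drop_incomplete_last)}
    for s in step1_pass:
        s = s.with_validity(Validity.VALID if s.sid in surviving else Validity.FAILED_FEEDBACK)
        dispositions[s.sid] = s.validity
        out.append(s)
    order = {s.sid: i for i, s in enumerate(solutions)}
    out.sort(key=lambda s: order[s.sid])
    return ScreeningReport(
        n_input=len(out),
        n_pass_step1=len(step1_pass),
        n_valid=sum(1 for v in dispositions.values() if v is Validity.VALID),
        dispositions=dispositions,
        solutions=out,
    )


def screen_aut(
    answers: Sequence[tuple[str, str]],
    judge: Judge,
    transcript: TranscriptWriter | None = None,
) -> AutScreeningReport:
    """Three-step AUT completeness screen over (item, answer) pairs."""
    report = AutScreeningReport()
    for item, text in answers:
        if text.rstrip().endswith(JAPANESE_PERIOD):
            report.complete.append((item, text))
            continue
        if text.strip() == item.strip():
            report.incomplete.append((item, text))
            continue
        prompt = AUT_STEP3_TEMPLATE.format(answer=text, item=item)
        try:
            vote = _vote(prompt, judge, attempt=1, transcript=transcript, sid=text[:40])
        except JudgeError:
            report.undecided.append((item, text))
            continue
        # judge answers the *cut-off* question: "No" means not cut off.
        (report.complete if vote.verdict == "no" else report.incomplete).append((item, text))
    return report
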