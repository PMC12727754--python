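"""Individual performance quantification and questionnaire aggregation.

A participant's FIT performance is four scalars: Fluency (mean number of
solutions per question) and, per rating dimension, the mean across questions
of the highest solution score within each question ("best-of" scoring, which
mirrors picking the best idea from a brainstorming round).  AUT performance
is three analogous scalars.  CAQ and K-DOCS self-report questionnaires are
collapsed into science and art domain scores following the instruments'
published factor structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Dimension, Solution, Validity
from .errors import DegenerateDataError, ValidationError

__all__ = [
    "CAQ_SCIENCE_SUBSCALES",
    "CAQ_ART_SUBSCALES",
    "CAQ_EXCLUDED_SUBSCALES",
    "KDOCS_SCIENCE_SUBSCALES",
    "KDOCS_ART_SUBSCALES",
    "ParticipantScorecard",
    "fluency",
    "best_of_question_score",
    "caq_domains",
    "kdocs_domains",
    "scorecard_correlations",
]

# CAQ: 10 achievement domains; architectural design is excluded from the
# science/art aggregation (low factor loading, floor effects in young samples).
CAQ_SCIENCE_SUBSCALES = ("culinary arts", "inventions", "scientific inquiry")
CAQ_ART_SUBSCALES = (
    "visual arts",
    "music",
    "dance",
    "creative writing",
    "humor",
    "theater and film",
)
CAQ_EXCLUDED_SUBSCALES = ("architectural design",)

# K-DOCS: 5 self-perceived creativity domains on a 1-5 scale.
KDOCS_SCIENCE_SUBSCALES = ("self/everyday", "scholarly", "mechanics/scientific")
KDOCS_ART_SUBSCALES = ("performance", "artistic")


@dataclass
class ParticipantScorecard:
    participant: str
    fit: dict[str, float] = field(default_factory=dict)
    aut: dict[str, float] = field(default_factory=dict)
    caq: dict[str, float] = field(default_factory=dict)
    kdocs: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"participant": self.participant}
        for prefix, scores in (
            ("fit", self.fit),
            ("aut", self.aut),
            ("caq", self.caq),
            ("kdocs", self.kdocs),
        ):
            for key, val in scores.items():
                row[f"{prefix}_{key}"] = val
        return row


def fluency(
    solutions: Sequence[Solution],
    question_ids: Sequence[int],
    valid_only: bool = False,
) -> float:
    """Mean number of solutions per question over ``question_ids``.

    Counts all submitted solutions by default; ``valid_only`` restricts to
    screened-valid ones.  A question with no solutions contributes 0.
    """
    if not question_ids:
        raise DegenerateDataError("fluency undefined over zero questions")
    counts = {qid: 0 for qid in question_ids}
    for s in solutions:
        if s.qid in counts and (not valid_only or s.validity is Validity.VALID):
            counts[s.qid] += 1
    return float(np.mean(list(counts.values())))


def best_of_question_score(
    score_table: pd.DataFrame,
    solutions: Sequence[Solution],
    participant: str,
    dimension: Dimension,
) -> float:
    """Mean across questions of the participant's best solution score.

    Questions where none of the participant's solutions were scored are
    excluded from the mean (a maximum over an empty set is undefined).
    """
    if hasattr(score_table, "scores"):
        score_table = score_table.scores
    dimension = Dimension(dimension)
    own = {s.sid: s.qid for s in solutions if s.participant == participant}
    sub = score_table[
        (score_table["dimension"] == dimension.value) & score_table["sid"].isin(own)
    ]
    if sub.empty:
        raise DegenerateDataError(
            f"participant {participant} has no scored solutions on {dimension.value}"
        )
    maxima = sub.groupby("qid")["score_mean"].max()
    return float(maxima.mean())


def _domains(
    response: Mapping[str, float],
    science: Sequence[str],
    art: Sequence[str],
    instrument: str,
) -> dict[str, float]:
    missing = [k for k in (*science, *art) if k not in response]
    if missing:
        raise ValidationError(f"{instrument} response missing subscale(s): {missing}")
    return {
        "science": float(sum(response[k] for k in science)),
        "art": float(sum(response[k] for k in art)),
    }


def caq_domains(response: Mapping[str, float]) -> dict[str, float]:
    """CAQ-Science / CAQ-Art domain sums (architectural design excluded)."""
    return _domains(response, CAQ_SCIENCE_SUBSCALES, CAQ_ART_SUBSCALES, "CAQ")


def kdocs_domains(response: Mapping[str, float]) -> dict[str, float]:
    """K-DOCS-Science / K-DOCS-Art domain sums."""
    return _domains(response, KDOCS_SCIENCE_SUBSCALES, KDOCS_ART_SUBSCALES, "K-DOCS")


def scorecard_correlations(
    scorecards: Sequence[ParticipantScorecard] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation matrix (rho, p) over scorecard fields.

    Constant columns yield NaN entries, which are left in place as the flag.
    """
    from scipy import stats as sps

    if not isinstance(scorecards, pd.DataFrame):
        scorecards = pd.DataFrame([s.as_row() for s in scorecards])
    if len(scorecards) < 10:
        raise ValidationError("need at least 10 scorecards")
    numeric = scorecards.drop(columns=["participant"], errors="ignore")
    cols = list(numeric.columns)
    n = len(cols)
    rho = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((n, n)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, n):
            b = cols[j]
            x, y = numeric[a].to_numpy(float), numeric[b].to_numpy(float)
            if np.var(x) == 0 or np.var(y) == 0:
                r = p = np.nan
            else:
                r, p = sps.spearmanr(x, y)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval
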