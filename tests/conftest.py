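import numpy as np
import pytest

from fitkit.core import FeedbackFlags, Solution, load_question_bank


@pytest.fixture(scope="session")
def bank():
    return load_question_bank("en")


def make_solution(sid, qid=1, participant="P001", text=None, order_index=0,
                  elements=True, goal=True, completed=True):
    return Solution(
        sid=sid,
        participant=participant,
        qid=qid,
        text=text or f"Solution {sid} combining both elements of question {qid}.",
        order_index=order_index,
        feedback=FeedbackFlags(elements, goal, completed),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
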