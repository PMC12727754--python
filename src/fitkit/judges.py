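"""Pluggable text-in/text-out judges and JSONL transcript logging.

A judge is any callable ``(prompt: str) -> str``.  Screening and rating code
never talks to a network directly; deterministic mocks implement the same
contract for tests and simulation, and a live adapter can wrap any LLM API.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Callable, Iterable

Judge = Callable[[str], str]

_LEAD_TOKEN = re.compile(r"[a-z]+")


def parse_verdict(response: str) -> str | None:
    """Extract a leading yes/no token, case-insensitive, ignoring punctuation.

    Returns "yes", "no", or None when the response starts with anything else.
    """
    m = _LEAD_TOKEN.search(response.strip().lower())
    if m and m.start() <= 2 and m.group() in ("yes", "no"):
        return m.group()
    return None


class ConstantJudge:
    """Always answers with the same text."""

    def __init__(self, response: str):
        self.response = response

    def __call__(self, prompt: str) -> str:
        return self.response


class SequenceJudge:
    """Replays a fixed sequence of responses, then raises."""

    def __init__(self, responses: Iterable[str]):
        self._responses = list(responses)
        self.calls: list[str] = []

    def __call__(self, prompt: str) -> str:
        self.calls.append(prompt)
        if not self._responses:
            raise RuntimeError("SequenceJudge exhausted")
        return self._responses.pop(0)


class LiveJudge:
    """Adapter for an OpenAI-compatible chat API (optional dependency).

    Instantiating requires the ``openai`` package; nothing in the library or
    tests needs it.
    """

    def __init__(self, model: str = "gpt-4o", **client_kwargs):
        try:
            import openai  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "LiveJudge requires the optional 'openai' package; "
                "install it or use a mock judge"
            ) from exc
        from openai import OpenAI  # pragma: no cover

        self._client = OpenAI(**client_kwargs)  # pragma: no cover
        self.model = model  # pragma: no cover

    def __call__(self, prompt: str) -> str:  # pragma: no cover - network path
        resp = self._client.chat.completions.create(
            model=self.model, messages=[{"role": "user", "content": prompt}]
        )
        return resp.choices[0].message.content or ""


class TranscriptWriter:
    """Appends one JSON record per judge call to a JSONL file (audit trail)."""

    def __init__(self, path: str | Path | None):
        self._fh = Path(path).open("a", encoding="utf-8") if path else None
        self.records: list[dict] = []

    def log(self, **record) -> None:
        self.records.append(record)
        if self._fh:
            self._fh.write(json.dumps(record, ensure_ascii=False) + "\n")
            self._fh.flush()

    def close(self) -> None:
        if self._fh:
            self._fh.close()
            self._fh = None

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
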