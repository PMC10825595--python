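"""Interactive session layer: question rendering, answer parsing, belief
statement and transcript.

The engine never sees free text: this layer parses raw answers into strict
yes/no, re-prompts on anything it cannot parse (up to a budget), and supports
the meta-command "why", which prints the justification for the pending
question without consuming the budget or recording a fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

from .inference import (
    Diagnosis,
    Session,
    SessionError,
    explain_why,
)
from .kb_model import KnowledgeBase

INVALID = "invalid"


def parse_answer(raw: str) -> str:
    """Parse free text to 'yes' / 'no' / 'invalid' (case-insensitive,
    whitespace-trimmed; accepts y/yes/n/no)."""
    t = raw.strip().lower()
    if t in ("y", "yes"):
        return "yes"
    if t in ("n", "no"):
        return "no"
    return INVALID


@dataclass(frozen=True)
class Turn:
    question_text: str
    raw_answer: str
    parsed_value: str


@dataclass
class Transcript:
    turns: list[Turn] = field(default_factory=list)
    final_statement: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "turns": [
                    {"question": t.question_text, "raw": t.raw_answer, "parsed": t.parsed_value}
                    for t in self.turns
                ],
                "final_statement": self.final_statement,
            },
            indent=2,
        )

    def pretty(self) -> str:
        lines = [f"Q: {t.question_text}\nA: {t.raw_answer} ({t.parsed_value})" for t in self.turns]
        lines.append(self.final_statement)
        return "\n".join(lines)


class SessionAborted(Exception):
    """Re-prompt budget exhausted; carries the partial transcript."""

    def __init__(self, message: str, transcript: Transcript):
        super().__init__(message)
        self.transcript = transcript


class Channel(Protocol):
    """I/O channel: asked a question, returns the raw user reply."""

    def ask(self, prompt: str, symptom_id: str) -> str: ...

    def tell(self, text: str) -> None: ...


class ScriptedChannel:
    """Replays a fixed sequence of raw answers; collects output."""

    def __init__(self, answers: Sequence[str]):
        self._answers = list(answers)
        self._i = 0
        self.output: list[str] = []

    def ask(self, prompt: str, symptom_id: str) -> str:
        if self._i >= len(self._answers):
            raise IndexError(f"scripted channel exhausted at question {prompt!r}")
        raw = self._answers[self._i]
        self._i += 1
        return raw

    def tell(self, text: str) -> None:
        self.output.append(text)


class MappingChannel:
    """Answers by symptom id from a mapping; unknown symptoms get `default`."""

    def __init__(self, answers: Mapping[str, str], default: str = "no"):
        self._answers = dict(answers)
        self._default = default
        self.output: list[str] = []

    def ask(self, prompt: str, symptom_id: str) -> str:
        return self._answers.get(symptom_id, self._default)

    def tell(self, text: str) -> None:
        self.output.append(text)


class TerminalChannel:
    """Plain stdin/stdout channel for interactive use."""

    def ask(self, prompt: str, symptom_id: str) -> str:
        return input(f"{prompt} [yes/no/why] ")

    def tell(self, text: str) -> None:
        print(text)


class _Abort(Exception):
    pass


def run_session(
    kb: KnowledgeBase,
    channel: Channel,
    max_reprompts: int = 3,
    stop_at_first: bool = False,
    exhaustive: bool = False,
) -> tuple[Diagnosis, Transcript]:
    """Drive a full consultation over a channel.

    Each invalid answer re-prompts up to `max_reprompts` times, after which
    the session aborts cleanly with the partial transcript. The transcript's
    turn count equals the engine's question count.
    """
    session = Session(kb, stop_at_first=stop_at_first, exhaustive=exhaustive)
    transcript = Transcript()

    def provider(symptom_id: str) -> str:
        prompt = kb.symptom(symptom_id).question_text
        reprompts = 0
        while True:
            raw = channel.ask(prompt, symptom_id)
            if raw.strip().lower() == "why":
                channel.tell(explain_why(session))
                continue
            value = parse_answer(raw)
            if value != INVALID:
                transcript.turns.append(Turn(prompt, raw, value))
                return value
            reprompts += 1
            if reprompts > max_reprompts:
                raise _Abort(f"no valid answer to {prompt!r} after {max_reprompts} re-prompts")
            channel.tell("Please answer 'yes' or 'no'.")

    try:
        diagnosis = session.run(provider)
    except SessionError as e:
        cause = e.__cause__
        if isinstance(cause, _Abort):
            raise SessionAborted(str(cause), transcript) from None
        raise
    transcript.final_statement = render_belief_statement(diagnosis, kb)
    channel.tell(transcript.final_statement)
    return diagnosis, transcript


def render_belief_statement(d: Diagnosis, kb: KnowledgeBase) -> str:
    """Deterministic belief statement naming every confirmed disorder, its
    taxonomy path, and the primary disorder's treatments.

    When nothing is confirmed, reports the failure and — as a clearly
    labeled extension beyond the all-or-nothing rule — ranks the nearest
    hypotheses by confirmed-symptom fraction.
    """
    lines: list[str] = []
    if d.confirmed:
        primary = kb.disorder(d.primary)
        lines.append(
            f'The plant has been classified as having "{primary.name}" '
            f"({primary.category} > {primary.subcategory})."
        )
        for did in d.confirmed[1:]:
            other = kb.disorder(did)
            lines.append(
                f'Also confirmed: "{other.name}" ({other.category} > {other.subcategory}).'
            )
        if d.treatments:
            lines.append("Recommended treatment for the primary disorder:")
            for tid in d.treatments:
                t = kb.treatment(tid)
                ing = f" Ingredients: {', '.join(t.ingredients)}." if t.ingredients else ""
                lines.append(f"  - {t.description}{ing}")
        else:
            lines.append("No treatment is recorded for the primary disorder.")
    else:
        lines.append("No disorder could be identified from the reported symptoms.")
        ranked = sorted(
            d.belief_state.items(),
            key=lambda kv: -kv[1]["confirmed_fraction"],
        )
        near = [(did, st) for did, st in ranked if st["confirmed_fraction"] > 0][:3]
        if near:
            lines.append("Nearest hypotheses by confirmed-symptom fraction (informational ranking;")
            lines.append("a disorder is only ever concluded when all its symptoms are present):")
            for did, st in near:
                disorder = kb.disorder(did)
                lines.append(f"  - {disorder.name}: {st['confirmed_fraction']:.2f}")
    return "\n".join(lines)
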