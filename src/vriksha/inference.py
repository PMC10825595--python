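"""Backward-chaining inference engine with belief tracking and explanation.

Diagnosis is goal-driven: each disorder is taken up as a hypothesis in
taxonomy order (internal doshas first), and the engine works backwards from
the goal to the symptom facts its rule needs, asking the answer provider only
for symptoms not already in working memory. Conclusions are strictly
conjunctive — a disorder is confirmed only when every symptom in its rule
body is answered yes; a single no rejects the hypothesis (by default without
asking its remaining questions). A graded belief, the confirmed-symptom
fraction, is tracked per disorder but never licenses a partial-match
conclusion.

Every step (goal selection, question, fact, belief update, conclusion) is
appended to an ordered trace, which backs the why/how explanation facility
and serializes to JSON lines for replay and audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

from .kb_model import KnowledgeBase, compile_rules, hypothesis_order

YES = "yes"
NO = "no"

AnswerProvider = Callable[[str], str]
"""Maps a symptom id to "yes" or "no"."""


class ContractError(Exception):
    """A caller violated an operation's precondition."""


class UnknownDisorderError(KeyError):
    pass


class StateError(Exception):
    """The session is not in a state that supports the requested operation."""


class SessionError(Exception):
    """The answer provider failed mid-session; carries the partial trace."""

    def __init__(self, message: str, partial_trace: list["TraceEntry"]):
        super().__init__(message)
        self.partial_trace = partial_trace


@dataclass(frozen=True)
class Fact:
    """A memoized yes/no answer about one symptom."""

    symptom_id: str
    value: str  # YES or NO
    provenance: str = "user_answer"  # or "scripted"

    def __post_init__(self) -> None:
        if self.value not in (YES, NO):
            raise ContractError(f"fact value must be 'yes' or 'no', got {self.value!r}")


@dataclass
class WorkingMemory:
    """Session-wide fact store: at most one Fact per symptom, reused across
    hypotheses so no question is ever asked twice."""

    facts: dict[str, Fact] = field(default_factory=dict)
    question_log: list[str] = field(default_factory=list)

    def has(self, symptom_id: str) -> bool:
        return symptom_id in self.facts

    def value(self, symptom_id: str) -> str:
        return self.facts[symptom_id].value

    def record(self, fact: Fact, asked: bool = True) -> None:
        if fact.symptom_id in self.facts:
            raise ContractError(f"symptom {fact.symptom_id!r} already has a fact (memoization)")
        self.facts[fact.symptom_id] = fact
        if asked:
            self.question_log.append(fact.symptom_id)


class BeliefState:
    """Per-disorder status and confirmed-symptom fraction.

    status is derived from the facts: rejected iff some symptom of the
    disorder carries a no-fact; confirmed iff every symptom carries a
    yes-fact (fraction 1); open otherwise. The fraction is the number of
    yes-facts among the disorder's symptoms divided by its symptom count.
    """

    def __init__(self, kb: KnowledgeBase):
        self._bodies: dict[str, tuple[str, ...]] = {d.id: tuple(d.symptom_ids) for d in kb.disorders}
        self._yes: dict[str, set[str]] = {d: set() for d in self._bodies}
        self._no: dict[str, set[str]] = {d: set() for d in self._bodies}

    def disorders(self) -> list[str]:
        return list(self._bodies)

    def body(self, disorder_id: str) -> tuple[str, ...]:
        try:
            return self._bodies[disorder_id]
        except KeyError:
            raise UnknownDisorderError(disorder_id) from None

    def confirmed_fraction(self, disorder_id: str) -> float:
        body = self.body(disorder_id)
        return len(self._yes[disorder_id]) / len(body) if body else 0.0

    def status(self, disorder_id: str) -> str:
        body = self.body(disorder_id)
        if self._no[disorder_id]:
            return "rejected"
        if body and len(self._yes[disorder_id]) == len(body):
            return "confirmed"
        return "open"

    def snapshot(self) -> dict[str, dict]:
        return {
            d: {"status": self.status(d), "confirmed_fraction": self.confirmed_fraction(d)}
            for d in self._bodies
        }


def update_belief(bs: BeliefState, disorder_id: str, fact: Fact) -> BeliefState:
    """Fold one fact into the belief about one disorder (in place).

    The fact must concern a symptom of that disorder; adding a yes-fact never
    decreases the confirmed fraction.
    """
    body = bs.body(disorder_id)
    if fact.symptom_id not in body:
        raise ContractError(
            f"fact about {fact.symptom_id!r} does not concern disorder {disorder_id!r}"
        )
    if fact.value == YES:
        bs._yes[disorder_id].add(fact.symptom_id)
    else:
        bs._no[disorder_id].add(fact.symptom_id)
    return bs


@dataclass(frozen=True)
class TraceEntry:
    ordinal: int
    kind: str  # goal_selected | question_asked | fact_recorded | belief_updated | hypothesis_concluded
    payload: dict

    def to_json(self) -> str:
        return json.dumps(
            {"ordinal": self.ordinal, "kind": self.kind, "payload": self.payload}, sort_keys=True
        )


def trace_to_jsonl(trace: Iterable[TraceEntry]) -> str:
    """One TraceEntry per line, for replay and audit."""
    return "\n".join(e.to_json() for e in trace)


def trace_from_jsonl(text: str) -> list[TraceEntry]:
    entries = []
    for line in text.splitlines():
        if line.strip():
            obj = json.loads(line)
            entries.append(TraceEntry(obj["ordinal"], obj["kind"], obj["payload"]))
    return entries


@dataclass
class Diagnosis:
    """Outcome of a session: confirmed disorders (hypothesis order), the
    primary one, final beliefs, the full trace, and the primary's treatments."""

    confirmed: list[str]
    primary: str | None
    belief_state: dict[str, dict]
    trace: list[TraceEntry]
    treatments: list[str]
    questions_asked: int

    def trace_jsonl(self) -> str:
        return trace_to_jsonl(self.trace)

    def to_dict(self) -> dict:
        return {
            "confirmed": self.confirmed,
            "primary": self.primary,
            "belief_state": self.belief_state,
            "treatments": self.treatments,
            "questions_asked": self.questions_asked,
            "trace": [{"ordinal": e.ordinal, "kind": e.kind, "payload": e.payload} for e in self.trace],
        }


class Session:
    """One diagnostic consultation over a KB.

    Exposes the live state (current goal, pending question, working memory,
    beliefs, trace) needed by the why-explanation and the dialogue layer.
    """

    def __init__(self, kb: KnowledgeBase, stop_at_first: bool = False, exhaustive: bool = False):
        self.kb = kb
        self.stop_at_first = stop_at_first
        self.exhaustive = exhaustive
        self.rules = {r.disorder_id: r for r in compile_rules(kb)}
        self.order = hypothesis_order(kb)
        self.wm = WorkingMemory()
        self.beliefs = BeliefState(kb)
        self.trace: list[TraceEntry] = []
        self.current_goal: str | None = None
        self.pending_symptom: str | None = None
        self._by_symptom: dict[str, list[str]] = {}
        for d in kb.disorders:
            for sid in d.symptom_ids:
                self._by_symptom.setdefault(sid, []).append(d.id)

    def _log(self, kind: str, **payload) -> None:
        self.trace.append(TraceEntry(len(self.trace), kind, payload))

    def _acquire(self, symptom_id: str, answers: AnswerProvider) -> str:
        """Fetch a fact from working memory or the provider, memoizing it and
        updating beliefs of every disorder whose rule mentions the symptom."""
        if self.wm.has(symptom_id):
            return self.wm.value(symptom_id)
        self.pending_symptom = symptom_id
        self._log("question_asked", symptom_id=symptom_id, goal=self.current_goal)
        try:
            value = answers(symptom_id)
        except Exception as e:
            self.pending_symptom = None
            raise SessionError(f"answer provider failed on {symptom_id!r}: {e}", list(self.trace)) from e
        self.pending_symptom = None
        if value not in (YES, NO):
            raise SessionError(
                f"answer provider returned {value!r} for {symptom_id!r} (expected 'yes'/'no')",
                list(self.trace),
            )
        fact = Fact(symptom_id, value)
        self.wm.record(fact)
        self._log("fact_recorded", symptom_id=symptom_id, value=value)
        for did in self._by_symptom.get(symptom_id, []):
            update_belief(self.beliefs, did, fact)
        self._log(
            "belief_updated",
            disorder_id=self.current_goal,
            status=self.beliefs.status(self.current_goal) if self.current_goal else None,
            confirmed_fraction=(
                self.beliefs.confirmed_fraction(self.current_goal) if self.current_goal else None
            ),
        )
        return value

    def evaluate_hypothesis(self, disorder_id: str, answers: AnswerProvider) -> str:
        """Backward-chain on one goal: ask its symptoms in rule order, reusing
        memoized facts; reject at the first no (unless exhaustive), confirm
        iff all are yes. Returns "confirmed" or "rejected"."""
        if disorder_id not in self.rules:
            raise UnknownDisorderError(disorder_id)
        prev_goal = self.current_goal
        self.current_goal = disorder_id
        self._log("goal_selected", disorder_id=disorder_id)
        rejected = False
        deciding: str | None = None
        for sid in self.rules[disorder_id].body:
            value = self._acquire(sid, answers)
            if value == NO:
                rejected = True
                if deciding is None:
                    deciding = sid
                if not self.exhaustive:
                    break
        status = "rejected" if rejected else "confirmed"
        self._log("hypothesis_concluded", disorder_id=disorder_id, status=status, deciding_symptom=deciding)
        self.current_goal = prev_goal
        return status

    def run(self, answers: AnswerProvider) -> Diagnosis:
        """Iterate hypotheses in taxonomy order and assemble the Diagnosis."""
        confirmed: list[str] = []
        for did in self.order:
            status = self.evaluate_hypothesis(did, answers)
            if status == "confirmed":
                confirmed.append(did)
                if self.stop_at_first:
                    break
        primary = confirmed[0] if confirmed else None
        treatments = list(self.kb.disorder(primary).treatment_ids) if primary else []
        return Diagnosis(
            confirmed=confirmed,
            primary=primary,
            belief_state=self.beliefs.snapshot(),
            trace=list(self.trace),
            treatments=treatments,
            questions_asked=len(self.wm.question_log),
        )


def diagnose(
    kb: KnowledgeBase,
    answers: AnswerProvider,
    stop_at_first: bool = False,
    exhaustive: bool = False,
) -> Diagnosis:
    """Run a full consultation. Deterministic: identical KB and answer
    function yield an identical Diagnosis (byte-for-byte trace)."""
    return Session(kb, stop_at_first=stop_at_first, exhaustive=exhaustive).run(answers)


def evaluate_hypothesis(
    kb: KnowledgeBase,
    disorder_id: str,
    wm: WorkingMemory,
    answers: AnswerProvider,
    exhaustive: bool = False,
) -> str:
    """Standalone single-goal evaluation sharing the caller's working memory."""
    session = Session(kb, exhaustive=exhaustive)
    session.wm = wm
    for fact in wm.facts.values():
        for did in session._by_symptom.get(fact.symptom_id, []):
            update_belief(session.beliefs, did, fact)
    return session.evaluate_hypothesis(disorder_id, answers)


def explain_why(session: Session) -> str:
    """Justify the pending question: the current goal and the remaining
    unconfirmed symptoms of its rule."""
    if session.pending_symptom is None or session.current_goal is None:
        raise StateError("no question is pending; why-explanation unavailable")
    goal = session.kb.disorder(session.current_goal)
    body = session.rules[session.current_goal].body
    untested = [s for s in body if not session.wm.has(s)]
    untested_labels = ", ".join(session.kb.symptom(s).label or s for s in untested)
    asked = session.kb.symptom(session.pending_symptom)
    return (
        f"Testing the hypothesis that the plant has {goal.name!r} "
        f"({goal.category}/{goal.subcategory}). Its rule requires every listed symptom; "
        f"still untested: {untested_labels}. "
        f"The current question checks {asked.label or asked.id!r}."
    )


def render_trace(trace: Iterable[TraceEntry], kb: KnowledgeBase | None = None) -> str:
    """Human-readable linearized trace: each hypothesis with the facts that
    decided it."""

    def name(did: str | None) -> str:
        if did is None:
            return "?"
        if kb is not None:
            try:
                return kb.disorder(did).name
            except KeyError:
                pass
        return did

    lines: list[str] = []
    facts: dict[str, str] = {}
    current: str | None = None
    for e in trace:
        p = e.payload
        if e.kind == "goal_selected":
            current = p["disorder_id"]
            lines.append(f"Hypothesis: {name(current)}")
        elif e.kind == "fact_recorded":
            facts[p["symptom_id"]] = p["value"]
            lines.append(f"  asked {p['symptom_id']} -> {p['value']}")
        elif e.kind == "hypothesis_concluded":
            verdict = p["status"]
            if verdict == "rejected" and p.get("deciding_symptom"):
                lines.append(f"  rejected: {p['deciding_symptom']} answered no")
            else:
                lines.append(f"  {verdict}: all symptoms answered yes" if verdict == "confirmed" else f"  {verdict}")
    return "\n".join(lines)


def explain_how(d: Diagnosis, kb: KnowledgeBase | None = None) -> str:
    """How-explanation of a completed diagnosis, from its trace."""
    header = (
        f"Conclusion: {', '.join(d.confirmed) if d.confirmed else 'no disorder identified'}"
    )
    return header + "\n" + render_trace(d.trace, kb)


def trace_facts(trace: Iterable[TraceEntry]) -> dict[str, str]:
    """The symptom facts recorded in a trace."""
    return {
        e.payload["symptom_id"]: e.payload["value"]
        for e in trace
        if e.kind == "fact_recorded"
    }


def replay_trace(kb: KnowledgeBase, trace: Iterable[TraceEntry]) -> set[str]:
    """Re-derive the confirmed set from a trace's facts via the brute-force
    oracle. Symptoms the session never asked (skipped after an early
    rejection) are completed with 'no', which cannot alter the confirmed set:
    every confirmed rule already has yes-facts for its whole body."""
    vector = {sid: NO for sid in kb.symptom_ids}
    vector.update(trace_facts(trace))
    return brute_force_diagnose(kb, vector)


def brute_force_diagnose(kb: KnowledgeBase, full_vector: Mapping[str, str]) -> set[str]:
    """Oracle: disorders whose entire symptom list maps to yes in a complete
    answer vector. Pure, no dialogue."""
    missing = [s for s in kb.symptom_ids if s not in full_vector]
    if missing:
        raise ContractError(f"answer vector incomplete; missing symptoms: {missing}")
    bad = {v for v in full_vector.values() if v not in (YES, NO)}
    if bad:
        raise ContractError(f"answer vector contains non-yes/no values: {bad}")
    return {d.id for d in kb.disorders if all(full_vector[s] == YES for s in d.symptom_ids)}


def scripted_provider(vector: Mapping[str, str], default: str | None = None) -> AnswerProvider:
    """Answer provider backed by a symptom->yes/no mapping. With a default,
    unknown symptoms get that value; without, they raise KeyError (which the
    engine surfaces as a SessionError)."""

    def provider(symptom_id: str) -> str:
        if symptom_id in vector:
            return vector[symptom_id]
        if default is not None:
            return default
        raise KeyError(symptom_id)

    return provider
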