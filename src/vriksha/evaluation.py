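"""Synthetic case generation and diagnostic-accuracy evaluation.

A case is a complete yes/no answer vector labeled with its true disorder.
The base vector is the indicator of the disorder's symptoms (yes on its own
symptoms, no everywhere else); observation noise is modeled as independent
symmetric flips with probability `noise_rate`, a stand-in for imperfect
field observation. One master seed expands to per-case seeds by fixed
arithmetic so any individual case can be regenerated.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .inference import NO, YES, diagnose, scripted_provider
from .kb_model import KnowledgeBase, detect_nested_rules

NO_PREDICTION = "none"

_SEED_MULT = 1_000_003
_SEED_MOD = 2**31


def per_case_seed(master_seed: int, index: int) -> int:
    """Fixed-arithmetic seed expansion, recorded in Metrics for replay."""
    return (master_seed * _SEED_MULT + index) % _SEED_MOD


@dataclass(frozen=True)
class Case:
    """A labeled synthetic consultation: true disorder + full answer vector."""

    true_disorder_id: str
    answer_vector: dict[str, str]
    noise_rate: float
    seed: int


@dataclass
class Metrics:
    """Accuracy, dialogue cost and confusion structure over a case suite."""

    accuracy: float
    mean_questions: float
    confusion: dict[str, dict[str, int]]
    n_cases: int
    master_seed: int | None = None
    case_seeds: list[int] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "accuracy": self.accuracy,
                "mean_questions": self.mean_questions,
                "confusion": self.confusion,
                "n_cases": self.n_cases,
                "master_seed": self.master_seed,
                "case_seeds": self.case_seeds,
            },
            indent=2,
            sort_keys=True,
        )

    def confusion_csv(self) -> str:
        """Confusion table as CSV: rows are true disorders, columns predicted."""
        predicted = sorted({p for row in self.confusion.values() for p in row})
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["true_disorder"] + predicted)
        for true_id in sorted(self.confusion):
            row = self.confusion[true_id]
            writer.writerow([true_id] + [row.get(p, 0) for p in predicted])
        return buf.getvalue()


def generate_case(kb: KnowledgeBase, disorder_id: str, noise_rate: float, seed: int) -> Case:
    """Indicator vector of the disorder's symptoms with independent symmetric
    flips at `noise_rate`. Same seed, same case."""
    if not (0.0 <= noise_rate <= 1.0):
        raise ValueError(f"noise_rate must be in [0, 1], got {noise_rate}")
    disorder = kb.disorder(disorder_id)  # raises KeyError for unknown ids
    own = set(disorder.symptom_ids)
    rng = np.random.default_rng(seed)
    flips = rng.random(len(kb.symptoms)) < noise_rate
    vector: dict[str, str] = {}
    for i, sid in enumerate(kb.symptom_ids):
        base = YES if sid in own else NO
        if flips[i]:
            base = NO if base == YES else YES
        vector[sid] = base
    return Case(disorder_id, vector, noise_rate, seed)


def generate_suite(
    kb: KnowledgeBase, n_per_disorder: int, noise_rate: float, master_seed: int
) -> list[Case]:
    """One suite: `n_per_disorder` cases for every disorder, seeded from one
    master seed. Warns if the KB has nested rule bodies, which make noise-free
    indicators of the outer disorder ambiguous."""
    nested = detect_nested_rules(kb)
    if nested:
        warnings.warn(
            f"KB has nested rule bodies {nested}; noise-free cases for the outer "
            "disorder will also satisfy the inner rule",
            stacklevel=2,
        )
    cases: list[Case] = []
    idx = 0
    for d in kb.disorders:
        for _ in range(n_per_disorder):
            cases.append(generate_case(kb, d.id, noise_rate, per_case_seed(master_seed, idx)))
            idx += 1
    return cases


def evaluate(kb: KnowledgeBase, cases: Sequence[Case], master_seed: int | None = None) -> Metrics:
    """Run every case through the engine (scripted provider, all hypotheses
    evaluated) and score it.

    A case counts as correct iff the primary diagnosis equals the true
    disorder; cases matching no disorder are predicted "none" and count as
    incorrect. Deterministic given the cases.
    """
    if not cases:
        raise ValueError("case list must be non-empty")
    correct = 0
    questions = 0
    confusion: dict[str, dict[str, int]] = {}
    for case in cases:
        d = diagnose(kb, scripted_provider(case.answer_vector), stop_at_first=False)
        predicted = d.primary if d.primary is not None else NO_PREDICTION
        if predicted == case.true_disorder_id:
            correct += 1
        questions += d.questions_asked
        row = confusion.setdefault(case.true_disorder_id, {})
        row[predicted] = row.get(predicted, 0) + 1
    return Metrics(
        accuracy=correct / len(cases),
        mean_questions=questions / len(cases),
        confusion=confusion,
        n_cases=len(cases),
        master_seed=master_seed,
        case_seeds=[c.seed for c in cases],
    )
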