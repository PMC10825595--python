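"""Knowledge-base model: schema, validation, taxonomy and rule compilation.

The knowledge base is a single declarative JSON document holding the three
databases of the diagnostic shell — disorder descriptions, symptom questions
and treatments — together with the two-level disorder taxonomy (internal
disorders caused by the three doshas vata/pitta/kapha; external disorders
caused by insects, cold, wind, sun, or general disease signs).

Structural parsing is done with pydantic; semantic invariants (referential
integrity, rule-body sanity, category constraints, rule distinguishability)
are checked by :func:`validate_kb`, which returns violations as data rather
than raising, so a caller can always obtain the complete violation list.
A draft-2020-12 JSON Schema describing the document format is shipped at
``vriksha/data/kb.schema.json``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Iterable

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

INTERNAL_SUBCATEGORIES = ("vata", "pitta", "kapha")
EXTERNAL_SUBCATEGORIES = ("insects", "cold", "wind", "sun", "general")
CATEGORIES = ("internal", "external")

_ID_RE = re.compile(r"^[a-z][a-z0-9_]*$")


class KBFormatError(Exception):
    """The document could not be parsed as a KB (bad JSON/YAML or bad shape)."""


class KBValidationError(Exception):
    """A structurally valid KB violated semantic invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(f"{v.code}({v.offending_id}): {v.message}" for v in violations)
        super().__init__(f"knowledge base failed validation with {len(violations)} violation(s): {lines}")


class Symptom(BaseModel):
    """A yes/no observable sign with the question used to elicit it."""

    model_config = ConfigDict(extra="forbid")

    id: str
    question_text: str
    label: str = ""


class Disorder(BaseModel):
    """A disorder and its conjunctive rule body (ordered symptom ids)."""

    model_config = ConfigDict(extra="forbid")

    id: str
    name: str
    category: str
    subcategory: str
    description: str = ""
    curated: bool = False
    symptom_ids: list[str] = Field(default_factory=list)
    treatment_ids: list[str] = Field(default_factory=list)


class Treatment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    description: str = ""
    ingredients: list[str] = Field(default_factory=list)
    source_note: str = ""


class KnowledgeBase(BaseModel):
    """The full KB document. Disorder order is significant: it breaks ties in
    hypothesis ordering."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str
    symptoms: list[Symptom] = Field(default_factory=list)
    disorders: list[Disorder] = Field(default_factory=list)
    treatments: list[Treatment] = Field(default_factory=list)

    def symptom(self, symptom_id: str) -> Symptom:
        for s in self.symptoms:
            if s.id == symptom_id:
                return s
        raise KeyError(f"unknown symptom id: {symptom_id!r}")

    def disorder(self, disorder_id: str) -> Disorder:
        for d in self.disorders:
            if d.id == disorder_id:
                return d
        raise KeyError(f"unknown disorder id: {disorder_id!r}")

    def treatment(self, treatment_id: str) -> Treatment:
        for t in self.treatments:
            if t.id == treatment_id:
                return t
        raise KeyError(f"unknown treatment id: {treatment_id!r}")

    @property
    def symptom_ids(self) -> list[str]:
        return [s.id for s in self.symptoms]

    @property
    def disorder_ids(self) -> list[str]:
        return [d.id for d in self.disorders]


@dataclass(frozen=True)
class Violation:
    """A machine-readable invariant violation: code + the offending id."""

    code: str
    offending_id: str
    message: str


@dataclass(frozen=True)
class Rule:
    """IF every symptom in `body` is yes THEN `disorder_id`."""

    disorder_id: str
    body: tuple[str, ...]


def load_kb(path: str | Path, validate: bool = True) -> KnowledgeBase:
    """Load and (by default) validate a KB document.

    JSON is the canonical format; ``.yaml``/``.yml`` files are accepted as a
    reading convenience. Raises :class:`KBFormatError` on parse/shape failure
    (naming line/position where the parser provides one) and
    :class:`KBValidationError` carrying the full violation list when semantic
    invariants fail.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise KBFormatError(f"{path}: YAML parse error: {e}") from e
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as e:
            raise KBFormatError(
                f"{path}: JSON parse error at line {e.lineno}, column {e.colno}: {e.msg}"
            ) from e
    return parse_kb(raw, validate=validate, source=str(path))


def parse_kb(raw: Any, validate: bool = True, source: str = "<document>") -> KnowledgeBase:
    """Build a KnowledgeBase from an already-parsed document object."""
    try:
        kb = KnowledgeBase.model_validate(raw)
    except ValidationError as e:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in e.errors()
        )
        raise KBFormatError(f"{source}: document does not match the KB schema: {locs}") from e
    if validate:
        violations = validate_kb(kb)
        if violations:
            raise KBValidationError(violations)
    return kb


def serialize_kb(kb: KnowledgeBase) -> str:
    """Canonical JSON serialization (round-trips through load/parse)."""
    return json.dumps(kb.model_dump(), indent=2, ensure_ascii=False)


def validate_kb(kb: KnowledgeBase) -> list[Violation]:
    """Check every semantic invariant; return the complete violation list.

    Total over structurally parsed documents: never raises, an empty list
    means the KB is valid.
    """
    out: list[Violation] = []

    def seen_dupes(items: Iterable[str], code: str, kind: str) -> None:
        seen: set[str] = set()
        for i in items:
            if i in seen:
                out.append(Violation(code, i, f"duplicate {kind} id {i!r}"))
            seen.add(i)

    seen_dupes(kb.symptom_ids, "DUPLICATE_ID", "symptom")
    seen_dupes(kb.disorder_ids, "DUPLICATE_ID", "disorder")
    seen_dupes((t.id for t in kb.treatments), "DUPLICATE_ID", "treatment")

    for s in kb.symptoms:
        if not _ID_RE.match(s.id):
            out.append(Violation("BAD_ID", s.id, f"symptom id {s.id!r} is not lowercase snake_case"))
        if not s.question_text.strip() or not s.question_text.rstrip().endswith("?"):
            out.append(
                Violation("BAD_QUESTION_TEXT", s.id, "question_text must be non-empty and end in '?'")
            )

    symptom_ids = set(kb.symptom_ids)
    treatment_ids = {t.id for t in kb.treatments}
    for t in kb.treatments:
        if not _ID_RE.match(t.id):
            out.append(Violation("BAD_ID", t.id, f"treatment id {t.id!r} is not lowercase snake_case"))

    for d in kb.disorders:
        if not _ID_RE.match(d.id):
            out.append(Violation("BAD_ID", d.id, f"disorder id {d.id!r} is not lowercase snake_case"))
        if not d.symptom_ids:
            out.append(Violation("EMPTY_RULE_BODY", d.id, "disorder has no symptoms (empty rule body)"))
        if len(set(d.symptom_ids)) != len(d.symptom_ids):
            out.append(Violation("DUPLICATE_RULE_SYMPTOM", d.id, "symptom_ids contains duplicates"))
        for sid in d.symptom_ids:
            if sid not in symptom_ids:
                out.append(
                    Violation("DANGLING_SYMPTOM_REF", d.id, f"references unknown symptom {sid!r}")
                )
        for tid in d.treatment_ids:
            if tid not in treatment_ids:
                out.append(
                    Violation("DANGLING_TREATMENT_REF", d.id, f"references unknown treatment {tid!r}")
                )
        if d.category not in CATEGORIES:
            out.append(Violation("BAD_CATEGORY", d.id, f"category {d.category!r} not in {CATEGORIES}"))
        elif d.category == "internal" and d.subcategory not in INTERNAL_SUBCATEGORIES:
            out.append(
                Violation(
                    "BAD_SUBCATEGORY",
                    d.id,
                    f"internal disorder subcategory {d.subcategory!r} not one of the doshas {INTERNAL_SUBCATEGORIES}",
                )
            )
        elif d.category == "external" and d.subcategory not in EXTERNAL_SUBCATEGORIES:
            out.append(
                Violation(
                    "BAD_SUBCATEGORY",
                    d.id,
                    f"external disorder subcategory {d.subcategory!r} not in {EXTERNAL_SUBCATEGORIES}",
                )
            )

    # Rules must be pairwise distinguishable: no two identical symptom sets.
    by_set: dict[frozenset[str], str] = {}
    for d in kb.disorders:
        key = frozenset(d.symptom_ids)
        if not key:
            continue
        if key in by_set:
            out.append(
                Violation(
                    "INDISTINGUISHABLE_RULES",
                    d.id,
                    f"symptom set identical to disorder {by_set[key]!r}",
                )
            )
        else:
            by_set[key] = d.id
    return out


def taxonomy(kb: KnowledgeBase) -> dict[str, dict[str, list[str]]]:
    """Two-level taxonomy tree: category -> subcategory -> disorder ids.

    Subcategories appear in canonical order (doshas for internal; the four
    external causes then 'general'); disorders keep file order within a leaf.
    """
    tree: dict[str, dict[str, list[str]]] = {}
    order = {
        "internal": INTERNAL_SUBCATEGORIES,
        "external": EXTERNAL_SUBCATEGORIES,
    }
    for cat in CATEGORIES:
        subs: dict[str, list[str]] = {}
        for sub in order[cat]:
            members = [d.id for d in kb.disorders if d.category == cat and d.subcategory == sub]
            if members:
                subs[sub] = members
        if subs:
            tree[cat] = subs
    return tree


def hypothesis_order(kb: KnowledgeBase) -> list[str]:
    """Taxonomy pre-order: internal (vata, pitta, kapha) then external, file
    order breaking ties within each leaf."""
    tree = taxonomy(kb)
    return [did for subs in tree.values() for members in subs.values() for did in members]


def compile_rules(kb: KnowledgeBase) -> list[Rule]:
    """One conjunctive production rule per disorder, in disorder file order."""
    return [Rule(d.id, tuple(d.symptom_ids)) for d in kb.disorders]


def detect_nested_rules(kb: KnowledgeBase) -> list[tuple[str, str]]:
    """Pairs (inner, outer) where inner's symptom set is a strict subset of
    outer's. A nested inner rule fires on the outer disorder's indicator
    vector, making noise-free cases for the outer disorder ambiguous."""
    pairs: list[tuple[str, str]] = []
    sets = {d.id: frozenset(d.symptom_ids) for d in kb.disorders}
    for a in kb.disorders:
        for b in kb.disorders:
            if a.id != b.id and sets[a.id] < sets[b.id]:
                pairs.append((a.id, b.id))
    return pairs


def reference_kb_path() -> Path:
    """Filesystem path of the packaged reference KB (ten disorders)."""
    return Path(str(resources.files("vriksha").joinpath("data/reference_kb.json")))


def load_reference_kb() -> KnowledgeBase:
    return load_kb(reference_kb_path())


def kb_schema() -> dict:
    """The published JSON Schema for KB documents."""
    with resources.files("vriksha").joinpath("data/kb.schema.json").open("r", encoding="utf-8") as f:
        return json.load(f)
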