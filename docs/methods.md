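# Methods

## The diagnostic model

The shell implements a classic consultation-style expert system in the
MYCIN lineage, specialized to Vrikshayurvedic plant pathology and stripped
of certainty factors: conclusions are strictly all-or-nothing.

**Knowledge base.** A single declarative JSON document holds three
databases — disorder descriptions, symptom questions, treatments — and the
two-level taxonomy: internal disorders subdivided by the three doshas
(vata, pitta, kapha), external disorders subdivided by cause (insects,
cold, wind, sun) plus a `general` leaf for disease signs not tied to one
cause. Each disorder's ordered `symptom_ids` list is the body of one
conjunctive production rule. Array order is semantic: it breaks ties in
hypothesis ordering. Structural parsing uses pydantic; semantic invariants
(unique ids, referential integrity, non-empty duplicate-free rule bodies,
category/subcategory constraints, pairwise-distinct rule bodies) are
checked by a validator that returns *all* violations as data, so a curator
sees the complete report rather than the first failure. A draft-2020-12
JSON Schema documenting the format ships alongside the reference KB; the
pydantic models are the enforced mirror of it.

**Inference.** Backward chaining over hypotheses in taxonomy pre-order:
internal (vata, pitta, kapha) first, then external, file order within each
leaf. For the active goal the engine asks the symptoms of its rule in
listed order, consulting working memory first — one fact per symptom per
session, so overlapping rule bodies never cause a repeated question. A "no"
rejects the goal immediately and skips its remaining questions (an
`exhaustive` flag asks them anyway; it cannot change any conclusion, only
the belief fractions and question count). Confirmation requires yes on the
entire body. By default every hypothesis is evaluated so the final
statement can report all matching disorders; `stop_at_first` halts at the
first confirmation, leaving later hypotheses open.

**Beliefs.** Per disorder the engine derives status and confirmed-symptom
fraction from the recorded facts: rejected iff any of its symptoms has a
no-fact; confirmed iff all have yes-facts (fraction 1); open otherwise.
Deriving status from facts, rather than storing it, makes the
status/fraction invariants hold by construction and makes belief updates
monotone in yes-facts. The fraction is reported as a graded belief and used
to rank near-miss hypotheses when nothing is confirmed — an explicitly
labeled extension of the all-or-nothing rule, kept out of the conclusion
logic.

**Explanation.** The ordered trace (goal selections, questions, facts,
belief updates, conclusions; strictly increasing ordinals) serializes to
JSON lines. *Why* reads the live session: current goal, the rule symptoms
still untested, the pending question. *How* linearizes the trace per
hypothesis with the deciding facts. Replaying a trace's facts through the
brute-force rule oracle reproduces the confirmed set; symptoms a session
never asked (skipped after an early rejection) are completed with "no",
which cannot alter the confirmed set because every confirmed rule already
has yes-facts on its whole body.

**Dialogue.** The engine only ever sees `yes`/`no`. The dialogue layer
parses free text case-insensitively ({y, yes, n, no} after trimming),
re-prompts on anything else up to a budget (default 3 re-prompts per
question, then a clean abort carrying the partial transcript), and treats
the literal token `why` as a meta-command that prints the justification
without consuming the budget or recording a fact. Question phrasing comes
from the KB's `question_text`, keeping terminology under curator control.

## The reference knowledge base

Ten disorder records: three internal (one per dosha), four external
single-cause (insects, cold, wind, sun), and three external `general`
records for the classical signs of a diseased plant — etiolation,
bud-growth arrest, and sap exudation with branch drying. The vata symptom
list (dryness, roughness, wilting, stunted growth) and the pitta list
(inflammation/heat, yellowing leaves, burning sensation, irritability,
excessive wind) follow the transmitted descriptions; "excessive wind" is
kept under pitta as transmitted, despite its apparent affinity with vata.
The kapha list and the three general records are curator-assigned and
flagged `curated: true` in the document, as are two of the four treatment
records. Rule bodies are pairwise distinct and nesting-free; exactly one
symptom (yellowing leaves) is shared between two disorders, which exercises
cross-hypothesis memoization without creating subset ambiguity.

## Synthetic evaluation

`generate_case` emulates a consultation about a plant with one known
disorder: the base answer vector is the indicator of the true disorder's
symptoms, and observer error is modeled as independent symmetric flips of
each answer with probability `noise_rate` (default 0 — the noise-free
condition). This captures inattentive or ambiguous field observation; it
does **not** model structured error (correlated symptoms, systematically
over-reported signs, co-occurring disorders, prevalence), so a perfect
noise-free score shows rule/engine correctness and identifiability of the
KB, not field accuracy. One master seed expands to per-case seeds by fixed
arithmetic, `seed_i = (master * 1000003 + i) mod 2^31`, recorded in the
Metrics for replay; all randomness flows through numpy's seeded generator.
Accuracy counts a case correct iff the primary diagnosis equals the true
label; vectors matching no rule predict "none" and count as incorrect.
Suite generation warns when a KB has nested rule bodies (one body a strict
subset of another), since the outer disorder's indicator then also fires
the inner rule and the primary is decided by hypothesis order — the
ambiguity is visible in the confusion matrix.

Problem sizes: the test suite sweeps noise {0, 0.1, 0.3, 0.5} with 500
cases per disorder per level on a 3-disorder fixture and 50 per disorder on
the reference KB; the oracle-equivalence checks enumerate all 2^|symptoms|
vectors for fixtures up to 10 symptoms; randomized-session invariants run
1000 sessions. These sizes give sub-percent standard errors on the
monotonicity comparisons while keeping the whole suite under a few seconds.

## Numerical and design choices

- Ties in near-miss ranking are broken by disorder file order (stable sort
  on descending fraction); disorders with fraction 0 are not listed.
- A disorder with an empty rule body is a validation error, so the
  fraction's denominator is never zero in a valid KB; the defensive value
  for an empty body is 0.
- Provider failures mid-session raise a session error carrying the partial
  trace; a provider returning anything but yes/no is treated the same way.
- `unknown` answers are a dialogue-layer concern (re-prompt); the fact
  store only ever holds yes/no.
- Exit-code contract of the CLI: 0 success, 1 validation/diagnostic
  failure, 2 usage/parse error, 3 aborted session (distinct so scripted
  callers can tell an abort from an invalid KB).

## Limitations

- Strictly conjunctive single-level rules: no rule chaining beyond the
  goal's own body, no negated or disjunctive conditions, no certainty
  factors, no forward chaining or rule learning.
- The taxonomy is fixed at two levels with a closed subcategory vocabulary.
- The synthetic noise model is unstructured; reported accuracies
  characterize the shell under that model only.
- Treatment records are provenance-annotated text; no efficacy modeling.
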