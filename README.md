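# vriksha

A rule-based, backward-chaining expert-system shell for diagnosing plant
disorders in the tradition of **Vrikshayurveda**, the ancient Indian science
of plant life. The package is aimed at people building or studying
knowledge-based diagnostic dialogues — agronomists curating traditional
plant-pathology knowledge, and students of classic expert-system
architecture (declarative knowledge base, goal-driven inference, working
memory, why/how explanation).

## The model

Plant disorders are organized in a two-level taxonomy: **internal**
disorders caused by an imbalance of one of the three doshas — *vata*
(air/space), *pitta* (fire), *kapha* (earth/water) — and **external**
disorders caused by insects, cold weather, wind, or sun, plus general
disease signs (etiolation, bud-growth arrest, sap exudation with branch
drying).

Each disorder *d* carries an ordered list of symptoms *S(d)* and compiles
to one conjunctive production rule:

```
IF  every s in S(d) is answered "yes"  THEN  d
```

Inference is **backward chaining**: each disorder is taken up as a goal in
taxonomy order (internal doshas first), and the engine asks only for the
symptom facts that goal's rule needs, memoizing every answer in working
memory so no question is ever asked twice. A hypothesis is *rejected at the
first "no"* (its remaining questions are skipped unless `exhaustive` is
set) and *confirmed* only when **all** its symptoms are present — a partial
match never licenses a conclusion. Per disorder the engine also tracks a
graded belief, the confirmed-symptom fraction

```
confirmed_fraction(d) = #{s in S(d) answered yes} / |S(d)|  in [0, 1]
```

reported in the belief statement (and used to rank near-misses when nothing
is confirmed) but never used to conclude. Every step — goal selection,
question, fact, belief update, conclusion — is appended to an ordered trace
that backs the *why* (current goal and the symptoms its rule still needs)
and *how* (which facts decided each hypothesis) explanations and serializes
to JSON lines for replay.

The packaged reference knowledge base holds **ten disorders** over 25
symptom questions and four treatment records, including *Kunapajala*, the
traditional fermented liquid manure (hog fat, porpoise oil, ghee, hemp,
horse hair, boiled cow horn, punchmula). Records whose symptom lists are
curator-assigned rather than transmitted are flagged `curated: true` in the
document.

## Worked example

```python
from vriksha import diagnose, load_reference_kb, render_belief_statement, scripted_provider

kb = load_reference_kb()
vata = kb.disorder("vata_disorder")
vector = {s: ("yes" if s in vata.symptom_ids else "no") for s in kb.symptom_ids}
d = diagnose(kb, scripted_provider(vector))
print(d.confirmed, d.questions_asked)
print(render_belief_statement(d, kb))
```

prints

```
['vata_disorder'] 13
The plant has been classified as having "Vata disorder" (internal > vata).
Recommended treatment for the primary disorder:
  - Kunapajala, the traditional fermented liquid manure, applied to the root zone. Ingredients: hog fat, porpoise oil, ghee, hemp, horse hair, boiled cow horn, punchmula.
  - Dressing of ghee and honey smeared over wounds and dry branches, sealed with mud. Ingredients: ghee, honey, mud.
```

Thirteen questions (of 25 symptoms) sufficed: the four vata questions were
answered yes, and each of the other nine hypotheses was dropped at its
first no, with shared answers reused from working memory. The scripts in
`examples/` walk through diagnosis, explanation, KB validation and the
noise sweep of the evaluation harness.

## Command line

```sh
vriksha validate path/to/kb.json          # full violation report, exit 0 iff clean
vriksha diagnose                          # interactive yes/no consultation
vriksha diagnose --scripted answers.json --trace trace.jsonl
vriksha evaluate --noise 0.3 --n 50 --seed 7 --out metrics.json
vriksha replay trace.jsonl                # re-render the how-explanation
```

Exit codes: 0 success, 1 validation/diagnostic failure, 2 usage or parse
error, 3 session aborted (re-prompt budget exhausted). The KB document
format is JSON (YAML accepted for reading); its JSON Schema ships at
`src/vriksha/data/kb.schema.json`.

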