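"""Inspect and validate a knowledge-base document.

Loads the packaged reference KB, prints the two-level disorder taxonomy
(internal doshas vs external causes), and shows what the validator reports
when a document breaks an invariant (here: a dangling symptom reference).
"""

import json

from vriksha import load_reference_kb, parse_kb, serialize_kb, taxonomy, validate_kb

kb = load_reference_kb()
print(f"reference KB: {len(kb.disorders)} disorders, {len(kb.symptoms)} symptoms, "
      f"{len(kb.treatments)} treatments; violations: {validate_kb(kb)}")
print()
for category, subs in taxonomy(kb).items():
    print(category)
    for sub, members in subs.items():
        print(f"  {sub}: {', '.join(members)}")

# Break a cross-reference and show the aggregated violation report.
doc = json.loads(serialize_kb(kb))
doc["disorders"][0]["symptom_ids"].append("phantom_symptom")
broken = parse_kb(doc, validate=False)
print()
print("after adding a dangling reference:")
for v in validate_kb(broken):
    print(f"  [{v.code}] {v.offending_id}: {v.message}")
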