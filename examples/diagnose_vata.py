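"""Diagnose a plant showing the classic vata signs.

Builds a scripted answer vector that says yes to exactly the vata disorder's
symptoms (dryness, roughness, wilting, stunted growth) and no to everything
else, runs the backward chainer over all ten hypotheses, and prints the
belief statement. The primary diagnosis should be the vata disorder, with
Kunapajala among the recommended treatments.
"""

from vriksha import diagnose, load_reference_kb, render_belief_statement, scripted_provider

kb = load_reference_kb()
vata = kb.disorder("vata_disorder")
vector = {s: ("yes" if s in vata.symptom_ids else "no") for s in kb.symptom_ids}

diagnosis = diagnose(kb, scripted_provider(vector))

print(f"confirmed disorders: {diagnosis.confirmed}")
print(f"questions asked:     {diagnosis.questions_asked} (of {len(kb.symptoms)} symptoms)")
print()
print(render_belief_statement(diagnosis, kb))
print()
print("The question count is below the symptom count because a hypothesis is")
print("dropped at its first 'no' and answers are memoized across hypotheses.")
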