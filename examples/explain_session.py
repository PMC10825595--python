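"""Why/how explanations of a consultation.

Runs a scripted dialogue in which the user first asks "why" before answering,
then prints the full how-explanation (the linearized reasoning trace) after
the diagnosis. The why-text names the hypothesis under test and the symptoms
its rule still needs; the how-text shows, per hypothesis, the facts that
decided it.
"""

from vriksha import ScriptedChannel, explain_how, load_reference_kb, run_session

kb = load_reference_kb()

# "why" is a meta-command: it prints the justification and re-asks.
answers = ["why", "yes", "yes", "yes", "yes"] + ["no"] * 30
channel = ScriptedChannel(answers)
diagnosis, transcript = run_session(kb, channel)

print("--- why-explanation shown during the session ---")
print(next(o for o in channel.output if "hypothesis" in o))
print()
print("--- how the conclusion was reached ---")
print(explain_how(diagnosis, kb))
print()
print(f"{len(transcript.turns)} questions were answered; the trace above lists")
print("every hypothesis with the deciding facts, and replaying those facts")
print("through the rule oracle reproduces the same confirmed set.")
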