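"""Backward-chaining engine: hypothesis evaluation, memoization, beliefs,
explanation, and exhaustive equivalence with the brute-force oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vriksha import (
    BeliefState,
    ContractError,
    Fact,
    Session,
    SessionError,
    StateError,
    UnknownDisorderError,
    WorkingMemory,
    brute_force_diagnose,
    diagnose,
    evaluate_hypothesis,
    explain_how,
    explain_why,
    replay_trace,
    scripted_provider,
    update_belief,
)

from conftest import make_kb


def counting_provider(vector):
    """Scripted provider that counts how many questions were actually asked."""
    calls = []

    def provider(sid):
        calls.append(sid)
        return vector[sid]

    provider.calls = calls
    return provider


def indicator(kb, disorder_id):
    own = set(kb.disorder(disorder_id).symptom_ids)
    return {s: ("yes" if s in own else "no") for s in kb.symptom_ids}


class TestEvaluateHypothesis:
    def test_all_yes_confirms_and_asks_each_symptom_once(self, ref_kb):
        provider = counting_provider({s: "yes" for s in ref_kb.symptom_ids})
        wm = WorkingMemory()
        status = evaluate_hypothesis(ref_kb, "vata_disorder", wm, provider)
        assert status == "confirmed"
        assert provider.calls == list(ref_kb.disorder("vata_disorder").symptom_ids)

    def test_rejects_at_first_no_and_stops_asking(self, disjoint_kb):
        # leaf_blight's rule is (s1, s2, s3); a no on s2 must end the interview
        provider = counting_provider({"s1": "yes", "s2": "no", "s3": "yes"})
        status = evaluate_hypothesis(disjoint_kb, "leaf_blight", WorkingMemory(), provider)
        assert status == "rejected"
        assert provider.calls == ["s1", "s2"]

    def test_exhaustive_mode_asks_all_symptoms(self, disjoint_kb):
        provider = counting_provider({"s1": "yes", "s2": "no", "s3": "yes"})
        status = evaluate_hypothesis(
            disjoint_kb, "leaf_blight", WorkingMemory(), provider, exhaustive=True
        )
        assert status == "rejected"
        assert provider.calls == ["s1", "s2", "s3"]

    def test_shared_symptoms_not_re_asked_across_hypotheses(self, overlap_kb):
        # alpha=(s1,s2,s3), beta=(s2,s3,s4): evaluating beta after alpha may
        # only ask the one symptom alpha did not cover
        provider = counting_provider({s: "yes" for s in overlap_kb.symptom_ids})
        wm = WorkingMemory()
        evaluate_hypothesis(overlap_kb, "alpha", wm, provider)
        evaluate_hypothesis(overlap_kb, "beta", wm, provider)
        assert provider.calls == ["s1", "s2", "s3", "s4"]
        assert wm.question_log == ["s1", "s2", "s3", "s4"]

    def test_unknown_disorder_raises(self, disjoint_kb):
        with pytest.raises(UnknownDisorderError):
            evaluate_hypothesis(disjoint_kb, "ghost", WorkingMemory(), lambda s: "yes")


class TestDiagnose:
    def test_vata_indicator_yields_vata_primary(self, ref_kb):
        d = diagnose(ref_kb, scripted_provider(indicator(ref_kb, "vata_disorder")))
        assert d.primary == "vata_disorder"
        assert d.confirmed == ["vata_disorder"]
        assert d.treatments == ["kunapajala", "ghee_honey_dressing"]

    def test_all_no_confirms_nothing(self, ref_kb):
        d = diagnose(ref_kb, scripted_provider({s: "no" for s in ref_kb.symptom_ids}))
        assert d.confirmed == [] and d.primary is None and d.treatments == []

    def test_every_reference_disorder_recovered_from_its_indicator(self, ref_kb):
        for did in ref_kb.disorder_ids:
            d = diagnose(ref_kb, scripted_provider(indicator(ref_kb, did)))
            assert d.confirmed == [did], did

    def test_stop_at_first_halts_and_leaves_later_hypotheses_open(self, disjoint_kb):
        provider = counting_provider({s: "yes" for s in disjoint_kb.symptom_ids})
        d = diagnose(disjoint_kb, provider, stop_at_first=True)
        assert d.confirmed == ["leaf_blight"]
        assert provider.calls == ["s1", "s2", "s3"]
        assert d.belief_state["stem_canker"]["status"] == "open"

    def test_provider_failure_carries_partial_trace(self, disjoint_kb):
        def flaky(sid):
            if sid == "s2":
                raise RuntimeError("sensor offline")
            return "yes"

        with pytest.raises(SessionError) as exc:
            diagnose(disjoint_kb, flaky)
        kinds = [e.kind for e in exc.value.partial_trace]
        assert "question_asked" in kinds and "fact_recorded" in kinds

    def test_non_yes_no_provider_value_rejected(self, disjoint_kb):
        with pytest.raises(SessionError):
            diagnose(disjoint_kb, lambda s: "maybe")

    def test_determinism_byte_identical_traces(self, ref_kb):
        vec = indicator(ref_kb, "pitta_disorder")
        d1 = diagnose(ref_kb, scripted_provider(vec))
        d2 = diagnose(ref_kb, scripted_provider(vec))
        assert d1.trace_jsonl() == d2.trace_jsonl()
        assert d1.to_dict() == d2.to_dict()


class TestOracleEquivalence:
    @pytest.mark.parametrize("fixture", ["disjoint_kb", "overlap_kb", "nested_kb"])
    def test_exhaustive_over_all_answer_vectors(self, fixture, request):
        """diagnose (all hypotheses) confirms exactly the brute-force set for
        every one of the 2^|symptoms| complete answer vectors."""
        kb = request.getfixturevalue(fixture)
        symptoms = kb.symptom_ids
        assert len(symptoms) <= 10
        for bits in itertools.product("yn", repeat=len(symptoms)):
            vec = {s: ("yes" if b == "y" else "no") for s, b in zip(symptoms, bits)}
            d = diagnose(kb, scripted_provider(vec), stop_at_first=False)
            assert set(d.confirmed) == brute_force_diagnose(kb, vec)

    def test_brute_force_all_yes_and_all_no(self, overlap_kb):
        all_yes = {s: "yes" for s in overlap_kb.symptom_ids}
        all_no = {s: "no" for s in overlap_kb.symptom_ids}
        assert brute_force_diagnose(overlap_kb, all_yes) == set(overlap_kb.disorder_ids)
        assert brute_force_diagnose(overlap_kb, all_no) == set()

    def test_brute_force_indicator_on_disjoint_kb(self, disjoint_kb):
        vec = indicator(disjoint_kb, "root_rot")
        assert brute_force_diagnose(disjoint_kb, vec) == {"root_rot"}

    def test_brute_force_requires_complete_vector(self, disjoint_kb):
        with pytest.raises(ContractError, match="incomplete"):
            brute_force_diagnose(disjoint_kb, {"s1": "yes"})


class TestBeliefState:
    def test_fresh_state_open_fraction_zero(self, disjoint_kb):
        bs = BeliefState(disjoint_kb)
        assert bs.status("leaf_blight") == "open"
        assert bs.confirmed_fraction("leaf_blight") == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_fraction_is_yes_count_over_symptom_count(self, disjoint_kb, k):
        bs = BeliefState(disjoint_kb)
        body = disjoint_kb.disorder("leaf_blight").symptom_ids
        for sid in body[:k]:
            update_belief(bs, "leaf_blight", Fact(sid, "yes"))
        # brute-force recount over the fact set
        assert bs.confirmed_fraction("leaf_blight") == pytest.approx(k / len(body))
        assert bs.status("leaf_blight") == ("confirmed" if k == len(body) else "open")

    def test_any_no_fact_rejects_regardless_of_fraction(self, disjoint_kb):
        bs = BeliefState(disjoint_kb)
        update_belief(bs, "leaf_blight", Fact("s1", "yes"))
        update_belief(bs, "leaf_blight", Fact("s2", "yes"))
        update_belief(bs, "leaf_blight", Fact("s3", "no"))
        assert bs.status("leaf_blight") == "rejected"
        assert bs.confirmed_fraction("leaf_blight") == pytest.approx(2 / 3)

    def test_unrelated_fact_is_contract_violation(self, disjoint_kb):
        bs = BeliefState(disjoint_kb)
        with pytest.raises(ContractError):
            update_belief(bs, "leaf_blight", Fact("s4", "yes"))

    def test_fact_value_must_be_yes_or_no(self):
        with pytest.raises(ContractError):
            Fact("s1", "maybe")

    @given(st.lists(st.sampled_from(["s1", "s2", "s3"]), max_size=6))
    @settings(deadline=None)
    def test_monotonicity_yes_facts_never_decrease_fraction(self, yes_stream):
        kb = make_kb({"leaf_blight": ["s1", "s2", "s3"], "other": ["s4"]})
        bs = BeliefState(kb)
        last = 0.0
        for sid in yes_stream:
            try:
                update_belief(bs, "leaf_blight", Fact(sid, "yes"))
            except ContractError:
                continue
            frac = bs.confirmed_fraction("leaf_blight")
            assert frac >= last
            last = frac


class TestExplanation:
    def test_why_names_goal_and_untested_symptoms(self, ref_kb):
        """Mid-interrogation of the first hypothesis, the why-text cites it."""
        captured = {}

        def provider(sid):
            if sid == "rough_bark":  # second vata question
                captured["why"] = explain_why(session)
            return "yes"

        session = Session(ref_kb)
        session.run(provider)
        why = captured["why"]
        assert "Vata" in why
        assert "roughness" in why and "wilting" in why

    def test_why_after_hypothesis_switch_cites_new_goal(self, disjoint_kb):
        captured = {}

        def provider(sid):
            if sid == "s4":  # first root_rot question, after leaf_blight rejected
                captured["why"] = explain_why(session)
            return "no"

        session = Session(disjoint_kb)
        session.run(provider)
        assert "Root Rot" in captured["why"]
        assert "Leaf Blight" not in captured["why"]

    def test_why_without_pending_question_is_state_error(self, disjoint_kb):
        session = Session(disjoint_kb)
        with pytest.raises(StateError):
            explain_why(session)

    def test_how_lists_confirming_facts(self, ref_kb):
        d = diagnose(ref_kb, scripted_provider(indicator(ref_kb, "vata_disorder")))
        how = explain_how(d, ref_kb)
        for sid in ref_kb.disorder("vata_disorder").symptom_ids:
            assert f"asked {sid} -> yes" in how
        assert "confirmed" in how

    def test_how_shows_one_deciding_no_per_rejected_hypothesis(self, disjoint_kb):
        d = diagnose(disjoint_kb, scripted_provider({s: "no" for s in disjoint_kb.symptom_ids}))
        how = explain_how(d, disjoint_kb)
        assert how.count("answered no") == 3  # one per rejected hypothesis

    @pytest.mark.parametrize("target", ["vata_disorder", "sun_scorch", None])
    def test_trace_replay_reproduces_confirmed_set(self, ref_kb, target):
        vec = (
            indicator(ref_kb, target)
            if target
            else {s: "no" for s in ref_kb.symptom_ids}
        )
        d = diagnose(ref_kb, scripted_provider(vec))
        assert replay_trace(ref_kb, d.trace) == set(d.confirmed)

    def test_trace_ordinals_strictly_increasing(self, ref_kb):
        d = diagnose(ref_kb, scripted_provider(indicator(ref_kb, "kapha_disorder")))
        ordinals = [e.ordinal for e in d.trace]
        assert ordinals == sorted(ordinals) and len(set(ordinals)) == len(ordinals)


class TestSessionInvariants:
    @given(bits=st.integers(min_value=0, max_value=2**25 - 1))
    @settings(deadline=None, max_examples=200)
    def test_no_repeated_questions_any_vector(self, ref_kb, bits):
        symptoms = ref_kb.symptom_ids
        vec = {s: ("yes" if (bits >> i) & 1 else "no") for i, s in enumerate(symptoms)}
        session = Session(ref_kb)
        session.run(scripted_provider(vec))
        log = session.wm.question_log
        assert len(log) == len(set(log)) == len(session.wm.facts)
        assert len(log) <= len(symptoms)

    @given(bits=st.integers(min_value=0, max_value=2**25 - 1))
    @settings(deadline=None, max_examples=100)
    def test_early_stop_never_asks_more_than_exhaustive(self, ref_kb, bits):
        symptoms = ref_kb.symptom_ids
        vec = {s: ("yes" if (bits >> i) & 1 else "no") for i, s in enumerate(symptoms)}
        early = diagnose(ref_kb, scripted_provider(vec), exhaustive=False)
        full = diagnose(ref_kb, scripted_provider(vec), exhaustive=True)
        assert early.questions_asked <= full.questions_asked
        assert early.confirmed == full.confirmed
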