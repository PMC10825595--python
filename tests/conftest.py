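import pytest

from vriksha import KnowledgeBase, load_reference_kb, parse_kb


def make_kb(disorders: dict[str, list[str]], categories: dict[str, tuple[str, str]] | None = None,
            validate: bool = True) -> KnowledgeBase:
    """Build a small KB from {disorder_id: [symptom ids]}; symptoms inferred.

    Categories default to external/general so any disorder set is legal.
    """
    categories = categories or {}
    symptom_ids: list[str] = []
    for body in disorders.values():
        for s in body:
            if s not in symptom_ids:
                symptom_ids.append(s)
    doc = {
        "schema_version": "1.0",
        "symptoms": [
            {"id": s, "question_text": f"Does the plant show {s.replace('_', ' ')}?", "label": s}
            for s in symptom_ids
        ],
        "disorders": [
            {
                "id": did,
                "name": did.replace("_", " ").title(),
                "category": categories.get(did, ("external", "general"))[0],
                "subcategory": categories.get(did, ("external", "general"))[1],
                "symptom_ids": body,
                "treatment_ids": [],
            }
            for did, body in disorders.items()
        ],
        "treatments": [],
    }
    return parse_kb(doc, validate=validate)


@pytest.fixture(scope="session")
def ref_kb() -> KnowledgeBase:
    return load_reference_kb()


@pytest.fixture
def disjoint_kb() -> KnowledgeBase:
    """Three disorders with pairwise-disjoint symptom sets (7 symptoms)."""
    return make_kb({
        "leaf_blight": ["s1", "s2", "s3"],
        "root_rot": ["s4", "s5"],
        "stem_canker": ["s6", "s7"],
    })


@pytest.fixture
def overlap_kb() -> KnowledgeBase:
    """Disorders sharing symptoms but forming an antichain (no nesting)."""
    return make_kb({
        "alpha": ["s1", "s2", "s3"],
        "beta": ["s2", "s3", "s4"],
        "gamma": ["s1", "s4", "s5"],
    })


@pytest.fixture
def nested_kb() -> KnowledgeBase:
    """inner's symptoms are a strict subset of outer's."""
    return make_kb({
        "inner": ["s1", "s2"],
        "outer": ["s1", "s2", "s3"],
    })
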