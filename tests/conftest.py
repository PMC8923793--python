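import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mixsym.corpus import (
    AnnotatedDocument,
    EntitySpan,
    RelationTriple,
    Sentence,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20220308)


def make_doc(sid, text, entities, relations=()):
    """entities: (type, start, end); relations: (label, src_idx, tgt_idx)."""
    spans = [EntitySpan(*e) for e in entities]
    rels = {RelationTriple(lab, spans[s], spans[t]) for lab, s, t in relations}
    return AnnotatedDocument(Sentence.from_text(sid, text), set(spans), rels)


@pytest.fixture
def mixture_doc():
    """A 6-token mixture mention: two body parts share one severity+symptom.

    layout: B1=[0,1) B2=[1,2) V=[2,3) S=[3,5) filler [5,6)
    relations: S->B1, S->B2 (located_at), V->S (is_a_description_of).
    """
    return make_doc(
        "mix-1", "头身强痛甚也",
        [("body_part", 0, 1), ("body_part", 1, 2), ("severity", 2, 3),
         ("symptom", 3, 5)],
        [("located_at", 3, 0), ("located_at", 3, 1),
         ("is_a_description_of", 2, 3)],
    )


def random_document(rng, sid="r", max_len=30) -> AnnotatedDocument:
    """Random schema-valid document (random non-overlapping typed spans plus
    schema-consistent relations)."""
    n = int(rng.integers(1, max_len + 1))
    text = "".join(chr(0x4E00 + int(c)) for c in rng.integers(0, 200, size=n))
    sent = Sentence.from_text(sid, text)
    entities = []
    pos = 0
    types = ("symptom", "body_part", "severity")
    while pos < n:
        if rng.random() < 0.4:
            length = int(rng.integers(1, min(3, n - pos) + 1))
            entities.append(EntitySpan(types[int(rng.integers(3))],
                                       pos, pos + length))
            pos += length
        else:
            pos += 1
    rels = set()
    syms = [e for e in entities if e.entity_type == "symptom"]
    bodies = [e for e in entities if e.entity_type == "body_part"]
    sevs = [e for e in entities if e.entity_type == "severity"]
    for s in syms:
        for b in bodies:
            if rng.random() < 0.5:
                rels.add(RelationTriple("located_at", s, b))
    for v in sevs:
        for s in syms:
            if rng.random() < 0.5:
                rels.add(RelationTriple("is_a_description_of", v, s))
    return AnnotatedDocument(sent, set(entities), rels)
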