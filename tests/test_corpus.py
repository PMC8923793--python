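"""Data model, BIO codec, token-arc encoding and corpus statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixsym.corpus import (
    AnnotatedDocument,
    EntitySpan,
    RelationTriple,
    SchemaError,
    Sentence,
    Token,
    TokenArc,
    corpus_statistics,
    decode_bio,
    encode_bio,
    from_token_arcs,
    stats_from_counts,
    to_token_arcs,
)
from .conftest import make_doc, random_document


class TestTypes:
    def test_token_must_be_single_character(self):
        with pytest.raises(SchemaError):
            Token("ab", 0)

    def test_sentence_requires_contiguous_indices(self):
        with pytest.raises(SchemaError):
            Sentence("s", (Token("a", 0), Token("b", 2)))

    def test_span_bounds(self):
        with pytest.raises(SchemaError):
            EntitySpan("symptom", 3, 3)
        assert EntitySpan("symptom", 0, 2).last_token == 1

    def test_relation_rejects_self_loop(self):
        e = EntitySpan("symptom", 0, 1)
        with pytest.raises(SchemaError):
            RelationTriple("located_at", e, e)

    def test_none_arc_must_be_self_arc(self):
        with pytest.raises(SchemaError):
            TokenArc(0, 1, "none")

    def test_validate_catches_dangling_relation(self):
        doc = make_doc("d", "甲乙丙", [("symptom", 0, 1), ("body_part", 1, 2)],
                       [("located_at", 0, 1)])
        doc.entities = {EntitySpan("symptom", 0, 1)}
        with pytest.raises(SchemaError):
            doc.validate()

    def test_strict_validation_checks_direction(self):
        doc = make_doc("d", "甲乙丙", [("symptom", 0, 1), ("body_part", 1, 2)],
                       [("located_at", 1, 0)])  # body -> symptom: wrong way
        doc.validate()  # lax mode accepts
        with pytest.raises(SchemaError):
            doc.validate(strict_schema=True)


class TestBIO:
    @pytest.mark.parametrize("entities,expected", [
        ([("symptom", 0, 2)], ["B-symptom", "I-symptom", "O", "O"]),
        ([], ["O", "O", "O", "O"]),
        ([("body_part", 0, 1), ("symptom", 1, 3)],
         ["B-body_part", "B-symptom", "I-symptom", "O"]),
    ])
    def test_encode(self, entities, expected):
        sent = Sentence.from_text("s", "甲乙丙丁")
        assert encode_bio(sent, {EntitySpan(*e) for e in entities}) == expected

    def test_encode_rejects_overlap(self):
        sent = Sentence.from_text("s", "甲乙丙")
        with pytest.raises(SchemaError):
            encode_bio(sent, {EntitySpan("symptom", 0, 2),
                              EntitySpan("body_part", 1, 3)})

    def test_decode_simple(self):
        assert decode_bio(["B-symptom", "I-symptom", "O"]) == {
            EntitySpan("symptom", 0, 2)}

    def test_decode_rejects_unknown_tag(self):
        with pytest.raises(SchemaError):
            decode_bio(["B-symptom", "X-symptom"])
        with pytest.raises(SchemaError):
            decode_bio(["B-disease"])

    def test_repair_rule_all_length2_sequences(self):
        # exhaustively derive the conll-style repair on every length-2 tag
        # pair: a dangling I- opens a span exactly like B- would
        tags = ["O", "B-symptom", "I-symptom", "B-body_part", "I-body_part"]
        for t1 in tags:
            for t2 in tags:
                got = decode_bio([t1, t2])
                repaired = []
                for t in (t1, t2):
                    repaired.append("B" + t[1:] if t.startswith("I") else t)
                # reference: greedy span builder on the repaired-at-start tags
                expected = set()
                start = None
                cur = None
                for i, t in enumerate([t1, t2]):
                    if t == "O":
                        if start is not None:
                            expected.add(EntitySpan(cur, start, i))
                            start = None
                    elif t.startswith("B") or cur != t[2:] or start is None:
                        if start is not None:
                            expected.add(EntitySpan(cur, start, i))
                        start, cur = i, t[2:]
                if start is not None:
                    expected.add(EntitySpan(cur, start, 2))
                assert got == expected, (t1, t2)

    def test_leading_inside_tag_repaired(self):
        assert decode_bio(["I-symptom", "O"]) == {EntitySpan("symptom", 0, 1)}

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_roundtrip_random_documents(self, seed):
        import numpy as np
        doc = random_document(np.random.default_rng(seed))
        tags = encode_bio(doc.sentence, doc.entities)
        assert len(tags) == len(doc.sentence)
        assert decode_bio(tags) == doc.entities


class TestTokenArcs:
    def test_mixture_doc_multihead(self, mixture_doc):
        arcs = to_token_arcs(mixture_doc)
        # symptom last token (4) carries both located_at arcs
        sym_arcs = [a for a in arcs if a.dep == 4 and a.label != "none"]
        assert {(a.head, a.label) for a in sym_arcs} == {
            (0, "located_at"), (1, "located_at")}
        # severity token 2 points at symptom last token 4
        assert TokenArc(2, 4, "is_a_description_of") in arcs
        # every token without an outgoing labeled arc has a none self-arc
        deps_labeled = {a.dep for a in arcs if a.label != "none"}
        for i in range(6):
            if i not in deps_labeled:
                assert TokenArc(i, i, "none") in arcs
        # every token carries at least one arc
        assert {a.dep for a in arcs} == set(range(6))

    def test_relation_free_doc_all_none(self):
        doc = make_doc("d", "甲乙", [("symptom", 0, 1)])
        assert to_token_arcs(doc) == [TokenArc(0, 0, "none"),
                                      TokenArc(1, 1, "none")]

    def test_single_relation_example(self):
        doc = make_doc("d", "甲乙丙丁", [("body_part", 0, 1), ("symptom", 2, 4)],
                       [("located_at", 1, 0)])
        arcs = to_token_arcs(doc)
        assert TokenArc(3, 0, "located_at") in arcs
        for i in (0, 1, 2):
            assert TokenArc(i, i, "none") in arcs

    def test_from_arcs_drops_non_entity_tokens(self):
        ents = {EntitySpan("symptom", 0, 2), EntitySpan("body_part", 3, 4)}
        arcs = [TokenArc(1, 3, "located_at"),   # valid: both entity-final
                TokenArc(0, 3, "located_at"),   # dep not entity-final
                TokenArc(1, 2, "located_at")]   # head not entity-final
        triples = from_token_arcs(ents, arcs)
        assert triples == {RelationTriple(
            "located_at", EntitySpan("symptom", 0, 2),
            EntitySpan("body_part", 3, 4))}

    def test_two_arcs_one_token_two_triples(self):
        ents = {EntitySpan("symptom", 0, 2), EntitySpan("body_part", 2, 3),
                EntitySpan("body_part", 3, 5)}
        arcs = [TokenArc(1, 2, "located_at"), TokenArc(1, 4, "located_at")]
        assert len(from_token_arcs(ents, arcs)) == 2

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_arc_roundtrip_random_documents(self, seed):
        import numpy as np
        doc = random_document(np.random.default_rng(seed))
        arcs = to_token_arcs(doc)
        assert from_token_arcs(doc.entities, arcs) == doc.relations
        # invariant: labeled arcs only at entity-final tokens; full coverage
        finals = {e.last_token for e in doc.entities}
        assert all(a.dep in finals for a in arcs if a.label != "none")
        assert {a.dep for a in arcs} == set(range(len(doc.sentence)))


class TestStatistics:
    def test_printed_annotation_tables(self):
        # published counts: percentages must reproduce the printed values
        st_ = stats_from_counts(
            entity_counts={"symptom": 41004, "body_part": 26829,
                           "severity": 5061},
            relation_counts={"located_at": 35804,
                             "is_a_description_of": 5442},
            degree_histogram={0: 4706, 1: 56046, 2: 10387, 3: 1440, 4: 241,
                              5: 65, 6: 7, 7: 3},
        )
        # 41004/72894 = 56.2512%, 26829/72894 = 36.8055%, 5061/72894 = 6.9429%
        assert st_.entity_percentages == {"symptom": 56.25,
                                          "body_part": 36.81,
                                          "severity": 6.94}
        assert st_.relation_percentages == {"located_at": 86.81,
                                            "is_a_description_of": 13.19}
        assert st_.degree_percentages[0] == 6.456
        assert st_.degree_percentages[1] == 76.886
        assert st_.degree_percentages[2] == 14.249
        assert st_.n_entities == 72894
        assert st_.n_relations == 41246
        assert abs(st_.overlap_fraction() - 16.658) < 5e-3

    def test_percentages_sum_to_100(self, mixture_doc):
        stats = corpus_statistics([mixture_doc])
        assert abs(sum(stats.entity_percentages.values()) - 100.0) <= 0.02
        assert abs(sum(stats.relation_percentages.values()) - 100.0) <= 0.02
        assert abs(sum(stats.degree_percentages.values()) - 100.0) <= 0.02

    def test_degree_histogram_counts_entities(self, mixture_doc):
        stats = corpus_statistics([mixture_doc])
        # B1:1, B2:1, V:1, S:3
        assert stats.degree_histogram == {1: 3, 3: 1}
        assert sum(stats.degree_histogram.values()) == stats.n_entities

    def test_all_degree_one(self):
        doc = make_doc("d", "甲乙", [("symptom", 0, 1), ("body_part", 1, 2)],
                       [("located_at", 0, 1)])
        stats = corpus_statistics([doc])
        assert stats.degree_percentages == {1: 100.0}
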