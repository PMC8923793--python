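"""Multihead relation scoring, probabilities, losses and threshold decoding."""

import numpy as np
import pytest

from mixsym.corpus import EntitySpan, RelationTriple, TokenArc
from mixsym.nn import Parameter, Tensor
from mixsym.relations import (
    ARC_LABELS,
    NONE_INDEX,
    LabelEmbedding,
    RelationParams,
    RelationScorer,
    build_gold_arc_tensor,
    decode_relations,
    relation_bce,
    relation_loss,
    relation_probabilities,
    relation_scores,
)


def make_params(rng, d_z=3, d_r=2):
    R = len(ARC_LABELS)
    return RelationParams(U=rng.normal(size=(R, d_z, d_r)),
                          W=rng.normal(size=(R, d_z, d_r)),
                          b=rng.normal(size=(R, d_r)),
                          V=rng.normal(size=(R, d_r)))


class TestScores:
    def test_zero_parameters_zero_scores(self, rng):
        p = make_params(rng)
        p.U[:] = p.W[:] = 0.0
        p.b[:] = p.V[:] = 0.0
        s = relation_scores(rng.normal(size=(4, 3)), p)
        np.testing.assert_array_equal(s, np.zeros((4, 4, len(ARC_LABELS))))

    def test_hand_computed_identity_case(self):
        # d_z = d_r = 2, U = W = I, b = 0, V = [1, 1], f = tanh
        # z_j = [1, 0], z_i = [0, 1] -> V . tanh([1, 1]) = 2 tanh(1)
        R = len(ARC_LABELS)
        eye = np.stack([np.eye(2)] * R)
        p = RelationParams(U=eye, W=eye.copy(), b=np.zeros((R, 2)),
                           V=np.ones((R, 2)))
        z = np.array([[0.0, 1.0],   # token i = 0 (dependent)
                      [1.0, 0.0]])  # token j = 1 (head)
        s = relation_scores(z, p)
        assert s[0, 1, 0] == pytest.approx(2 * np.tanh(1.0))

    def test_scores_generally_asymmetric(self, rng):
        p = make_params(rng)
        s = relation_scores(rng.normal(size=(3, 3)), p)
        assert not np.allclose(s[0, 1], s[1, 0])

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            relation_scores(rng.normal(size=(3, 5)), make_params(rng, d_z=3))

    def test_probability_identities(self, rng):
        s = rng.normal(scale=3.0, size=(3, 3, len(ARC_LABELS)))
        probs = relation_probabilities(s)
        assert probs[s == 0].size == 0 or np.all(probs[s == 0] == 0.5)
        assert relation_probabilities(np.zeros((1, 1, 1)))[0, 0, 0] == 0.5
        np.testing.assert_allclose(probs + relation_probabilities(-s), 1.0)
        assert ((probs > 0) & (probs < 1)).all()
        big = relation_probabilities(np.array(50.0))
        assert big == pytest.approx(1.0, abs=1e-12)


class TestLosses:
    def test_certain_gold_zero_loss(self):
        probs = np.ones((2, 2, len(ARC_LABELS)))
        arcs = [TokenArc(0, 0, "none"), TokenArc(1, 0, "located_at")]
        assert relation_loss(probs, arcs) == pytest.approx(0.0)

    def test_single_arc_closed_form(self):
        p = 0.37
        probs = np.full((1, 1, len(ARC_LABELS)), p)
        assert relation_loss(probs, [TokenArc(0, 0, "none")]) == pytest.approx(
            -np.log(p))

    def test_hand_summed_fixture(self, rng):
        # 3 tokens, 4 gold arcs with hand-set probabilities
        probs = np.full((3, 3, len(ARC_LABELS)), 0.5)
        k_loc = ARC_LABELS.index("located_at")
        k_desc = ARC_LABELS.index("is_a_description_of")
        probs[2, 0, k_loc] = 0.9
        probs[2, 1, k_loc] = 0.8
        probs[1, 2, k_desc] = 0.7
        probs[0, 0, NONE_INDEX] = 0.6
        arcs = [TokenArc(2, 0, "located_at"), TokenArc(2, 1, "located_at"),
                TokenArc(1, 2, "is_a_description_of"), TokenArc(0, 0, "none")]
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.7) + np.log(0.6))
        assert relation_loss(probs, arcs) == pytest.approx(expected)

    def test_out_of_range_arc_rejected(self):
        probs = np.full((2, 2, len(ARC_LABELS)), 0.5)
        with pytest.raises(ValueError):
            relation_loss(probs, [TokenArc(5, 5, "none")])

    def test_bce_includes_negative_terms(self, rng):
        scores = rng.normal(size=(2, 2, len(ARC_LABELS)))
        arcs = [TokenArc(0, 0, "none"), TokenArc(1, 1, "none")]
        y = np.zeros_like(scores)
        y[0, 0, NONE_INDEX] = 1
        y[1, 1, NONE_INDEX] = 1
        expected = (np.logaddexp(0, scores) - y * scores).sum()
        assert relation_bce(scores, arcs) == pytest.approx(expected)
        # and its gold terms agree with relation_loss
        gold_only = relation_loss(relation_probabilities(scores), arcs)
        negs = (np.logaddexp(0, scores) * (1 - y)).sum()
        assert relation_bce(scores, arcs) == pytest.approx(gold_only + negs)


class TestDecode:
    ENTS = {EntitySpan("symptom", 0, 2), EntitySpan("body_part", 3, 4)}

    def _probs(self, n=4):
        return np.zeros((n, n, len(ARC_LABELS)))

    def test_all_below_threshold_empty(self):
        assert decode_relations(self._probs() + 0.1, 0.5, self.ENTS) == set()

    def test_threshold_anti_monotone(self, rng):
        probs = rng.random(size=(4, 4, len(ARC_LABELS)))
        lo = decode_relations(probs, 0.3, self.ENTS)
        hi = decode_relations(probs, 0.7, self.ENTS)
        assert hi <= lo

    def test_two_arcs_from_one_token(self):
        ents = {EntitySpan("symptom", 2, 3), EntitySpan("body_part", 0, 1),
                EntitySpan("body_part", 1, 2)}
        probs = self._probs(3)
        k = ARC_LABELS.index("located_at")
        probs[2, 0, k] = 0.9
        probs[2, 1, k] = 0.8
        got = decode_relations(probs, 0.5, ents)
        assert got == {
            RelationTriple("located_at", EntitySpan("symptom", 2, 3),
                           EntitySpan("body_part", 0, 1)),
            RelationTriple("located_at", EntitySpan("symptom", 2, 3),
                           EntitySpan("body_part", 1, 2))}

    def test_none_label_never_decoded(self):
        probs = self._probs()
        probs[1, 1, NONE_INDEX] = 0.99
        assert decode_relations(probs, 0.5, self.ENTS) == set()

    def test_non_entity_dependent_ignored(self):
        probs = self._probs()
        probs[2, 3, 0] = 0.99  # token 2 is not an entity-final token
        assert decode_relations(probs, 0.5, self.ENTS) == set()

    def test_schema_filter_drops_inconsistent(self):
        ents = {EntitySpan("body_part", 0, 1), EntitySpan("symptom", 1, 2)}
        probs = self._probs(2)
        k = ARC_LABELS.index("located_at")
        probs[0, 1, k] = 0.9  # body -> symptom: wrong direction for located_at
        assert len(decode_relations(probs, 0.5, ents)) == 1
        assert decode_relations(probs, 0.5, ents, schema_filter=True) == set()

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            decode_relations(self._probs(), 0.0, self.ENTS)


class TestTrainableScorer:
    def test_matches_functional_reference(self, rng):
        scorer = RelationScorer(d_z=4, d_r=3, rng=rng)
        z = rng.normal(size=(2, 5, 4))
        batched = scorer(Tensor(z)).data
        params = scorer.to_params()
        for b in range(2):
            np.testing.assert_allclose(batched[b],
                                       relation_scores(z[b], params),
                                       atol=1e-12)

    def test_label_embedding_lookup(self, rng):
        emb = LabelEmbedding(7, 4, rng)
        tags = np.array([[1, 1, 3]])
        g = emb(tags).data
        np.testing.assert_array_equal(g[0, 0], g[0, 1])
        assert not np.array_equal(g[0, 0], g[0, 2])
        with pytest.raises(ValueError):
            emb(np.array([[9]]))

    def test_concatenated_input_dimension(self, rng):
        from mixsym.nn import concat
        h = Tensor(rng.normal(size=(1, 3, 6)))
        g = LabelEmbedding(7, 4, rng)(np.zeros((1, 3), dtype=int))
        z = concat([h, g], axis=-1)
        assert z.shape == (1, 3, 10)

    def test_bce_gradients(self, rng):
        from .test_autodiff import check_gradients
        scorer = RelationScorer(d_z=3, d_r=2, rng=rng)
        z = Parameter(rng.normal(size=(1, 3, 3)))
        gold = build_gold_arc_tensor(
            [[TokenArc(0, 0, "none"), TokenArc(1, 1, "none"),
              TokenArc(2, 0, "located_at")]], 3)
        mask2d = np.ones((1, 3, 3))
        check_gradients(
            lambda: scorer.bce_loss(scorer(z), gold, mask2d),
            [z] + scorer.parameters(), rtol=1e-5, atol=1e-7)

    def test_loss_decreases_under_gradient_descent(self, rng):
        from mixsym.nn import Adam
        scorer = RelationScorer(d_z=3, d_r=4, rng=rng)
        z = Tensor(rng.normal(size=(4, 6, 3)))
        arcs = []
        for b in range(4):
            sent = [TokenArc(i, i, "none") for i in range(5)]
            sent.append(TokenArc(5, 0, "located_at"))
            arcs.append(sent)
        gold = build_gold_arc_tensor(arcs, 6)
        mask2d = np.ones((4, 6, 6))
        opt = Adam(scorer.parameters(), lr=0.01)
        losses = []
        for _ in range(20):
            loss = scorer.bce_loss(scorer(z), gold, mask2d)
            losses.append(loss.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert all(b < a for a, b in zip(losses, losses[1:]))
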