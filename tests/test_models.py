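"""Joint and pipeline extractors: wiring, determinism, convergence behaviour."""

import numpy as np
import pytest

from mixsym.corpus import Sentence
from mixsym.models import (
    JointExtractorModel,
    PipelineModel,
    TrainConfig,
    _JointNetwork,
    load_checkpoint,
    save_checkpoint,
    train_joint,
    train_pipeline,
)
from mixsym.evaluation import entity_prf, relation_prf
from mixsym.synthetic import Vocabulary, default_config, generate_corpus

SMALL = dict(d_emb=16, d_lstm=12, d_g=6, d_r=12, batch_size=16)


def tiny_corpus(n, seed=0, degree=None):
    cfg = default_config(n_sentences=n, seed=seed)
    # a small vocabulary keeps these fixtures learnable in a few epochs
    cfg.vocabulary = Vocabulary(
        body_words=["一二", "三四", "五六", "七八"],
        symptom_words=["疼痛", "疮疡", "疯癫", "疲癃", "疟疾", "痂痈"],
        severity_words=["弱", "强"],
    )
    if degree is not None:
        cfg.degree_distribution = degree
    return generate_corpus(cfg)


@pytest.fixture(scope="module")
def small_split():
    docs = tiny_corpus(340, seed=21)
    return docs[:300], docs[300:]


class TestJointTraining:
    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            JointExtractorModel([])

    def test_zero_epochs_returns_untrained(self, small_split):
        train, dev = small_split
        res = train_joint(train, dev, TrainConfig(epochs=0, **SMALL))
        assert res.report.epochs == []
        preds = res.predict([d.sentence for d in dev[:4]])
        assert len(preds) == 4

    def test_report_structure_and_loss_finiteness(self, small_split):
        train, dev = small_split
        res = train_joint(train[:100], dev[:30],
                          TrainConfig(epochs=2, seed=3, **SMALL))
        assert len(res.report.epochs) == 2
        for e in res.report.epochs:
            assert np.isfinite(e["loss_ner"]) and e["loss_ner"] >= 0
            assert np.isfinite(e["loss_re"]) and e["loss_re"] >= 0
            assert 0.0 <= e["dev_relation_f1"] <= 1.0
        assert [e["epoch"] for e in res.report.epochs] == [1, 2]
        assert "L_ner" in res.summary()

    def test_seed_determinism(self, small_split):
        train, dev = small_split
        cfg = TrainConfig(epochs=2, seed=11, **SMALL)
        r1 = train_joint(train[:80], dev[:20], cfg)
        r2 = train_joint(train[:80], dev[:20], cfg)
        assert r1.report.epochs == r2.report.epochs
        assert r1.threshold == r2.threshold

    def test_label_embedding_ablation_wiring(self, small_split):
        train, dev = small_split
        cfg = TrainConfig(epochs=1, label_embedding=False, **SMALL)
        res = train_joint(train[:60], dev[:20], cfg)
        net = res.network
        assert not net.use_label_embedding
        assert net.scorer.d_z == net.encoder.d_h  # z_i = h_i
        cfg_on = TrainConfig(epochs=1, label_embedding=True, **SMALL)
        res_on = train_joint(train[:60], dev[:20], cfg_on)
        assert res_on.network.scorer.d_z == res_on.network.encoder.d_h + cfg_on.d_g

    def test_convergence_reproduces_gold(self, small_split):
        train, dev = small_split
        res = train_joint(train, dev,
                          TrainConfig(epochs=20, seed=7, patience=20))
        pred = res.predict([d.sentence for d in dev])
        ent = entity_prf(dev, pred)["micro"].f1
        rel = relation_prf(dev, pred)["micro"].f1
        assert ent >= 0.95
        assert rel >= 0.90
        for d in pred:
            d.validate()

    def test_overlap_pattern_fully_recovered(self):
        # overlap-heavy corpus: entities with two heads must have BOTH arcs
        # recovered at convergence (the multihead selling point)
        from mixsym.evaluation import overlap_stratified
        docs = tiny_corpus(260, seed=5, degree={1: 0.6, 2: 0.4})
        train, dev = docs[:220], docs[220:]
        res = train_joint(train, dev,
                          TrainConfig(epochs=35, seed=7, patience=35))
        pred = res.predict([d.sentence for d in dev])
        assert overlap_stratified(dev, pred)["2+"].recall == 1.0

    def test_predict_empty_and_truncation(self, small_split):
        train, dev = small_split
        cfg = TrainConfig(epochs=1, max_seq_len=8, **SMALL)
        with pytest.warns(UserWarning, match="truncat"):
            res = train_joint(train[:40], None, cfg)
        assert res.predict([]) == []
        long = Sentence.from_text("long", "疼痛" * 10)
        with pytest.warns(UserWarning, match="truncat"):
            out = res.predict([long])
        assert len(out[0].sentence) == 8


class TestPipeline:
    def test_determinism(self, small_split):
        train, dev = small_split
        cfg = TrainConfig(epochs=2, seed=5, mode="pipeline", **SMALL)
        r1 = train_pipeline(train[:80], dev[:20], cfg)
        r2 = train_pipeline(train[:80], dev[:20], cfg)
        assert r1.report.epochs == r2.report.epochs

    def test_gold_entity_oracle_bounds_predicted(self, small_split):
        train, dev = small_split
        cfg = TrainConfig(epochs=6, seed=5, mode="pipeline", **SMALL)
        res = train_pipeline(train, dev, cfg)
        sentences = [d.sentence for d in dev]
        on_pred = res.predict(sentences)
        on_gold = res.predict(sentences,
                              gold_entities=[d.entities for d in dev])
        f1_pred = relation_prf(dev, on_pred)["micro"].f1
        f1_gold = relation_prf(dev, on_gold)["micro"].f1
        assert f1_gold >= f1_pred  # error propagation can only hurt

    def test_separable_pair_classification(self):
        # degree-1 only corpus: each sentence factors into independent pairs
        docs = tiny_corpus(200, seed=9, degree={1: 1.0})
        train, dev = docs[:170], docs[170:]
        cfg = TrainConfig(epochs=20, seed=2, mode="pipeline", patience=20)
        res = train_pipeline(train, dev, cfg)
        on_gold = res.predict([d.sentence for d in dev],
                              gold_entities=[d.entities for d in dev])
        assert relation_prf(dev, on_gold)["micro"].f1 >= 0.95


class TestJointObjectiveGradients:
    def test_finite_difference_full_model(self):
        """d(L_ner + L_re)/dtheta matches central differences at rtol 1e-4."""
        from .test_autodiff import numeric_grad
        from mixsym.models import _doc_batch_arrays
        docs = tiny_corpus(2, seed=3)
        cfg = TrainConfig(d_emb=4, d_lstm=3, d_g=2, d_r=3, dropout=0.0)
        vocab = {"<pad>": 0, "<unk>": 1}
        for d in docs:
            for t in d.sentence.tokens:
                vocab.setdefault(t.text, len(vocab))
        net = _JointNetwork(vocab, cfg, np.random.default_rng(0))
        net.eval()  # dropout off; deterministic loss
        sentences, tags, gold = _doc_batch_arrays(docs)

        def loss_fn():
            return net.loss(sentences, tags, gold)[0]

        loss = loss_fn()
        loss.backward()
        for name, p in net.named_parameters().items():
            ng = numeric_grad(lambda: loss_fn().item(), p.data, eps=1e-5)
            ag = np.zeros_like(p.data) if p.grad is None else p.grad
            np.testing.assert_allclose(
                ag, ng, rtol=1e-4, atol=1e-6,
                err_msg=f"gradient mismatch for {name}")


class TestCheckpointing:
    def test_joint_roundtrip(self, tmp_path, small_split):
        train, dev = small_split
        res = train_joint(train[:60], dev[:20],
                          TrainConfig(epochs=2, seed=4, **SMALL))
        save_checkpoint(res, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        sents = [d.sentence for d in dev[:10]]
        a = res.predict(sents)
        b = back.predict(sents)
        assert [(d.id, sorted(d.entities), sorted(d.relations)) for d in a] \
            == [(d.id, sorted(d.entities), sorted(d.relations)) for d in b]
        assert back.threshold == res.threshold

    def test_pipeline_roundtrip(self, tmp_path, small_split):
        train, dev = small_split
        cfg = TrainConfig(epochs=1, seed=4, mode="pipeline", **SMALL)
        res = train_pipeline(train[:60], dev[:20], cfg)
        save_checkpoint(res, tmp_path / "ckpt")
        back = load_checkpoint(tmp_path / "ckpt")
        sents = [d.sentence for d in dev[:10]]
        assert [sorted(d.relations) for d in res.predict(sents)] \
            == [sorted(d.relations) for d in back.predict(sents)]


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(dropout=1.0), dict(batch_size=0), dict(mode="cascade"),
        dict(threshold=1.0), dict(epochs=-1),
    ])
    def test_rejected(self, bad):
        with pytest.raises(ValueError):
            TrainConfig(**bad).validate()
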