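"""Extraction models in a Model / Results idiom.

Two estimators share one configuration object:

* :class:`JointExtractorModel` — the joint entity-relation extractor: a
  character encoder feeds a bi-LSTM whose states drive (a) a linear-chain CRF
  entity tagger trained with the path negative log-likelihood ``L_ner`` and
  (b) a multihead sigmoid relation scorer over ``z_i = [h_i, g_i]`` (hidden
  state plus entity-label embedding) trained with sigmoid cross-entropy
  ``L_re``; the objective is ``L_ner + L_re`` and both tasks are optimized in
  one pass.

* :class:`PipelineModel` — the two-stage baseline: stage 1 is the same
  bi-LSTM-CRF tagger trained on tags alone; stage 2 is a bi-GRU classifier
  over candidate ordered entity pairs (entity-position indicator embeddings
  concatenated to the character embeddings, max-pooled, softmax over the
  relation labels plus "none"), trained on gold entities and applied to
  predicted entities at inference — so stage-1 errors propagate, which is the
  point of the comparison.

``Model(train_docs, dev_docs, config).fit()`` returns a Results object
carrying the trained network, the per-epoch report, the tuned decision
threshold, and ``predict`` / ``evaluate`` / ``summary`` methods.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    BIO_TAGS,
    DEFAULT_MAX_SEQ_LEN,
    AnnotatedDocument,
    EntitySpan,
    RelationTriple,
    Sentence,
    decode_bio,
    encode_bio,
    to_token_arcs,
    truncate_document,
)
from .crf import CRFLayer, EmissionHead
from .encoder import EmbeddingSource, SentenceEncoder, build_char_vocab
from .evaluation import entity_prf, relation_prf
from .nn import Adam, BiGRU, Embedding, Linear, Module, Tensor, clip_grad_norm, no_grad
from .relations import (
    ARC_LABELS,
    NONE_LABEL,
    LabelEmbedding,
    RelationScorer,
    build_gold_arc_tensor,
    decode_relations,
)

TAG_TO_ID = {t: i for i, t in enumerate(BIO_TAGS)}
THRESHOLD_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class TrainConfig:
    """Hyperparameters shared by the joint model and the pipeline baseline."""

    mode: str = "joint"                  # "joint" | "pipeline"
    learning_rate: float = 0.001         # Adam, all RNN layers
    dropout: float = 0.5                 # on RNN outputs
    max_seq_len: int = DEFAULT_MAX_SEQ_LEN
    epochs: int = 30
    batch_size: int = 16
    patience: int = 5                    # early stop on dev relation F1
    seed: int = 13
    threshold: float = 0.5               # sigmoid decision threshold
    tune_threshold: bool = True          # grid-search threshold on dev
    label_embedding: bool = True         # the ablation axis
    use_predicted_tags_in_training: bool = False
    schema_filter: bool = True           # drop type-inconsistent triples
    d_emb: int = 64
    d_lstm: int = 64                     # per direction; d_h = 128
    d_g: int = 25                        # label-embedding dim
    d_r: int = 64                        # relation-scorer reduced dim
    grad_clip: float = 5.0
    stop_f1: float = 0.999               # stop once dev entity+relation F1 here

    def validate(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.mode not in ("joint", "pipeline"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class TrainReport:
    """Per-epoch training record."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    chosen_threshold: float = 0.5
    truncated_sentences: int = 0

    def log(self, **kwargs) -> None:
        self.epochs.append(dict(kwargs))

    def to_json_lines(self) -> str:
        return "\n".join(json.dumps(e) for e in self.epochs)


def _prepare_docs(docs: list[AnnotatedDocument],
                  max_seq_len: int) -> tuple[list[AnnotatedDocument], int]:
    out, clipped = [], 0
    for d in docs:
        if len(d.sentence) > max_seq_len:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = truncate_document(d, max_seq_len)
            clipped += 1
        out.append(d)
    if clipped:
        # one aggregate warning instead of one per document
        warnings.warn(f"truncated {clipped} over-length sentences", stacklevel=3)
    return out, clipped


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo:lo + batch_size]


# ---------------------------------------------------------------------------
# joint network
# ---------------------------------------------------------------------------

class _JointNetwork(Module):
    def __init__(self, vocab: dict[str, int], cfg: TrainConfig,
                 rng: np.random.Generator,
                 external_vectors: dict[str, np.ndarray] | None = None):
        super().__init__()
        if external_vectors is not None:
            source = EmbeddingSource("external_contextual", cfg.d_emb,
                                     vectors=external_vectors)
        else:
            source = EmbeddingSource("trainable_lookup", cfg.d_emb,
                                     vocab=vocab, rng=rng)
        self.encoder = SentenceEncoder(source, cfg.d_lstm, cfg.dropout, rng)
        self.emission = EmissionHead(self.encoder.d_h, len(BIO_TAGS), rng)
        self.crf = CRFLayer(len(BIO_TAGS), rng)
        self.use_label_embedding = cfg.label_embedding
        d_z = self.encoder.d_h
        if cfg.label_embedding:
            self.label_emb = LabelEmbedding(len(BIO_TAGS), cfg.d_g, rng)
            d_z += cfg.d_g
        self.scorer = RelationScorer(d_z, cfg.d_r, rng)

    def _relation_input(self, states: Tensor, tag_ids: np.ndarray) -> Tensor:
        if not self.use_label_embedding:
            return states
        from .nn import concat
        return concat([states, self.label_emb(tag_ids)], axis=-1)

    def loss(self, sentences: list[Sentence], tags: np.ndarray,
             gold_arcs: np.ndarray,
             use_predicted_tags: bool = False) -> tuple[Tensor, float, float]:
        """(total loss, L_ner value, L_re value) for one padded batch."""
        states, mask = self.encoder(sentences)
        emissions = self.emission(states)
        l_ner = self.crf.nll(emissions, tags, mask)
        if use_predicted_tags:
            rel_tags = _pad_tag_lists(self.crf.decode(emissions.data, mask),
                                      tags.shape[1])
        else:
            rel_tags = tags
        z = self._relation_input(states, rel_tags)
        scores = self.scorer(z)
        mask2d = mask[:, :, None] * mask[:, None, :]
        l_re = self.scorer.bce_loss(scores, gold_arcs, mask2d)
        return l_ner + l_re, l_ner.item(), l_re.item()

    def predict_batch(self, sentences: list[Sentence]):
        """Per-sentence (tag list, entity set, probability tensor)."""
        self.eval()
        with no_grad():
            states, mask = self.encoder(sentences)
            emissions = self.emission(states)
            tag_paths = self.crf.decode(emissions.data, mask)
            T = states.shape[1]
            tag_ids = _pad_tag_lists(tag_paths, T)
            z = self._relation_input(states, tag_ids)
            probs = self.scorer(z).sigmoid().data
        out = []
        for b, sent in enumerate(sentences):
            n = len(sent)
            tags = [BIO_TAGS[t] for t in tag_paths[b]]
            entities = decode_bio(tags)
            out.append((tags, entities, probs[b, :n, :n, :]))
        return out


def _pad_tag_lists(paths: list[list[int]], T: int) -> np.ndarray:
    out = np.zeros((len(paths), T), dtype=int)
    for b, p in enumerate(paths):
        out[b, :len(p)] = p
    return out


# ---------------------------------------------------------------------------
# pipeline networks
# ---------------------------------------------------------------------------

class _NERNetwork(Module):
    """Stage 1 of the pipeline: bi-LSTM-CRF tagger."""

    def __init__(self, vocab: dict[str, int], cfg: TrainConfig,
                 rng: np.random.Generator):
        super().__init__()
        source = EmbeddingSource("trainable_lookup", cfg.d_emb,
                                 vocab=vocab, rng=rng)
        self.encoder = SentenceEncoder(source, cfg.d_lstm, cfg.dropout, rng)
        self.emission = EmissionHead(self.encoder.d_h, len(BIO_TAGS), rng)
        self.crf = CRFLayer(len(BIO_TAGS), rng)

    def loss(self, sentences: list[Sentence], tags: np.ndarray) -> Tensor:
        states, mask = self.encoder(sentences)
        return self.crf.nll(self.emission(states), tags, mask)

    def predict_batch(self, sentences: list[Sentence]) -> list[set[EntitySpan]]:
        self.eval()
        with no_grad():
            states, mask = self.encoder(sentences)
            paths = self.crf.decode(self.emission(states).data, mask)
        return [decode_bio([BIO_TAGS[t] for t in p]) for p in paths]


#: pair-classifier output classes: the relation labels plus none
_PAIR_CLASSES = ARC_LABELS


class _PairClassifier(Module):
    """Stage 2 of the pipeline: bi-GRU relation classifier over entity pairs."""

    def __init__(self, vocab: dict[str, int], cfg: TrainConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.vocab = vocab
        source = EmbeddingSource("trainable_lookup", cfg.d_emb,
                                 vocab=vocab, rng=rng)
        self.source = source
        self.indicator = Embedding(3, 8, rng)  # 0 outside, 1 source, 2 target
        self.bigru = BiGRU(cfg.d_emb + 8, cfg.d_lstm, rng)
        self.out = Linear(2 * cfg.d_lstm, len(_PAIR_CLASSES), rng)
        self.dropout_p = cfg.dropout
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 31))

    def logits(self, sentences: list[Sentence],
               pairs: list[tuple[EntitySpan, EntitySpan]]) -> Tensor:
        from .nn import concat, dropout
        x, mask = self.source.embed_batch(sentences)
        B, T = mask.shape
        ind = np.zeros((B, T), dtype=int)
        for b, (src, tgt) in enumerate(pairs):
            ind[b, src.start:src.end] = 1
            ind[b, tgt.start:tgt.end] = 2
        feats = concat([x, self.indicator(ind)], axis=-1)
        h = self.bigru(feats, mask)
        h = dropout(h, self.dropout_p, self._drop_rng, self.training)
        # masked max-pool over time
        neg = Tensor((mask[:, :, None] - 1.0) * 1e6)
        pooled = (h + neg).logsumexp(axis=1)  # smooth max over valid steps
        return self.out(pooled)

    def loss(self, sentences, pairs, labels: np.ndarray) -> Tensor:
        logits = self.logits(sentences, pairs)
        lse = logits.logsumexp(axis=1)
        gold = logits[np.arange(len(labels)), labels]
        return (lse - gold).sum()

    def classify(self, sentences, pairs) -> list[str]:
        self.eval()
        with no_grad():
            logits = self.logits(sentences, pairs).data
        return [_PAIR_CLASSES[int(np.argmax(row))] for row in logits]


def _candidate_pairs(entities: set[EntitySpan]):
    ents = sorted(entities)
    return [(a, b) for a in ents for b in ents if a != b]


# ---------------------------------------------------------------------------
# shared fitting machinery
# ---------------------------------------------------------------------------

def _doc_batch_arrays(docs: list[AnnotatedDocument]):
    sentences = [d.sentence for d in docs]
    T = max(len(s) for s in sentences)
    tags = np.zeros((len(docs), T), dtype=int)
    for b, d in enumerate(docs):
        enc = encode_bio(d.sentence, d.entities)
        tags[b, :len(enc)] = [TAG_TO_ID[t] for t in enc]
    arcs = [to_token_arcs(d) for d in docs]
    gold = build_gold_arc_tensor(arcs, T)
    return sentences, tags, gold


def _dev_f1(results_predict, dev_docs: list[AnnotatedDocument]):
    pred = results_predict([d.sentence for d in dev_docs])
    ent = entity_prf(dev_docs, pred)["micro"].f1
    rel = relation_prf(dev_docs, pred)["micro"].f1
    return ent, rel


class _ResultsBase:
    """Common evaluate/summary surface for fitted extractors."""

    model: object
    report: TrainReport
    threshold: float

    def predict(self, sentences: list[Sentence]) -> list[AnnotatedDocument]:
        raise NotImplementedError

    def evaluate(self, gold_docs: list[AnnotatedDocument]) -> dict:
        from .evaluation import evaluation_report
        pred = self.predict([d.sentence for d in gold_docs])
        return evaluation_report(gold_docs, pred)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            f"{type(self).__name__}",
            "=" * 64,
            f"mode: {cfg.mode}   label embedding: {cfg.label_embedding}   "
            f"seed: {cfg.seed}",
            f"optimizer: Adam(lr={cfg.learning_rate})   dropout: {cfg.dropout}   "
            f"batch: {cfg.batch_size}",
            f"decision threshold: {self.threshold:.2f}   "
            f"best epoch: {self.report.best_epoch}",
            "-" * 64,
            f"{'epoch':>5s}{'L_ner':>12s}{'L_re':>12s}{'dev entF1':>11s}"
            f"{'dev relF1':>11s}",
        ]
        for e in self.report.epochs:
            lines.append(
                f"{e['epoch']:5d}{e['loss_ner']:12.2f}{e['loss_re']:12.2f}"
                f"{e.get('dev_entity_f1', float('nan')):11.4f}"
                f"{e.get('dev_relation_f1', float('nan')):11.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# joint model
# ---------------------------------------------------------------------------

class JointExtractorModel:
    """Joint entity-relation extractor (multihead selection).

    Parameters
    ----------
    train_docs : annotated training documents (non-empty).
    dev_docs : development documents for early stopping and threshold tuning;
        optional — without them training runs the full epoch budget.
    config : :class:`TrainConfig`; ``config.mode`` is forced to ``"joint"``.
    external_vectors : optional precomputed per-sentence contextual embeddings
        replacing the trainable lookup table (see :mod:`mixsym.encoder`).
    """

    def __init__(self, train_docs: list[AnnotatedDocument],
                 dev_docs: list[AnnotatedDocument] | None = None,
                 config: TrainConfig | None = None,
                 external_vectors: dict[str, np.ndarray] | None = None):
        if not train_docs:
            raise ValueError("empty training corpus")
        self.config = dataclasses.replace(config or TrainConfig(), mode="joint")
        self.config.validate()
        self.train_docs, self._clipped = _prepare_docs(train_docs,
                                                       self.config.max_seq_len)
        self.dev_docs = (None if dev_docs is None
                         else _prepare_docs(dev_docs, self.config.max_seq_len)[0])
        self.vocab = build_char_vocab([d.sentence for d in self.train_docs])
        self.external_vectors = external_vectors

    def fit(self) -> "JointResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        net = _JointNetwork(self.vocab, cfg, rng, self.external_vectors)
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        report = TrainReport(truncated_sentences=self._clipped)
        results = JointResults(self, net, report, cfg.threshold)
        best_state, best_f1, best_epoch, since_best = None, -1.0, -1, 0

        for epoch in range(1, cfg.epochs + 1):
            net.train()
            tot_ner = tot_re = 0.0
            for idx in _batches(len(self.train_docs), cfg.batch_size, rng):
                batch = [self.train_docs[i] for i in idx]
                sentences, tags, gold = _doc_batch_arrays(batch)
                loss, l_ner, l_re = net.loss(
                    sentences, tags, gold,
                    use_predicted_tags=cfg.use_predicted_tags_in_training)
                opt.zero_grad()
                loss.backward()
                clip_grad_norm(net.parameters(), cfg.grad_clip)
                opt.step()
                tot_ner += l_ner
                tot_re += l_re
            entry = {"epoch": epoch, "loss_ner": tot_ner, "loss_re": tot_re,
                     "loss": tot_ner + tot_re}
            if self.dev_docs:
                ent_f1, rel_f1 = _dev_f1(results.predict, self.dev_docs)
                entry.update(dev_entity_f1=ent_f1, dev_relation_f1=rel_f1)
                if rel_f1 > best_f1:
                    best_f1, best_epoch, since_best = rel_f1, epoch, 0
                    best_state = net.state_dict()
                else:
                    since_best += 1
                report.log(**entry)
                if ent_f1 >= cfg.stop_f1 and rel_f1 >= cfg.stop_f1:
                    break
                if since_best >= cfg.patience:
                    break
            else:
                report.log(**entry)

        if best_state is not None:
            net.load_state_dict(best_state)
            report.best_epoch = best_epoch
        elif report.epochs:
            report.best_epoch = report.epochs[-1]["epoch"]
        if self.dev_docs and cfg.tune_threshold and cfg.epochs > 0:
            results.threshold = _tune_threshold(net, self.dev_docs, cfg)
        report.chosen_threshold = results.threshold
        return results


def _tune_threshold(net: _JointNetwork, dev_docs, cfg: TrainConfig) -> float:
    """Pick the grid threshold maximizing dev relation micro-F1."""
    preds = _joint_raw_predictions(net, [d.sentence for d in dev_docs],
                                   cfg.batch_size)
    best_t, best_f1 = cfg.threshold, -1.0
    for t in THRESHOLD_GRID:
        docs = [_assemble_doc(s, ents, probs, t, cfg.schema_filter)
                for (s, (tags, ents, probs)) in preds]
        f1 = relation_prf(dev_docs, docs)["micro"].f1
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t


def _joint_raw_predictions(net: _JointNetwork, sentences, batch_size):
    out = []
    for lo in range(0, len(sentences), batch_size):
        chunk = sentences[lo:lo + batch_size]
        out.extend(zip(chunk, net.predict_batch(chunk)))
    return out


def _assemble_doc(sentence: Sentence, entities, probs, threshold,
                  schema_filter) -> AnnotatedDocument:
    relations = decode_relations(probs, threshold, entities,
                                 schema_filter=schema_filter)
    return AnnotatedDocument(sentence, set(entities), relations)


class JointResults(_ResultsBase):
    """Fitted joint extractor."""

    def __init__(self, model: JointExtractorModel, network: _JointNetwork,
                 report: TrainReport, threshold: float):
        self.model = model
        self.network = network
        self.report = report
        self.threshold = threshold

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    def predict(self, sentences: list[Sentence]) -> list[AnnotatedDocument]:
        if not sentences:
            return []
        cfg = self.config
        clipped = []
        for s in sentences:
            if len(s) > cfg.max_seq_len:
                warnings.warn(f"sentence {s.id!r} truncated to {cfg.max_seq_len}")
                s = Sentence(s.id, s.tokens[:cfg.max_seq_len])
            clipped.append(s)
        preds = _joint_raw_predictions(self.network, clipped, cfg.batch_size)
        return [_assemble_doc(s, ents, probs, self.threshold, cfg.schema_filter)
                for (s, (tags, ents, probs)) in preds]


# ---------------------------------------------------------------------------
# pipeline model
# ---------------------------------------------------------------------------

class PipelineModel:
    """Two-stage pipeline baseline (tagger, then pair classifier)."""

    def __init__(self, train_docs: list[AnnotatedDocument],
                 dev_docs: list[AnnotatedDocument] | None = None,
                 config: TrainConfig | None = None):
        if not train_docs:
            raise ValueError("empty training corpus")
        self.config = dataclasses.replace(config or TrainConfig(),
                                          mode="pipeline")
        self.config.validate()
        self.train_docs, self._clipped = _prepare_docs(train_docs,
                                                       self.config.max_seq_len)
        self.dev_docs = (None if dev_docs is None
                         else _prepare_docs(dev_docs, self.config.max_seq_len)[0])
        self.vocab = build_char_vocab([d.sentence for d in self.train_docs])
        self.negative_ratio = 3

    def _pair_samples(self, docs, rng: np.random.Generator):
        """Training pairs from gold entities; negative (none) pairs are
        subsampled to ``negative_ratio`` per positive to keep the candidate
        set balanced (all pairs are still scored at inference)."""
        positives, negatives = [], []
        for d in docs:
            gold = {(r.source, r.target): r.label for r in d.relations}
            for a, b in _candidate_pairs(d.entities):
                label = gold.get((a, b), NONE_LABEL)
                sample = (d.sentence, (a, b), _PAIR_CLASSES.index(label))
                (negatives if label == NONE_LABEL else positives).append(sample)
        keep = min(len(negatives),
                   max(len(positives) * self.negative_ratio, 32))
        idx = rng.choice(len(negatives), size=keep, replace=False) \
            if negatives else []
        return positives + [negatives[i] for i in idx]

    def fit(self) -> "PipelineResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        ner = _NERNetwork(self.vocab, cfg, rng)
        clf = _PairClassifier(self.vocab, cfg, rng)
        opt_ner = Adam(ner.parameters(), lr=cfg.learning_rate)
        opt_clf = Adam(clf.parameters(), lr=cfg.learning_rate)
        report = TrainReport(truncated_sentences=self._clipped)
        results = PipelineResults(self, ner, clf, report)
        pair_samples = self._pair_samples(self.train_docs, rng)
        pair_batch = 4 * cfg.batch_size
        best_state, best_f1, best_epoch, since_best = None, -1.0, -1, 0

        for epoch in range(1, cfg.epochs + 1):
            ner.train()
            clf.train()
            tot_ner = 0.0
            for idx in _batches(len(self.train_docs), cfg.batch_size, rng):
                batch = [self.train_docs[i] for i in idx]
                sentences, tags, _ = _doc_batch_arrays(batch)
                loss = ner.loss(sentences, tags)
                opt_ner.zero_grad()
                loss.backward()
                clip_grad_norm(ner.parameters(), cfg.grad_clip)
                opt_ner.step()
                tot_ner += loss.item()
            tot_re = 0.0
            for idx in _batches(len(pair_samples), pair_batch, rng):
                chunk = [pair_samples[i] for i in idx]
                loss = clf.loss([c[0] for c in chunk], [c[1] for c in chunk],
                                np.array([c[2] for c in chunk]))
                opt_clf.zero_grad()
                loss.backward()
                clip_grad_norm(clf.parameters(), cfg.grad_clip)
                opt_clf.step()
                tot_re += loss.item()
            entry = {"epoch": epoch, "loss_ner": tot_ner, "loss_re": tot_re,
                     "loss": tot_ner + tot_re}
            if self.dev_docs:
                ent_f1, rel_f1 = _dev_f1(results.predict, self.dev_docs)
                entry.update(dev_entity_f1=ent_f1, dev_relation_f1=rel_f1)
                if rel_f1 > best_f1:
                    best_f1, best_epoch, since_best = rel_f1, epoch, 0
                    best_state = (ner.state_dict(), clf.state_dict())
                else:
                    since_best += 1
                report.log(**entry)
                if ent_f1 >= cfg.stop_f1 and rel_f1 >= cfg.stop_f1:
                    break
                if since_best >= cfg.patience:
                    break
            else:
                report.log(**entry)

        if best_state is not None:
            ner.load_state_dict(best_state[0])
            clf.load_state_dict(best_state[1])
            report.best_epoch = best_epoch
        elif report.epochs:
            report.best_epoch = report.epochs[-1]["epoch"]
        report.chosen_threshold = results.threshold
        return results


class PipelineResults(_ResultsBase):
    """Fitted pipeline baseline."""

    def __init__(self, model: PipelineModel, ner: _NERNetwork,
                 clf: _PairClassifier, report: TrainReport):
        self.model = model
        self.ner = ner
        self.classifier = clf
        self.report = report
        self.threshold = model.config.threshold  # unused; kept for symmetry

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    def predict(self, sentences: list[Sentence],
                gold_entities: list[set[EntitySpan]] | None = None
                ) -> list[AnnotatedDocument]:
        """Predict entities then relations.

        ``gold_entities`` switches stage 2 to an oracle-entity evaluation
        (no stage-1 error propagation), for diagnosing the pipeline gap.
        """
        if not sentences:
            return []
        cfg = self.config
        clipped = []
        for s in sentences:
            if len(s) > cfg.max_seq_len:
                warnings.warn(f"sentence {s.id!r} truncated to {cfg.max_seq_len}")
                s = Sentence(s.id, s.tokens[:cfg.max_seq_len])
            clipped.append(s)
        if gold_entities is None:
            ent_sets: list[set[EntitySpan]] = []
            for lo in range(0, len(clipped), cfg.batch_size):
                ent_sets.extend(self.ner.predict_batch(
                    clipped[lo:lo + cfg.batch_size]))
        else:
            ent_sets = gold_entities
        # classify all candidate pairs, batched across sentences
        queries = []
        for si, (s, ents) in enumerate(zip(clipped, ent_sets)):
            for pair in _candidate_pairs(ents):
                queries.append((si, s, pair))
        labels: list[str] = []
        pb = 4 * cfg.batch_size
        for lo in range(0, len(queries), pb):
            chunk = queries[lo:lo + pb]
            labels.extend(self.classifier.classify(
                [q[1] for q in chunk], [q[2] for q in chunk]))
        rels_by_sentence: list[set[RelationTriple]] = [set() for _ in clipped]
        for (si, _, (a, b)), label in zip(queries, labels):
            if label == NONE_LABEL:
                continue
            triple = RelationTriple(label, a, b)
            if cfg.schema_filter and not triple.schema_valid():
                continue
            rels_by_sentence[si].add(triple)
        return [AnnotatedDocument(s, set(e), r)
                for s, e, r in zip(clipped, ent_sets, rels_by_sentence)]


# ---------------------------------------------------------------------------
# functional wrappers and checkpointing
# ---------------------------------------------------------------------------

def train_joint(train_docs, dev_docs=None, config=None,
                external_vectors=None) -> JointResults:
    return JointExtractorModel(train_docs, dev_docs, config,
                               external_vectors).fit()


def train_pipeline(train_docs, dev_docs=None, config=None) -> PipelineResults:
    return PipelineModel(train_docs, dev_docs, config).fit()


def predict(results: _ResultsBase,
            sentences: list[Sentence]) -> list[AnnotatedDocument]:
    return results.predict(sentences)


def save_checkpoint(results: _ResultsBase, directory: str | Path) -> None:
    """Write config + parameters + threshold to a checkpoint directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(results.config)
    meta = {"config": cfg, "threshold": results.threshold,
            "vocab": results.model.vocab}
    (directory / "checkpoint.json").write_text(
        json.dumps(meta, ensure_ascii=False), encoding="utf-8")
    (directory / "report.jsonl").write_text(results.report.to_json_lines(),
                                            encoding="utf-8")
    if isinstance(results, JointResults):
        np.savez(directory / "params.npz", **results.network.state_dict())
    else:
        np.savez(directory / "params_ner.npz", **results.ner.state_dict())
        np.savez(directory / "params_clf.npz",
                 **results.classifier.state_dict())


def load_checkpoint(directory: str | Path) -> _ResultsBase:
    directory = Path(directory)
    meta = json.loads((directory / "checkpoint.json").read_text(encoding="utf-8"))
    cfg = TrainConfig(**meta["config"])
    vocab = {k: int(v) for k, v in meta["vocab"].items()}
    rng = np.random.default_rng(cfg.seed)
    report = TrainReport(chosen_threshold=meta["threshold"])
    dummy_model = object.__new__(
        JointExtractorModel if cfg.mode == "joint" else PipelineModel)
    dummy_model.config = cfg
    dummy_model.vocab = vocab
    if cfg.mode == "joint":
        net = _JointNetwork(vocab, cfg, rng)
        net.load_state_dict(dict(np.load(directory / "params.npz")))
        net.eval()
        return JointResults(dummy_model, net, report, meta["threshold"])
    ner = _NERNetwork(vocab, cfg, rng)
    ner.load_state_dict(dict(np.load(directory / "params_ner.npz")))
    clf = _PairClassifier(vocab, cfg, rng)
    clf.load_state_dict(dict(np.load(directory / "params_clf.npz")))
    ner.eval()
    clf.eval()
    return PipelineResults(dummy_model, ner, clf, report)
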