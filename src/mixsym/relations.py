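"""Multihead-selection relation scoring.

Every token ``i`` may select, for every relation label ``r``, any number of
"head" tokens ``j`` (the last token of a target entity) via independent
sigmoid probabilities — this is what lets one entity participate in several
relations.  For each label ``r`` with parameters ``U_r, W_r, b_r, V_r`` the
pair score is

    s_r(z_j, z_i) = V_r . f(U_r z_j + W_r z_i + b_r),      f = tanh

and ``P(head=j, label=r | token i) = sigmoid(s_r(z_j, z_i))``.  The input
``z_i = [h_i, g_i]`` concatenates the encoder hidden state with a learned
embedding of the token's entity tag (the label embedding); ablating the label
embedding sets ``z_i = h_i``.

Tokens with no outgoing relation carry a gold ``none`` self-arc, so every
token contributes gold terms to the relation objective.  Two losses are
provided:

* :func:`relation_loss` — the per-gold-arc negative log-likelihood
  ``sum_i sum_{gold arcs of i} -log P(head, label | i)``;
* :func:`relation_bce` / :meth:`RelationScorer.bce_loss` — the full binary
  cross-entropy over all (i, j, label) cells, which additionally pushes
  non-gold probabilities toward 0.  Training uses the latter (with only the
  gold-arc terms, non-gold cells receive no gradient and threshold decoding
  is impossible); its gold terms coincide with :func:`relation_loss`.

Decoding keeps every cell with probability >= threshold whose dependent token
is the last token of a predicted entity, and converts kept arcs to relation
triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    NONE_LABEL,
    RELATION_LABELS,
    EntitySpan,
    RelationTriple,
    TokenArc,
    from_token_arcs,
)
from .nn import Linear, Module, Parameter, Tensor, glorot

#: scoring-label inventory: the real relation labels plus the reserved none
ARC_LABELS = RELATION_LABELS + (NONE_LABEL,)
NONE_INDEX = ARC_LABELS.index(NONE_LABEL)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (np.tanh(0.5 * x) + 1.0)


# ---------------------------------------------------------------------------
# functional (plain numpy) reference
# ---------------------------------------------------------------------------

@dataclass
class RelationParams:
    """Per-label scoring parameters; arrays indexed like :data:`ARC_LABELS`."""

    U: np.ndarray  # (R, d_z, d_r)
    W: np.ndarray  # (R, d_z, d_r)
    b: np.ndarray  # (R, d_r)
    V: np.ndarray  # (R, d_r)
    labels: tuple[str, ...] = field(default=ARC_LABELS)

    def __post_init__(self) -> None:
        R, d_z, d_r = self.U.shape
        if self.W.shape != (R, d_z, d_r) or self.b.shape != (R, d_r) \
                or self.V.shape != (R, d_r):
            raise ValueError("inconsistent relation-parameter dimensions")
        if len(self.labels) != R:
            raise ValueError(f"{len(self.labels)} labels but {R} parameter sets")
        if NONE_LABEL not in self.labels:
            raise ValueError("label inventory must include the reserved none label")


def relation_scores(z: np.ndarray, params: RelationParams) -> np.ndarray:
    """Pair scores ``s[i, j, k] = V_k . tanh(U_k z_j + W_k z_i + b_k)``.

    ``z``: (n, d_z) array of per-token relation inputs.  Returns (n, n, R).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != params.U.shape[1]:
        raise ValueError(
            f"z has shape {z.shape}, expected (n, {params.U.shape[1]})")
    zU = np.einsum("jd,rde->jre", z, params.U)   # head side
    zW = np.einsum("id,rde->ire", z, params.W)   # dependent side
    hidden = np.tanh(zU[None, :, :, :] + zW[:, None, :, :] + params.b[None, None])
    return np.einsum("ijre,re->ijr", hidden, params.V)


def relation_probabilities(scores: np.ndarray) -> np.ndarray:
    """Elementwise sigmoid; independent per cell (not normalized over heads)."""
    return _sigmoid(np.asarray(scores, dtype=float))


def relation_loss(probs: np.ndarray, gold_arcs: list[TokenArc],
                  labels: tuple[str, ...] = ARC_LABELS) -> float:
    """Sum over gold arcs of ``-log P(head, label | dependent)``."""
    probs = np.asarray(probs, dtype=float)
    n = probs.shape[0]
    idx = {l: k for k, l in enumerate(labels)}
    total = 0.0
    for a in gold_arcs:
        if not (0 <= a.dep < n and 0 <= a.head < n):
            raise ValueError(f"arc {a} out of range for sentence length {n}")
        total += -np.log(probs[a.dep, a.head, idx[a.label]])
    return float(total)


def relation_bce(scores: np.ndarray, gold_arcs: list[TokenArc],
                 labels: tuple[str, ...] = ARC_LABELS) -> float:
    """Binary cross-entropy over all (i, j, label) cells, from raw scores."""
    scores = np.asarray(scores, dtype=float)
    y = np.zeros_like(scores)
    idx = {l: k for k, l in enumerate(labels)}
    for a in gold_arcs:
        y[a.dep, a.head, idx[a.label]] = 1.0
    return float((np.logaddexp(0.0, scores) - y * scores).sum())


def decode_relations(probs: np.ndarray, threshold: float,
                     entities: set[EntitySpan],
                     labels: tuple[str, ...] = ARC_LABELS,
                     schema_filter: bool = False) -> set[RelationTriple]:
    """Threshold the probability tensor and convert kept arcs to triples.

    Only cells whose dependent token is the last token of a predicted entity
    are considered; the ``none`` label is never decoded.  With
    ``schema_filter`` type-inconsistent triples are dropped.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    probs = np.asarray(probs, dtype=float)
    last_tokens = {e.last_token for e in entities}
    arcs = []
    for i, j, k in zip(*np.nonzero(probs >= threshold)):
        if labels[k] == NONE_LABEL or int(i) not in last_tokens:
            continue
        arcs.append(TokenArc(int(i), int(j), labels[k]))
    triples = from_token_arcs(entities, arcs)
    if schema_filter:
        triples = {t for t in triples if t.schema_valid()}
    return triples


# ---------------------------------------------------------------------------
# trainable layers
# ---------------------------------------------------------------------------

class LabelEmbedding(Module):
    """Learned vector per entity tag, appended to the encoder state."""

    def __init__(self, n_tags: int, d_g: int, rng: np.random.Generator):
        super().__init__()
        self.n_tags, self.d_g = n_tags, d_g
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_tags, d_g)))

    def __call__(self, tag_ids: np.ndarray) -> Tensor:
        tag_ids = np.asarray(tag_ids)
        if tag_ids.size and (tag_ids.min() < 0 or tag_ids.max() >= self.n_tags):
            raise ValueError("tag id outside the tag inventory")
        from .nn import embedding
        return embedding(self.weight, tag_ids)


class RelationScorer(Module):
    """Batched trainable version of :func:`relation_scores`.

    Label-specific maps are stored stacked — ``U``/``W`` as
    ``(d_z, R * d_r)`` — so one matmul scores all labels at once.
    """

    def __init__(self, d_z: int, d_r: int, rng: np.random.Generator,
                 labels: tuple[str, ...] = ARC_LABELS):
        super().__init__()
        self.d_z, self.d_r = d_z, d_r
        self.labels = labels
        self.R = len(labels)
        self.U = Parameter(glorot(rng, (d_z, self.R * d_r)))
        self.W = Parameter(glorot(rng, (d_z, self.R * d_r)))
        self.b = Parameter(np.zeros(self.R * d_r))
        self.V = Parameter(glorot(rng, (self.R, d_r)))

    def __call__(self, z: Tensor) -> Tensor:
        """Scores (B, T, T, R) from relation inputs ``z`` of shape (B, T, d_z);
        cell [b, i, j, k] scores head ``j`` for dependent ``i`` under label k."""
        B, T, _ = z.shape
        zU = (z @ self.U).reshape(B, T, self.R, self.d_r)
        zW = (z @ self.W).reshape(B, T, self.R, self.d_r)
        bias = self.b.reshape(1, 1, 1, self.R, self.d_r)
        hidden = (zU.reshape(B, 1, T, self.R, self.d_r)
                  + zW.reshape(B, T, 1, self.R, self.d_r) + bias).tanh()
        return (hidden * self.V.reshape(1, 1, 1, self.R, self.d_r)).sum(axis=-1)

    def to_params(self) -> RelationParams:
        """Export as the functional per-label parameter container."""
        U = np.stack([self.U.data[:, k * self.d_r:(k + 1) * self.d_r]
                      for k in range(self.R)])
        W = np.stack([self.W.data[:, k * self.d_r:(k + 1) * self.d_r]
                      for k in range(self.R)])
        b = self.b.data.reshape(self.R, self.d_r)
        return RelationParams(U=U, W=W, b=b, V=self.V.data.copy(),
                              labels=self.labels)

    def bce_loss(self, scores: Tensor, gold: np.ndarray,
                 mask2d: np.ndarray) -> Tensor:
        """Masked binary cross-entropy from raw scores.

        ``gold``: (B, T, T, R) 0/1 targets; ``mask2d``: (B, T, T) validity of
        the (i, j) pair (both tokens real).
        """
        m = Tensor(mask2d[..., None])
        y = Tensor(gold)
        return ((scores.softplus() - y * scores) * m).sum()


def build_gold_arc_tensor(arc_lists: list[list[TokenArc]], T: int,
                          labels: tuple[str, ...] = ARC_LABELS) -> np.ndarray:
    """Stack per-sentence gold arcs into a (B, T, T, R) 0/1 target tensor."""
    idx = {l: k for k, l in enumerate(labels)}
    B = len(arc_lists)
    y = np.zeros((B, T, T, len(labels)))
    for b, arcs in enumerate(arc_lists):
        for a in arcs:
            y[b, a.dep, a.head, idx[a.label]] = 1.0
    return y
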