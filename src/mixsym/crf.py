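"""Linear-chain conditional random field for BIO entity tagging.

A tag path ``y_1..y_n`` is scored as

    score(y) = start[y_1] + sum_t emissions[t, y_t]
             + sum_t transitions[y_{t-1}, y_t] + stop[y_n]

and the model is the globally normalized distribution
``P(y|x) = exp(score(y)) / Z`` with ``log Z`` computed by the forward
recursion in ``O(n K^2)``.  Training minimizes the negative conditional
log-likelihood of the gold path (the NER loss); decoding is exact Viterbi
with ties broken toward the lowest tag index.

Two layers of API are provided: plain-numpy functions operating on explicit
score matrices (`crf_log_partition`, `crf_viterbi`, `crf_nll`, ...) and a
trainable :class:`CRFLayer` whose batched loss participates in autodiff.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .nn import Linear, Module, Parameter, Tensor


def _as_start_stop(K: int, start, stop):
    s0 = np.zeros(K) if start is None else np.asarray(start, dtype=float)
    s1 = np.zeros(K) if stop is None else np.asarray(stop, dtype=float)
    return s0, s1


def crf_path_score(emissions: np.ndarray, transitions: np.ndarray,
                   tags: list[int] | np.ndarray,
                   start: np.ndarray | None = None,
                   stop: np.ndarray | None = None) -> float:
    """Unnormalized log-score of one tag path."""
    em = np.asarray(emissions, dtype=float)
    n, K = em.shape
    tags = list(tags)
    if len(tags) != n:
        raise ValueError(f"path length {len(tags)} != sequence length {n}")
    s0, s1 = _as_start_stop(K, start, stop)
    score = s0[tags[0]] + s1[tags[-1]] + sum(em[t, y] for t, y in enumerate(tags))
    score += sum(transitions[a, b] for a, b in zip(tags, tags[1:]))
    return float(score)


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray,
                      start: np.ndarray | None = None,
                      stop: np.ndarray | None = None) -> float:
    """log of the sum over all ``K^n`` paths of ``exp(path score)``."""
    em = np.asarray(emissions, dtype=float)
    n, K = em.shape
    trans = np.asarray(transitions, dtype=float)
    s0, s1 = _as_start_stop(K, start, stop)
    alpha = s0 + em[0]
    for t in range(1, n):
        alpha = logsumexp(alpha[:, None] + trans, axis=0) + em[t]
    return float(logsumexp(alpha + s1))


def crf_viterbi(emissions: np.ndarray, transitions: np.ndarray,
                start: np.ndarray | None = None,
                stop: np.ndarray | None = None) -> list[int]:
    """Highest-scoring tag path; ties resolve to the lowest tag index."""
    em = np.asarray(emissions, dtype=float)
    n, K = em.shape
    trans = np.asarray(transitions, dtype=float)
    s0, s1 = _as_start_stop(K, start, stop)
    delta = s0 + em[0]
    back = np.zeros((n, K), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + trans  # (prev, cur)
        back[t] = np.argmax(cand, axis=0)  # argmax -> first (lowest) index
        delta = cand[back[t], np.arange(K)] + em[t]
    last = int(np.argmax(delta + s1))
    path = [last]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


def crf_nll(emissions: np.ndarray, transitions: np.ndarray,
            tags: list[int] | np.ndarray,
            start: np.ndarray | None = None,
            stop: np.ndarray | None = None) -> float:
    """Negative conditional log-likelihood of the gold path (>= 0)."""
    return crf_log_partition(emissions, transitions, start, stop) - \
        crf_path_score(emissions, transitions, tags, start, stop)


class CRFLayer(Module):
    """Trainable CRF over ``K`` tags with start/stop transitions."""

    def __init__(self, n_tags: int, rng: np.random.Generator):
        super().__init__()
        self.n_tags = n_tags
        self.transitions = Parameter(rng.normal(0.0, 0.01, size=(n_tags, n_tags)))
        self.start = Parameter(rng.normal(0.0, 0.01, size=n_tags))
        self.stop = Parameter(rng.normal(0.0, 0.01, size=n_tags))

    def nll(self, emissions: Tensor, tags: np.ndarray,
            mask: np.ndarray) -> Tensor:
        """Summed NLL over a padded batch.

        ``emissions``: (B, T, K) tensor; ``tags``: (B, T) int array;
        ``mask``: (B, T) 0/1 float array, right-padded.
        """
        B, T, K = emissions.shape
        lengths = mask.sum(axis=1).astype(int)
        batch = np.arange(B)

        # log-partition by masked forward recursion
        alpha = self.start.reshape(1, K) + emissions[:, 0, :]
        for t in range(1, T):
            prev = alpha.reshape(B, K, 1) + self.transitions.reshape(1, K, K)
            nxt = prev.logsumexp(axis=1) + emissions[:, t, :]
            m = Tensor(mask[:, t][:, None])
            alpha = m * nxt + Tensor(1.0 - mask[:, t][:, None]) * alpha
        logz = (alpha + self.stop.reshape(1, K)).logsumexp(axis=1)

        # gold path score
        gold = self.start[tags[:, 0]]
        gold = gold + (emissions[batch[:, None], np.arange(T)[None, :], tags]
                       * Tensor(mask)).sum(axis=1)
        if T > 1:
            tmask = Tensor(mask[:, 1:])
            gold = gold + (self.transitions[tags[:, :-1], tags[:, 1:]] * tmask).sum(axis=1)
        gold = gold + self.stop[tags[batch, lengths - 1]]
        return (logz - gold).sum()

    def decode(self, emissions: np.ndarray, mask: np.ndarray) -> list[list[int]]:
        """Viterbi decode a padded batch of raw emission scores."""
        lengths = mask.sum(axis=1).astype(int)
        out = []
        for b in range(emissions.shape[0]):
            n = int(lengths[b])
            out.append(crf_viterbi(emissions[b, :n], self.transitions.data,
                                   self.start.data, self.stop.data))
        return out


class EmissionHead(Module):
    """Linear projection from encoder states to per-tag emission scores."""

    def __init__(self, d_h: int, n_tags: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(d_h, n_tags, rng)

    def __call__(self, states: Tensor) -> Tensor:
        return self.proj(states)
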