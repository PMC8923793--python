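"""Token embedding and contextual sequence encoding.

Characters are mapped to vectors either by a trainable lookup table built
from the training corpus (unknown characters share a dedicated UNK row) or by
*external contextual* vectors precomputed per sentence by any outside encoder
(e.g. a fine-tuned transformer) and loaded from a plain-text file; computing
such vectors is out of scope here.  A bidirectional LSTM then produces one
hidden state ``h_i`` per token — the concatenation of the forward and
backward states — with dropout applied to the encoder output in training
mode only.

External-embedding file format: for each sentence, a line with the sentence
id, then ``n`` lines of ``d_emb`` whitespace-separated floats (one per
token), then a blank line.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .corpus import Sentence
from .nn import BiLSTM, Embedding, Module, Tensor, dropout

PAD_ID = 0
UNK_ID = 1


def build_char_vocab(sentences: list[Sentence]) -> dict[str, int]:
    """Character -> id map with reserved PAD (0) and UNK (1) rows."""
    vocab: dict[str, int] = {"<pad>": PAD_ID, "<unk>": UNK_ID}
    for sent in sentences:
        for tok in sent.tokens:
            if tok.text not in vocab:
                vocab[tok.text] = len(vocab)
    return vocab


def read_embedding_file(path: str | Path) -> dict[str, np.ndarray]:
    """Parse the external per-token embedding file into ``{sentence id: (n, d)}``."""
    out: dict[str, np.ndarray] = {}
    sid: str | None = None
    rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                if sid is not None:
                    out[sid] = np.asarray(rows, dtype=float)
                sid, rows = None, []
            elif sid is None:
                sid = line
            else:
                try:
                    rows.append([float(x) for x in line.split()])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric row") from exc
    if sid is not None:
        out[sid] = np.asarray(rows, dtype=float)
    return out


def write_embedding_file(vectors: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, arr in vectors.items():
            fh.write(sid + "\n")
            for row in np.asarray(arr, dtype=float):
                fh.write(" ".join(format(v, ".8g") for v in row) + "\n")
            fh.write("\n")


class EmbeddingSource(Module):
    """Maps token sequences to ``d_emb`` vectors.

    ``mode="trainable_lookup"``: a character embedding table (trained with the
    model).  ``mode="external_contextual"``: fixed per-sentence vectors keyed
    by sentence id, standing in for a pretrained contextual encoder.
    """

    def __init__(self, mode: str, d_emb: int,
                 vocab: dict[str, int] | None = None,
                 vectors: dict[str, np.ndarray] | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if mode not in ("trainable_lookup", "external_contextual"):
            raise ValueError(f"unknown embedding mode {mode!r}")
        self.mode = mode
        self.d_emb = d_emb
        if mode == "trainable_lookup":
            if vocab is None or rng is None:
                raise ValueError("lookup mode needs a vocabulary and an rng")
            self.vocab = vocab
            self.table = Embedding(len(vocab), d_emb, rng)
        else:
            if vectors is None:
                raise ValueError("external mode needs per-sentence vectors")
            self.vectors = vectors

    # -- single sentence (module contract) ---------------------------------

    def embed(self, sentence: Sentence) -> Tensor:
        """(n, d_emb) vectors for one sentence."""
        if self.mode == "trainable_lookup":
            ids = np.array([self.vocab.get(t.text, UNK_ID)
                            for t in sentence.tokens])
            return self.table(ids)
        if sentence.id not in self.vectors:
            raise KeyError(f"no external embeddings for sentence id {sentence.id!r}")
        arr = self.vectors[sentence.id]
        if arr.shape != (len(sentence), self.d_emb):
            raise ValueError(
                f"sentence {sentence.id!r}: embedding shape {arr.shape} != "
                f"({len(sentence)}, {self.d_emb})")
        return Tensor(arr)

    # -- padded batch --------------------------------------------------------

    def embed_batch(self, sentences: list[Sentence]) -> tuple[Tensor, np.ndarray]:
        """Right-padded (B, T, d_emb) tensor plus the (B, T) mask."""
        B = len(sentences)
        T = max(len(s) for s in sentences)
        mask = np.zeros((B, T))
        for b, s in enumerate(sentences):
            mask[b, :len(s)] = 1.0
        if self.mode == "trainable_lookup":
            ids = np.full((B, T), PAD_ID, dtype=int)
            for b, s in enumerate(sentences):
                ids[b, :len(s)] = [self.vocab.get(t.text, UNK_ID)
                                   for t in s.tokens]
            return self.table(ids), mask
        arr = np.zeros((B, T, self.d_emb))
        for b, s in enumerate(sentences):
            arr[b, :len(s)] = self.embed(s).data
        return Tensor(arr), mask


class SentenceEncoder(Module):
    """Embedding source + bidirectional LSTM; output dim ``d_h = 2 * d_lstm``."""

    def __init__(self, source: EmbeddingSource, d_lstm: int,
                 dropout_p: float, rng: np.random.Generator):
        super().__init__()
        self.source = source
        self.bilstm = BiLSTM(source.d_emb, d_lstm, rng)
        self.dropout_p = dropout_p
        self.d_h = 2 * d_lstm
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 31))

    def encode(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """(B, T, d_h) hidden states; dropout only in training mode."""
        if x.shape[1] < 1:
            raise ValueError("cannot encode an empty sequence")
        h = self.bilstm(x, mask)
        return dropout(h, self.dropout_p, self._drop_rng, self.training)

    def __call__(self, sentences: list[Sentence]) -> tuple[Tensor, np.ndarray]:
        x, mask = self.source.embed_batch(sentences)
        return self.encode(x, mask), mask
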