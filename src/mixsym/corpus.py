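"""Data model for annotated TCM symptom-mention corpora.

Sentences are sequences of single-character tokens.  Annotations follow a
three-entity / two-relation schema used to disassemble "mixture symptom
mentions": compound clinical phrases that pack several symptoms, body parts
and severity modifiers into one span (e.g. one severity adverb qualifying a
symptom that is located at two body parts).

Entity types
    symptom      the clinical finding itself
    body_part    anatomical location of a symptom
    severity     degree adverb qualifying a symptom

Relation labels
    located_at             symptom -> body_part
    is_a_description_of    severity -> symptom

Spans use 0-based half-open token offsets.  Relation arcs at the token level
("multihead" encoding) run from the last token of the dependent entity to the
last token of the head entity; tokens with no outgoing relation carry a single
``none`` self-arc so that every token contributes to the relation objective.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

ENTITY_TYPES = ("symptom", "body_part", "severity")
RELATION_LABELS = ("located_at", "is_a_description_of")
NONE_LABEL = "none"

#: dependent-entity type -> head-entity type required by each relation label
SCHEMA_DIRECTIONS = {
    "located_at": ("symptom", "body_part"),
    "is_a_description_of": ("severity", "symptom"),
}

DEFAULT_MAX_SEQ_LEN = 480

BIO_TAGS = ("O",) + tuple(
    f"{p}-{t}" for t in ENTITY_TYPES for p in ("B", "I")
)


class SchemaError(ValueError):
    """Raised when annotations violate the corpus schema."""


@dataclass(frozen=True)
class Token:
    """A single character of a sentence."""

    text: str
    index: int

    def __post_init__(self) -> None:
        if len(self.text) != 1:
            raise SchemaError(
                f"token text must be exactly one character, got {self.text!r}"
            )
        if self.index < 0:
            raise SchemaError("token index must be non-negative")


@dataclass(frozen=True)
class Sentence:
    """A character-tokenized sentence."""

    id: str
    tokens: tuple[Token, ...]

    @classmethod
    def from_text(cls, sid: str, text: str) -> "Sentence":
        return cls(sid, tuple(Token(c, i) for i, c in enumerate(text)))

    @property
    def text(self) -> str:
        return "".join(t.text for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise SchemaError(f"sentence {self.id!r} is empty")
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise SchemaError(
                    f"sentence {self.id!r}: token index {tok.index} at position {i}"
                )


@dataclass(frozen=True, order=True)
class EntitySpan:
    """An entity occupying tokens ``[start, end)`` of a sentence."""

    entity_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.entity_type not in ENTITY_TYPES:
            raise SchemaError(f"unknown entity type {self.entity_type!r}")
        if not (0 <= self.start < self.end):
            raise SchemaError(
                f"bad span [{self.start}, {self.end}) for {self.entity_type}"
            )

    @property
    def last_token(self) -> int:
        """Index of the final token — the 'head' position for relation arcs."""
        return self.end - 1

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True, order=True)
class RelationTriple:
    """A directed relation from a dependent entity to its head entity."""

    label: str
    source: EntitySpan
    target: EntitySpan

    def __post_init__(self) -> None:
        if self.label not in RELATION_LABELS:
            raise SchemaError(f"unknown relation label {self.label!r}")
        if self.source == self.target:
            raise SchemaError("relation source and target must differ")

    def schema_valid(self) -> bool:
        src_t, tgt_t = SCHEMA_DIRECTIONS[self.label]
        return self.source.entity_type == src_t and self.target.entity_type == tgt_t


@dataclass(frozen=True, order=True)
class TokenArc:
    """Token-level multihead arc: dependent token -> head token with a label.

    ``label == "none"`` marks the self-arc carried by tokens with no outgoing
    relation (then ``head == dep``).
    """

    dep: int
    head: int
    label: str

    def __post_init__(self) -> None:
        if self.label == NONE_LABEL:
            if self.head != self.dep:
                raise SchemaError("none arc must be a self-arc")
        elif self.label not in RELATION_LABELS:
            raise SchemaError(f"unknown arc label {self.label!r}")


@dataclass
class AnnotatedDocument:
    """A sentence plus its gold (or predicted) entities and relations."""

    sentence: Sentence
    entities: set[EntitySpan] = field(default_factory=set)
    relations: set[RelationTriple] = field(default_factory=set)

    @property
    def id(self) -> str:
        return self.sentence.id

    def validate(self, strict_schema: bool = False,
                 max_seq_len: int = DEFAULT_MAX_SEQ_LEN) -> None:
        """Check structural invariants; raise :class:`SchemaError` on failure.

        With ``strict_schema`` the relation-direction rules are enforced and a
        warning is emitted for relation-free body_part / severity entities
        (legal only for symptoms in the annotation guidelines).
        """
        n = len(self.sentence)
        if n > max_seq_len:
            raise SchemaError(f"doc {self.id!r}: length {n} > {max_seq_len}")
        spans = sorted(self.entities)
        for a, b in zip(spans, spans[1:]):
            if a.overlaps(b):
                raise SchemaError(f"doc {self.id!r}: overlapping spans {a} / {b}")
        for e in spans:
            if e.end > n:
                raise SchemaError(f"doc {self.id!r}: span {e} exceeds length {n}")
        for r in self.relations:
            if r.source not in self.entities or r.target not in self.entities:
                raise SchemaError(
                    f"doc {self.id!r}: relation endpoint not among entities: {r}"
                )
            if strict_schema and not r.schema_valid():
                raise SchemaError(f"doc {self.id!r}: schema-invalid relation {r}")
        if strict_schema:
            linked = {r.source for r in self.relations} | {
                r.target for r in self.relations
            }
            for e in self.entities:
                if e.entity_type != "symptom" and e not in linked:
                    warnings.warn(
                        f"doc {self.id!r}: relation-free {e.entity_type} entity {e}",
                        stacklevel=2,
                    )


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------

def encode_bio(sentence: Sentence, entities: set[EntitySpan]) -> list[str]:
    """Encode non-overlapping spans as a BIO tag sequence of length ``n``."""
    n = len(sentence)
    tags = ["O"] * n
    for e in sorted(entities):
        if e.end > n:
            raise SchemaError(f"span {e} exceeds sentence length {n}")
        for i in range(e.start, e.end):
            if tags[i] != "O":
                raise SchemaError(f"overlapping spans at token {i}")
            tags[i] = ("B-" if i == e.start else "I-") + e.entity_type
    return tags


def decode_bio(tags: list[str]) -> set[EntitySpan]:
    """Decode BIO tags to spans.

    Ill-formed sequences are repaired deterministically: an ``I-x`` with no
    open ``x`` span (after ``O``, at sentence start, or after a different
    type) is treated as ``B-x``.
    """
    for t in tags:
        if t != "O" and (len(t) < 3 or t[:2] not in ("B-", "I-")
                         or t[2:] not in ENTITY_TYPES):
            raise SchemaError(f"unknown BIO tag {t!r}")
    spans: set[EntitySpan] = set()
    start = None
    cur_type = None
    for i, t in enumerate(tags):
        if t == "O":
            if start is not None:
                spans.add(EntitySpan(cur_type, start, i))
                start = None
        elif t.startswith("B-") or (start is None or t[2:] != cur_type):
            if start is not None:
                spans.add(EntitySpan(cur_type, start, i))
            start, cur_type = i, t[2:]
        # else: I- continuing the open span of the same type
    if start is not None:
        spans.add(EntitySpan(cur_type, start, len(tags)))
    return spans


# ---------------------------------------------------------------------------
# Token-arc (multihead) encoding
# ---------------------------------------------------------------------------

def to_token_arcs(doc: AnnotatedDocument) -> list[TokenArc]:
    """Project span-level relations to token-level multihead arcs.

    Each relation becomes an arc from the last token of its dependent entity
    to the last token of its head entity; every token without an outgoing
    labeled arc gets one ``none`` self-arc.  A token may carry several labeled
    arcs (relation overlap).
    """
    arcs: list[TokenArc] = []
    has_out = [False] * len(doc.sentence)
    for r in sorted(doc.relations):
        dep = r.source.last_token
        arcs.append(TokenArc(dep, r.target.last_token, r.label))
        has_out[dep] = True
    for i, out in enumerate(has_out):
        if not out:
            arcs.append(TokenArc(i, i, NONE_LABEL))
    return sorted(arcs)


def from_token_arcs(entities: set[EntitySpan],
                    arcs: list[TokenArc]) -> set[RelationTriple]:
    """Inverse of :func:`to_token_arcs` given a set of (predicted) entities.

    ``none`` arcs and arcs whose endpoints are not the last token of any known
    entity are dropped.
    """
    by_last = {e.last_token: e for e in entities}
    triples: set[RelationTriple] = set()
    for a in arcs:
        if a.label == NONE_LABEL:
            continue
        src = by_last.get(a.dep)
        tgt = by_last.get(a.head)
        if src is None or tgt is None or src == tgt:
            continue
        triples.add(RelationTriple(a.label, src, tgt))
    return triples


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------

@dataclass
class CorpusStats:
    """Entity/relation counts with percentages, plus the relation-degree
    histogram (how many relations each entity participates in, as source or
    target)."""

    entity_counts: dict[str, int]
    entity_percentages: dict[str, float]
    relation_counts: dict[str, int]
    relation_percentages: dict[str, float]
    degree_histogram: dict[int, int]
    degree_percentages: dict[int, float]

    @property
    def n_entities(self) -> int:
        return sum(self.entity_counts.values())

    @property
    def n_relations(self) -> int:
        return sum(self.relation_counts.values())

    def overlap_fraction(self) -> float:
        """Percentage of entities participating in >= 2 relations."""
        total = sum(self.degree_histogram.values())
        if total == 0:
            return 0.0
        ge2 = sum(c for d, c in self.degree_histogram.items() if d >= 2)
        return 100.0 * ge2 / total

    def to_dict(self) -> dict:
        return {
            "entities": {
                t: {"count": self.entity_counts.get(t, 0),
                    "percentage": self.entity_percentages.get(t, 0.0)}
                for t in sorted(self.entity_counts)
            },
            "relations": {
                l: {"count": self.relation_counts.get(l, 0),
                    "percentage": self.relation_percentages.get(l, 0.0)}
                for l in sorted(self.relation_counts)
            },
            "degree_histogram": {
                str(d): {"count": self.degree_histogram[d],
                         "percentage": self.degree_percentages[d]}
                for d in sorted(self.degree_histogram)
            },
            "totals": {"entities": self.n_entities,
                       "relations": self.n_relations},
        }


def percentages(counts: dict, ndigits: int = 2) -> dict:
    """Counts -> percentages of the total, rounded to ``ndigits`` decimals."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: round(100.0 * v / total, ndigits) for k, v in counts.items()}


def corpus_statistics(docs: list[AnnotatedDocument]) -> CorpusStats:
    """Tabulate entity-type, relation-label and relation-degree distributions."""
    ent_counts: Counter = Counter()
    rel_counts: Counter = Counter()
    degree: Counter = Counter()
    for doc in docs:
        per_entity: dict[EntitySpan, int] = defaultdict(int)
        for e in doc.entities:
            ent_counts[e.entity_type] += 1
            per_entity[e] = 0
        for r in doc.relations:
            rel_counts[r.label] += 1
            per_entity[r.source] += 1
            per_entity[r.target] += 1
        for d in per_entity.values():
            degree[d] += 1
    return CorpusStats(
        entity_counts=dict(ent_counts),
        entity_percentages=percentages(ent_counts, 2),
        relation_counts=dict(rel_counts),
        relation_percentages=percentages(rel_counts, 2),
        degree_histogram=dict(degree),
        degree_percentages=percentages(degree, 3),
    )


def stats_from_counts(entity_counts: dict[str, int],
                      relation_counts: dict[str, int],
                      degree_histogram: dict[int, int]) -> CorpusStats:
    """Build :class:`CorpusStats` directly from count tables (e.g. a published
    annotation summary) without a document collection."""
    return CorpusStats(
        entity_counts=dict(entity_counts),
        entity_percentages=percentages(entity_counts, 2),
        relation_counts=dict(relation_counts),
        relation_percentages=percentages(relation_counts, 2),
        degree_histogram=dict(degree_histogram),
        degree_percentages=percentages(degree_histogram, 3),
    )


def truncate_document(doc: AnnotatedDocument, max_len: int) -> AnnotatedDocument:
    """Clip a document to its first ``max_len`` tokens, dropping annotations
    that no longer fit."""
    if len(doc.sentence) <= max_len:
        return doc
    warnings.warn(f"doc {doc.id!r}: truncating to {max_len} tokens", stacklevel=2)
    sent = Sentence(doc.sentence.id, doc.sentence.tokens[:max_len])
    ents = {e for e in doc.entities if e.end <= max_len}
    rels = {r for r in doc.relations if r.source in ents and r.target in ents}
    return AnnotatedDocument(sent, ents, rels)
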