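"""Synthetic annotated-corpus generator.

Real annotated TCM clinical notes are licensed and cannot be redistributed,
so training, ablation and evaluation run on generated corpora that reproduce
the statistical structure of such an annotation project: the entity-type mix
(symptom / body_part / severity), the relation-label mix (located_at /
is_a_description_of) and — the property that matters for overlapping-relation
extraction — the per-entity relation-degree distribution (how many relations
each entity participates in, with a configurable mass at degree >= 2).

Sentences are built from *mention groups*, each drawn from a small template
inventory: a lone symptom, a symptom located at ``k`` body parts with or
without a severity modifier (the classic mixture mention — one severity and
one symptom shared across coordinated body parts), a body part shared by two
symptoms, and a severity shared by two symptoms.  Every template contributes
a known vector of entity types, relation labels and entity degrees, so
template frequencies can be *calibrated* to any requested target
distributions by non-negative least squares; the defaults target the printed
statistics of a large clinical annotation effort (56.26/36.8/6.94% entity
types, 86.81/13.19% relation labels, 16.658% of entities in >= 2 relations).

Surface forms use disjoint per-type character alphabets and fixed word
lengths, so entity boundaries, types and relation arcs are a deterministic
function of the surface string — a correct model can reach near-perfect F1.
This is intentionally easier than real clinical prose; see docs/methods.md.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .corpus import (
    AnnotatedDocument,
    EntitySpan,
    RelationTriple,
    Sentence,
)

# ---------------------------------------------------------------------------
# default target distributions (annotated-corpus statistics)
# ---------------------------------------------------------------------------

DEFAULT_ENTITY_TYPE_MIX = {
    "symptom": 0.5626,
    "body_part": 0.3680,
    "severity": 0.0694,
}
DEFAULT_RELATION_LABEL_MIX = {
    "located_at": 0.8681,
    "is_a_description_of": 0.1319,
}
DEFAULT_DEGREE_DISTRIBUTION = {
    0: 0.06456,
    1: 0.76886,
    2: 0.14249,
    3: 0.01975,
    4: 0.00331,
    5: 0.00089,
    6: 0.00010,
    7: 0.00004,
}

MAX_DEGREE = 7


# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

@dataclass
class Vocabulary:
    """Closed surface vocabulary with disjoint per-type character alphabets.

    Word lengths are fixed per type (body 2, symptom 2, severity 1 character)
    so that concatenated mentions segment unambiguously.
    """

    body_words: list[str]
    symptom_words: list[str]
    severity_words: list[str]
    separator: str = "，"   # full-width comma between mention groups
    terminator: str = "。"  # full-width stop at sentence end

    def words(self, entity_type: str) -> list[str]:
        return {"symptom": self.symptom_words, "body_part": self.body_words,
                "severity": self.severity_words}[entity_type]


def default_vocabulary() -> Vocabulary:
    """Deterministic pseudo-Chinese vocabulary from three disjoint CJK blocks."""
    body_alpha = [chr(0x4E00 + i) for i in range(16)]
    symptom_alpha = [chr(0x75B0 + i) for i in range(16)]
    severity_alpha = [chr(0x5F00 + i) for i in range(8)]
    rng = np.random.default_rng(758203)  # fixed: vocabulary is part of the task
    pairs = list(itertools.product(range(16), repeat=2))
    body_idx = rng.choice(len(pairs), size=24, replace=False)
    sym_idx = rng.choice(len(pairs), size=40, replace=False)
    return Vocabulary(
        body_words=[body_alpha[pairs[i][0]] + body_alpha[pairs[i][1]]
                    for i in body_idx],
        symptom_words=[symptom_alpha[pairs[i][0]] + symptom_alpha[pairs[i][1]]
                       for i in sym_idx],
        severity_words=list(severity_alpha),
    )


# ---------------------------------------------------------------------------
# mention-group templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Template:
    """A mention-group pattern with its deterministic annotation structure.

    ``entity_types``: surface order of entity words.
    ``relations``: (label, source position, target position) over that order.
    """

    name: str
    entity_types: tuple[str, ...]
    relations: tuple[tuple[str, int, int], ...]

    def degree_of(self, pos: int) -> int:
        return sum(1 for _, s, t in self.relations if s == pos or t == pos)

    @property
    def n_entities(self) -> int:
        return len(self.entity_types)


def _sym_k_bodies(k: int, with_severity: bool) -> Template:
    """k body parts (+ optional severity) modifying one symptom:
    surface ``B1 .. Bk [V] S`` with located_at(S -> Bi) and
    is_a_description_of(V -> S)."""
    types = ["body_part"] * k
    rels = []
    if with_severity:
        types.append("severity")
    types.append("symptom")
    sym = len(types) - 1
    for b in range(k):
        rels.append(("located_at", sym, b))
    if with_severity:
        rels.append(("is_a_description_of", k, sym))
    return Template(f"sym{k}b{'v' if with_severity else ''}",
                    tuple(types), tuple(rels))


def build_templates() -> list[Template]:
    ts = [Template("lone", ("symptom",), ())]
    for k in range(0, MAX_DEGREE + 1):
        for v in (False, True):
            d = k + (1 if v else 0)
            if 1 <= d <= MAX_DEGREE:
                ts.append(_sym_k_bodies(k, v))
    # body shared by two symptoms: B S1 S2
    ts.append(Template("shared_body", ("body_part", "symptom", "symptom"),
                       (("located_at", 1, 0), ("located_at", 2, 0))))
    # shared body, first symptom qualified: B V S1 S2
    ts.append(Template(
        "shared_body_sev", ("body_part", "severity", "symptom", "symptom"),
        (("located_at", 2, 0), ("located_at", 3, 0),
         ("is_a_description_of", 1, 2))))
    # severity shared by two symptoms, no body: S1 S2 V
    ts.append(Template("shared_sev", ("symptom", "symptom", "severity"),
                       (("is_a_description_of", 2, 0),
                        ("is_a_description_of", 2, 1))))
    # two located symptoms whose shared severity closes the group:
    # B1 S1 B2 S2 V
    ts.append(Template(
        "shared_sev_body",
        ("body_part", "symptom", "body_part", "symptom", "severity"),
        (("located_at", 1, 0), ("located_at", 3, 2),
         ("is_a_description_of", 4, 1), ("is_a_description_of", 4, 3))))
    return ts


TEMPLATES = build_templates()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    n_sentences: int = 1000
    entity_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_TYPE_MIX))
    relation_label_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RELATION_LABEL_MIX))
    degree_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DEGREE_DISTRIBUTION))
    noise: float = 0.0  # probability of an extra relation-free distractor sentence
    vocabulary: Vocabulary = field(default_factory=default_vocabulary)
    seed: int = 0
    #: distribution of mention groups per sentence
    groups_per_sentence: tuple[float, ...] = (0.45, 0.35, 0.20)

    def validate(self) -> None:
        if self.n_sentences < 0:
            raise ValueError("n_sentences must be >= 0")
        for name, dist in (("entity_type_mix", self.entity_type_mix),
                           ("relation_label_mix", self.relation_label_mix),
                           ("degree_distribution", self.degree_distribution)):
            s = sum(dist.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {s}, expected 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has a negative probability")
        if not (0.0 <= self.noise < 1.0):
            raise ValueError("noise must lie in [0, 1)")
        for t, p in self.entity_type_mix.items():
            if p > 0 and not self.vocabulary.words(t):
                raise ValueError(f"empty vocabulary for entity type {t!r}")
        if max(self.degree_distribution) > MAX_DEGREE:
            raise ValueError(f"degrees above {MAX_DEGREE} are not supported")


def default_config(n_sentences: int = 1000, seed: int = 0) -> GeneratorConfig:
    """Defaults mirroring the reference annotated-corpus statistics."""
    return GeneratorConfig(n_sentences=n_sentences, seed=seed)


# ---------------------------------------------------------------------------
# template-frequency calibration
# ---------------------------------------------------------------------------

def template_weights(config: GeneratorConfig,
                     templates: list[Template] = TEMPLATES) -> np.ndarray:
    """Template sampling probabilities matching the configured distributions.

    Solves a non-negative least-squares moment problem: each template
    contributes fixed counts of entity types, relation labels and entity
    degrees, and the mixture is chosen so the induced proportions match the
    configured ones.  Degree rows are weighted hardest (the overlap statistic
    is the point of the generator); type and label rows are soft.
    """
    _n_all = len(templates)
    p_deg = np.array([config.degree_distribution.get(d, 0.0)
                      for d in range(MAX_DEGREE + 1)])
    p_typ = config.entity_type_mix
    p_lab = config.relation_label_mix

    # hard feasibility: a template containing an entity degree whose target
    # probability is zero can never be sampled
    feasible = [i for i, tpl in enumerate(templates)
                if all(p_deg[tpl.degree_of(pos)] > 0.0
                       for pos in range(tpl.n_entities))]
    if not feasible:
        raise ValueError("calibration failed: no template fits the "
                         "requested degree distribution")
    templates = [templates[i] for i in feasible]

    rows, targets, weights = [], [], []
    n_t = len(templates)

    def counts(tpl: Template):
        type_c = {t: tpl.entity_types.count(t)
                  for t in ("symptom", "body_part", "severity")}
        lab_c = {l: sum(1 for lab, _, _ in tpl.relations if lab == l)
                 for l in ("located_at", "is_a_description_of")}
        deg_c = np.zeros(MAX_DEGREE + 1)
        for pos in range(tpl.n_entities):
            deg_c[tpl.degree_of(pos)] += 1
        return type_c, lab_c, deg_c

    per_tpl = [counts(t) for t in templates]
    ents = np.array([t.n_entities for t in templates], dtype=float)
    rels = np.array([len(t.relations) for t in templates], dtype=float)

    for d in range(MAX_DEGREE + 1):
        rows.append(np.array([per_tpl[i][2][d] for i in range(n_t)]) - p_deg[d] * ents)
        targets.append(0.0)
        weights.append(100.0)
    for t, p in p_typ.items():
        rows.append(np.array([per_tpl[i][0][t] for i in range(n_t)]) - p * ents)
        targets.append(0.0)
        weights.append(10.0)
    for l, p in p_lab.items():
        rows.append(np.array([per_tpl[i][1][l] for i in range(n_t)]) - p * rels)
        targets.append(0.0)
        weights.append(10.0)
    rows.append(ents)
    targets.append(1.0)
    weights.append(10.0)

    A = np.asarray(rows) * np.asarray(weights)[:, None]
    b = np.asarray(targets) * np.asarray(weights)
    sol = lsq_linear(A, b, bounds=(0.0, np.inf), tol=1e-12)
    w = np.maximum(sol.x, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("calibration failed: no feasible template mixture")
    full = np.zeros(_n_all)
    for i, wi in zip(feasible, w / total):
        full[i] = wi
    return full


def induced_distributions(weights: np.ndarray,
                          templates: list[Template] = TEMPLATES):
    """Expected entity-type / relation-label / degree proportions implied by
    template sampling probabilities (sampling noise aside)."""
    type_c: dict[str, float] = {t: 0.0 for t in ("symptom", "body_part", "severity")}
    lab_c: dict[str, float] = {l: 0.0
                               for l in ("located_at", "is_a_description_of")}
    deg_c = np.zeros(MAX_DEGREE + 1)
    for w, tpl in zip(weights, templates):
        for t in tpl.entity_types:
            type_c[t] += w
        for lab, _, _ in tpl.relations:
            lab_c[lab] += w
        for pos in range(tpl.n_entities):
            deg_c[tpl.degree_of(pos)] += w
    n_e = sum(type_c.values())
    n_r = sum(lab_c.values())
    return (
        {t: c / n_e for t, c in type_c.items()},
        {l: c / n_r if n_r else 0.0 for l, c in lab_c.items()},
        {d: deg_c[d] / n_e for d in range(MAX_DEGREE + 1)},
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _realize_group(tpl: Template, vocab: Vocabulary,
                   rng: np.random.Generator, offset: int):
    """Render one template instance starting at token ``offset``."""
    text_parts: list[str] = []
    spans: list[EntitySpan] = []
    pos = offset
    for etype in tpl.entity_types:
        word = vocab.words(etype)[int(rng.integers(len(vocab.words(etype))))]
        spans.append(EntitySpan(etype, pos, pos + len(word)))
        text_parts.append(word)
        pos += len(word)
    rels = {RelationTriple(lab, spans[s], spans[t])
            for lab, s, t in tpl.relations}
    return "".join(text_parts), spans, rels


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedDocument]:
    """Generate a schema-valid corpus; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    weights = template_weights(config)
    gps = np.asarray(config.groups_per_sentence, dtype=float)
    gps = gps / gps.sum()
    lone = next(i for i, t in enumerate(TEMPLATES) if t.name == "lone")

    docs: list[AnnotatedDocument] = []
    for i in range(config.n_sentences):
        distractor = config.noise > 0.0 and rng.random() < config.noise
        n_groups = 1 + int(rng.choice(len(gps), p=gps))
        parts: list[str] = []
        entities: set[EntitySpan] = set()
        relations: set[RelationTriple] = set()
        offset = 0
        for g in range(n_groups):
            if g > 0:
                parts.append(config.vocabulary.separator)
                offset += 1
            tix = lone if distractor else int(rng.choice(len(weights), p=weights))
            text, spans, rels = _realize_group(TEMPLATES[tix],
                                               config.vocabulary, rng, offset)
            parts.append(text)
            entities.update(spans)
            relations.update(rels)
            offset += len(text)
        parts.append(config.vocabulary.terminator)
        sent = Sentence.from_text(f"syn-{i:06d}", "".join(parts))
        doc = AnnotatedDocument(sent, entities, relations)
        docs.append(doc)
    return docs


def train_dev_test_split(docs: list[AnnotatedDocument], seed: int,
                         fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)):
    """Shuffle with ``seed`` and split by sentence into train/dev/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    order = np.random.default_rng(seed).permutation(len(docs))
    shuffled = [docs[i] for i in order]
    n = len(docs)
    n_train = int(round(fractions[0] * n))
    n_dev = int(round(fractions[1] * n))
    return (shuffled[:n_train], shuffled[n_train:n_train + n_dev],
            shuffled[n_train + n_dev:])
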