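"""Strict-match precision / recall / F1 for entities and relations.

An entity prediction counts as a true positive iff its type, start and end
all match a gold entity exactly; a relation counts iff its label matches and
both endpoint entities match exactly (type and span) in the correct
direction.  An undirected mode is available for schemas with uncertain
relation direction.  Relation metrics can additionally be stratified by the
gold relation-degree of the endpoints, isolating performance on overlapping
relations (entities participating in >= 2 relations).
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import (
    ENTITY_TYPES,
    RELATION_LABELS,
    AnnotatedDocument,
    EntitySpan,
)

OVERLAP_BUCKETS = ("0", "1", "2+")


@dataclass
class PRF:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def add(self, other: "PRF") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn

    def as_dict(self) -> dict[str, float]:
        return {"precision": self.precision, "recall": self.recall,
                "f1": self.f1, "tp": self.tp, "fp": self.fp, "fn": self.fn}


def _paired(gold_docs: list[AnnotatedDocument],
            pred_docs: list[AnnotatedDocument]):
    gold_by_id = {d.id: d for d in gold_docs}
    pred_by_id = {d.id: d for d in pred_docs}
    if set(gold_by_id) != set(pred_by_id):
        missing = set(gold_by_id) ^ set(pred_by_id)
        raise ValueError(f"gold/pred document ids differ; e.g. {sorted(missing)[:3]}")
    return [(gold_by_id[i], pred_by_id[i]) for i in sorted(gold_by_id)]


def entity_prf(gold_docs: list[AnnotatedDocument],
               pred_docs: list[AnnotatedDocument]) -> dict[str, PRF]:
    """Strict entity PRF per type plus pooled micro counts."""
    out: dict[str, PRF] = {t: PRF() for t in ENTITY_TYPES}
    out["micro"] = PRF()
    for gold, pred in _paired(gold_docs, pred_docs):
        for t in ENTITY_TYPES:
            g = {e for e in gold.entities if e.entity_type == t}
            p = {e for e in pred.entities if e.entity_type == t}
            cell = PRF(tp=len(g & p), fp=len(p - g), fn=len(g - p))
            out[t].add(cell)
            out["micro"].add(cell)
    return out


def _rel_key(r, directed: bool):
    if directed:
        return (r.label, r.source, r.target)
    return (r.label, frozenset((r.source, r.target)))


def relation_prf(gold_docs: list[AnnotatedDocument],
                 pred_docs: list[AnnotatedDocument],
                 directed: bool = True) -> dict[str, PRF]:
    """Strict relation PRF per label plus pooled micro counts."""
    out: dict[str, PRF] = {l: PRF() for l in RELATION_LABELS}
    out["micro"] = PRF()
    for gold, pred in _paired(gold_docs, pred_docs):
        for l in RELATION_LABELS:
            g = {_rel_key(r, directed) for r in gold.relations if r.label == l}
            p = {_rel_key(r, directed) for r in pred.relations if r.label == l}
            cell = PRF(tp=len(g & p), fp=len(p - g), fn=len(g - p))
            out[l].add(cell)
            out["micro"].add(cell)
    return out


def _gold_degrees(doc: AnnotatedDocument) -> dict[EntitySpan, int]:
    deg = {e: 0 for e in doc.entities}
    for r in doc.relations:
        deg[r.source] += 1
        deg[r.target] += 1
    return deg


def _bucket(degree: int) -> str:
    return "2+" if degree >= 2 else str(degree)


def overlap_stratified(gold_docs: list[AnnotatedDocument],
                       pred_docs: list[AnnotatedDocument],
                       directed: bool = True) -> dict[str, PRF]:
    """Relation PRF per gold-degree bucket of the relation's endpoints.

    A relation is assigned the bucket of the *maximum* gold degree of its two
    endpoint entities; predicted relations with an endpoint that is not a gold
    entity fall into bucket "0".
    """
    out = {b: PRF() for b in OVERLAP_BUCKETS}
    for gold, pred in _paired(gold_docs, pred_docs):
        deg = _gold_degrees(gold)

        def bucket_of(r) -> str:
            if r.source not in deg or r.target not in deg:
                return "0"
            return _bucket(max(deg[r.source], deg[r.target]))

        g_by_b: dict[str, set] = {b: set() for b in OVERLAP_BUCKETS}
        p_by_b: dict[str, set] = {b: set() for b in OVERLAP_BUCKETS}
        for r in gold.relations:
            g_by_b[bucket_of(r)].add(_rel_key(r, directed))
        for r in pred.relations:
            p_by_b[bucket_of(r)].add(_rel_key(r, directed))
        for b in OVERLAP_BUCKETS:
            out[b].add(PRF(tp=len(g_by_b[b] & p_by_b[b]),
                           fp=len(p_by_b[b] - g_by_b[b]),
                           fn=len(g_by_b[b] - p_by_b[b])))
    return out


def evaluation_report(gold_docs: list[AnnotatedDocument],
                      pred_docs: list[AnnotatedDocument],
                      directed: bool = True) -> dict:
    """Full JSON-ready report: entity, relation and overlap-stratified PRF."""
    return {
        "matching": "strict span; relations require exact endpoints"
                    + (" and direction" if directed else " (undirected)"),
        "entities": {k: v.as_dict()
                     for k, v in entity_prf(gold_docs, pred_docs).items()},
        "relations": {k: v.as_dict()
                      for k, v in relation_prf(gold_docs, pred_docs,
                                               directed).items()},
        "overlap": {k: v.as_dict()
                    for k, v in overlap_stratified(gold_docs, pred_docs,
                                                   directed).items()},
    }


def format_report(report: dict) -> str:
    """Aligned-column text rendering of :func:`evaluation_report`."""
    lines = [f"strict-match evaluation ({report['matching']})",
             f"{'':22s}{'F1':>8s}{'Prec':>8s}{'Rec':>8s}{'TP':>7s}{'FP':>7s}{'FN':>7s}"]
    for section in ("entities", "relations", "overlap"):
        lines.append(section)
        for name, m in report[section].items():
            lines.append(
                f"  {name:20s}{m['f1']:8.4f}{m['precision']:8.4f}"
                f"{m['recall']:8.4f}{m['tp']:7d}{m['fp']:7d}{m['fn']:7d}")
    return "\n".join(lines)
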