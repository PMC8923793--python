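"""Corpus serialization.

Three interchange formats are supported:

* **standoff JSON** (read/write, the native format): one JSON object per line,
  ``{"id", "text", "entities": [{"id","type","start","end"}], "relations":
  [{"label","source_id","target_id"}]}``.  Offsets are character offsets into
  ``text``; tokens are single characters so character and token offsets
  coincide.
* **CoNLL-style TSV** (read/write): one token per row — token, BIO tag,
  space-separated head token indices, space-separated relation labels — with a
  blank line between sentences (the multihead export convention).
* **BRAT standoff** ``.ann`` (import only): ``T``/``R`` lines against a ``.txt``
  file with one sentence per line.
"""

from __future__ import annotations

import json
from pathlib import Path

from .corpus import (
    NONE_LABEL,
    AnnotatedDocument,
    EntitySpan,
    RelationTriple,
    SchemaError,
    Sentence,
    TokenArc,
    decode_bio,
    encode_bio,
    from_token_arcs,
    to_token_arcs,
)

FORMATS = ("json", "tsv")


class CorpusFormatError(ValueError):
    """Malformed corpus file; the message names the offending record."""


# ---------------------------------------------------------------------------
# standoff JSON
# ---------------------------------------------------------------------------

def doc_to_record(doc: AnnotatedDocument) -> dict:
    ents = sorted(doc.entities)
    ent_ids = {e: f"T{i + 1}" for i, e in enumerate(ents)}
    return {
        "id": doc.id,
        "text": doc.sentence.text,
        "entities": [
            {"id": ent_ids[e], "type": e.entity_type,
             "start": e.start, "end": e.end}
            for e in ents
        ],
        "relations": [
            {"label": r.label, "source_id": ent_ids[r.source],
             "target_id": ent_ids[r.target]}
            for r in sorted(doc.relations)
        ],
    }


def doc_from_record(record: dict, where: str = "?") -> AnnotatedDocument:
    try:
        sent = Sentence.from_text(record["id"], record["text"])
        by_id: dict[str, EntitySpan] = {}
        for e in record.get("entities", []):
            by_id[e["id"]] = EntitySpan(e["type"], e["start"], e["end"])
        rels = {
            RelationTriple(r["label"], by_id[r["source_id"]],
                           by_id[r["target_id"]])
            for r in record.get("relations", [])
        }
        return AnnotatedDocument(sent, set(by_id.values()), rels)
    except (KeyError, SchemaError, TypeError) as exc:
        raise CorpusFormatError(f"{where}: bad record ({exc})") from exc


def read_json(path: str | Path) -> list[AnnotatedDocument]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: not JSON ({exc})") from exc
            docs.append(doc_from_record(record, where=f"{path}:{lineno}"))
    return docs


def write_json(docs: list[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc_to_record(doc), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# CoNLL-style TSV (token, BIO, heads, labels)
# ---------------------------------------------------------------------------

def write_tsv(docs: list[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            tags = encode_bio(doc.sentence, doc.entities)
            arcs_by_dep: dict[int, list[TokenArc]] = {}
            for a in to_token_arcs(doc):
                arcs_by_dep.setdefault(a.dep, []).append(a)
            fh.write(f"#id {doc.id}\n")
            for tok, tag in zip(doc.sentence.tokens, tags):
                arcs = sorted(arcs_by_dep[tok.index])
                heads = " ".join(str(a.head) for a in arcs)
                labels = " ".join(a.label for a in arcs)
                fh.write(f"{tok.text}\t{tag}\t{heads}\t{labels}\n")
            fh.write("\n")


def read_tsv(path: str | Path) -> list[AnnotatedDocument]:
    docs: list[AnnotatedDocument] = []
    rows: list[tuple[str, str, str, str]] = []
    sid: str | None = None

    def flush(where: str) -> None:
        nonlocal rows, sid
        if not rows:
            sid = None
            return
        text = "".join(r[0] for r in rows)
        sent = Sentence.from_text(sid if sid is not None else f"s{len(docs)}", text)
        entities = decode_bio([r[1] for r in rows])
        arcs: list[TokenArc] = []
        for i, (_, _, heads, labels) in enumerate(rows):
            hs = heads.split()
            ls = labels.split()
            if len(hs) != len(ls):
                raise CorpusFormatError(f"{where}: head/label arity mismatch")
            for h, l in zip(hs, ls):
                arcs.append(TokenArc(i, int(h), l))
        rels = from_token_arcs(entities, arcs)
        docs.append(AnnotatedDocument(sent, entities, rels))
        rows, sid = [], None

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(f"{path}:{lineno}")
                continue
            if line.startswith("#id "):
                sid = line[4:].strip()
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, got {len(parts)}"
                )
            rows.append(tuple(parts))  # type: ignore[arg-type]
    flush(f"{path}:EOF")
    return docs


# ---------------------------------------------------------------------------
# BRAT import
# ---------------------------------------------------------------------------

_BRAT_TYPES = {"symptom": "symptom", "body_part": "body_part",
               "severity": "severity"}
_BRAT_LABELS = {"located_at": "located_at",
                "is_a_description_of": "is_a_description_of"}


def read_brat(txt_path: str | Path, ann_path: str | Path) -> list[AnnotatedDocument]:
    """Import a BRAT document pair; each line of the ``.txt`` becomes one
    sentence, with global character offsets mapped to per-sentence offsets."""
    text = Path(txt_path).read_text(encoding="utf-8")
    lines = text.split("\n")
    # global offset of each line start (newline counts one character)
    line_start = []
    off = 0
    for ln in lines:
        line_start.append(off)
        off += len(ln) + 1

    def locate(gstart: int, gend: int) -> tuple[int, int, int]:
        for li in range(len(lines) - 1, -1, -1):
            if gstart >= line_start[li]:
                if gend > line_start[li] + len(lines[li]):
                    raise CorpusFormatError(
                        f"{ann_path}: span {gstart}-{gend} crosses a line break"
                    )
                return li, gstart - line_start[li], gend - line_start[li]
        raise CorpusFormatError(f"{ann_path}: bad offset {gstart}")

    ent_by_tid: dict[str, tuple[int, EntitySpan]] = {}
    rels_raw: list[tuple[str, str, str]] = []
    with open(ann_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            where = f"{ann_path}:{lineno}"
            fields = line.split("\t")
            if line.startswith("T"):
                if len(fields) < 2:
                    raise CorpusFormatError(f"{where}: malformed T line")
                tid = fields[0]
                typ, s, e = fields[1].split()
                if typ not in _BRAT_TYPES:
                    raise CorpusFormatError(f"{where}: unknown entity type {typ!r}")
                li, ls, le = locate(int(s), int(e))
                ent_by_tid[tid] = (li, EntitySpan(_BRAT_TYPES[typ], ls, le))
            elif line.startswith("R"):
                if len(fields) < 2:
                    raise CorpusFormatError(f"{where}: malformed R line")
                label, arg1, arg2 = fields[1].split()
                if label not in _BRAT_LABELS:
                    raise CorpusFormatError(f"{where}: unknown relation {label!r}")
                rels_raw.append((label,
                                 arg1.split(":", 1)[1], arg2.split(":", 1)[1]))

    docs: dict[int, AnnotatedDocument] = {}
    stem = Path(txt_path).stem
    for li, ln in enumerate(lines):
        if ln:
            docs[li] = AnnotatedDocument(Sentence.from_text(f"{stem}-{li}", ln))
    for li, span in ent_by_tid.values():
        docs[li].entities.add(span)
    for label, t1, t2 in rels_raw:
        if t1 not in ent_by_tid or t2 not in ent_by_tid:
            raise CorpusFormatError(f"{ann_path}: relation references unknown {t1}/{t2}")
        l1, s1 = ent_by_tid[t1]
        l2, s2 = ent_by_tid[t2]
        if l1 != l2:
            raise CorpusFormatError(f"{ann_path}: cross-sentence relation {t1}->{t2}")
        docs[l1].relations.add(RelationTriple(_BRAT_LABELS[label], s1, s2))
    return [docs[li] for li in sorted(docs)]


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, format: str = "json") -> list[AnnotatedDocument]:
    if format == "json":
        return read_json(path)
    if format == "tsv":
        return read_tsv(path)
    raise ValueError(f"unknown corpus format {format!r}; expected one of {FORMATS}")


def write_corpus(docs: list[AnnotatedDocument], path: str | Path,
                 format: str = "json") -> None:
    if format == "json":
        write_json(docs, path)
    elif format == "tsv":
        write_tsv(docs, path)
    else:
        raise ValueError(f"unknown corpus format {format!r}; expected one of {FORMATS}")
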