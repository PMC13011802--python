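"""Documents, PubAnnotation JSON interchange, and sentence segmentation.

A Document bundles the text of one abstract with its source metadata
(sourcedb/sourceid, e.g. "PubMed"/"37991561"), one denotation layer per
dictionary, and optional sentence spans.  The JSON shape follows the
PubAnnotation convention: {"text", "sourcedb", "sourceid", "denotations":
[{"id", "span": {"begin", "end"}, "obj"}], "tracks": [...]}.  Sentence
spans travel as a denotation layer named "sentences" with obj "Sentence"
so segmented corpora survive a round-trip through plain PubAnnotation
JSON.
"""

from __future__ import annotations

import json
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import IO, Iterable

from .matcher import Denotation, Span

SENTENCE_LAYER = "sentences"
SENTENCE_OBJ = "Sentence"

#: Tokens after which a period does not end a sentence.  Extensible.
DEFAULT_ABBREVIATIONS = frozenset(
    {"e.g.", "i.e.", "fig.", "figs.", "et al.", "al.", "vs.", "ca.", "cf.",
     "etc.", "no.", "dr.", "approx."}
)

_RESERVED_KEYS = {"text", "sourcedb", "sourceid", "denotations", "tracks"}


@dataclass
class Document:
    """One text with its annotation layers."""

    text: str
    sourcedb: str = ""
    sourceid: str = ""
    layers: dict[str, list[Denotation]] = field(default_factory=dict)
    sentence_spans: list[Span] | None = None
    extra: dict = field(default_factory=dict)  # unknown JSON keys, verbatim

    @property
    def key(self) -> str:
        return f"{self.sourcedb}/{self.sourceid}" if self.sourceid else ""

    def add_layer(self, name: str, denotations: Iterable[Denotation]) -> None:
        self.layers.setdefault(name, []).extend(denotations)

    def all_denotations(self) -> list[Denotation]:
        return [d for dens in self.layers.values() for d in dens]

    def segment(self, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS) -> list[Span]:
        self.sentence_spans = segment_sentences(self.text, abbreviations)
        return self.sentence_spans


class ValidationError(ValueError):
    """A denotation span does not fit the document text."""


# -- PubAnnotation JSON ----------------------------------------------------


def _parse_denotation(obj: dict, text_len: int, layer: str) -> Denotation:
    tag = obj.get("id", "")
    span = obj.get("span", {})
    begin, end = span.get("begin"), span.get("end")
    if (
        not isinstance(begin, int)
        or not isinstance(end, int)
        or not 0 <= begin < end <= text_len
    ):
        raise ValidationError(
            f"denotation {tag or '<unnamed>'}: span {begin}..{end} "
            f"outside text of length {text_len}"
        )
    extra = {k: v for k, v in obj.items() if k not in ("id", "span", "obj")}
    return Denotation(
        tag=tag,
        span=Span(begin, end),
        obj=obj.get("obj", ""),
        layer=layer,
        extra=extra,
    )


def document_from_dict(data: dict, default_layer: str = "default") -> Document:
    """Build a Document from a PubAnnotation-shaped mapping."""
    if "text" not in data:
        raise ValidationError("document object has no 'text'")
    text = data["text"]
    doc = Document(
        text=text,
        sourcedb=data.get("sourcedb", ""),
        sourceid=str(data.get("sourceid", "")),
        extra={k: v for k, v in data.items() if k not in _RESERVED_KEYS},
    )
    groups: list[tuple[str, list[dict]]] = []
    if data.get("denotations"):
        groups.append((default_layer, data["denotations"]))
    for track in data.get("tracks", ()):
        groups.append((track.get("project", default_layer), track.get("denotations", ())))
    for layer, dens in groups:
        parsed = [_parse_denotation(d, len(text), layer) for d in dens]
        sentences = [d for d in parsed if d.obj == SENTENCE_OBJ]
        others = [d for d in parsed if d.obj != SENTENCE_OBJ]
        if sentences:
            merged = set(doc.sentence_spans or ()) | {d.span for d in sentences}
            doc.sentence_spans = sorted(merged)
        if others:
            doc.add_layer(layer, others)
    return doc


def document_to_dict(doc: Document, flat_layer: str | None = None) -> dict:
    """Serialize back to the PubAnnotation shape (inverse of from_dict)."""
    out: dict = {"text": doc.text}
    if doc.sourcedb:
        out["sourcedb"] = doc.sourcedb
    if doc.sourceid:
        out["sourceid"] = doc.sourceid
    out.update(doc.extra)

    def dump(dens: Iterable[Denotation]) -> list[dict]:
        return [
            {
                "id": d.tag,
                "span": {"begin": d.span.begin, "end": d.span.end},
                "obj": d.obj,
                **d.extra,
            }
            for d in sorted(dens, key=lambda d: (d.span.begin, d.span.end, d.obj))
        ]

    layers = dict(doc.layers)
    if doc.sentence_spans is not None:
        layers[SENTENCE_LAYER] = [
            Denotation(tag=f"S{i}", span=s, obj=SENTENCE_OBJ, layer=SENTENCE_LAYER)
            for i, s in enumerate(doc.sentence_spans, start=1)
        ]
    if flat_layer is None and len(layers) == 1:
        flat_layer = next(iter(layers))
    if flat_layer is not None and set(layers) <= {flat_layer}:
        if layers:
            out["denotations"] = dump(layers[flat_layer])
    elif layers:
        out["tracks"] = [
            {"project": name, "denotations": dump(dens)}
            for name, dens in sorted(layers.items())
        ]
    return out


def read_pubannotation(stream: IO[str] | str, default_layer: str = "default"):
    """Read one document or a list of documents from PubAnnotation JSON."""
    data = json.loads(stream if isinstance(stream, str) else stream.read())
    if isinstance(data, list):
        return [document_from_dict(d, default_layer) for d in data]
    return document_from_dict(data, default_layer)


def write_pubannotation(docs, stream: IO[str] | None = None, **json_kwargs) -> str:
    """Write one document or a list as PubAnnotation JSON; returns the text."""
    if isinstance(docs, Document):
        payload = document_to_dict(docs)
    else:
        payload = [document_to_dict(d) for d in docs]
    json_kwargs.setdefault("ensure_ascii", False)
    json_kwargs.setdefault("indent", 2)
    text = json.dumps(payload, **json_kwargs)
    if stream is not None:
        stream.write(text)
    return text


# -- sentence segmentation -------------------------------------------------


def _is_decimal_context(text: str, i: int) -> bool:
    """True when the '.' at *i* sits between two digits (e.g. "3.5")."""
    return (
        text[i] == "."
        and i > 0
        and text[i - 1].isdigit()
        and i + 1 < len(text)
        and text[i + 1].isdigit()
    )


def _preceding_abbreviation(text: str, i: int, abbreviations: frozenset[str]) -> bool:
    tail = text[: i + 1].lower()
    for a in abbreviations:
        # the abbreviation must be a whole token, not a word suffix
        if tail.endswith(a) and (
            len(tail) == len(a) or not tail[-len(a) - 1].isalnum()
        ):
            return True
    return False


def segment_sentences(
    text: str, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> list[Span]:
    """Rule-based sentence segmentation of abstract-style text.

    A boundary is a '.', '!' or '?' (or ':' before a heading-style
    continuation) followed by whitespace and an uppercase letter or digit —
    except after a known abbreviation token, between the digits of a
    decimal number, or inside unbalanced parentheses.  The returned spans
    are trimmed of flanking whitespace and jointly cover every
    non-whitespace character exactly once.
    """
    spans: list[Span] = []
    if not text:
        return spans
    start = 0
    depth = 0
    n = len(text)

    def emit(lo: int, hi: int) -> None:
        while lo < hi and text[lo].isspace():
            lo += 1
        while hi > lo and text[hi - 1].isspace():
            hi -= 1
        if lo < hi:
            spans.append(Span(lo, hi))

    i = 0
    while i < n:
        c = text[i]
        if c == "(":
            depth += 1
        elif c == ")":
            depth = max(0, depth - 1)
        elif c in ".!?:" and depth == 0:
            j = i + 1
            while j < n and text[j] in " \t":
                j += 1
            follows = (
                j < n
                and j > i + 1
                and (text[j].isupper() or text[j].isdigit())
            )
            newline_break = j < n and text[j] == "\n"
            if (follows or newline_break) and not (
                c == "." and (_is_decimal_context(text, i)
                              or _preceding_abbreviation(text, i, abbreviations))
            ):
                emit(start, i + 1)
                start = i + 1
        elif c == "\n" and text[i : i + 2] == "\n\n":
            emit(start, i)
            start = i
        i += 1
    emit(start, n)
    return spans


def sentence_index_of(denotation: Denotation, sentence_spans: list[Span]) -> int:
    """Ordinal of the sentence owning the denotation's begin offset.

    A denotation starting in a whitespace gap belongs to the nearest
    following sentence; if none exists, that is an error.
    """
    if not sentence_spans:
        raise ValueError("no sentence spans supplied")
    spans = sorted(sentence_spans)
    begin = denotation.span.begin
    idx = bisect_right([s.begin for s in spans], begin) - 1
    if idx >= 0 and begin < spans[idx].end:
        return idx
    if idx + 1 < len(spans):
        return idx + 1
    raise ValueError(
        f"denotation at offset {begin} lies after the last sentence"
    )


__all__ = [
    "DEFAULT_ABBREVIATIONS",
    "Document",
    "SENTENCE_LAYER",
    "SENTENCE_OBJ",
    "ValidationError",
    "document_from_dict",
    "document_to_dict",
    "read_pubannotation",
    "segment_sentences",
    "sentence_index_of",
    "write_pubannotation",
]
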