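"""Dictionary-based span annotation.

The annotator slides token windows over the text, normalizes each window
the same way dictionary labels are normalized, and scores it against the
dictionary: exact matches through a token-sequence index, approximate
matches through an inverted token index filtered by token-set Jaccard
against a threshold.  Overlapping hits within one annotation layer are then
resolved longest-match-first.

Spans are 0-based half-open character offsets and always start and end on
word boundaries, so "GM1" never matches inside "GM12".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .dictionary import Dictionary, jaccard, normalize_label

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval [begin, end)."""

    begin: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.begin < self.end:
            raise ValueError(f"invalid span [{self.begin}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.begin

    def overlaps(self, other: "Span") -> bool:
        return self.begin < other.end and other.begin < self.end

    def contains(self, other: "Span") -> bool:
        return self.begin <= other.begin and other.end <= self.end


@dataclass
class Denotation:
    """A span annotated with a concept identifier.

    ``source`` records provenance: "dictionary-match" for hits produced by
    the matcher, "abbreviation" for hits propagated from a local
    abbreviation definition.  ``matched_label`` is the dictionary label the
    span was matched to (used by evaluation error reports).
    """

    tag: str
    span: Span
    obj: str
    score: float = 1.0
    source: str = "dictionary-match"
    layer: str = "default"
    matched_label: str | None = None
    extra: dict = field(default_factory=dict, repr=False)

    def key(self) -> tuple[int, int, str]:
        return (self.span.begin, self.span.end, self.obj)


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Word tokens with their character offsets."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def candidate_spans(
    text: str,
    max_tokens: int,
    sentence_spans: Sequence[Span] | None = None,
) -> list[Span]:
    """All windows of 1..max_tokens consecutive word tokens, as spans.

    Windows never cross a sentence boundary when sentence spans are given
    (entity names do not span sentences).  Spans start and end at token
    boundaries, so they carry no flanking punctuation or whitespace.
    """
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    tokens = tokenize_with_spans(text)
    if not tokens:
        return []
    if sentence_spans:
        groups = _group_by_sentence(tokens, sentence_spans)
    else:
        groups = [tokens]
    spans = []
    for group in groups:
        n = len(group)
        for i in range(n):
            for w in range(1, max_tokens + 1):
                if i + w > n:
                    break
                spans.append(Span(group[i][1], group[i + w - 1][2]))
    return spans


def _group_by_sentence(
    tokens: list[tuple[str, int, int]], sentence_spans: Sequence[Span]
) -> list[list[tuple[str, int, int]]]:
    groups: list[list[tuple[str, int, int]]] = []
    spans = sorted(sentence_spans)
    si = 0
    current: list[tuple[str, int, int]] = []
    for tok in tokens:
        while si < len(spans) and tok[1] >= spans[si].end:
            if current:
                groups.append(current)
                current = []
            si += 1
        current.append(tok)
    if current:
        groups.append(current)
    return groups


def annotate(
    text: str,
    dictionary: Dictionary,
    threshold: float | None = None,
    exact_only: bool = False,
    sentence_spans: Sequence[Span] | None = None,
    max_tokens: int | None = None,
    layer: str | None = None,
    resolve: bool = True,
) -> list[Denotation]:
    """Annotate *text* against *dictionary*.

    For every candidate window the best-scoring entries with Jaccard ≥
    threshold yield denotations; polysemous entries that tie at the best
    score each contribute one denotation on the same span.  Hits are then
    passed through :func:`resolve_overlaps` (unless ``resolve=False``,
    which exposes the raw pre-resolution hits).  Deterministic for fixed
    inputs.
    """
    if threshold is None:
        threshold = dictionary.default_threshold
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    layer = layer if layer is not None else dictionary.name
    if max_tokens is None:
        max_tokens = dictionary.max_key_tokens
    hits: list[Denotation] = []
    for span in candidate_spans(text, max_tokens, sentence_spans):
        window = normalize_label(text[span.begin : span.end])
        if not window:
            continue
        best: dict[str, tuple[float, str]] = {}  # obj -> (score, label)
        if exact_only:
            scored = [(e, 1.0) for e in dictionary.entries_for_key(window)]
        else:
            scored = [
                (e, jaccard(window, e.norm_key))
                for e in dictionary.candidate_entries(window)
            ]
        top = 0.0
        for e, score in scored:
            if score < threshold:
                continue
            if score > top:
                top = score
                best = {}
            if score == top:
                prev = best.get(e.identifier)
                if prev is None or e.label < prev[1]:
                    best[e.identifier] = (score, e.label)
        for obj in sorted(best):
            score, label = best[obj]
            hits.append(
                Denotation(
                    tag="",
                    span=span,
                    obj=obj,
                    score=score,
                    source="dictionary-match",
                    layer=layer,
                    matched_label=label,
                )
            )
    hits.sort(key=lambda d: (d.span.begin, d.span.end, d.obj))
    if resolve:
        hits = resolve_overlaps(hits)
    for i, d in enumerate(hits, start=1):
        d.tag = f"T{i}"
    return hits


def resolve_overlaps(denotations: Iterable[Denotation]) -> list[Denotation]:
    """Prune overlapping spans within each layer, longest match first.

    Preference order: longer span, then higher score, then smaller begin,
    then lexicographically smaller obj.  Denotations sharing the exact same
    span and score are all retained (polysemous ties), and layers never
    suppress each other.
    """
    result: list[Denotation] = []
    by_layer: dict[str, list[Denotation]] = {}
    for d in denotations:
        by_layer.setdefault(d.layer, []).append(d)
    for layer_dens in by_layer.values():
        ranked = sorted(
            layer_dens,
            key=lambda d: (-len(d.span), -d.score, d.span.begin, d.obj),
        )
        kept: list[Denotation] = []
        for d in ranked:
            blocked = any(
                d.span.overlaps(k.span)
                and not (d.span == k.span and d.score == k.score)
                for k in kept
            )
            if not blocked:
                kept.append(d)
        result.extend(kept)
    result.sort(key=lambda d: (d.span.begin, d.span.end, d.layer, d.obj))
    return result


def brute_force_annotate(
    text: str,
    dictionary: Dictionary,
    threshold: float,
    sentence_spans: Sequence[Span] | None = None,
    max_tokens: int | None = None,
) -> set[tuple[int, int, str, float]]:
    """Reference scorer: test every candidate window against every entry.

    Returns the raw (begin, end, obj, score) hit set before overlap
    resolution, keeping only the best score per span as the annotator does.
    Quadratic; intended for cross-checking on small instances.
    """
    if max_tokens is None:
        max_tokens = dictionary.max_key_tokens
    hits: set[tuple[int, int, str, float]] = set()
    for span in candidate_spans(text, max_tokens, sentence_spans):
        window = normalize_label(text[span.begin : span.end])
        if not window:
            continue
        scores = [
            (jaccard(window, e.norm_key), e.identifier) for e in dictionary
        ]
        top = max((s for s, _ in scores), default=0.0)
        if top >= threshold and top > 0:
            for s, obj in scores:
                if s == top:
                    hits.add((span.begin, span.end, obj, s))
    return hits


__all__ = [
    "Denotation",
    "Span",
    "annotate",
    "brute_force_annotate",
    "candidate_spans",
    "resolve_overlaps",
    "tokenize_with_spans",
]
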