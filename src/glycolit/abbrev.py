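"""Local abbreviation detection and expansion.

Authors commonly define an abbreviation once — "rheumatoid arthritis (RA)"
— and then use only the short form.  Short abbreviations are deliberately
kept out of the dictionaries (they are the most ambiguous entries), so the
annotator recovers them per document: when an annotated long form is
immediately followed by a parenthesized short form that validates against
it, every whole-word occurrence of the short form in the same document is
annotated with the long form's identifier.

Validation follows the long-form/short-form letter-subsequence heuristic in
the style of Schwartz & Hearst: every alphabetic character of the short
form must occur in the long form in order, and its first character must
start a word of the long form.  Nested parentheses inside the short form
("sLe(x)") are accepted when balanced.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .matcher import Denotation, Span

MAX_SHORT_CHARS = 10
MAX_SHORT_TOKENS = 2

_WORD_CHAR = re.compile(r"\w")


@dataclass(frozen=True)
class AbbrevDefinition:
    """A locally defined short form and the identifier it inherits."""

    short_form: str
    long_form: str
    identifier: str
    definition_span: Span  # span of the parenthesized short form
    layer: str = "default"


def _balanced_paren_content(text: str, open_idx: int) -> tuple[str, int] | None:
    """Content of the parenthesis opened at *open_idx* and its close index."""
    depth = 0
    for i in range(open_idx, len(text)):
        if text[i] == "(":
            depth += 1
        elif text[i] == ")":
            depth -= 1
            if depth == 0:
                return text[open_idx + 1 : i], i
    return None


def is_valid_short_form(short: str, long: str) -> bool:
    """Letter-subsequence validation of a candidate (short, long) pair."""
    short = short.strip()
    if not short or len(short) > MAX_SHORT_CHARS:
        return False
    if len(re.findall(r"\w+", short)) > MAX_SHORT_TOKENS:
        return False
    letters = [c for c in short.lower() if c.isalpha()]
    if not letters:
        return False
    long_l = long.lower()
    # first letter of the short form must start a word of the long form
    word_initials = {m.group()[0] for m in re.finditer(r"[^\W\d_]\w*", long_l)}
    if letters[0] not in word_initials:
        return False
    pos = 0
    for c in letters:
        idx = long_l.find(c, pos)
        if idx < 0:
            return False
        pos = idx + 1
    return True


def detect_definitions(
    text: str, denotations: Iterable[Denotation]
) -> list[AbbrevDefinition]:
    """Find "LONG (SHORT)" definitions whose LONG is already annotated.

    One definition per (denotation, parenthesis) pair that validates; the
    short form inherits the long form's identifier and layer.
    """
    definitions: list[AbbrevDefinition] = []
    for d in denotations:
        i = d.span.end
        while i < len(text) and text[i] in " \t":
            i += 1
        if i >= len(text) or text[i] != "(":
            continue
        found = _balanced_paren_content(text, i)
        if found is None:
            continue
        short, close_idx = found
        long_form = text[d.span.begin : d.span.end]
        if not is_valid_short_form(short, long_form):
            continue
        definitions.append(
            AbbrevDefinition(
                short_form=short.strip(),
                long_form=long_form,
                identifier=d.obj,
                definition_span=Span(i, close_idx + 1),
                layer=d.layer,
            )
        )
    return definitions


def _whole_word_occurrences(text: str, short: str) -> list[Span]:
    """Spans of *short* anchored at word boundaries on both sides."""
    pattern = re.compile(
        r"(?<!\w)" + re.escape(short) + r"(?!\w)"
    )
    return [Span(m.start(), m.end()) for m in pattern.finditer(text)]


def expand_and_annotate(
    text: str,
    definitions: Sequence[AbbrevDefinition],
    existing: Iterable[Denotation] = (),
) -> list[Denotation]:
    """Annotate every whole-word occurrence of each defined short form.

    All occurrences in the document count — before or after the definition,
    including the parenthesized definition itself.  Occurrences already
    covered by an identical (span, obj) denotation in *existing* are not
    duplicated.  Returns only the new abbreviation denotations; merging
    with dictionary-match denotations is additive.
    """
    seen = {d.key() for d in existing}
    out: list[Denotation] = []
    for defn in definitions:
        for span in _whole_word_occurrences(text, defn.short_form):
            key = (span.begin, span.end, defn.identifier)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                Denotation(
                    tag="",
                    span=span,
                    obj=defn.identifier,
                    score=1.0,
                    source="abbreviation",
                    layer=defn.layer,
                    matched_label=defn.long_form,
                )
            )
    out.sort(key=lambda d: (d.span.begin, d.span.end, d.obj))
    for i, d in enumerate(out, start=1):
        d.tag = f"A{i}"
    return out


def annotate_with_abbreviations(
    text: str, denotations: list[Denotation]
) -> list[Denotation]:
    """Convenience: detect definitions and merge expansions additively."""
    definitions = detect_definitions(text, denotations)
    extra = expand_and_annotate(text, definitions, existing=denotations)
    return sorted(
        denotations + extra, key=lambda d: (d.span.begin, d.span.end, d.obj)
    )


__all__ = [
    "AbbrevDefinition",
    "annotate_with_abbreviations",
    "detect_definitions",
    "expand_and_annotate",
    "is_valid_short_form",
]
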