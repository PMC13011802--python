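"""Synthetic dictionaries, documents and gold annotations.

The generator builds a controlled stand-in for an annotated abstract
collection: a dictionary whose labels mix printed glycobiology examples
(sialyl Lewis x, rheumatoid arthritis, GM1, cholera, ...) with
pronounceable nonsense terms, and multi-sentence documents that embed
those labels at recorded gold spans.  Two rates steer the difficulty:
``variation_rate`` gives a fraction of mentions a morphological suffix
(plural "-s", "-ated", "-ic"), and ``abbrev_rate`` makes a fraction of
documents define an initialism — "brontal kivur (BK)" — whose later bare
occurrences are gold-annotated with the long form's identifier.

Filler words and dictionary labels draw on disjoint consonant inventories
(checked after stemming), so with no variation and no abbreviations,
exact-threshold annotation recovers the gold standard perfectly; that
makes the generator usable as an end-to-end oracle.

Generation is a pure function of the CorpusSpec (seed included): the same
spec always yields byte-identical corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import Document
from .dictionary import Dictionary, Entry
from .matcher import Denotation, Span

#: Labels and identifiers taken from the printed worked examples, so the
#: fixtures double as the paper-style snippets.  The "sialyl Lewis A"
#: identifier is synthetic (no identifier is printed for it).
SEED_LABELS: list[tuple[str, str]] = [
    ("sialyl Lewis x", "Glycan:G00054MO"),
    ("sialyl Lewis A", "Glycan:GSYN0001A"),  # synthetic identifier
    ("GM1", "Glycan:G48558GR"),
    ("GalNAc", "Glycan:G39738WL"),
    ("Chondroitin", "Glycan:G43702JT"),
    ("Neu5Ac", "Glycan:G76685HR"),
    ("T Antigen", "Glycan:G00031MO"),
    ("rheumatoid arthritis", "MONDO:0008383"),
    ("cholera", "MONDO:0015766"),
    ("neoplasm", "MONDO:0005070"),
    ("cancer", "MONDO:0004992"),
    ("melanoma", "MONDO:0005105"),
    ("influenza", "MONDO:0005812"),
]

_FILLER_CONSONANTS = ["m", "n", "f", "s", "h", "sh"]
_ENTRY_CONSONANTS = ["br", "gl", "kr", "pl", "tr", "dr", "b", "d", "k"]
_VOWELS = ["a", "e", "i", "o", "u"]
_SUFFIXES = ["s", "ated", "ic"]


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus; generation is pure in these."""

    n_docs: int = 20
    n_entries: int = 30
    terms_per_doc: float = 5.0
    variation_rate: float = 0.0
    abbrev_rate: float = 0.0
    seed: int = 0
    layer: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("variation_rate", "abbrev_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_docs < 1 or self.n_entries < 1:
            raise ValueError("n_docs and n_entries must be positive")


def _syllable_word(rng: random.Random, consonants: list[str], n_syll: int) -> str:
    return "".join(
        rng.choice(consonants) + rng.choice(_VOWELS) for _ in range(n_syll)
    )


def _make_vocabulary(spec: CorpusSpec, rng: random.Random):
    """Dictionary entries plus a filler lexicon with disjoint stems."""
    from ._porter import stem

    entries = [
        Entry(label, identifier, canonical=True)
        for label, identifier in SEED_LABELS[: spec.n_entries]
    ]
    used_stems = {t for e in entries for t in e.norm_key}
    serial = 0
    while len(entries) < spec.n_entries:
        n_tokens = rng.choice([1, 2, 2, 3])
        tokens = [
            _syllable_word(rng, _ENTRY_CONSONANTS, rng.choice([2, 3]))
            for _ in range(n_tokens)
        ]
        stems = tuple(stem(t) for t in tokens)
        if any(s in used_stems for s in stems) or len(set(stems)) < len(stems):
            continue
        used_stems.update(stems)
        serial += 1
        entries.append(
            Entry(" ".join(tokens), f"SYN:{serial:07d}", canonical=True)
        )
    fillers: list[str] = []
    while len(fillers) < 40:
        w = _syllable_word(rng, _FILLER_CONSONANTS, rng.choice([2, 3]))
        if stem(w) in used_stems or w in fillers:
            continue
        fillers.append(w)
    return entries, fillers


def _vary(label: str, rng: random.Random) -> str:
    return label + rng.choice(_SUFFIXES)


def _initialism(label: str) -> str:
    return "".join(tok[0].upper() for tok in label.split())


@dataclass
class _DocBuilder:
    parts: list[str] = field(default_factory=list)
    length: int = 0
    gold: list[Denotation] = field(default_factory=list)

    def add(self, s: str) -> None:
        self.parts.append(s)
        self.length += len(s)

    def add_mention(self, surface: str, obj: str, layer: str) -> None:
        begin = self.length
        self.add(surface)
        self.gold.append(
            Denotation(
                tag=f"G{len(self.gold) + 1}",
                span=Span(begin, begin + len(surface)),
                obj=obj,
                layer=layer,
            )
        )

    def text(self) -> str:
        return "".join(self.parts)


def _build_document(
    idx: int,
    spec: CorpusSpec,
    rng: random.Random,
    entries: list[Entry],
    fillers: list[str],
) -> tuple[Document, list[Denotation]]:
    b = _DocBuilder()
    n_mentions = max(1, round(rng.uniform(0.5, 1.5) * spec.terms_per_doc))
    mentions = [rng.choice(entries) for _ in range(n_mentions)]

    abbrev_entry = None
    short_form = ""
    if rng.random() < spec.abbrev_rate:
        multi = [e for e in entries if " " in e.label]
        if multi:
            abbrev_entry = rng.choice(multi)
            short_form = _initialism(abbrev_entry.label)
            mentions[0] = abbrev_entry

    n_sentences = max(2, (n_mentions + 1) // 2 + 1)
    per_sentence: list[list[int]] = [[] for _ in range(n_sentences)]
    for m in range(n_mentions):
        per_sentence[m % n_sentences].append(m)

    sf_remaining = 2 if abbrev_entry is not None else 0
    for s in range(n_sentences):
        lead = rng.choice(fillers).capitalize()
        b.add(lead)
        for m in per_sentence[s]:
            for _ in range(rng.randint(1, 2)):
                b.add(" " + rng.choice(fillers))
            b.add(" ")
            entry = mentions[m]
            surface = entry.label
            if (
                entry is not abbrev_entry or m != 0
            ) and rng.random() < spec.variation_rate:
                surface = _vary(surface, rng)
            b.add_mention(surface, entry.identifier, spec.layer)
            if abbrev_entry is not None and m == 0 and entry is abbrev_entry:
                b.add(" (")
                b.add_mention(short_form, abbrev_entry.identifier, spec.layer)
                b.add(")")
        if not per_sentence[s] and sf_remaining > 0 and s > 0:
            b.add(" " + rng.choice(fillers) + " ")
            b.add_mention(short_form, abbrev_entry.identifier, spec.layer)
            sf_remaining -= 1
        b.add(" " + rng.choice(fillers) + ". ")
    while sf_remaining > 0:
        b.add(rng.choice(fillers).capitalize() + " ")
        b.add_mention(short_form, abbrev_entry.identifier, spec.layer)
        b.add(" " + rng.choice(fillers) + ". ")
        sf_remaining -= 1

    doc = Document(
        text=b.text().rstrip(), sourcedb="Synthetic", sourceid=str(idx)
    )
    doc.segment()
    for d in b.gold:
        d.extra["doc_key"] = doc.key
    return doc, b.gold


def generate(
    spec: CorpusSpec,
) -> tuple[Dictionary, list[Document], dict[str, list[Denotation]]]:
    """Generate (dictionary, documents, gold annotations) from *spec*.

    Gold spans always lie on word boundaries; documents come pre-segmented
    into sentences.  Deterministic for a given spec.
    """
    rng = random.Random(spec.seed)
    entries, fillers = _make_vocabulary(spec, rng)
    dictionary = Dictionary(spec.layer, entries=entries)
    documents: list[Document] = []
    gold: dict[str, list[Denotation]] = {}
    for i in range(1, spec.n_docs + 1):
        doc, doc_gold = _build_document(i, spec, rng, entries, fillers)
        documents.append(doc)
        gold[doc.key] = doc_gold
    return dictionary, documents, gold


__all__ = ["CorpusSpec", "SEED_LABELS", "generate"]
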