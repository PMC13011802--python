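"""Identifier-level statistics, sentence co-occurrence, and RDF export.

Statistics are aggregated over ontology identifiers, not surface strings:
annotations of "tumor", "neoplasm" and "tumour disease" all count toward
MONDO:0005070.  Co-occurrence is counted at the sentence level — a
sentence contributes at most once to each identifier pair however many
mentions it holds — which mirrors the semantics of querying for two
entities "in the same sentence".

Annotations export to RDF through a minimal six-predicate schema (one
Annotation node per denotation linking concept URI, document URI, offsets
and layer) so the graph can be loaded into any SPARQL store.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from .corpus import Document, sentence_index_of
from .dictionary import Dictionary
from .matcher import Span

#: CURIE prefix expansions used at RDF export; extensible by callers.
DEFAULT_PREFIX_MAP = {
    "Glycan": "https://glycosmos.org/glycans/show/",
    "GlycoEpitope": "https://glycosmos.org/epitopes/show/",
    "MONDO": "http://purl.obolibrary.org/obo/MONDO_",
    "HP": "http://purl.obolibrary.org/obo/HP_",
    "UBERON": "http://purl.obolibrary.org/obo/UBERON_",
    "NCBITaxon": "http://purl.obolibrary.org/obo/NCBITaxon_",
}

ANN = Namespace("https://w3id.org/glycolit/schema#")
DEFAULT_DOC_BASE = "http://pubannotation.org/docs/sourcedb/"


@dataclass(frozen=True)
class IdCount:
    identifier: str
    preferred_label: str
    count: int


@dataclass(frozen=True)
class CooccurrencePair:
    id_a: str
    id_b: str
    count: int


@dataclass(frozen=True)
class SentenceHit:
    """One sentence returned by a query template."""

    doc_key: str
    span: Span
    excerpt: str


# -- identifier statistics -------------------------------------------------


def count_by_identifier(
    documents: Iterable[Document],
    layer: str,
    dictionary: Dictionary | None = None,
) -> list[IdCount]:
    """Denotation counts per identifier in *layer*, most frequent first.

    Ties are broken by identifier so the ranking is deterministic.  When a
    dictionary is given, its first label for each identifier is used as the
    preferred label; otherwise the identifier itself is shown.
    """
    documents = list(documents)
    if not any(layer in doc.layers for doc in documents):
        raise KeyError(f"no document carries layer {layer!r}")
    counts: Counter[str] = Counter()
    for doc in documents:
        for d in doc.layers.get(layer, ()):
            counts[d.obj] += 1
    out = []
    for identifier, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        label = identifier
        if dictionary is not None:
            labels = dictionary.lookup_terms_by_id(identifier)
            if labels:
                label = labels[0]
        out.append(IdCount(identifier, label, count))
    return out


# -- sentence co-occurrence ------------------------------------------------


def _ids_per_sentence(doc: Document, layer: str) -> dict[int, set[str]]:
    if doc.sentence_spans is None:
        raise ValueError(
            f"document {doc.key or '<unnamed>'} has no sentence spans; "
            "run sentence segmentation first"
        )
    out: dict[int, set[str]] = {}
    for d in doc.layers.get(layer, ()):
        idx = sentence_index_of(d, doc.sentence_spans)
        out.setdefault(idx, set()).add(d.obj)
    return out


def cooccurrence(
    documents: Iterable[Document], layer_a: str, layer_b: str
) -> list[CooccurrencePair]:
    """Sentence-level co-occurrence counts between two layers.

    Each sentence contributes at most 1 to each distinct (id_a, id_b)
    pair.  With layer_a == layer_b, self-pairs are excluded and each
    unordered pair is reported once (id_a < id_b).  Sorted by count
    descending, then by pair.
    """
    counts: Counter[tuple[str, str]] = Counter()
    same = layer_a == layer_b
    for doc in documents:
        per_a = _ids_per_sentence(doc, layer_a)
        per_b = per_a if same else _ids_per_sentence(doc, layer_b)
        for idx, ids_a in per_a.items():
            ids_b = per_b.get(idx)
            if not ids_b:
                continue
            if same:
                pairs = itertools.combinations(sorted(ids_a), 2)
            else:
                pairs = itertools.product(sorted(ids_a), sorted(ids_b))
            for a, b in pairs:
                if same or a != b or layer_a != layer_b:
                    counts[(a, b)] += 1
    return [
        CooccurrencePair(a, b, c)
        for (a, b), c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


# -- RDF export ------------------------------------------------------------


def expand_curie(identifier: str, prefix_map: dict[str, str]) -> str:
    """Expand a CURIE via *prefix_map*; absolute URIs pass through."""
    if "://" in identifier:
        return identifier
    prefix, sep, local = identifier.partition(":")
    if sep and prefix in prefix_map:
        return prefix_map[prefix] + local
    raise KeyError(f"cannot resolve CURIE {identifier!r}: unknown prefix {prefix!r}")


def document_uri(doc: Document, base: str = DEFAULT_DOC_BASE) -> str:
    return f"{base}{doc.sourcedb}/{doc.sourceid}"


def export_rdf(
    documents: Iterable[Document],
    layers: Sequence[str] | None = None,
    prefix_map: dict[str, str] | None = None,
    syntax: str = "turtle",
    doc_base: str = DEFAULT_DOC_BASE,
) -> str:
    """Serialize annotations as RDF (turtle or ntriples).

    Emits, per denotation, six triples — type, hasBody (the expanded
    concept URI), onDocument, beginsAt, endsAt, fromLayer — plus one
    (document, hasTextLength, int) triple per document, so the graph holds
    exactly 6·denotations + documents triples.
    """
    if syntax not in ("turtle", "ntriples"):
        raise ValueError("syntax must be 'turtle' or 'ntriples'")
    if prefix_map is None:
        prefix_map = DEFAULT_PREFIX_MAP
    g = Graph()
    g.bind("ann", ANN)
    for doc in documents:
        duri = URIRef(document_uri(doc, doc_base))
        g.add((duri, ANN.hasTextLength, Literal(len(doc.text), datatype=XSD.integer)))
        wanted = layers if layers is not None else sorted(doc.layers)
        counter = 0
        for layer in wanted:
            for d in sorted(
                doc.layers.get(layer, ()),
                key=lambda d: (d.span.begin, d.span.end, d.obj),
            ):
                counter += 1
                ann = URIRef(f"{duri}#{layer}/{d.tag or counter}")
                g.add((ann, RDF.type, ANN.Annotation))
                g.add((ann, ANN.hasBody, URIRef(expand_curie(d.obj, prefix_map))))
                g.add((ann, ANN.onDocument, duri))
                g.add((ann, ANN.beginsAt, Literal(d.span.begin, datatype=XSD.integer)))
                g.add((ann, ANN.endsAt, Literal(d.span.end, datatype=XSD.integer)))
                g.add((ann, ANN.fromLayer, Literal(layer)))
    fmt = "turtle" if syntax == "turtle" else "nt"
    return g.serialize(format=fmt)


# -- query templates -------------------------------------------------------


def _sentence_hit(doc: Document, span: Span) -> SentenceHit:
    return SentenceHit(doc.key, span, doc.text[span.begin : span.end])


def sentences_with_id(
    documents: Iterable[Document], identifier: str, layer: str | None = None
) -> list[SentenceHit]:
    """Template: all sentences containing a denotation of *identifier*."""
    hits = []
    for doc in documents:
        if doc.sentence_spans is None:
            raise ValueError("run sentence segmentation first")
        found: set[int] = set()
        for name, dens in doc.layers.items():
            if layer is not None and name != layer:
                continue
            for d in dens:
                if d.obj == identifier:
                    found.add(sentence_index_of(d, doc.sentence_spans))
        for idx in sorted(found):
            hits.append(_sentence_hit(doc, doc.sentence_spans[idx]))
    return hits


def sentences_with_both_ids(
    documents: Iterable[Document], id1: str, id2: str
) -> list[SentenceHit]:
    """Template: sentences containing denotations of both identifiers."""
    documents = list(documents)
    first = {(h.doc_key, h.span) for h in sentences_with_id(documents, id1)}
    return [
        h for h in sentences_with_id(documents, id2) if (h.doc_key, h.span) in first
    ]


def sentences_with_both_layers(
    documents: Iterable[Document], layer_a: str, layer_b: str
) -> list[SentenceHit]:
    """Template: sentences with at least one denotation from each layer."""
    documents = list(documents)
    for layer in (layer_a, layer_b):
        if not any(layer in doc.layers for doc in documents):
            raise KeyError(f"no document carries layer {layer!r}")
    hits = []
    for doc in documents:
        per_a = _ids_per_sentence(doc, layer_a)
        per_b = _ids_per_sentence(doc, layer_b)
        for idx in sorted(set(per_a) & set(per_b)):
            hits.append(_sentence_hit(doc, doc.sentence_spans[idx]))
    return hits


def all_term_statistics(
    documents: Iterable[Document], dictionary: Dictionary | None = None
) -> dict[str, list[IdCount]]:
    """Template: identifier statistics for every annotation layer."""
    documents = list(documents)
    layers = sorted({name for doc in documents for name in doc.layers})
    return {
        layer: count_by_identifier(documents, layer, dictionary)
        for layer in layers
    }


def statistics_near_glycans(
    documents: Iterable[Document], layer: str, glycan_layer: str = "Glycan"
) -> list[IdCount]:
    """Template: identifier statistics for *layer*, restricted to sentences
    that also contain a glycan denotation."""
    documents = list(documents)
    if not any(glycan_layer in doc.layers for doc in documents):
        raise KeyError(f"no document carries layer {glycan_layer!r}")
    counts: Counter[str] = Counter()
    for doc in documents:
        glycan_sentences = set(_ids_per_sentence(doc, glycan_layer))
        for d in doc.layers.get(layer, ()):
            if sentence_index_of(d, doc.sentence_spans) in glycan_sentences:
                counts[d.obj] += 1
    return [
        IdCount(i, i, c)
        for i, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def query_templates(
    documents: Iterable[Document],
    glycan_layer: str = "Glycan",
    disease_layer: str = "MONDO",
    dictionary: Dictionary | None = None,
) -> dict[str, object]:
    """Run the full named report set over in-memory annotations.

    Reports: "all_term_statistics", "statistics_near_glycans" (per layer),
    and "glycan_disease_sentences"; the per-identifier templates are
    exposed as :func:`sentences_with_id` / :func:`sentences_with_both_ids`.
    """
    documents = list(documents)
    stats = all_term_statistics(documents, dictionary)
    return {
        "all_term_statistics": stats,
        "statistics_near_glycans": {
            layer: statistics_near_glycans(documents, layer, glycan_layer)
            for layer in stats
            if layer != glycan_layer
        },
        "glycan_disease_sentences": sentences_with_both_layers(
            documents, glycan_layer, disease_layer
        ),
    }


__all__ = [
    "ANN",
    "CooccurrencePair",
    "DEFAULT_PREFIX_MAP",
    "IdCount",
    "SentenceHit",
    "all_term_statistics",
    "cooccurrence",
    "count_by_identifier",
    "document_uri",
    "expand_curie",
    "export_rdf",
    "query_templates",
    "sentences_with_both_ids",
    "sentences_with_both_layers",
    "sentences_with_id",
    "statistics_near_glycans",
]
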