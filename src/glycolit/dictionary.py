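"""Term↔identifier dictionaries.

A dictionary is a named collection of mappings between natural-language
labels and concept identifiers (CURIEs or absolute URIs).  One identifier
may carry many labels (polymorphism: "neoplasm", "tumor", "tumour disease"
→ MONDO:0005070) and one label may map to several identifiers (polysemy).
Dictionaries can be loaded from two-column delimited text, compiled from an
OBO ontology subtree, filtered, and queried in both directions — by term
(exact or similarity-based via token-set Jaccard) and by identifier.

Curation is tracked in two ledgers that survive recompilation from an
updated source ontology: white entries (custom additions) and black entries
(custom suppressions).
"""

from __future__ import annotations

import io
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import networkx as nx
import obonet

from ._porter import stem

logger = logging.getLogger(__name__)

#: Default similarity threshold applied when a lookup or annotation call
#: does not override it.  The similarity is a token-set Jaccard computed
#: after normalization, so 0.85 tolerates roughly one divergent token in a
#: six-token label while rejecting single-token coincidences.
DEFAULT_THRESHOLD = 0.85

#: Synonym scopes harvested from an ontology by default.  "name" stands for
#: the term's primary label; EXACT and RELATED are OBO synonym scopes.
DEFAULT_SYNONYM_SCOPES = frozenset({"name", "EXACT", "RELATED"})

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


def normalize_label(text: str) -> tuple[str, ...]:
    """Normalize a term to the token sequence used for matching.

    Lowercase, split on Unicode word boundaries (punctuation-only runs are
    dropped), and Porter-stem each token.  Total on any input; the empty
    string yields an empty tuple.

    >>> normalize_label("sialyl Lewis A")
    ('sialyl', 'lewi', 'a')
    """
    return tuple(stem(t) for t in _TOKEN_RE.findall(text.lower()))


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Token-set Jaccard |a∩b| / |a∪b|; 1.0 when both sets are empty."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class Entry:
    """One label→identifier mapping.

    ``norm_key`` is derived from the label and kept consistent with it;
    ``canonical`` marks the term's primary name (as opposed to a synonym),
    which the short-entry filter can choose to spare.
    """

    label: str
    identifier: str
    origin: str = "base"  # base | white | abbreviation-local
    canonical: bool = False
    norm_key: tuple[str, ...] = field(init=False, repr=False)

    def __setattr__(self, name: str, value) -> None:
        object.__setattr__(self, name, value)
        if name == "label":  # keep norm_key consistent with the label
            object.__setattr__(self, "norm_key", normalize_label(value))

    def __post_init__(self) -> None:
        self.label = self.label.strip()
        self.identifier = self.identifier.strip()
        if not self.label or not self.identifier:
            raise ValueError("Entry label and identifier must be non-empty")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.label, self.identifier)


@dataclass
class LoadReport:
    loaded: int = 0
    collapsed: int = 0
    rejected: int = 0


class Dictionary:
    """A named multiset of entries with white/black curation ledgers.

    Duplicate (label, identifier) pairs are collapsed; a black-listed pair
    is never live, even if re-added by recompilation from a source ontology.
    """

    def __init__(
        self,
        name: str = "dictionary",
        entries: Iterable[Entry] = (),
        default_threshold: float = DEFAULT_THRESHOLD,
    ) -> None:
        if not 0.0 <= default_threshold <= 1.0:
            raise ValueError("default_threshold must be in [0, 1]")
        self.name = name
        self.default_threshold = default_threshold
        self._entries: dict[tuple[str, str], Entry] = {}
        self.black: set[tuple[str, str]] = set()
        self._white: dict[tuple[str, str], Entry] = {}
        self._index_dirty = True
        for e in entries:
            self.add_entry(e)

    # -- basic container protocol ------------------------------------------

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[Entry]:
        return iter(self._entries.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._entries

    @property
    def entries(self) -> list[Entry]:
        return list(self._entries.values())

    # -- mutation ----------------------------------------------------------

    def add_entry(self, entry: Entry) -> None:
        if entry.pair in self.black:
            return
        self._entries.setdefault(entry.pair, entry)
        self._index_dirty = True

    def add_white_entry(self, label: str, identifier: str) -> None:
        """Add a custom entry; recorded in the white ledger (idempotent)."""
        entry = Entry(label, identifier, origin="white")
        self._white[entry.pair] = entry
        self.black.discard(entry.pair)
        self.add_entry(entry)

    def add_black_entry(self, label: str, identifier: str) -> None:
        """Suppress a mapping; recorded in the black ledger (idempotent)."""
        pair = (label.strip(), identifier.strip())
        if not pair[0] or not pair[1]:
            raise ValueError("black entry label and identifier must be non-empty")
        self.black.add(pair)
        self._white.pop(pair, None)
        if pair in self._entries:
            del self._entries[pair]
            self._index_dirty = True

    def rebuild_from(self, entries: Iterable[Entry]) -> None:
        """Replace the base entries, re-applying both curation ledgers.

        Used when the source ontology is updated: black pairs stay
        suppressed, white entries stay live.
        """
        self._entries = {}
        self._index_dirty = True
        for e in entries:
            self.add_entry(e)
        for e in self._white.values():
            self.add_entry(e)

    # -- indexes -----------------------------------------------------------

    def _build_indexes(self) -> None:
        self._by_norm_key: dict[tuple[str, ...], list[Entry]] = defaultdict(list)
        self._by_token: dict[str, set[tuple[str, str]]] = defaultdict(set)
        self._by_id: dict[str, list[str]] = defaultdict(list)
        for e in self._entries.values():
            self._by_norm_key[e.norm_key].append(e)
            for tok in set(e.norm_key):
                self._by_token[tok].add(e.pair)
            if e.label not in self._by_id[e.identifier]:
                self._by_id[e.identifier].append(e.label)
        self._index_dirty = False

    def _indexes(self):
        if self._index_dirty:
            self._build_indexes()
        return self._by_norm_key, self._by_token, self._by_id

    @property
    def max_key_tokens(self) -> int:
        """Length of the longest normalized key (window size for matching)."""
        return max((len(e.norm_key) for e in self._entries.values()), default=1)

    # -- lookup ------------------------------------------------------------

    def entries_for_key(self, norm_key: tuple[str, ...]) -> list[Entry]:
        by_key, _, _ = self._indexes()
        return list(by_key.get(norm_key, ()))

    def candidate_entries(self, tokens: Iterable[str]) -> list[Entry]:
        """Entries sharing at least one normalized token with *tokens*.

        Sound for any Jaccard threshold > 0: an entry with no shared token
        has similarity 0 and can never pass.
        """
        _, by_token, _ = self._indexes()
        pairs: set[tuple[str, str]] = set()
        for tok in set(tokens):
            pairs |= by_token.get(tok, set())
        return [self._entries[p] for p in pairs]

    def lookup_ids_by_term(
        self, term: str, threshold: float | None = None
    ) -> list[tuple[str, str, float]]:
        """Rank identifiers matching *term* by token-set Jaccard.

        Returns (identifier, matched label, score) triples with score ≥
        threshold, sorted by score descending then label.  Black-listed
        pairs are never returned.
        """
        if threshold is None:
            threshold = self.default_threshold
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        key = normalize_label(term)
        if not key:
            return []
        if threshold > 0:
            candidates = self.candidate_entries(key)
        else:
            candidates = self.entries
        hits = []
        for e in candidates:
            score = jaccard(key, e.norm_key)
            if score >= threshold:
                hits.append((e.identifier, e.label, score))
        hits.sort(key=lambda h: (-h[2], h[1], h[0]))
        return hits

    def lookup_terms_by_id(self, identifier: str) -> list[str]:
        """All live labels for *identifier*, deduplicated, stable order."""
        _, _, by_id = self._indexes()
        return list(by_id.get(identifier, ()))

    # -- filtering ---------------------------------------------------------

    def filter_short_entries(
        self, min_len: int = 4, scope: str = "synonyms-only"
    ) -> int:
        """Drop entries whose label is shorter than *min_len* characters.

        Short harvested abbreviations are the most error-prone entries;
        locally-defined abbreviations are recovered at annotation time
        instead.  With scope "synonyms-only" canonical names are spared
        (so 3-character primary labels like "GM1" survive); "all" removes
        every short label.  Returns the number of entries removed.
        """
        if min_len < 1:
            raise ValueError("min_len must be >= 1")
        if scope not in ("all", "synonyms-only"):
            raise ValueError("scope must be 'all' or 'synonyms-only'")
        doomed = [
            pair
            for pair, e in self._entries.items()
            if len(e.label) < min_len
            and (scope == "all" or not e.canonical)
        ]
        for pair in doomed:
            del self._entries[pair]
        if doomed:
            self._index_dirty = True
        return len(doomed)


# -- delimited I/O ---------------------------------------------------------


def load_delimited(
    source: TextIO | str,
    name: str = "dictionary",
    delimiter: str = "\t",
    default_threshold: float = DEFAULT_THRESHOLD,
) -> tuple[Dictionary, LoadReport]:
    """Read a dictionary from two-column delimited text.

    Columns: label, identifier, then optional origin and canonical flag.
    Lines starting with "#" are comments.  Malformed lines are skipped with
    a warning and counted in the report; an empty stream yields an empty
    dictionary.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    d = Dictionary(name, default_threshold=default_threshold)
    report = LoadReport()
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split(delimiter)
        if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
            logger.warning("%s: skipping malformed line %d: %r", name, lineno, line)
            report.rejected += 1
            continue
        origin = cols[2].strip() if len(cols) > 2 and cols[2].strip() else "base"
        if origin == "black":
            d.add_black_entry(cols[0], cols[1])
            continue
        canonical = len(cols) > 3 and cols[3].strip().lower() in ("y", "yes", "true", "1")
        entry = Entry(cols[0], cols[1], origin=origin, canonical=canonical)
        if entry.pair in d:
            report.collapsed += 1
        else:
            report.loaded += 1
        if origin == "white":
            d.add_white_entry(entry.label, entry.identifier)
        else:
            d.add_entry(entry)
    return d, report


def write_delimited(dictionary: Dictionary, out: TextIO, delimiter: str = "\t") -> None:
    """Write the live entries as delimited text (round-trips with load)."""
    out.write("# label\tidentifier\torigin\tcanonical\n")
    for e in sorted(dictionary, key=lambda e: e.pair):
        out.write(
            delimiter.join(
                (e.label, e.identifier, e.origin, "y" if e.canonical else "n")
            )
            + "\n"
        )
    for label, identifier in sorted(dictionary.black):
        out.write(delimiter.join((label, identifier, "black")) + "\n")


# -- ontology compilation --------------------------------------------------

_SYNONYM_RE = re.compile(r'"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]*)')


def _iter_term_entries(node_id: str, data: dict, scopes: frozenset[str]) -> Iterator[Entry]:
    name = data.get("name")
    if name and "name" in scopes:
        yield Entry(name, node_id, canonical=True)
    for raw in data.get("synonym", ()):
        m = _SYNONYM_RE.match(raw)
        if not m:
            continue
        scope = m.group("scope") or "RELATED"
        if scope in scopes:
            text = m.group("text").replace('\\"', '"').strip()
            if text:
                yield Entry(text, node_id)


def compile_from_ontology(
    source: TextIO | str,
    root_id: str,
    synonym_scopes: Iterable[str] = DEFAULT_SYNONYM_SCOPES,
    name: str | None = None,
) -> Dictionary:
    """Compile a dictionary from the is_a-descendant subtree of *root_id*.

    *source* is OBO-format content (a path, stream, or the text itself).
    One entry per primary name or in-scope synonym of each non-obsolete
    term in the subtree, root inclusive.  Raises ``KeyError`` if the root
    is absent and ``ValueError`` on a cyclic is_a graph.
    """
    scopes = frozenset(synonym_scopes)
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=True)
    # restrict to is_a edges: obonet keys multigraph edges by relation type
    isa = nx.DiGraph()
    isa.add_nodes_from(graph.nodes(data=True))
    for u, v, key in graph.edges(keys=True):
        if key == "is_a":
            isa.add_edge(u, v)
    if root_id not in isa:
        raise KeyError(f"root term {root_id!r} not found in ontology")
    if not nx.is_directed_acyclic_graph(isa):
        raise ValueError("ontology is_a graph is cyclic")
    # obonet edges point child → parent, so descendants of the root are the
    # nodes from which the root is reachable
    members = nx.ancestors(isa, root_id) | {root_id}
    d = Dictionary(name or root_id)
    for node_id in sorted(members):
        data = isa.nodes[node_id]
        for entry in _iter_term_entries(node_id, data, scopes):
            d.add_entry(entry)
    return d


__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_SYNONYM_SCOPES",
    "Dictionary",
    "Entry",
    "LoadReport",
    "compile_from_ontology",
    "jaccard",
    "load_delimited",
    "normalize_label",
    "write_delimited",
]
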