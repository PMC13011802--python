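# Methods

## The annotation model

`glycolit` performs dictionary-based named-entity annotation: a
dictionary is a multiset of mappings from natural-language labels to
concept identifiers, and annotation is the search for text spans whose
normalized form is sufficiently similar to some label. There is no
learned component; all behaviour is determined by the dictionary content,
the normalization pipeline, and one similarity threshold.

**Normalization.** A label or candidate span is lowercased, tokenized at
Unicode word boundaries (`\w+`; punctuation-only runs are dropped), and
each token is stemmed with the classic Porter algorithm (the original
1980 rule set, implemented in `_porter.py` without later extensions, and
validated in the test suite against the algorithm definition's own
example transformations). Tokens shorter than three characters or
containing non-letters (`GM1`) pass through unchanged. Word-boundary
tokenization is a deliberate approximation of ICU boundary analysis that
behaves identically on scientific English. The policy is isolated behind
`normalize_label` so it can be swapped without touching the matcher.

**Similarity.** Matching uses the Jaccard coefficient of the *sets* of
normalized tokens (set, not multiset: the coefficient is set-based, and
token repetition within an entity name carries no signal). It is 1.0 when
both sets are empty. Stemming does the morphological work: `sialylated`
reduces to `sialyl` (suffix `-ed` → `-ate` → ∅ at measure > 1), so
"sialylated Lewis A" and "sialyl Lewis A" have identical token sets and
similarity 1.0 — which is how a 0.91 threshold finds the unregistered
variant.

**Matching strategy.** Candidate spans are all windows of 1..k
consecutive word tokens (k = the longest dictionary key; windows never
cross sentence boundaries when sentence spans are available, since entity
names do not span sentences). Exact lookups go through a token-sequence
hash index; approximate lookups go through an inverted token→entry index
restricted to entries sharing at least one token with the window, which
is lossless for any threshold > 0 because a disjoint entry has similarity
0. A brute-force scorer that tests every window against every entry is
kept in the package (`matcher.brute_force_annotate`) purely as an
independent oracle; the test suite asserts set equality of the two routes
on synthetic corpora across thresholds.

**Overlap resolution.** Within one annotation layer, overlapping spans
are pruned greedily with the preference order: longer span, higher score,
smaller begin offset, lexicographically smaller identifier. One deliberate
exception: denotations with *identical* spans and scores are all retained,
because a polysemous surface legitimately denotes several identifiers and
suppressing one by identifier order would silently discard information.
Layers never suppress each other. Note a consequence of length-first
preference: at permissive thresholds a longer, lower-scoring window can
displace a shorter exact match, so corpus-level recall under an
*exact-span* criterion is not monotone in the threshold; the monotonicity
guarantees are stated pre-resolution, and corpus recall is monotone under
the overlap matching criterion.

## Abbreviation processing

Short harvested abbreviations are the most error-prone dictionary
entries, so entries shorter than 4 characters are removed at compile time
(by default only synonym entries; canonical names such as `GM1` are
spared, since frequency statistics show 3-character canonical glycan
labels are legitimate and common). Locally defined abbreviations are
recovered per document instead: when an annotated long form is
immediately followed by a parenthesized short form (≤ 10 characters, ≤ 2
tokens, balanced internal parentheses allowed), validated by the
letter-subsequence heuristic in the style of Schwartz & Hearst (every
letter of the short form occurs in the long form in order; the first
letter starts a word of the long form), every whole-word occurrence of
the short form in the document inherits the long form's identifier with
score 1.0 — including occurrences *preceding* the definition, which
matches how authors use abbreviations defined in the abstract body.
Definitions are document-local and expansion is strictly additive over
dictionary matches.

## Sentence segmentation and co-occurrence

Segmentation is rule-based: a boundary is `.`, `!`, `?` (or `:` before a
heading-style continuation) followed by whitespace and an uppercase
letter or digit, except after a configurable abbreviation list (`e.g.`,
`Fig.`, `et al.`, ...; matched as whole tokens so words ending in "al."
still split), between the digits of a decimal number, or inside
unbalanced parentheses. The produced spans partition the non-whitespace
text, are deterministic, and travel through PubAnnotation JSON as a
denotation layer named `sentences` with object `Sentence`.

Co-occurrence between two annotation layers is counted at the sentence
level: a sentence contributes at most 1 to each distinct identifier pair
regardless of mention multiplicity. This "once per sentence" unit is the
natural reading of querying for two entities in the same sentence; it
makes the table symmetric under layer exchange and insensitive to
repeated mentions. A denotation starting in an inter-sentence gap is
assigned to the nearest following sentence.

## RDF export

Each denotation becomes one Annotation node with six triples (type,
`hasBody` = expanded concept URI, `onDocument`, `beginsAt`, `endsAt`,
`fromLayer`) plus one `hasTextLength` triple per document, under a
minimal project namespace — a deliberately small schema that any SPARQL
store can ingest; total triple count is exactly 6·denotations +
documents, which the tests use as a conservation check in both Turtle
and N-Triples. CURIEs are stored verbatim throughout the pipeline and
expanded only at export, via a configurable prefix map (e.g. `MONDO:` →
`http://purl.obolibrary.org/obo/MONDO_`); an unresolvable prefix is an
error naming the CURIE. The five query templates (all-term statistics,
per-layer statistics near glycans, sentences with one identifier, with
two identifiers, and with glycan + disease layers) are implemented as
native computations with the same semantics rather than through an
embedded SPARQL engine.

## Evaluation and the agile loop

Predicted and reference denotation sets are matched greedily 1-to-1,
exact span + identifier first; the `overlap-and-id` criterion then pairs
remaining same-identifier denotations by maximal character overlap. Both
criteria are provided because reconciled reference sets differ in whether
boundary disagreements count as errors. Precision, recall and F-score
use the standard zero-denominator convention (0); values are kept at full
precision and rounded half-up to 2 decimals only for display.

The error report ranks FP-causing (label, identifier) pairs as black-list
candidates and frequent FN surface strings as white-list candidates. The
agile loop samples 10 documents without replacement (seeded, hence
reproducible), annotates, triages, applies the suggestions, and repeats
up to 10 iterations or until the report is empty; on synthetic corpora
with morphological variation it converges to F = 1.0 within a few rounds.

## The synthetic corpus generator

The generator emulates the aspects of abstract annotation the pipeline
exercises: a dictionary of 30 labels by default — printed glycobiology
examples (sialyl Lewis x, rheumatoid arthritis, GM1, cholera, ...) plus
pronounceable nonsense terms — and 20 multi-sentence documents averaging
5 embedded mentions each, with gold spans recorded at generation time.
`variation_rate` gives mentions a morphological suffix (`-s`, `-ated`,
`-ic`); `abbrev_rate` makes documents define an initialism whose bare
occurrences are gold. Filler words and label tokens draw on disjoint
consonant inventories checked after stemming, so with no variation and
no abbreviations, exact-threshold annotation recovers gold with
P = R = F = 1.0 — the generator doubles as an end-to-end oracle.
Generation is a pure function of the spec (seed included). It does not
model realistic abstract length, section structure, nested entities, or
the vocabulary ambiguity of real ontologies, so perfect recovery on
fixtures demonstrates pipeline correctness, not real-corpus accuracy;
published corpus-scale counts depend on a full PubMed harvest and are
out of scope at desk scale. Test and acceptance runs use corpora of
4–15 documents, which exercise every code path in seconds.

## Numerical and design choices

- Spans are 0-based half-open character offsets everywhere
  (PubAnnotation convention).
- The default similarity threshold is 0.85, overridable per dictionary
  and per call; the worked example value 0.91 is a published operating
  point, not the default.
- Matching is case-insensitive after normalization; surface casing is
  preserved in outputs. Short-form abbreviation matching is
  case-sensitive ("RA" does not match "ra"), as initialisms are
  case-meaningful.
- Ties everywhere (ranking, overlap resolution, count ordering) are
  broken lexicographically so output is deterministic and byte-identical
  across runs.
- OBO input honours `[Term]` stanzas with `id`, `name`, `synonym`,
  `is_a`, `is_obsolete`; synonym scopes default to {name, EXACT,
  RELATED}; obsolete terms are excluded; a cyclic `is_a` graph is an
  error. Subtree membership is the `is_a`-descendant closure of the
  requested root, root inclusive.
- Known limitations: no nested or discontinuous entities ("HPV-16 or
  -18"), no coreference, no cross-document abbreviation accumulation,
  and no embedding-based synonym expansion — approximate matching is
  purely morphological.
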