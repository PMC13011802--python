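# glycolit

Dictionary-driven annotation of glycobiology literature.

Curated databases cover glycans, diseases and anatomy with stable
identifiers, but the newest findings live in free text. `glycolit`
implements the dictionary-based ("agile") annotation approach for
screening abstracts: no trained model and no gold-standard training
corpus, just a curated mapping between natural-language terms and
ontology identifiers, refined iteratively against small annotated
samples. It is aimed at database curators and text-mining practitioners
who need identifier-grounded entity annotations (GlyTouCan/GlyCosmos
glycan IDs, MONDO diseases, NCBI taxa, ...) that link literature to
structured resources.

## What it does

- **Dictionaries** — label ↔ identifier multisets supporting polysemy and
  polymorphism, loaded from TSV or compiled from the `is_a` subtree of an
  OBO ontology, with persistent *white* (addition) and *black*
  (suppression) curation ledgers that survive recompilation, and a
  short-entry filter that drops harvested abbreviations (< 4 characters).
- **Matching** — a term or text window matches an entry when the Jaccard
  coefficient of their normalized token sets meets a threshold *t*:

  `sim(a, b) = |T(a) ∩ T(b)| / |T(a) ∪ T(b)| ≥ t`

  where `T(·)` lowercases, tokenizes at word boundaries, and Porter-stems.
  Stemming makes morphological variants collide by design:
  `T("sialylated Lewis A") = T("sialyl Lewis A") = {sialyl, lewi, a}`, so
  the unregistered variant is annotated at a threshold of 0.91 without
  listing it in the dictionary. Exact matching is the `t = 1` special
  case; overlapping hits are resolved longest-match-first per layer.
- **Abbreviations** — a "long form (SF)" pattern whose long form is
  annotated defines SF locally (letter-subsequence validation); every
  whole-word SF occurrence in the document inherits the identifier.
- **Corpus handling** — PubAnnotation JSON in/out with lossless round
  trips, plus rule-based sentence segmentation.
- **Analytics** — identifier-level annotation counts, sentence-level
  co-occurrence tables between annotation layers (e.g. glycan motifs ×
  diseases), RDF export (6 triples per annotation + 1 per document), and
  the five query-template reports over in-memory annotations.
- **Evaluation** — TP/FP/FN partitioning against a reference set with
  precision / recall / F-score, error reports ranking black-list and
  white-list candidates, and the agile refinement loop (annotate 10
  random documents, triage, edit, repeat).
- **Fixtures** — a seeded generator of synthetic dictionaries, documents
  and gold annotations with controlled morphological variation and
  abbreviation usage, so the whole pipeline is testable offline.

## Worked example

```python
from glycolit import Dictionary, Entry, annotate, annotate_with_abbreviations

glycan = Dictionary("Glycan", entries=[
    Entry("sialyl Lewis x", "Glycan:G00054MO"),
    Entry("sialyl Lewis A", "Glycan:GSYN0001A"),
])
mondo = Dictionary("MONDO", entries=[
    Entry("rheumatoid arthritis", "MONDO:0008383"),
])

text = ("Serum sialylated Lewis A rises in rheumatoid arthritis (RA). "
        "RA patients also show sialyl Lewis x (sLe(x)). "
        "Levels of sLe(x) track RA activity.")

for dic in (glycan, mondo):
    dens = annotate_with_abbreviations(text, annotate(text, dic, threshold=0.91))
    for d in dens:
        print(f"{dic.name:7s} {d.span.begin:3d}-{d.span.end:<3d} "
              f"{text[d.span.begin:d.span.end]!r:22s} -> {d.obj}  "
              f"(score {d.score:.2f}, {d.source})")
```

prints

```
Glycan    6-24  'sialylated Lewis A'   -> Glycan:GSYN0001A  (score 1.00, dictionary-match)
Glycan   83-97  'sialyl Lewis x'       -> Glycan:G00054MO  (score 1.00, dictionary-match)
Glycan   99-105 'sLe(x)'               -> Glycan:G00054MO  (score 1.00, abbreviation)
Glycan  118-124 'sLe(x)'               -> Glycan:G00054MO  (score 1.00, abbreviation)
MONDO    34-54  'rheumatoid arthritis' -> MONDO:0008383  (score 1.00, dictionary-match)
MONDO    56-58  'RA'                   -> MONDO:0008383  (score 1.00, abbreviation)
MONDO    61-63  'RA'                   -> MONDO:0008383  (score 1.00, abbreviation)
MONDO   131-133 'RA'                   -> MONDO:0008383  (score 1.00, abbreviation)
```

The variant "sialylated Lewis A" is not a dictionary label, yet it is
annotated because its normalized token set is identical to that of
"sialyl Lewis A" (similarity 1.0 ≥ 0.91). "RA" and "sLe(x)" are not in
any dictionary either; they are picked up from their local definitions
and propagated across the document — including the occurrence *before*
each mention would otherwise be resolvable — while "RAS" is untouched by
whole-word anchoring.

The same operations are available from a shell:

```sh
glycolit compile --obo mondo.obo --root MONDO:0000001 -o mondo.tsv
glycolit annotate --dict mondo.tsv --threshold 0.85 -i doc.json -o doc.ann.json
glycolit cooccur -i corpus.json --layer-a Glycan --layer-b MONDO
glycolit eval --ref gold.json --pred doc.ann.json
```

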