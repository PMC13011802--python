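"""Evaluation against a reference annotation set and the agile loop.

Predicted and reference denotation sets are partitioned into true
positives (1-to-1 matches), false positives and false negatives, from
which precision, recall and F-score follow.  Matching is exact span + id
by default; the "overlap-and-id" criterion additionally pairs remaining
denotations with the same identifier by maximal character overlap.

The error report turns the partitions into dictionary curation
suggestions — FP-causing entries are black-list candidates, frequent FN
surface strings are white-list candidates — which drives the agile
refinement loop: annotate a small random sample, triage, edit the
dictionary, repeat until the report is empty.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .abbrev import annotate_with_abbreviations
from .corpus import Document
from .dictionary import Dictionary
from .matcher import Denotation, annotate


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals, for display parity with tables."""
    return int(x * 100 + 0.5) / 100


def metrics_from_counts(tp: int, fn: int, fp: int) -> tuple[float, float, float]:
    """(precision, recall, F-score) from contingency counts.

    Zero denominators yield 0 by convention.  Full precision — round only
    at presentation.
    """
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


@dataclass
class EvalResult:
    """TP/FP/FN partitions of a (reference, predicted) comparison."""

    tp: list[tuple[Denotation, Denotation]]  # (reference, predicted)
    fp: list[Denotation]
    fn: list[Denotation]

    @property
    def precision(self) -> float:
        return metrics_from_counts(len(self.tp), len(self.fn), len(self.fp))[0]

    @property
    def recall(self) -> float:
        return metrics_from_counts(len(self.tp), len(self.fn), len(self.fp))[1]

    @property
    def fscore(self) -> float:
        return metrics_from_counts(len(self.tp), len(self.fn), len(self.fp))[2]

    def counts(self) -> tuple[int, int, int]:
        return len(self.tp), len(self.fn), len(self.fp)

    def as_row(self) -> dict[str, float | int]:
        """A table row in the conventional TPs/FNs/FPs/R/P/F layout."""
        tp, fn, fp = self.counts()
        return {
            "TPs": tp, "FNs": fn, "FPs": fp,
            "Recall": _round2(self.recall),
            "Prec.": _round2(self.precision),
            "F-Score": _round2(self.fscore),
        }


def _as_doc_map(dens) -> dict[str, list[Denotation]]:
    if isinstance(dens, Mapping):
        return {k: list(v) for k, v in dens.items()}
    return {"": list(dens)}


def _overlap(a: Denotation, b: Denotation) -> int:
    return max(0, min(a.span.end, b.span.end) - max(a.span.begin, b.span.begin))


def compare(
    reference,
    predicted,
    criterion: str = "exact-span-and-id",
) -> EvalResult:
    """Partition predicted vs reference denotations into TP/FP/FN.

    Inputs are either flat denotation lists (one document) or mappings
    document-key → denotations; the two sides must cover the same
    documents.  Matching is greedy 1-to-1: exact span + id first, then —
    under "overlap-and-id" — remaining same-id pairs by maximal character
    overlap.
    """
    if criterion not in ("exact-span-and-id", "overlap-and-id"):
        raise ValueError(f"unknown criterion {criterion!r}")
    ref_map, pred_map = _as_doc_map(reference), _as_doc_map(predicted)
    only = set(ref_map) ^ set(pred_map)
    if only and not all(
        not ref_map.get(k) and not pred_map.get(k) for k in only
    ):
        raise ValueError(f"document sets differ: {sorted(only)}")
    tp: list[tuple[Denotation, Denotation]] = []
    fp: list[Denotation] = []
    fn: list[Denotation] = []
    for key in sorted(set(ref_map) | set(pred_map)):
        refs = sorted(ref_map.get(key, ()), key=lambda d: d.key())
        preds = sorted(pred_map.get(key, ()), key=lambda d: d.key())
        unmatched_ref = list(refs)
        unmatched_pred = list(preds)
        # pass 1: exact span and id
        by_key: dict[tuple[int, int, str], list[Denotation]] = {}
        for r in unmatched_ref:
            by_key.setdefault(r.key(), []).append(r)
        still = []
        for p in unmatched_pred:
            bucket = by_key.get(p.key())
            if bucket:
                tp.append((bucket.pop(0), p))
            else:
                still.append(p)
        unmatched_ref = [r for bucket in by_key.values() for r in bucket]
        unmatched_pred = still
        # pass 2: same id, maximal character overlap
        if criterion == "overlap-and-id":
            candidates = [
                (_overlap(r, p), r, p)
                for r in unmatched_ref
                for p in unmatched_pred
                if r.obj == p.obj and _overlap(r, p) > 0
            ]
            candidates.sort(key=lambda t: (-t[0], t[1].key(), t[2].key()))
            used_r, used_p = set(), set()
            for ov, r, p in candidates:
                if id(r) in used_r or id(p) in used_p:
                    continue
                used_r.add(id(r))
                used_p.add(id(p))
                tp.append((r, p))
            unmatched_ref = [r for r in unmatched_ref if id(r) not in used_r]
            unmatched_pred = [p for p in unmatched_pred if id(p) not in used_p]
        fn.extend(unmatched_ref)
        fp.extend(unmatched_pred)
    return EvalResult(tp=tp, fp=fp, fn=fn)


# -- error report and agile loop -------------------------------------------


@dataclass
class ErrorReport:
    """Dictionary curation suggestions derived from an evaluation.

    ``blacklist``: (label, identifier, FP count) for entries that caused
    false positives, most damaging first.  ``whitelist``: (surface string,
    reference identifier, FN count) for missed mentions, most frequent
    first.
    """

    blacklist: list[tuple[str, str, int]] = field(default_factory=list)
    whitelist: list[tuple[str, str, int]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.blacklist or self.whitelist)


def error_report(
    result: EvalResult,
    texts: Mapping[str, str] | str | None = None,
) -> ErrorReport:
    """Rank FP-causing entries and FN surfaces as curation candidates.

    *texts* supplies document text (a mapping doc-key → text, or one text
    for single-document comparisons) so FN surface strings can be sliced;
    without it, FN suggestions fall back to the denotations' matched
    labels when present.
    """
    from collections import Counter

    if isinstance(texts, str):
        texts = {"": texts}
    fp_counts: Counter[tuple[str, str]] = Counter()
    for p in result.fp:
        if p.matched_label:
            fp_counts[(p.matched_label, p.obj)] += 1
    fn_counts: Counter[tuple[str, str]] = Counter()
    for r in result.fn:
        surface = None
        doc_key = r.extra.get("doc_key", "") if r.extra else ""
        if texts is not None and doc_key in texts:
            surface = texts[doc_key][r.span.begin : r.span.end]
        elif r.matched_label:
            surface = r.matched_label
        if surface:
            fn_counts[(surface, r.obj)] += 1
    return ErrorReport(
        blacklist=[
            (label, obj, c)
            for (label, obj), c in sorted(
                fp_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
        whitelist=[
            (surface, obj, c)
            for (surface, obj), c in sorted(
                fn_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
    )


def _annotate_doc(
    doc: Document,
    dictionary: Dictionary,
    threshold: float | None,
    abbreviations: bool,
) -> list[Denotation]:
    dens = annotate(
        doc.text,
        dictionary,
        threshold=threshold,
        sentence_spans=doc.sentence_spans,
    )
    if abbreviations:
        dens = annotate_with_abbreviations(doc.text, dens)
    for d in dens:
        d.extra.setdefault("doc_key", doc.key)
    return dens


def agile_iteration(
    corpus: Sequence[Document],
    dictionary: Dictionary,
    n_docs: int = 10,
    seed: int = 0,
    reference: Mapping[str, list[Denotation]] | None = None,
    threshold: float | None = None,
    abbreviations: bool = True,
    criterion: str = "exact-span-and-id",
):
    """One agile refinement pass: sample, annotate, triage.

    Samples ``n_docs`` documents without replacement (all of them when the
    corpus is smaller), reproducibly for a given seed, annotates them, and
    — when a reference is available — returns the evaluation and error
    report alongside.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    rng = random.Random(seed)
    k = min(n_docs, len(corpus))
    sample = rng.sample(list(corpus), k)
    predicted = {
        doc.key: _annotate_doc(doc, dictionary, threshold, abbreviations)
        for doc in sample
    }
    if reference is None:
        return sample, predicted, None, None
    ref = {doc.key: list(reference.get(doc.key, ())) for doc in sample}
    result = compare(ref, predicted, criterion=criterion)
    report = error_report(result, {doc.key: doc.text for doc in sample})
    return sample, predicted, result, report


def agile_refine(
    corpus: Sequence[Document],
    dictionary: Dictionary,
    reference: Mapping[str, list[Denotation]],
    n_docs: int = 10,
    seed: int = 0,
    max_iterations: int = 10,
    threshold: float | None = None,
    abbreviations: bool = True,
) -> tuple[Dictionary, list[EvalResult]]:
    """Iterate sampling + triage, applying the top suggestions each round.

    FP-causing entries are black-listed and FN surfaces white-listed after
    each pass; the loop stops early once a pass yields an empty report.
    Returns the refined dictionary and the per-iteration evaluations.
    """
    history: list[EvalResult] = []
    for it in range(max_iterations):
        _, _, result, report = agile_iteration(
            corpus,
            dictionary,
            n_docs=n_docs,
            seed=seed + it,
            reference=reference,
            threshold=threshold,
            abbreviations=abbreviations,
        )
        history.append(result)
        if not report:
            break
        for label, obj, _count in report.blacklist:
            dictionary.add_black_entry(label, obj)
        for surface, obj, _count in report.whitelist:
            dictionary.add_white_entry(surface, obj)
    return dictionary, history


__all__ = [
    "ErrorReport",
    "EvalResult",
    "agile_iteration",
    "agile_refine",
    "compare",
    "error_report",
    "metrics_from_counts",
]
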