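"""Annotation curation: agreement, annotator scoring, filtering and merging.

Crowd annotation of disinformation categories is noisy; this module turns a
multi-annotator table (document, annotator, category, confidence 0-9) into a
single reliable label per document.  The pipeline is: measure pairwise
agreement and Cohen's kappa, score annotators by the agreement change their
removal causes, drop low-confidence annotations, then merge the survivors by
majority vote with confidence as tie-breaker.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

__all__ = [
    "AnnotationRecord",
    "AnnotatorQuality",
    "MergedLabel",
    "AgreementReport",
    "annotation_pairs",
    "pairwise_agreement",
    "cohens_kappa",
    "score_annotators",
    "remove_worst_annotators",
    "filter_by_confidence",
    "merge_labels",
    "category_counts",
    "agreement_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationRecord:
    doc_id: str
    annotator_id: str
    category: str
    confidence: int

    def __post_init__(self):
        if not 0 <= self.confidence <= 9:
            raise ValueError(f"confidence must be in 0..9, got {self.confidence}")


@dataclass(frozen=True)
class AnnotatorQuality:
    """Agreement gain from removing this annotator; larger = more harmful."""

    annotator_id: str
    score: float
    defined: bool = True


@dataclass(frozen=True)
class MergedLabel:
    doc_id: str
    category: str
    rule_used: str  # single | majority | confidence | tie_broken


@dataclass(frozen=True)
class AgreementReport:
    pairwise_agreement: float
    kappa: float
    n_single: int
    n_double: int
    n_multiple: int


def _by_doc(records) -> dict[str, list[AnnotationRecord]]:
    groups: dict[str, list[AnnotationRecord]] = defaultdict(list)
    for r in records:
        groups[r.doc_id].append(r)
    return groups


def annotation_pairs(records) -> list[tuple[str, str]]:
    """All unordered annotation pairs on multiply-annotated documents.

    Pair slots follow record order within a document: the earlier record
    fills slot 1.  This fixed convention makes the pooled kappa marginals
    well defined even though annotator pairing is anonymous.
    """
    pairs = []
    for recs in _by_doc(records).values():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                pairs.append((recs[i].category, recs[j].category))
    return pairs


def pairwise_agreement(records) -> float:
    """Fraction of same-document annotation pairs whose categories match."""
    pairs = annotation_pairs(records)
    if not pairs:
        raise ValueError("no multiply-annotated document: agreement undefined")
    return sum(a == b for a, b in pairs) / len(pairs)


def cohens_kappa(pairs: list[tuple[str, str]]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e comes from the two slots' marginal category
    frequencies.  Degenerate case p_e = 1 (both slots constant and equal)
    returns 1.0 by convention.
    """
    if not pairs:
        raise ValueError("kappa requires at least one pair")
    n = len(pairs)
    p_o = sum(a == b for a, b in pairs) / n
    m1 = Counter(a for a, _ in pairs)
    m2 = Counter(b for _, b in pairs)
    p_e = sum(m1[c] * m2.get(c, 0) for c in m1) / (n * n)
    if p_e >= 1.0:
        logger.info("kappa degenerate: both raters constant and equal; returning 1.0")
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def score_annotators(records) -> list[AnnotatorQuality]:
    """Leave-one-out agreement change per annotator.

    score = agreement(without annotator) - agreement(all): positive means
    the table agrees better without them, i.e. larger = more harmful.
    An annotator whose removal empties the pair set gets an undefined,
    flagged score.
    """
    records = list(records)
    annotators = sorted({r.annotator_id for r in records})
    if len(annotators) < 2:
        raise ValueError("need >= 2 annotators to score")
    base = pairwise_agreement(records)
    out = []
    for a in annotators:
        reduced = [r for r in records if r.annotator_id != a]
        try:
            agr = pairwise_agreement(reduced)
        except ValueError:
            out.append(AnnotatorQuality(a, float("nan"), defined=False))
            continue
        out.append(AnnotatorQuality(a, agr - base))
    return out


def remove_worst_annotators(records, n: int = 2) -> list[AnnotationRecord]:
    """Drop the n annotators whose removal most improves agreement."""
    scores = [q for q in score_annotators(records) if q.defined]
    worst = {q.annotator_id for q in sorted(scores, key=lambda q: -q.score)[:n]}
    return [r for r in records if r.annotator_id not in worst]


def filter_by_confidence(
    records,
    thresholds: dict[str, int] | None = None,
    default_threshold: int = 6,
) -> list[AnnotationRecord]:
    """Keep records with confidence >= the annotator's threshold (default 6)."""
    thresholds = thresholds or {}
    for t in list(thresholds.values()) + [default_threshold]:
        if not 0 <= t <= 9:
            raise ValueError(f"threshold must be in 0..9, got {t}")
    return [
        r
        for r in records
        if r.confidence >= thresholds.get(r.annotator_id, default_threshold)
    ]


def merge_labels(records) -> list[MergedLabel]:
    """One label per document: majority where possible, else highest confidence.

    Residual confidence ties across categories are broken lexicographically
    (rule ``tie_broken``) so the merge is deterministic.
    """
    merged = []
    groups = _by_doc(records)
    for doc_id in sorted(groups):
        recs = groups[doc_id]
        if len(recs) == 1:
            merged.append(MergedLabel(doc_id, recs[0].category, "single"))
            continue
        counts = Counter(r.category for r in recs)
        top_cat, top_n = counts.most_common(1)[0]
        if top_n > len(recs) / 2:
            merged.append(MergedLabel(doc_id, top_cat, "majority"))
            continue
        best_conf = max(r.confidence for r in recs)
        cands = sorted({r.category for r in recs if r.confidence == best_conf})
        rule = "confidence" if len(cands) == 1 else "tie_broken"
        merged.append(MergedLabel(doc_id, cands[0], rule))
    return merged


def category_counts(merged: list[MergedLabel]) -> tuple[dict[str, int], float]:
    """Per-category counts and the majority-class share as a percentage (1 dp)."""
    if not merged:
        raise ValueError("no merged labels")
    counts = dict(Counter(m.category for m in merged))
    share = round(100.0 * max(counts.values()) / len(merged), 1)
    return counts, share


def agreement_report(records) -> AgreementReport:
    """Agreement statistics plus single/double/multiple annotation counts."""
    sizes = Counter(len(v) for v in _by_doc(records).values())
    pairs = annotation_pairs(records)
    return AgreementReport(
        pairwise_agreement=pairwise_agreement(records),
        kappa=cohens_kappa(pairs),
        n_single=sizes.get(1, 0),
        n_double=sizes.get(2, 0),
        n_multiple=sum(v for k, v in sizes.items() if k > 2),
    )
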