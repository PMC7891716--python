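"""Synthetic corpora and annotation tables with known ground truth.

The document generator plants an exclusive token signature per class: each
token of a document comes from its class signature with probability
``separation`` and from the shared background vocabulary otherwise.  This is
the simplest structure that exercises classification, topic recovery and
curation end to end; the annotator simulator adds per-annotator confusion
matrices and correctness-conditional confidence scores in the 0-9 range.

Defaults mirror the study setting the package targets: 10 categories,
roughly 1,300 short documents (15-30 content tokens, matching fact-check
claims plus explanations), a 2,000-token vocabulary, and a pool of 27
annotators who mostly annotate each document once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document
from .curation import AnnotationRecord

__all__ = ["SyntheticSpec", "AnnotatorModel", "generate_corpus", "simulate_annotators"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_docs: int = 1300
    n_classes: int = 10
    vocab_size: int = 2000
    doc_length: tuple[int, int] = (15, 30)
    signature_size: int = 10
    separation: float = 0.9
    seed: int = 0
    class_marginals: tuple[float, ...] | None = None  # default uniform

    def __post_init__(self):
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must be in [0, 1]")
        if self.signature_size * self.n_classes > self.vocab_size:
            raise ValueError("signatures do not fit in the vocabulary")
        if self.separation < 1.0 and self.signature_size * self.n_classes == self.vocab_size:
            raise ValueError("no background tokens left for separation < 1")
        if self.doc_length[0] < 1 or self.doc_length[1] < self.doc_length[0]:
            raise ValueError("invalid document length range")
        if self.class_marginals is not None:
            m = np.asarray(self.class_marginals)
            if len(m) != self.n_classes or not np.isclose(m.sum(), 1.0):
                raise ValueError("class_marginals must be a length-n_classes simplex point")

    @property
    def labels(self) -> list[str]:
        return [f"class{c:02d}" for c in range(self.n_classes)]


def generate_corpus(spec: SyntheticSpec) -> tuple[list[Document], dict[str, list[str]]]:
    """Labelled documents plus the planted class -> signature-token map.

    Token strings are ``w0000`` ... so they pass text normalisation unchanged.
    Bit-reproducible for a given spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.vocab_size - 1)))
    tokens = [f"w{i:0{width}d}" for i in range(spec.vocab_size)]
    sig_map = {
        lab: tokens[c * spec.signature_size:(c + 1) * spec.signature_size]
        for c, lab in enumerate(spec.labels)
    }
    background = tokens[spec.n_classes * spec.signature_size:]
    marg = spec.class_marginals or tuple([1.0 / spec.n_classes] * spec.n_classes)
    lo, hi = spec.doc_length
    docs = []
    classes = rng.choice(spec.n_classes, size=spec.n_docs, p=marg)
    for i, c in enumerate(classes):
        n_tok = int(rng.integers(lo, hi + 1))
        from_sig = rng.random(n_tok) < spec.separation
        sig = sig_map[spec.labels[c]]
        words = [
            sig[rng.integers(len(sig))] if s else background[rng.integers(len(background))]
            for s in from_sig
        ]
        docs.append(Document(id=f"doc{i:05d}", text=" ".join(words), label=spec.labels[c]))
    return docs, sig_map


@dataclass(frozen=True)
class AnnotatorModel:
    """Noisy annotator pool: per-annotator confusion, confidence, coverage.

    ``confusions`` is (n_annotators, n_classes, n_classes); row c of annotator
    a is their label distribution given true class c.  Confidence is drawn
    from a correctness-conditional distribution over 0-9: by default correct
    annotations get confidence 6-9 and wrong ones 2-5, so the study's
    threshold of 6 separates them.  Coverage is the distribution of the
    number of annotators per document.
    """

    confusions: np.ndarray
    conf_given_correct: tuple[float, ...] = field(
        default=(0, 0, 0, 0, 0, 0, 0.2, 0.3, 0.3, 0.2)
    )
    conf_given_wrong: tuple[float, ...] = field(
        default=(0, 0, 0.2, 0.3, 0.3, 0.2, 0, 0, 0, 0)
    )
    coverage: dict[int, float] = field(
        default_factory=lambda: {1: 0.65, 2: 0.2, 3: 0.15}
    )

    def __post_init__(self):
        conf = np.asarray(self.confusions, dtype=float)
        if conf.ndim != 3 or conf.shape[1] != conf.shape[2]:
            raise ValueError("confusions must be (n_annotators, n_classes, n_classes)")
        if not np.allclose(conf.sum(axis=2), 1.0):
            raise ValueError("confusion rows must sum to 1")
        for dist in (self.conf_given_correct, self.conf_given_wrong):
            if len(dist) != 10 or not np.isclose(sum(dist), 1.0):
                raise ValueError("confidence distributions live on 0..9")
        if not np.isclose(sum(self.coverage.values()), 1.0):
            raise ValueError("coverage probabilities must sum to 1")

    @property
    def n_annotators(self) -> int:
        return self.confusions.shape[0]

    @classmethod
    def with_accuracy(
        cls,
        n_annotators: int,
        n_classes: int,
        accuracy: float = 0.9,
        adversarial: tuple[int, ...] = (),
        **kwargs,
    ) -> "AnnotatorModel":
        """Uniform off-diagonal confusion at the given accuracy; listed
        annotator indices get a fully uniform (adversarial) confusion."""
        good = np.full((n_classes, n_classes), (1 - accuracy) / (n_classes - 1))
        np.fill_diagonal(good, accuracy)
        conf = np.stack([good.copy() for _ in range(n_annotators)])
        for a in adversarial:
            conf[a] = np.full((n_classes, n_classes), 1.0 / n_classes)
        return cls(confusions=conf, **kwargs)


def simulate_annotators(
    docs: list[Document], am: AnnotatorModel, seed: int = 0
) -> list[AnnotationRecord]:
    """Draw annotation records for a labelled corpus under the annotator model."""
    rng = np.random.default_rng(seed)
    labels = sorted({d.label for d in docs})
    if None in labels:
        raise ValueError("corpus must be fully labelled")
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    cov_ns = sorted(am.coverage)
    cov_ps = [am.coverage[n] for n in cov_ns]
    records = []
    for doc in docs:
        n_ann = int(rng.choice(cov_ns, p=cov_ps))
        n_ann = min(n_ann, am.n_annotators)
        chosen = rng.choice(am.n_annotators, size=n_ann, replace=False)
        true_c = lab_idx[doc.label]
        for a in chosen:
            cat_idx = int(rng.choice(len(labels), p=am.confusions[a, true_c]))
            correct = cat_idx == true_c
            dist = am.conf_given_correct if correct else am.conf_given_wrong
            conf = int(rng.choice(10, p=np.asarray(dist)))
            records.append(
                AnnotationRecord(
                    doc_id=doc.id,
                    annotator_id=f"ann{a:02d}",
                    category=labels[cat_idx],
                    confidence=conf,
                )
            )
    return records
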