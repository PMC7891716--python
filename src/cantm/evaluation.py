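"""Perplexity, classification metrics and the k-fold cross-validation harness."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from .model import CantmNetwork

__all__ = [
    "ClassificationReport",
    "EvalReport",
    "perplexity",
    "classification_report",
    "cross_validate",
]


def perplexity(
    net: CantmNetwork,
    X_bow: np.ndarray,
    n_samples: int = 1,
    seed: int = 0,
    *,
    return_excluded: bool = False,
):
    """Corpus perplexity via the variational lower bound of the document model.

    exp( -(1/D) * sum_d ELBO_d / N_d ), where ELBO_d is the sample-averaged
    reconstruction log-likelihood minus the closed-form KL, and N_d the
    in-vocabulary token count.  Per-document length normalisation sits inside
    the average.  Empty documents are excluded and counted.
    """
    X = np.atleast_2d(np.asarray(X_bow, dtype=np.float64))
    lengths = X.sum(axis=1)
    excluded = int((lengths == 0).sum())
    X = X[lengths > 0]
    if len(X) == 0:
        raise ValueError("no non-empty documents")
    rng = np.random.default_rng(seed)
    per_doc = []
    for start in range(0, len(X), 256):
        batch = X[start:start + 256]
        g = net.forward_graph(batch, n_samples=n_samples, mode="train", rng=rng)
        elbo = g["recon_m1"].value - g["kl_m1"].value
        per_doc.append(elbo / batch.sum(axis=1))
    val = float(np.exp(-np.mean(np.concatenate(per_doc))))
    if return_excluded:
        return val, excluded
    return val


@dataclass(frozen=True)
class ClassificationReport:
    accuracy: float
    macro_f1: float
    per_class_f1: dict[str, float]
    confusion: np.ndarray              # rows = gold, cols = predicted
    label_set: list[str]
    empty_classes: list[str] = field(default_factory=list)

    @property
    def confusion_column_pct(self) -> np.ndarray:
        """Per-gold-class percentages (each gold row normalised to 100)."""
        totals = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.confusion / totals, 0.0)


def classification_report(preds, gold, label_set: list[str]) -> ClassificationReport:
    """Accuracy, macro-F1 (unweighted class mean), per-class F1 and confusion.

    A class with neither predictions nor gold instances contributes F1 = 0
    and is flagged in ``empty_classes``.
    """
    preds, gold = list(preds), list(gold)
    if len(preds) != len(gold):
        raise ValueError("prediction and gold lists differ in length")
    bad = (set(preds) | set(gold)) - set(label_set)
    if bad:
        raise ValueError(f"labels outside the label set: {sorted(bad)}")
    acc = accuracy_score(gold, preds)
    per_class = f1_score(gold, preds, labels=label_set, average=None, zero_division=0)
    conf = confusion_matrix(gold, preds, labels=label_set)
    empty = [
        lab for i, lab in enumerate(label_set)
        if conf[i].sum() == 0 and conf[:, i].sum() == 0
    ]
    return ClassificationReport(
        accuracy=float(acc),
        macro_f1=float(np.mean(per_class)),
        per_class_f1={lab: float(f) for lab, f in zip(label_set, per_class)},
        confusion=conf,
        label_set=list(label_set),
        empty_classes=empty,
    )


@dataclass
class EvalReport:
    accuracy_mean: float
    accuracy_std: float
    macro_f1_mean: float
    macro_f1_std: float
    per_class_f1: dict[str, tuple[float, float]]
    perplexity_mean: float
    perplexity_std: float
    confusion: np.ndarray
    label_set: list[str]
    fold_reports: list[ClassificationReport]

    def to_dict(self) -> dict:
        return {
            "accuracy": [self.accuracy_mean, self.accuracy_std],
            "macro_f1": [self.macro_f1_mean, self.macro_f1_std],
            "per_class_f1": {k: list(v) for k, v in self.per_class_f1.items()},
            "perplexity": [self.perplexity_mean, self.perplexity_std],
            "confusion": self.confusion.tolist(),
            "label_set": self.label_set,
        }


def cross_validate(docs, k: int = 5, *, seed: int = 0, estimator=None, **estimator_kwargs) -> EvalReport:
    """Train k models on k-1 folds each, evaluate on the held-out fold.

    Per-fold accuracy, macro-F1 and perplexity are summarised by their mean
    and population standard deviation; the confusion matrix is summed over
    folds.  A fold missing a class raises a warning but metrics are still
    computed.
    """
    import warnings

    from .corpus_io import make_folds, vectorize_corpus
    from .estimator import CantmClassifier

    if k < 2:
        raise ValueError("k must be >= 2")
    labels = sorted({d.label for d in docs if d.label is not None})
    split = make_folds(docs, k=k, seed=seed)
    accs, f1s, perps, reports = [], [], [], []
    per_class: dict[str, list[float]] = {lab: [] for lab in labels}
    conf_sum = np.zeros((len(labels), len(labels)), dtype=np.int64)

    for fold in range(k):
        train_docs = [d for d in docs if split.assignments[d.id] != fold]
        test_docs = [d for d in docs if split.assignments[d.id] == fold]
        fold_labels = {d.label for d in test_docs}
        if fold_labels != set(labels):
            warnings.warn(f"fold {fold} is missing classes {set(labels) - fold_labels}")
        if estimator is not None:
            from sklearn.base import clone

            clf = clone(estimator)
        else:
            clf = CantmClassifier(random_state=seed + fold, **estimator_kwargs)
        clf.fit(train_docs, [d.label for d in train_docs])
        preds = clf.predict(test_docs)
        rep = classification_report(preds, [d.label for d in test_docs], labels)
        X_test = vectorize_corpus(test_docs, clf.vocab_)
        perp, _ = perplexity(
            clf.network_, X_test[X_test.sum(axis=1) > 0],
            n_samples=clf.n_samples_test, seed=seed + fold, return_excluded=True,
        )
        accs.append(rep.accuracy)
        f1s.append(rep.macro_f1)
        perps.append(perp)
        conf_sum += rep.confusion
        for lab in labels:
            per_class[lab].append(rep.per_class_f1[lab])
        reports.append(rep)

    std = lambda v: float(np.std(v))  # population std, matching the reporting style
    return EvalReport(
        accuracy_mean=float(np.mean(accs)), accuracy_std=std(accs),
        macro_f1_mean=float(np.mean(f1s)), macro_f1_std=std(f1s),
        per_class_f1={lab: (float(np.mean(v)), std(v)) for lab, v in per_class.items()},
        perplexity_mean=float(np.mean(perps)), perplexity_std=std(perps),
        confusion=conf_sum, label_set=labels, fold_reports=reports,
    )
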