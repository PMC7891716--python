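"""scikit-learn style estimator wrapping the stacked-VAE classifier.

`CantmClassifier` follows the fit/predict contract so it composes with
sklearn pipelines and model selection.  Input may be raw texts, corpus
`Document` objects, or a precomputed bag-of-words matrix; labels are any
hashable category names.  At prediction time the classifier uses the
posterior mean of q(z|x) — no sampling — so predictions are deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .corpus_io import Document, Vocabulary, build_vocabulary, vectorize_corpus
from .model import CantmNetwork, ModelConfig
from .objective import TrainConfig, adapt_unlabelled, train_supervised
from .topics import TopicTable, extract_topics

__all__ = ["CantmClassifier"]


class CantmClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Joint classifier and topic model over short labelled texts.

    A variational document model (M1) infers a latent topic vector z per
    document; the classifier reads z, a decoder reconstructs the bag of
    words from z, a class decoder reconstructs it from the predicted label,
    and a second VAE (M2) learns classification-aware topics conditioned on
    that prediction.  All parts are trained jointly.

    Parameters mirror the study configuration: 2,000-token vocabulary,
    50-dimensional latent spaces, batch size 32, 10 latent samples during
    training and the posterior mean at test time, classifier weight
    lambda = |V|/|y|, and a first-order adaptive-moment optimiser at its
    default settings.

    Attributes (after fit): ``classes_``, ``vocab_``, ``network_``,
    ``training_log_``.
    """

    def __init__(
        self,
        vocab_size: int = 2000,
        d_h: int = 64,
        d_z: int = 50,
        d_zs: int = 50,
        lambda_cls: float | None = None,
        batch_size: int = 32,
        n_samples_train: int = 10,
        n_samples_test: int = 1,
        epochs: int = 50,
        lr: float = 1e-3,
        patience: int | None = 5,
        validation_fraction: float = 0.1,
        leaky_slope: float = 0.01,
        random_state: int = 0,
    ):
        self.vocab_size = vocab_size
        self.d_h = d_h
        self.d_z = d_z
        self.d_zs = d_zs
        self.lambda_cls = lambda_cls
        self.batch_size = batch_size
        self.n_samples_train = n_samples_train
        self.n_samples_test = n_samples_test
        self.epochs = epochs
        self.lr = lr
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.leaky_slope = leaky_slope
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _to_bow(self, X, vocab: Vocabulary | None = None) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 2 and vocab is None:
            return np.asarray(X, dtype=np.float64)
        docs = self._to_docs(X)
        if vocab is None:
            vocab = self.vocab_
        if isinstance(X, np.ndarray) and X.ndim == 2:
            if X.shape[1] != vocab.size:
                raise ValueError("bag-of-words width does not match the vocabulary")
            return np.asarray(X, dtype=np.float64)
        return vectorize_corpus(docs, vocab).astype(np.float64)

    @staticmethod
    def _to_docs(X) -> list[Document]:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return []
        docs = []
        for i, item in enumerate(X):
            if isinstance(item, Document):
                docs.append(item)
            else:
                docs.append(Document(id=str(i), text=str(item)))
        return docs

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            lambda_cls=self.lambda_cls,
            batch_size=self.batch_size,
            n_samples_train=self.n_samples_train,
            n_samples_test=self.n_samples_test,
            epochs=self.epochs,
            lr=self.lr,
            patience=self.patience,
            seed=self.random_state,
        )

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Learn vocabulary and all network parameters from labelled texts."""
        y = np.asarray(list(y))
        self.classes_ = np.array(sorted(set(y.tolist())))
        class_idx = {c: i for i, c in enumerate(self.classes_.tolist())}
        y_idx = np.array([class_idx[c] for c in y.tolist()], dtype=np.int64)

        if isinstance(X, np.ndarray) and X.ndim == 2:
            X_bow = np.asarray(X, dtype=np.float64)
            width = max(4, len(str(X.shape[1] - 1)))
            self.vocab_ = Vocabulary({f"w{i:0{width}d}": i for i in range(X.shape[1])})
        else:
            docs = self._to_docs(X)
            self.vocab_ = build_vocabulary(docs, max_size=self.vocab_size)
            X_bow = vectorize_corpus(docs, self.vocab_).astype(np.float64)

        cfg = ModelConfig(
            vocab_size=self.vocab_.size,
            n_classes=len(self.classes_),
            d_h=self.d_h, d_z=self.d_z, d_zs=self.d_zs,
            leaky_slope=self.leaky_slope,
        )
        rng = np.random.default_rng(self.random_state)
        self.network_ = CantmNetwork(cfg, rng)
        tc = self._train_config()

        X_val = y_val = None
        nonempty = X_bow.sum(axis=1) > 0
        if self.patience is not None and self.validation_fraction > 0:
            idx = np.arange(len(X_bow))[nonempty]
            if len(idx) >= 20 and np.min(np.bincount(y_idx[idx])) >= 2:
                tr, va = train_test_split(
                    idx, test_size=self.validation_fraction,
                    random_state=self.random_state, stratify=y_idx[idx],
                )
                X_val, y_val = X_bow[va], y_idx[va]
                X_bow, y_idx = X_bow[tr], y_idx[tr]
        self.training_log_ = train_supervised(
            self.network_, X_bow, y_idx, tc, X_val=X_val, y_val=y_val
        )
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities from the posterior mean (deterministic)."""
        proba, mask = self.predict_proba_flagged(X)
        if not mask.all():
            raise ValueError(
                f"{int((~mask).sum())} documents are empty after vectorisation"
            )
        return proba

    def predict_proba_flagged(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Like predict_proba but empty documents get a False flag and NaNs."""
        check_is_fitted(self, "network_")
        X_bow = self._to_bow(X)
        mask = X_bow.sum(axis=1) > 0
        proba = np.full((len(X_bow), len(self.classes_)), np.nan)
        if mask.any():
            h = self.network_.encode(X_bow[mask])
            params = self.network_.m1_infer(h)
            proba[mask] = self.network_.classify(params.mu)
        return proba, mask

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def transform(self, X) -> np.ndarray:
        """Latent topic features: the posterior mean of q(z|x) per document."""
        check_is_fitted(self, "network_")
        X_bow = self._to_bow(X)
        if np.any(X_bow.sum(axis=1) == 0):
            raise ValueError("empty document after vectorisation")
        return self.network_.m1_infer(self.network_.encode(X_bow)).mu

    # ------------------------------------------------------------------
    def adapt(self, X_unlabelled, epochs: int | None = None) -> "CantmClassifier":
        """Return a copy adapted to unlabelled texts; M1 and predictions frozen."""
        check_is_fitted(self, "network_")
        X_bow = self._to_bow(X_unlabelled)
        tc = self._train_config()
        if epochs is not None:
            tc.epochs = epochs
        adapted_net = adapt_unlabelled(self.network_, X_bow, tc)
        out = CantmClassifier(**self.get_params())
        out.classes_ = self.classes_.copy()
        out.vocab_ = self.vocab_
        out.network_ = adapted_net
        out.training_log_ = list(self.training_log_)
        return out

    def get_topics(self, source: str = "class", k: int = 10) -> TopicTable:
        """Ranked topic words from R ('m1'), R_ct ('class') or R_s ('m2')."""
        check_is_fitted(self, "network_")
        return extract_topics(
            self.network_, self.vocab_, source=source, k=k,
            labels=[str(c) for c in self.classes_],
        )
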