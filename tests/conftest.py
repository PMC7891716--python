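import numpy as np
import pytest

from cantm.estimator import CantmClassifier
from cantm.synthetic import SyntheticSpec, generate_corpus

SMALL_SPEC = SyntheticSpec(
    n_docs=200, n_classes=4, vocab_size=60, signature_size=5,
    separation=0.9, doc_length=(8, 15), seed=11,
)


@pytest.fixture(scope="session")
def small_corpus():
    """200 separable synthetic documents over 4 classes, with signatures."""
    docs, sig = generate_corpus(SMALL_SPEC)
    return docs, sig


@pytest.fixture(scope="session")
def trained_clf(small_corpus):
    """A small trained model shared across read-only tests."""
    docs, _ = small_corpus
    clf = CantmClassifier(
        vocab_size=60, d_h=32, d_z=10, d_zs=10, epochs=30,
        n_samples_train=5, patience=None, random_state=0,
    )
    clf.fit(docs, [d.label for d in docs])
    return clf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
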