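"""Loss assembly, closed-form KL, training and unlabelled adaptation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cantm.model import M1_PARAMS, CantmNetwork, GaussianParams, ModelConfig
from cantm.objective import (
    LossComponents,
    TrainConfig,
    adapt_unlabelled,
    cross_entropy_cls,
    kl_diag_gaussian,
    total_loss,
    train_supervised,
)

CFG = ModelConfig(vocab_size=6, n_classes=2, d_h=4, d_z=2, d_zs=2)


class TestKLDiagGaussian:
    def test_prior_equals_posterior(self):
        assert kl_diag_gaussian(GaussianParams(np.zeros(3), np.zeros(3))) == 0.0

    def test_unit_mean_shift(self):
        assert kl_diag_gaussian(GaussianParams(np.array([1.0]), np.array([0.0]))) == 0.5

    def test_monte_carlo_oracle(self, rng):
        """Closed form within 3 standard errors of a 1e5-draw estimate."""
        for _ in range(10):
            mu = rng.normal(size=3)
            lv = rng.normal(size=3)
            sigma = np.exp(lv / 2)
            z = mu + sigma * rng.standard_normal((100_000, 3))
            log_q = -0.5 * (((z - mu) / sigma) ** 2 + lv + np.log(2 * np.pi)).sum(axis=1)
            log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
            draws = log_q - log_p
            se = draws.std(ddof=1) / np.sqrt(len(draws))
            assert abs(kl_diag_gaussian(GaussianParams(mu, lv)) - draws.mean()) < 3 * se

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegative(self, mu, lv):
        n = min(len(mu), len(lv))
        val = kl_diag_gaussian(GaussianParams(np.array(mu[:n]), np.array(lv[:n])))
        assert val >= -1e-12


class TestCrossEntropy:
    def test_confident_correct_is_zero(self):
        assert cross_entropy_cls([np.array([0.0, 1.0])], 1) == 0.0

    def test_uniform_ten_classes(self):
        assert cross_entropy_cls([np.full(10, 0.1)], 3) == pytest.approx(np.log(10))

    def test_sample_average(self):
        ys = [np.array([0.5, 0.5]), np.array([0.25, 0.75])]
        assert cross_entropy_cls(ys, 0) == pytest.approx((np.log(2) + np.log(4)) / 2)


class TestLossComponents:
    def test_reconstruction_identity_on_random_values(self, rng):
        for _ in range(100):
            lc = LossComponents(
                l_cls=float(rng.uniform(0, 3)),
                recon_m1=float(-rng.uniform(0, 50)),
                kl_m1=float(rng.uniform(0, 5)),
                recon_m2=float(-rng.uniform(0, 50)),
                label_m2=float(-rng.uniform(0, 3)),
                kl_m2=float(rng.uniform(0, 5)),
                recon_ct=float(-rng.uniform(0, 50)),
                lambda_cls=float(rng.uniform(0, 10)),
            )
            expected = (
                lc.lambda_cls * lc.l_cls - lc.recon_m1 + lc.kl_m1
                - lc.recon_m2 - lc.label_m2 + lc.kl_m2 - lc.recon_ct
            )
            assert lc.total == pytest.approx(expected, abs=1e-6)

    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValueError):
            LossComponents(1, -1, 1, -1, -1, 1, -1, lambda_cls=1.0, total=123.0)

    def test_lambda_linearity(self, rng):
        net = CantmNetwork(CFG, rng)
        x = np.array([1, 0, 2, 0, 1, 0.0])
        fo = net.forward(x, n_samples=3, mode="train", seed=4)
        lo = total_loss(fo, 0, TrainConfig(), lambda_cls=1.0)
        hi = total_loss(fo, 0, TrainConfig(), lambda_cls=2.0)
        assert hi.total - lo.total == pytest.approx(lo.l_cls)

    def test_lambda_zero_reduces_toward_unsupervised(self, rng):
        net = CantmNetwork(CFG, rng)
        x = np.array([0, 1, 1, 0, 0, 2.0])
        fo = net.forward(x, n_samples=2, mode="train", seed=9)
        lc = total_loss(fo, 1, TrainConfig(), lambda_cls=0.0)
        # with the M2 and class-decoder terms removed, what is left of the
        # objective is the negative document-model ELBO
        nvdm_objective = lc.kl_m1 - lc.recon_m1
        assert lc.total - (-lc.recon_m2 - lc.label_m2 + lc.kl_m2 - lc.recon_ct) == (
            pytest.approx(nvdm_objective)
        )


def _independent_nvdm_neg_elbo(net, x, z):
    """Standalone unsupervised document-model objective on shared weights."""
    logits = z @ net.params["R"] + net.params["b_r"]
    logp = logits - logits.max()
    logp = logp - np.log(np.exp(logp).sum())
    recon = float((x * logp).sum())
    h = x / x.sum()
    pre = h @ net.params["enc_W"] + net.params["enc_b"]
    hh = np.where(pre >= 0, pre, 0.01 * pre)
    mu = hh @ net.params["W1"] + net.params["b1"]
    lv = np.clip(hh @ net.params["W2"] + net.params["b2"], -10, 10)
    kl = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1)
    return kl - recon, mu, lv


class TestNvdmReduction:
    def test_matches_independent_implementation(self, rng):
        """Unsupervised mode: per-document objective equals a standalone
        document-model negative ELBO on identical weights (deterministic
        z = mu path)."""
        net = CantmNetwork(CFG, rng)
        for _ in range(10):
            x = rng.integers(0, 4, size=6).astype(float)
            if x.sum() == 0:
                continue
            fo = net.forward(x, n_samples=1, mode="test", seed=0)
            lc = total_loss(fo, 0, TrainConfig(), lambda_cls=0.0)
            ours = lc.kl_m1 - lc.recon_m1
            independent, mu, _ = _independent_nvdm_neg_elbo(net, x, fo.samples[0].z[0])
            np.testing.assert_allclose(fo.samples[0].z[0], mu, atol=1e-12)
            assert ours == pytest.approx(independent, abs=1e-6)


class TestTraining:
    def _data(self, rng, n=60):
        X = np.zeros((n, 6))
        y = rng.integers(0, 2, size=n)
        for i in range(n):
            informative = rng.multinomial(6, [0.5, 0.5, 0, 0, 0, 0] if y[i] == 0
                                          else [0, 0, 0, 0, 0.5, 0.5])
            X[i] = informative + rng.multinomial(2, np.ones(6) / 6)
        return X, y

    def test_loss_decreases(self, rng):
        X, y = self._data(rng)
        net = CantmNetwork(CFG, rng)
        log = train_supervised(net, X, y, TrainConfig(epochs=15, n_samples_train=3,
                                                      patience=None, seed=0))
        assert log[-1]["total"] < log[0]["total"]

    def test_deterministic_given_seed(self, rng):
        X, y = self._data(rng)
        cfg = TrainConfig(epochs=3, n_samples_train=2, patience=None, seed=5)
        n1 = CantmNetwork(CFG, np.random.default_rng(2))
        n2 = CantmNetwork(CFG, np.random.default_rng(2))
        l1 = train_supervised(n1, X, y, cfg)
        l2 = train_supervised(n2, X, y, cfg)
        assert l1[-1]["total"] == l2[-1]["total"]
        for k in n1.params:
            np.testing.assert_array_equal(n1.params[k], n2.params[k])

    def test_classifier_weight_improves_training_accuracy(self, rng):
        X, y = self._data(rng, n=80)
        accs = {}
        for lam in (0.0, 50.0):
            net = CantmNetwork(CFG, np.random.default_rng(7))
            train_supervised(net, X, y, TrainConfig(
                epochs=40, n_samples_train=3, lambda_cls=lam, patience=None, seed=0))
            mu = net.m1_infer(net.encode(X)).mu
            preds = np.argmax(net.classify(mu), axis=1)
            accs[lam] = (preds == y).mean()
        assert accs[50.0] > accs[0.0]


class TestAdaptation:
    @pytest.fixture
    def trained(self, rng):
        X = rng.multinomial(8, np.ones(6) / 6, size=50).astype(float)
        y = rng.integers(0, 2, size=50)
        net = CantmNetwork(CFG, rng)
        train_supervised(net, X, y, TrainConfig(epochs=3, n_samples_train=2,
                                                patience=None, seed=0))
        return net, X

    def test_frozen_parameters_bit_identical(self, trained, rng):
        net, _ = trained
        X_new = rng.multinomial(8, np.ones(6) / 6, size=40).astype(float)
        before = {k: net.params[k].copy() for k in M1_PARAMS}
        adapted = adapt_unlabelled(net, X_new, TrainConfig(epochs=3, n_samples_train=2, seed=1))
        for k in M1_PARAMS:
            assert adapted.params[k].tobytes() == before[k].tobytes()
            assert net.params[k].tobytes() == before[k].tobytes()

    def test_predictions_unchanged(self, trained, rng):
        net, X = trained
        adapted = adapt_unlabelled(net, X, TrainConfig(epochs=3, n_samples_train=2, seed=1))
        mu = net.m1_infer(net.encode(X)).mu
        np.testing.assert_array_equal(net.classify(mu), adapted.classify(
            adapted.m1_infer(adapted.encode(X)).mu))

    def test_m2_reconstruction_improves_on_heldout(self, rng):
        # distinct word distribution in the adaptation corpus
        p_new = np.array([0.05, 0.05, 0.4, 0.4, 0.05, 0.05])
        X_lab = rng.multinomial(8, np.ones(6) / 6, size=60).astype(float)
        y = rng.integers(0, 2, size=60)
        net = CantmNetwork(CFG, rng)
        train_supervised(net, X_lab, y, TrainConfig(epochs=5, n_samples_train=2,
                                                    patience=None, seed=0))
        X_adapt = rng.multinomial(10, p_new, size=80).astype(float)
        X_held = rng.multinomial(10, p_new, size=40).astype(float)

        def m2_recon(model):
            g = model.forward_graph(X_held, n_samples=5, mode="test",
                                    rng=np.random.default_rng(3))
            return float(g["recon_m2"].value.mean())

        before = m2_recon(net)
        adapted = adapt_unlabelled(net, X_adapt, TrainConfig(
            epochs=20, n_samples_train=3, seed=1))
        assert m2_recon(adapted) > before
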