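"""The classification-aware neural topic model: a stacked variational autoencoder.

Six sub-modules share one parameter set:

* M1 encoder  q(z|x): document representation h -> Gaussian posterior (mu, sigma)
* M1 decoder  p(x_bow|z) = softmax(zR + b) under a multinomial bag-of-words likelihood
* M1 classifier  yhat = softmax(FC(z)) — the latent topic vector doubles as the
  classification feature, so topics explain the classifier
* classifier decoder  p(x_bow|yhat) = softmax(yhat R_ct + b_ct), whose rows are
  class-associated topics
* M2 encoder  q(z_s|x, yhat): merges h with the predicted label before inferring a
  second, classification-aware latent space
* M2 decoder  p(x_bow|yhat, z_s) and p(yhat|z_s) (the latter used only in the loss)

Latent posteriors are diagonal Gaussians reparameterised as z = mu + sigma * eps;
priors are N(0, I).  All computation runs on the autodiff tape in
:mod:`cantm._autodiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Var, clip, concat, leaky_relu, log_softmax

__all__ = [
    "ModelConfig",
    "GaussianParams",
    "LatentSample",
    "ForwardOutput",
    "CantmNetwork",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    n_classes: int
    d_h: int = 64          # document-representation width (reference encoder)
    d_z: int = 50          # M1 latent topics
    d_zs: int = 50         # M2 classification-aware latent topics
    leaky_slope: float = 0.01
    logvar_clip: float = 10.0

    def __post_init__(self):
        if min(self.vocab_size, self.n_classes, self.d_h, self.d_z, self.d_zs) < 1:
            raise ValueError("all model dimensions must be >= 1")


@dataclass(frozen=True)
class GaussianParams:
    """Diagonal Gaussian posterior: mean and log-variance per dimension."""

    mu: np.ndarray
    logvar: np.ndarray

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.logvar)


@dataclass(frozen=True)
class LatentSample:
    z: np.ndarray
    epsilon: np.ndarray


@dataclass
class ForwardOutput:
    """Everything one forward pass produces, per document (rows) and sample."""

    h: np.ndarray
    m1_params: GaussianParams
    samples: list[LatentSample]
    yhat: np.ndarray                      # sample-averaged (train) or mu-based (test)
    yhat_per_sample: list[np.ndarray]
    m2_params_per_sample: list[GaussianParams]
    zs_samples: list[LatentSample]
    log_px_z: np.ndarray                  # (S, n) log p(x_bow | z)
    log_px_y: np.ndarray                  # (S, n) log p(x_bow | yhat)
    log_px_yzs: np.ndarray                # (S, n) log p(x_bow | yhat, z_s)
    log_py_zs: np.ndarray                 # (S, n) log p(yhat | z_s)
    kl_m2_per_sample: np.ndarray          # (S, n)
    mode: str = "train"
    n_samples: int = field(default=1)


# parameter shapes, given config c
def _param_shapes(c: ModelConfig) -> dict[str, tuple[int, int] | tuple[int]]:
    return {
        "enc_W": (c.vocab_size, c.d_h), "enc_b": (c.d_h,),
        "W1": (c.d_h, c.d_z), "b1": (c.d_z,),
        "W2": (c.d_h, c.d_z), "b2": (c.d_z,),
        "Wc": (c.d_z, c.n_classes), "bc": (c.n_classes,),
        "R": (c.d_z, c.vocab_size), "b_r": (c.vocab_size,),
        "R_ct": (c.n_classes, c.vocab_size), "b_ct": (c.vocab_size,),
        "Wm": (c.d_h + c.n_classes, c.d_zs), "bm": (c.d_zs,),
        "W3": (c.d_zs, c.d_zs), "b3": (c.d_zs,),
        "W4": (c.d_zs, c.d_zs), "b4": (c.d_zs,),
        "Wy2": (c.d_zs, c.n_classes), "by2": (c.n_classes,),
        "Wt": (c.n_classes + c.d_zs, c.d_zs), "bt": (c.d_zs,),
        "R_s": (c.d_zs, c.vocab_size), "b_s": (c.vocab_size,),
    }


# parameters belonging to M1 (frozen during unlabelled adaptation) vs the rest
M1_PARAMS = frozenset(
    ["enc_W", "enc_b", "W1", "b1", "W2", "b2", "Wc", "bc", "R", "b_r"]
)
CLASS_DECODER_PARAMS = frozenset(["R_ct", "b_ct"])
M2_PARAMS = frozenset(
    ["Wm", "bm", "W3", "b3", "W4", "b4", "Wy2", "by2", "Wt", "bt", "R_s", "b_s"]
)


class CantmNetwork:
    """Parameter container plus the forward computation of all six sub-modules.

    The public single-input operations (``m1_infer``, ``classify``, ...) accept
    and return plain numpy arrays; training code uses the graph-building
    ``forward_graph`` directly.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(0)
        self.params: dict[str, np.ndarray] = {}
        for name, shape in _param_shapes(config).items():
            if len(shape) == 1:
                self.params[name] = np.zeros(shape)
            else:
                fan_in, fan_out = shape
                std = np.sqrt(2.0 / (fan_in + fan_out))
                self.params[name] = rng.normal(0.0, std, size=shape)

    # ------------------------------------------------------------------
    # graph building
    # ------------------------------------------------------------------
    def _vars(self) -> dict[str, Var]:
        return {k: Var(v) for k, v in self.params.items()}

    def _normalise(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        totals = X.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("empty document after vectorisation")
        return X / totals

    def encode_graph(self, X: np.ndarray, P: dict[str, Var]) -> Var:
        """Reference encoder: leaky-rectified affine map of L1-normalised counts."""
        Xn = self._normalise(X)
        return leaky_relu(Var(Xn) @ P["enc_W"] + P["enc_b"], self.config.leaky_slope)

    def m1_infer_graph(self, h: Var, P: dict[str, Var]) -> tuple[Var, Var]:
        mu = h @ P["W1"] + P["b1"]
        lv = clip(h @ P["W2"] + P["b2"], -self.config.logvar_clip, self.config.logvar_clip)
        return mu, lv

    def forward_graph(
        self,
        X: np.ndarray,
        *,
        n_samples: int = 1,
        mode: str = "train",
        rng: np.random.Generator | None = None,
        h_override: np.ndarray | None = None,
    ) -> dict:
        """Build the full stacked-VAE graph for a batch of bag-of-words rows.

        Returns a dict of Vars: per-document term vectors (log-likelihoods,
        KLs, classifier log-probabilities) averaged over latent samples, plus
        the parameter Vars so a caller can read gradients after backward().

        In ``test`` mode the classification path uses the posterior mean mu
        (no sampling), per the evaluation protocol.
        """
        if mode not in ("train", "test"):
            raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n = X.shape[0]
        rng = rng or np.random.default_rng(0)
        P = self._vars()
        slope = self.config.leaky_slope
        cl = self.config.logvar_clip

        if h_override is not None:
            h = Var(np.atleast_2d(h_override))
        else:
            h = self.encode_graph(X, P)
        mu, logvar = self.m1_infer_graph(h, P)
        sigma = (logvar * 0.5).exp()
        Xv = Var(X)

        # closed-form KL(q(z|x) || N(0,I)) per document
        kl_m1 = ((mu * mu + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1)

        per_sample: dict[str, list[Var]] = {
            "recon_m1": [], "log_yhat": [], "recon_ct": [],
            "recon_m2": [], "label_m2": [], "kl_m2": [],
        }
        samples, zs_samples, yhat_list, m2_params = [], [], [], []
        for _ in range(n_samples):
            if mode == "test":
                eps = np.zeros((n, self.config.d_z))
                z = mu
            else:
                eps = rng.standard_normal((n, self.config.d_z))
                z = mu + sigma * Var(eps)
            log_yhat = log_softmax(z @ P["Wc"] + P["bc"])
            yhat = log_yhat.exp()
            recon_m1 = (Xv * log_softmax(z @ P["R"] + P["b_r"])).sum(axis=1)
            recon_ct = (Xv * log_softmax(yhat @ P["R_ct"] + P["b_ct"])).sum(axis=1)

            m = leaky_relu(concat([h, yhat]) @ P["Wm"] + P["bm"], slope)
            mu_s = m @ P["W3"] + P["b3"]
            logvar_s = clip(m @ P["W4"] + P["b4"], -cl, cl)
            eps_s = rng.standard_normal((n, self.config.d_zs))
            z_s = mu_s + (logvar_s * 0.5).exp() * Var(eps_s)
            t = leaky_relu(concat([yhat, z_s]) @ P["Wt"] + P["bt"], slope)
            recon_m2 = (Xv * log_softmax(t @ P["R_s"] + P["b_s"])).sum(axis=1)
            label_m2 = (yhat * log_softmax(z_s @ P["Wy2"] + P["by2"])).sum(axis=1)
            kl_m2 = ((mu_s * mu_s + logvar_s.exp() - logvar_s - 1.0) * 0.5).sum(axis=1)

            per_sample["recon_m1"].append(recon_m1)
            per_sample["log_yhat"].append(log_yhat)
            per_sample["recon_ct"].append(recon_ct)
            per_sample["recon_m2"].append(recon_m2)
            per_sample["label_m2"].append(label_m2)
            per_sample["kl_m2"].append(kl_m2)
            samples.append(LatentSample(z=z.value.copy(), epsilon=eps))
            zs_samples.append(LatentSample(z=z_s.value.copy(), epsilon=eps_s))
            yhat_list.append(yhat)
            m2_params.append(GaussianParams(mu_s.value.copy(), logvar_s.value.copy()))

        def avg(key):
            acc = per_sample[key][0]
            for v in per_sample[key][1:]:
                acc = acc + v
            return acc / n_samples

        return {
            "params": P,
            "h": h,
            "mu": mu,
            "logvar": logvar,
            "kl_m1": kl_m1,
            "kl_m2": avg("kl_m2"),
            "recon_m1": avg("recon_m1"),
            "recon_ct": avg("recon_ct"),
            "recon_m2": avg("recon_m2"),
            "label_m2": avg("label_m2"),
            "log_yhat_per_sample": per_sample["log_yhat"],
            "yhat_per_sample": yhat_list,
            "per_sample": per_sample,
            "samples": samples,
            "zs_samples": zs_samples,
            "m2_params": m2_params,
            "n_samples": n_samples,
            "mode": mode,
        }

    # ------------------------------------------------------------------
    # public numpy-facing operations
    # ------------------------------------------------------------------
    def encode(self, x_bow: np.ndarray) -> np.ndarray:
        """Document representation h from a bag-of-words vector or matrix."""
        P = self._vars()
        h = self.encode_graph(x_bow, P).value
        return h[0] if np.asarray(x_bow).ndim == 1 else h

    def m1_infer(self, h: np.ndarray) -> GaussianParams:
        h = np.asarray(h, dtype=np.float64)
        if not np.all(np.isfinite(h)):
            raise ValueError("non-finite document representation")
        P = self._vars()
        mu, lv = self.m1_infer_graph(Var(np.atleast_2d(h)), P)
        if h.ndim == 1:
            return GaussianParams(mu.value[0], lv.value[0])
        return GaussianParams(mu.value, lv.value)

    @staticmethod
    def reparameterize(
        params: GaussianParams,
        n_samples: int = 1,
        seed: int | np.random.Generator = 0,
    ) -> list[LatentSample]:
        """Draw z = mu + sigma * eps with fresh standard-normal noise per sample."""
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = []
        for _ in range(n_samples):
            eps = rng.standard_normal(params.mu.shape)
            out.append(LatentSample(z=params.mu + params.sigma * eps, epsilon=eps))
        return out

    def _bow_loglik(self, feat: np.ndarray, W: str, b: str, x_bow: np.ndarray) -> float:
        x_bow = np.asarray(x_bow, dtype=np.float64)
        if x_bow.sum() == 0:
            raise ValueError("empty document after vectorisation")
        logits = np.atleast_2d(feat) @ self.params[W] + self.params[b]
        logp = logits - logits.max(axis=-1, keepdims=True)
        logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
        return float((x_bow * logp[0]).sum())

    def m1_reconstruct_logprob(self, z: np.ndarray, x_bow: np.ndarray) -> float:
        """Multinomial log-likelihood of x_bow under softmax(zR + b)."""
        return self._bow_loglik(z, "R", "b_r", x_bow)

    def classify(self, z: np.ndarray) -> np.ndarray:
        """Class probabilities yhat = softmax of an affine map of z."""
        logits = np.atleast_2d(z) @ self.params["Wc"] + self.params["bc"]
        logits = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=-1, keepdims=True)
        return p[0] if np.asarray(z).ndim == 1 else p

    def class_decoder_logprob(self, yhat: np.ndarray, x_bow: np.ndarray) -> float:
        """Log-likelihood of x_bow under the class-associated topic decoder."""
        return self._bow_loglik(yhat, "R_ct", "b_ct", x_bow)

    def m2_infer(self, h: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, GaussianParams]:
        """Merged feature m and the M2 posterior q(z_s | x, yhat)."""
        h2, y2 = np.atleast_2d(h), np.atleast_2d(yhat)
        if h2.shape[1] != self.config.d_h or y2.shape[1] != self.config.n_classes:
            raise ValueError("dimension mismatch in M2 encoder inputs")
        hy = np.concatenate([h2, y2], axis=1)
        pre = hy @ self.params["Wm"] + self.params["bm"]
        m = np.where(pre >= 0, pre, self.config.leaky_slope * pre)
        mu_s = m @ self.params["W3"] + self.params["b3"]
        lv_s = np.clip(
            m @ self.params["W4"] + self.params["b4"],
            -self.config.logvar_clip, self.config.logvar_clip,
        )
        if np.asarray(h).ndim == 1:
            return m[0], GaussianParams(mu_s[0], lv_s[0])
        return m, GaussianParams(mu_s, lv_s)

    def m2_reconstruct_logprob(
        self, yhat: np.ndarray, z_s: np.ndarray, x_bow: np.ndarray
    ) -> float:
        """Log-likelihood of x_bow from the classification-aware topic t."""
        yz = np.concatenate([np.atleast_2d(yhat), np.atleast_2d(z_s)], axis=1)
        pre = yz @ self.params["Wt"] + self.params["bt"]
        t = np.where(pre >= 0, pre, self.config.leaky_slope * pre)
        return self._bow_loglik(t[0], "R_s", "b_s", x_bow)

    def m2_label_logprob(self, z_s: np.ndarray, yhat: np.ndarray) -> float:
        """Soft-label cross-entropy term sum_c yhat[c] log softmax(FC(z_s))[c]."""
        logits = np.atleast_2d(z_s) @ self.params["Wy2"] + self.params["by2"]
        logp = logits - logits.max(axis=-1, keepdims=True)
        logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
        return float((np.atleast_2d(yhat)[0] * logp[0]).sum())

    def forward(
        self,
        x_bow: np.ndarray,
        *,
        n_samples: int = 1,
        mode: str = "test",
        seed: int | np.random.Generator = 0,
        h: np.ndarray | None = None,
    ) -> ForwardOutput:
        """One full pass; see :meth:`forward_graph` for the term definitions."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        X = np.atleast_2d(np.asarray(x_bow, dtype=np.float64))
        g = self.forward_graph(X, n_samples=n_samples, mode=mode, rng=rng, h_override=h)
        yhat_ps = [y.value.copy() for y in g["yhat_per_sample"]]
        yhat = np.mean(yhat_ps, axis=0)
        stack = lambda key: np.stack([v.value for v in g["per_sample"][key]])
        return ForwardOutput(
            h=g["h"].value.copy(),
            m1_params=GaussianParams(g["mu"].value.copy(), g["logvar"].value.copy()),
            samples=g["samples"],
            yhat=yhat,
            yhat_per_sample=yhat_ps,
            m2_params_per_sample=g["m2_params"],
            zs_samples=g["zs_samples"],
            log_px_z=stack("recon_m1"),
            log_px_y=stack("recon_ct"),
            log_px_yzs=stack("recon_m2"),
            log_py_zs=stack("label_m2"),
            kl_m2_per_sample=stack("kl_m2"),
            mode=mode,
            n_samples=n_samples,
        )


def save_checkpoint(path, network: CantmNetwork, vocab, labels: list[str]) -> None:
    """Single-file archive: all weight arrays + config + vocabulary + label set."""
    from .corpus_io import Vocabulary

    tokens = vocab.tokens if isinstance(vocab, Vocabulary) else list(vocab)
    header = {
        "format_version": 1,
        "config": {k: getattr(network.config, k) for k in (
            "vocab_size", "n_classes", "d_h", "d_z", "d_zs", "leaky_slope", "logvar_clip")},
        "vocab": tokens,
        "labels": list(labels),
    }
    np.savez(path, __header=np.array(json.dumps(header)), **network.params)


def load_checkpoint(path):
    """Returns (network, vocab, labels)."""
    from .corpus_io import Vocabulary

    with np.load(path, allow_pickle=False) as arc:
        header = json.loads(str(arc["__header"]))
        cfg = ModelConfig(**header["config"])
        net = CantmNetwork(cfg)
        for name in net.params:
            net.params[name] = arc[name].copy()
    vocab = Vocabulary({t: i for i, t in enumerate(header["vocab"])})
    return net, vocab, header["labels"]
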