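"""Loss assembly and training procedures for the stacked VAE.

The training objective combines, per document:

    L = lambda * L_cls  - E_z[log p(x_bow|z)]        + KL(q(z|x)    || N(0,I))
                        - E_zs[log p(x_bow|yhat,z_s)] - E_zs[log p(yhat|z_s)]
                        + KL(q(z_s|x,yhat) || N(0,I)) - E_yhat[log p(x_bow|yhat)]

i.e. the negative ELBO of the M1 document model, the negative ELBO of the M2
(classification-aware) model, the classifier cross-entropy weighted by
lambda = |V| / |y|, and the class-decoder reconstruction term.  Expectations
over latent draws are Monte-Carlo sample averages; both KL terms are closed
form because posterior and prior are diagonal Gaussians.

Two procedures are provided: fully supervised training, and adaptation to
unlabelled corpora in which every M1 parameter is frozen and only the
class-decoder and M2 parameters learn, driven by the frozen classifier's
predicted labels.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Var
from .model import (
    CLASS_DECODER_PARAMS,
    M2_PARAMS,
    CantmNetwork,
    ForwardOutput,
    GaussianParams,
)

__all__ = [
    "TrainConfig",
    "LossComponents",
    "kl_diag_gaussian",
    "cross_entropy_cls",
    "total_loss",
    "train_supervised",
    "adapt_unlabelled",
    "AdamState",
]


@dataclass
class TrainConfig:
    lambda_cls: float | None = None   # default |V| / |y|, resolved at train time
    batch_size: int = 32
    n_samples_train: int = 10
    n_samples_test: int = 1
    epochs: int = 50
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    patience: int | None = 5          # early stopping on validation loss
    seed: int = 0

    def resolve_lambda(self, vocab_size: int, n_classes: int) -> float:
        lam = self.lambda_cls
        if lam is None:
            lam = vocab_size / n_classes
        if lam < 0:
            raise ValueError("lambda_cls must be >= 0")
        return float(lam)


@dataclass(frozen=True)
class LossComponents:
    """The seven named loss terms, individually inspectable.

    Reconstruction and label terms are stored as log-likelihoods (<= 0);
    ``total`` equals
    lambda*l_cls - recon_m1 + kl_m1 - recon_m2 - label_m2 + kl_m2 - recon_ct.
    """

    l_cls: float
    recon_m1: float
    kl_m1: float
    recon_m2: float
    label_m2: float
    kl_m2: float
    recon_ct: float
    lambda_cls: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        expected = (
            self.lambda_cls * self.l_cls
            - self.recon_m1 + self.kl_m1
            - self.recon_m2 - self.label_m2 + self.kl_m2
            - self.recon_ct
        )
        if self.total is None:
            object.__setattr__(self, "total", expected)
        elif not np.isclose(self.total, expected, atol=1e-9):
            raise ValueError("total inconsistent with its components")


def kl_diag_gaussian(params: GaussianParams) -> float:
    """Closed-form KL(N(mu, diag sigma^2) || N(0, I)).

    0.5 * sum_i (mu_i^2 + sigma_i^2 - logvar_i - 1); non-negative for any input.
    """
    mu = np.asarray(params.mu, dtype=np.float64)
    lv = np.asarray(params.logvar, dtype=np.float64)
    return float(0.5 * np.sum(mu * mu + np.exp(lv) - lv - 1.0))


def cross_entropy_cls(yhat_per_sample, gold_idx: int) -> float:
    """-log yhat[gold], averaged over the latent samples' classifier outputs."""
    vals = [-np.log(np.atleast_2d(y)[0, gold_idx]) for y in yhat_per_sample]
    return float(np.mean(vals))


def total_loss(fo: ForwardOutput, gold_idx: int | None, cfg: TrainConfig,
               *, n_classes: int | None = None, vocab_size: int | None = None,
               lambda_cls: float | None = None) -> LossComponents:
    """Assemble the loss components from a single-document forward output."""
    if lambda_cls is None:
        if vocab_size is None or n_classes is None:
            raise ValueError("pass lambda_cls or (vocab_size and n_classes)")
        lambda_cls = cfg.resolve_lambda(vocab_size, n_classes)
    if gold_idx is None:
        raise ValueError("gold label required for the supervised loss")
    l_cls = cross_entropy_cls(fo.yhat_per_sample, gold_idx)
    kl_m1 = kl_diag_gaussian(GaussianParams(fo.m1_params.mu[0], fo.m1_params.logvar[0]))
    return LossComponents(
        l_cls=l_cls,
        recon_m1=float(fo.log_px_z.mean(axis=0)[0]),
        kl_m1=kl_m1,
        recon_m2=float(fo.log_px_yzs.mean(axis=0)[0]),
        label_m2=float(fo.log_py_zs.mean(axis=0)[0]),
        kl_m2=float(fo.kl_m2_per_sample.mean(axis=0)[0]),
        recon_ct=float(fo.log_px_y.mean(axis=0)[0]),
        lambda_cls=lambda_cls,
    )


def _batch_loss_graph(
    net: CantmNetwork,
    X: np.ndarray,
    gold_onehot: np.ndarray | None,
    lam: float,
    n_samples: int,
    rng: np.random.Generator,
    *,
    supervised: bool = True,
):
    """Scalar loss Var (mean over the batch) plus the component means."""
    g = net.forward_graph(X, n_samples=n_samples, mode="train", rng=rng)
    n = X.shape[0]

    if supervised:
        gold = Var(gold_onehot)
        acc = None
        for log_yhat in g["log_yhat_per_sample"]:
            term = -(gold * log_yhat).sum(axis=1)
            acc = term if acc is None else acc + term
        l_cls = acc / len(g["log_yhat_per_sample"])
        per_doc = (
            l_cls * lam
            - g["recon_m1"] + g["kl_m1"]
            - g["recon_m2"] - g["label_m2"] + g["kl_m2"]
            - g["recon_ct"]
        )
    else:
        l_cls = Var(np.zeros(n))
        per_doc = -g["recon_m2"] - g["label_m2"] + g["kl_m2"] - g["recon_ct"]

    loss = per_doc.mean()
    comps = LossComponents(
        l_cls=float(l_cls.value.mean()),
        recon_m1=float(g["recon_m1"].value.mean()),
        kl_m1=float(g["kl_m1"].value.mean()),
        recon_m2=float(g["recon_m2"].value.mean()),
        label_m2=float(g["label_m2"].value.mean()),
        kl_m2=float(g["kl_m2"].value.mean()),
        recon_ct=float(g["recon_ct"].value.mean()),
        lambda_cls=lam if supervised else 0.0,
    )
    return loss, g["params"], comps


class AdamState:
    """First-order adaptive-moment optimiser over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.cfg = cfg

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             trainable: frozenset | None = None) -> None:
        c = self.cfg
        self.t += 1
        for k in params:
            if trainable is not None and k not in trainable:
                continue
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            params[k] -= c.lr * mhat / (np.sqrt(vhat) + c.adam_eps)


def _drop_empty(X: np.ndarray, y: np.ndarray | None):
    keep = X.sum(axis=1) > 0
    if y is None:
        return X[keep], None
    return X[keep], y[keep]


def train_supervised(
    net: CantmNetwork,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    *,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> list[dict]:
    """Minimise the mean total loss by stochastic gradient steps (in place).

    Returns a per-epoch training log (each entry: epoch plus every loss
    component).  With a validation set and ``cfg.patience`` set, training
    stops once validation loss has not improved for `patience` epochs and the
    best parameters are restored.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    X, y = _drop_empty(X, y)
    if len(X) == 0:
        raise ValueError("no non-empty documents to train on")
    n_classes = net.config.n_classes
    lam = cfg.resolve_lambda(net.config.vocab_size, n_classes)
    onehot = np.eye(n_classes)[y]
    rng = np.random.default_rng(cfg.seed)
    opt = AdamState(net.params, cfg)
    log: list[dict] = []
    best_val, best_params, bad_epochs = np.inf, None, 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(X))
        epoch_comps: list[LossComponents] = []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, P, comps = _batch_loss_graph(
                net, X[idx], onehot[idx], lam, cfg.n_samples_train, rng
            )
            loss.backward()
            grads = {k: P[k].grad for k in net.params}
            opt.step(net.params, grads)
            epoch_comps.append(comps)
        entry = {"epoch": epoch}
        for f in ("l_cls", "recon_m1", "kl_m1", "recon_m2",
                  "label_m2", "kl_m2", "recon_ct", "total"):
            entry[f] = float(np.mean([getattr(c, f) for c in epoch_comps]))
        if X_val is not None and len(X_val) and cfg.patience is not None:
            val = evaluate_mean_loss(net, X_val, y_val, cfg, rng=np.random.default_rng(cfg.seed + 1))
            entry["val_total"] = val
            if val < best_val - 1e-9:
                best_val, bad_epochs = val, 0
                best_params = {k: v.copy() for k, v in net.params.items()}
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    log.append(entry)
                    break
        log.append(entry)
    if best_params is not None:
        net.params.update(best_params)
    return log


def evaluate_mean_loss(
    net: CantmNetwork, X: np.ndarray, y: np.ndarray, cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean supervised total loss over a corpus (no gradient updates)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    X, y = _drop_empty(X, y)
    lam = cfg.resolve_lambda(net.config.vocab_size, net.config.n_classes)
    onehot = np.eye(net.config.n_classes)[y]
    rng = rng or np.random.default_rng(cfg.seed)
    total, n = 0.0, 0
    for start in range(0, len(X), cfg.batch_size):
        sl = slice(start, start + cfg.batch_size)
        loss, _, _ = _batch_loss_graph(
            net, X[sl], onehot[sl], lam, cfg.n_samples_train, rng
        )
        total += float(loss.value) * (len(X[sl]))
        n += len(X[sl])
    return total / n


def adapt_unlabelled(
    net: CantmNetwork,
    X_unlabelled: np.ndarray,
    cfg: TrainConfig,
    *,
    train_class_decoder: bool = True,
) -> CantmNetwork:
    """Adapt to an unlabelled corpus; M1 stays frozen bit-for-bit.

    Returns a new network: the class-decoder (R_ct path, switchable) and all
    M2 parameters are trained on the unlabelled objective, with the frozen
    classifier's predictions yhat standing in for labels.  Classification
    outputs are untouched because every parameter on the prediction path is
    frozen.
    """
    adapted = CantmNetwork(net.config)
    adapted.params = {k: v.copy() for k, v in net.params.items()}
    X = np.asarray(X_unlabelled, dtype=np.float64)
    X, _ = _drop_empty(X, None)
    if len(X) == 0:
        raise ValueError("no non-empty documents to adapt on")
    trainable = M2_PARAMS | CLASS_DECODER_PARAMS if train_class_decoder else M2_PARAMS
    rng = np.random.default_rng(cfg.seed)
    opt = AdamState(adapted.params, cfg)
    for _ in range(cfg.epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, P, _ = _batch_loss_graph(
                adapted, X[idx], None, 0.0, cfg.n_samples_train, rng, supervised=False
            )
            loss.backward()
            grads = {k: P[k].grad for k in adapted.params}
            opt.step(adapted.params, grads, trainable=frozenset(trainable))
    return adapted
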