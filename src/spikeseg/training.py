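"""Objectives and optimization for the three network variants.

The stochastic variants maximize the mini-batch evidence lower bound
(stochastic gradient variational Bayes): the data term is scaled by N/M
(dataset size over batch size) with one weight/gate/mask sample per
mini-batch example, and the regularizer — the KL divergence from the
variational posterior to the prior (SSD), or the Gaussian-prior L2 penalty
(MAP/BD) — is added once per update at full weight.  Optimization uses Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .meshnet import MeshNet, softmax
from .volumes import ValidationError

__all__ = [
    "TrainConfig",
    "Adam",
    "TrainingDiverged",
    "sgvb_loss",
    "train",
    "search_keep_prob",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults follow the full-scale reference protocol (Adam at 1e-4, 32
    sub-volumes per mini-batch); desk-scale runs override them.  ``n_steps``
    counts parameter updates; ``dataset_size`` is N in the N/M ELBO scaling
    (defaults to the number of training tiles).  ``kl_anneal_steps`` ramps
    the regularizer weight linearly from 0 — off by default.
    """

    learning_rate: float = 1e-4
    minibatch_size: int = 32
    n_steps: int = 1000
    seed: int = 0
    dataset_size: int | None = None
    eval_every: int | None = None
    kl_anneal_steps: int = 0
    keep_best: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.minibatch_size < 1:
            raise ValidationError("minibatch_size must be >= 1")


class Adam:
    """Standard Adam on a named-parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k].astype(np.float64)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.lr * (self.m[k] / b1t)
                      / (np.sqrt(self.v[k] / b2t) + self.eps))
            p -= update.astype(p.dtype)


def _nll_and_grad(scores: np.ndarray, labels: np.ndarray, scale: float):
    """Per-example categorical negative log-likelihood summed over voxels,
    and d(scale * sum nll)/d(scores), computed with a stable log-softmax."""
    z = scores - scores.max(axis=-1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    log_probs = z - logsumexp
    onehot_ll = np.take_along_axis(log_probs, labels[..., None], axis=-1)[..., 0]
    nll = -onehot_ll.reshape(scores.shape[0], -1).sum(axis=1)
    probs = np.exp(log_probs)
    grad = probs
    np.put_along_axis(
        grad, labels[..., None],
        np.take_along_axis(grad, labels[..., None], axis=-1) - 1.0, axis=-1,
    )
    grad *= scale
    return nll, grad


def sgvb_loss(batch, model: MeshNet, config: TrainConfig,
              rng: np.random.Generator | None = None):
    """Mini-batch loss: ``(N/M) * sum_m nll_m + regularizer``.

    ``batch`` is an ``(x, y)`` pair of arrays with a leading example axis;
    one stochastic forward sample is used per example (gates, weight noise
    and dropout masks all carry an example axis).  For the MAP variant the
    regularizer is the L2 penalty and the forward pass is deterministic.

    Returns ``(loss, info)`` where info holds the data term, the
    regularizer term and the per-example negative log-likelihoods.
    """
    x, y = batch
    x = np.asarray(x)
    y = np.asarray(y)
    m = x.shape[0]
    if m == 0:
        raise ValidationError("empty mini-batch")
    n = config.dataset_size or m
    if m > n:
        raise ValidationError("minibatch larger than dataset_size")
    rng = rng or np.random.default_rng(config.seed)
    scores = model.forward(x, rng=rng, sample=True)
    scale = n / m
    nll, _ = _nll_and_grad(scores, y.astype(np.int64), scale)
    data_term = scale * float(nll.sum())
    reg_term = model.regularizer()
    loss = data_term + reg_term
    info = {
        "data_term": data_term,
        "reg_term": reg_term,
        "per_example_nll": nll,
    }
    return loss, info


def _mean_tile_dice(model: MeshNet, x, y, n_classes: int,
                    chunk: int = 8) -> float:
    """Validation mean Dice with TP/FN/FP pooled across all tiles.

    Pooling treats the validation tiles as one composite volume: per-tile
    scoring would credit absent-from-both classes on many tiles and rank an
    all-background model above a genuinely better one.  Deterministic
    forward (posterior means), chunked to bound memory."""
    from .evaluation import mean_dice

    pred = np.empty(y.shape, dtype=np.int64)
    for i in range(0, x.shape[0], chunk):
        scores = model.forward(x[i:i + chunk], sample=False)
        pred[i:i + chunk] = scores.argmax(axis=-1)
    return mean_dice(pred, y, n_classes)


def train(model: MeshNet, train_data, config: TrainConfig, val_data=None):
    """Optimize the model; returns ``(model, log)``.

    ``train_data``/``val_data`` are ``(X, Y)`` arrays of tile pairs (leading
    example axis).  The log is a DataFrame with one row per step (loss, data
    term, regularizer term) plus periodic validation mean Dice; with
    ``keep_best`` the parameters with the best validation Dice are restored
    at the end.  A non-finite loss aborts with :class:`TrainingDiverged`.
    """
    x_train, y_train = train_data
    x_train = np.asarray(x_train)
    y_train = np.asarray(y_train, dtype=np.int64)
    n = x_train.shape[0]
    if n == 0:
        raise ValidationError("empty training split")
    cfg = config
    if cfg.dataset_size is None:
        cfg = replace(cfg, dataset_size=n)
    if cfg.minibatch_size > n:
        cfg = replace(cfg, minibatch_size=n)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    eval_every = cfg.eval_every or max(cfg.n_steps // 5, 1)
    records = []
    best = (-np.inf, None)
    scale_n = cfg.dataset_size / cfg.minibatch_size
    for step in range(cfg.n_steps):
        idx = rng.choice(n, size=cfg.minibatch_size, replace=False)
        xb, yb = x_train[idx], y_train[idx]
        model.zero_grads()
        scores = model.forward(xb, rng=rng, sample=True)
        nll, dscores = _nll_and_grad(scores, yb, scale_n)
        data_term = scale_n * float(nll.sum())
        model.backward(dscores.astype(scores.dtype))
        kl_w = 1.0
        if cfg.kl_anneal_steps > 0:
            kl_w = min(1.0, (step + 1) / cfg.kl_anneal_steps)
        reg_term = model.regularizer()
        model.add_regularizer_grads(kl_w)
        loss = data_term + kl_w * reg_term
        if not np.isfinite(loss):
            raise TrainingDiverged(
                f"non-finite loss at step {step}: data={data_term}, reg={reg_term}"
            )
        opt.step(model.parameters(), model.gradients())
        rec = {"step": step, "loss": loss, "data_term": data_term,
               "reg_term": reg_term, "val_dice": np.nan}
        if val_data is not None and ((step + 1) % eval_every == 0
                                     or step == cfg.n_steps - 1):
            vd = _mean_tile_dice(model, np.asarray(val_data[0]),
                                 np.asarray(val_data[1], dtype=np.int64),
                                 model.spec.n_classes)
            rec["val_dice"] = vd
            if cfg.keep_best and vd > best[0]:
                best = (vd, model.copy_parameters())
        records.append(rec)
    if cfg.keep_best and best[1] is not None:
        model.set_parameters(best[1])
    return model, pd.DataFrame.from_records(records)


def search_keep_prob(make_model, train_data, val_data, config: TrainConfig,
                     candidates=(0.95, 0.9, 0.75, 0.5)):
    """Validation search over Bernoulli-dropout keep probabilities.

    ``make_model(keep_prob)`` builds a fresh BD network per candidate; each
    is trained under ``config`` and scored by validation mean Dice.  Returns
    ``(best_keep_prob, results_dict)``.
    """
    results = {}
    for p in candidates:
        model, log = train(make_model(p), train_data, config, val_data)
        results[p] = float(log["val_dice"].dropna().iloc[-1])
    best = max(results, key=results.get)
    return best, results
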