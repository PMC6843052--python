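"""Dilated 3D convolution layers under three weight models.

The segmentation network compares three treatments of the convolution
weights:

* **MAP** — a point estimate under a standard-normal prior (L2 penalty).
* **Bernoulli dropout (BD)** — point weights with a random 0/1 mask applied
  to every spatial element of the layer input (shared across channels),
  redrawn per example per forward pass, at train and test time alike.
* **Spike-and-slab dropout (SSD)** — each filter ``f`` has a learned
  inclusion gate ``b_f`` (concrete relaxation of a Bernoulli with learned
  probability ``p_f``) and each weight a Gaussian ``N(mu_ft, sigma_ft^2)``
  with learned mean and scale.  Sampling uses the local reparameterization
  trick: the Gaussian noise is moved from the weights into the convolution,
  so pre-activations are drawn from ``N(mu*, sigma*^2)`` with
  ``mu* = conv(h, mu)`` and ``sigma*^2 = conv(h^2, sigma^2)``.

All array layouts are channels-last: activations ``(B, X, Y, Z, C)`` and
weights ``(kx, ky, kz, C_in, F)``.  Gradients are hand-derived; every layer
caches what its backward pass needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .volumes import ValidationError

__all__ = [
    "FilterGeometry",
    "PriorSpec",
    "ConcreteSpec",
    "LayerPosterior",
    "sample_concrete",
    "ffg_moments",
    "ffg_dilated_conv",
    "bernoulli_dropout_conv",
    "kl_bernoulli",
    "kl_gaussian",
    "layer_kl",
    "map_penalty",
    "conv3d",
    "conv3d_grad_w",
    "conv3d_grad_h",
    "MapConvLayer",
    "BernoulliDropoutConvLayer",
    "SpikeSlabConvLayer",
]

_U_EPS = 1e-7  # clamp for uniform draws: log terms diverge at 0/1
_VAR_EPS = 1e-12


# ---------------------------------------------------------------------------
# small math helpers

def softplus(x):
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


def sigmoid(x):
    from scipy.special import expit

    return expit(x)


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


# ---------------------------------------------------------------------------
# geometry and parameter containers

@dataclass(frozen=True)
class FilterGeometry:
    """Tap layout of a dilated volumetric filter.

    Half-widths (a, b, c) give kernel edges (2a+1, 2b+1, 2c+1); taps are
    spaced ``dilation`` voxels apart.  Padding equal to ``half_width *
    dilation`` preserves spatial shape.
    """

    a: int = 1
    b: int = 1
    c: int = 1
    dilation: int = 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValidationError("filter half-widths must be non-negative")
        if self.dilation < 1:
            raise ValidationError("dilation must be >= 1")

    @property
    def kernel_shape(self) -> tuple[int, int, int]:
        return (2 * self.a + 1, 2 * self.b + 1, 2 * self.c + 1)

    @property
    def n_taps(self) -> int:
        kx, ky, kz = self.kernel_shape
        return kx * ky * kz

    @property
    def taps(self) -> list[tuple[int, int, int]]:
        """Tap index set {-a..a} x {-b..b} x {-c..c} in lexicographic order."""
        return list(
            product(
                range(-self.a, self.a + 1),
                range(-self.b, self.b + 1),
                range(-self.c, self.c + 1),
            )
        )


@dataclass(frozen=True)
class PriorSpec:
    """Spike-and-slab prior: Bernoulli inclusion x Gaussian slab."""

    p_prior: float = 0.5
    mu_prior: float = 0.0
    sigma_prior: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.p_prior < 1.0):
            raise ValidationError("p_prior must lie in (0, 1)")
        if self.sigma_prior <= 0:
            raise ValidationError("sigma_prior must be positive")


@dataclass(frozen=True)
class ConcreteSpec:
    """Temperature of the concrete (relaxed Bernoulli) gate distribution."""

    temperature: float = 0.02

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")


@dataclass
class LayerPosterior:
    """Variational parameters of one spike-and-slab conv layer.

    Per filter: inclusion probability ``p_f`` stored as a logit; per weight:
    Gaussian mean ``mu`` and scale ``sigma = softplus(rho) > 0`` (positivity
    by parameterization, not clipping).  Biases are deterministic.
    """

    p_logit: np.ndarray          # (F,)
    mu: np.ndarray               # (kx, ky, kz, C, F)
    rho: np.ndarray              # (kx, ky, kz, C, F)
    bias: np.ndarray             # (F,)

    @property
    def n_filters(self) -> int:
        return self.p_logit.shape[0]

    @property
    def p(self) -> np.ndarray:
        return sigmoid(self.p_logit)

    @property
    def sigma(self) -> np.ndarray:
        return softplus(self.rho)

    @classmethod
    def initialize(
        cls,
        geom: FilterGeometry,
        in_channels: int,
        n_filters: int,
        rng: np.random.Generator,
        init_p: float = 0.9,
        init_sigma: float = 0.01,
        dtype=np.float32,
    ) -> "LayerPosterior":
        """Fan-in-scaled means, sigma ~= init_sigma, p_f = init_p.

        The small sigma init keeps early training close to the
        deterministic regime: at sigma comparable to the prior scale the
        compounded pre-activation noise across the deep stack swamps the
        signal and gradients carry almost no information, while the KL
        pulls sigma up toward the prior scale as data allows.  Positivity
        and interval constraints hold by construction.
        """
        shape = geom.kernel_shape + (in_channels, n_filters)
        fan_in = in_channels * geom.n_taps
        mu = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        rho = np.full(shape, softplus_inv(init_sigma))
        return cls(
            p_logit=np.full(n_filters, float(logit(init_p)), dtype=dtype),
            mu=mu.astype(dtype),
            rho=rho.astype(dtype),
            bias=np.zeros(n_filters, dtype=dtype),
        )


# ---------------------------------------------------------------------------
# convolution primitives (tap-loop GEMM; channels-last)

def _pad_amounts(kernel_shape, dilation):
    return tuple(((k - 1) // 2) * dilation for k in kernel_shape)


def _check_conv_args(h, w):
    if h.ndim != 5:
        raise ValidationError("conv3d expects activations of shape (B,X,Y,Z,C)")
    if w.ndim != 5:
        raise ValidationError("conv3d expects weights of shape (kx,ky,kz,C,F)")
    if h.shape[-1] != w.shape[3]:
        raise ValidationError(
            f"channel mismatch: input has {h.shape[-1]}, weights expect {w.shape[3]}"
        )


def conv3d(h: np.ndarray, w: np.ndarray, dilation: int = 1) -> np.ndarray:
    """Shape-preserving dilated convolution (zero padding = half-width * l)."""
    _check_conv_args(h, w)
    B, X, Y, Z, C = h.shape
    kx, ky, kz, _, F = w.shape
    px, py, pz = _pad_amounts((kx, ky, kz), dilation)
    if min(X + 2 * px - (kx - 1) * dilation,
           Y + 2 * py - (ky - 1) * dilation,
           Z + 2 * pz - (kz - 1) * dilation) < 1:
        raise ValidationError("input smaller than dilated kernel extent")
    hp = np.pad(h, ((0, 0), (px, px), (py, py), (pz, pz), (0, 0)))
    wf = w.reshape(-1, C, F)
    out = np.zeros((B * X * Y * Z, F), dtype=h.dtype)
    buf = np.empty((B, X, Y, Z, C), dtype=h.dtype)
    n = 0
    d = dilation
    for i in range(kx):
        for j in range(ky):
            for k in range(kz):
                np.copyto(buf, hp[:, i * d:i * d + X, j * d:j * d + Y,
                                  k * d:k * d + Z, :])
                out += buf.reshape(-1, C) @ wf[n]
                n += 1
    return out.reshape(B, X, Y, Z, F)


def _conv3d_pair(h: np.ndarray, w1: np.ndarray, w2: np.ndarray,
                 dilation: int = 1):
    """Two convolutions sharing one input-slice pass: ``conv(h, w1)`` and
    ``conv(h^2, w2)`` (the SSD mean/variance pair).  Shares the per-tap
    buffer copy; the square is computed in place on the buffer."""
    _check_conv_args(h, w1)
    B, X, Y, Z, C = h.shape
    kx, ky, kz, _, F = w1.shape
    px, py, pz = _pad_amounts((kx, ky, kz), dilation)
    hp = np.pad(h, ((0, 0), (px, px), (py, py), (pz, pz), (0, 0)))
    w1f = w1.reshape(-1, C, F)
    w2f = w2.reshape(-1, C, F)
    out1 = np.zeros((B * X * Y * Z, F), dtype=h.dtype)
    out2 = np.zeros((B * X * Y * Z, F), dtype=h.dtype)
    buf = np.empty((B, X, Y, Z, C), dtype=h.dtype)
    n = 0
    d = dilation
    for i in range(kx):
        for j in range(ky):
            for k in range(kz):
                np.copyto(buf, hp[:, i * d:i * d + X, j * d:j * d + Y,
                                  k * d:k * d + Z, :])
                flat = buf.reshape(-1, C)
                out1 += flat @ w1f[n]
                np.square(flat, out=flat)
                out2 += flat @ w2f[n]
                n += 1
    shape = (B, X, Y, Z, F)
    return out1.reshape(shape), out2.reshape(shape)


def _conv3d_pair_grad_w(h: np.ndarray, dout1: np.ndarray, dout2: np.ndarray,
                        kernel_shape, dilation: int = 1):
    """Weight gradients for the mean/variance conv pair, sharing slices:
    returns (d/dw1 of conv(h, w1)·dout1, d/dw2 of conv(h^2, w2)·dout2)."""
    B, X, Y, Z, C = h.shape
    F = dout1.shape[-1]
    kx, ky, kz = kernel_shape
    px, py, pz = _pad_amounts(kernel_shape, dilation)
    hp = np.pad(h, ((0, 0), (px, px), (py, py), (pz, pz), (0, 0)))
    d1 = dout1.reshape(-1, F)
    d2 = dout2.reshape(-1, F)
    dw1 = np.empty((kx * ky * kz, C, F), dtype=h.dtype)
    dw2 = np.empty((kx * ky * kz, C, F), dtype=h.dtype)
    buf = np.empty((B, X, Y, Z, C), dtype=h.dtype)
    n = 0
    d = dilation
    for i in range(kx):
        for j in range(ky):
            for k in range(kz):
                np.copyto(buf, hp[:, i * d:i * d + X, j * d:j * d + Y,
                                  k * d:k * d + Z, :])
                flat = buf.reshape(-1, C)
                dw1[n] = flat.T @ d1
                np.square(flat, out=flat)
                dw2[n] = flat.T @ d2
                n += 1
    ks = (kx, ky, kz, C, F)
    return dw1.reshape(ks), dw2.reshape(ks)


def conv3d_grad_w(h: np.ndarray, dout: np.ndarray, kernel_shape,
                  dilation: int = 1) -> np.ndarray:
    """Gradient of ``conv3d`` w.r.t. the weights."""
    B, X, Y, Z, C = h.shape
    F = dout.shape[-1]
    kx, ky, kz = kernel_shape
    px, py, pz = _pad_amounts(kernel_shape, dilation)
    hp = np.pad(h, ((0, 0), (px, px), (py, py), (pz, pz), (0, 0)))
    dof = dout.reshape(-1, F)
    dw = np.empty((kx * ky * kz, C, F), dtype=h.dtype)
    buf = np.empty((B, X, Y, Z, C), dtype=h.dtype)
    n = 0
    d = dilation
    for i in range(kx):
        for j in range(ky):
            for k in range(kz):
                np.copyto(buf, hp[:, i * d:i * d + X, j * d:j * d + Y,
                                  k * d:k * d + Z, :])
                dw[n] = buf.reshape(-1, C).T @ dof
                n += 1
    return dw.reshape(kx, ky, kz, C, F)


def conv3d_grad_h(dout: np.ndarray, w: np.ndarray, dilation: int = 1) -> np.ndarray:
    """Gradient of ``conv3d`` w.r.t. the input (transposed convolution)."""
    B, X, Y, Z, F = dout.shape
    kx, ky, kz, C, _ = w.shape
    px, py, pz = _pad_amounts((kx, ky, kz), dilation)
    wf = w.reshape(-1, C, F)
    dhp = np.zeros((B, X + 2 * px, Y + 2 * py, Z + 2 * pz, C), dtype=dout.dtype)
    dof = dout.reshape(-1, F)
    n = 0
    d = dilation
    for i in range(kx):
        for j in range(ky):
            for k in range(kz):
                contrib = (dof @ wf[n].T).reshape(B, X, Y, Z, C)
                dhp[:, i * d:i * d + X, j * d:j * d + Y, k * d:k * d + Z, :] += contrib
                n += 1
    if px or py or pz:
        return np.ascontiguousarray(
            dhp[:, px:px + X, py:py + Y, pz:pz + Z, :]
        )
    return dhp


# ---------------------------------------------------------------------------
# functional operations (single-example API)

def sample_concrete(p_f, spec: ConcreteSpec | None = None, u=None,
                    rng: np.random.Generator | None = None):
    """Concrete-relaxed Bernoulli gate.

    ``b = sigmoid((log p - log(1-p) + log u - log(1-u)) / t)`` with
    ``u ~ Unif(0,1)``; converges in distribution to Bernoulli(p) as the
    temperature t -> 0.  Differentiable in ``p``.  ``u`` draws are clamped
    away from {0, 1} where the log terms diverge.
    """
    spec = spec or ConcreteSpec()
    p = np.asarray(p_f, dtype=float)
    if (p <= 0).any() or (p >= 1).any():
        raise ValidationError("p_f must lie in the open interval (0, 1)")
    if u is None:
        rng = rng or np.random.default_rng()
        u = rng.random(p.shape)
    u = np.clip(np.asarray(u, dtype=float), _U_EPS, 1.0 - _U_EPS)
    z = (logit(p) + logit(u)) / spec.temperature
    out = sigmoid(z)
    return out if out.shape else float(out)


def _single_to_batch(h):
    h = np.asarray(h)
    if h.ndim == 3:
        h = h[..., None]
    if h.ndim != 4:
        raise ValidationError("expected a single example of shape (X,Y,Z[,C])")
    return h[None]


def ffg_moments(h, posterior: LayerPosterior, geom: FilterGeometry):
    """Induced pre-activation moments of the fully factorized Gaussian slab:
    ``mu* = conv(h, mu)`` and ``sigma*^2 = conv(h^2, sigma^2)``."""
    hb = _single_to_batch(h)
    mu_star = conv3d(hb, posterior.mu.astype(hb.dtype), geom.dilation)[0]
    sig2 = (posterior.sigma ** 2).astype(hb.dtype)
    var_star = conv3d(hb * hb, sig2, geom.dilation)[0]
    return mu_star, var_star


def ffg_dilated_conv(h, posterior: LayerPosterior, geom: FilterGeometry,
                     noise=None, gates=None):
    """One local-reparameterization sample of a spike-and-slab conv layer.

    Output = ``gate_f * (mu* + sigma* * eps) + bias`` per voxel and filter.
    ``noise`` is a standard-normal grid (zeros when omitted); ``gates`` a
    per-filter vector (ones when omitted, i.e. slab only).
    """
    mu_star, var_star = ffg_moments(h, posterior, geom)
    sd_star = np.sqrt(var_star + _VAR_EPS)
    if noise is None:
        noise = np.zeros_like(mu_star)
    noise = np.asarray(noise, dtype=mu_star.dtype)
    if noise.shape != mu_star.shape:
        raise ValidationError(
            f"noise shape {noise.shape} != pre-activation shape {mu_star.shape}"
        )
    if gates is None:
        gates = np.ones(posterior.n_filters, dtype=mu_star.dtype)
    gates = np.asarray(gates, dtype=mu_star.dtype)
    return gates * (mu_star + sd_star * noise) + posterior.bias.astype(mu_star.dtype)


def bernoulli_dropout_conv(h, weights, keep_prob: float, geom: FilterGeometry,
                           mask=None, rng: np.random.Generator | None = None,
                           bias=None):
    """Bernoulli-dropout convolution: mask the input, then convolve.

    The 0/1 mask is indexed by the spatial axes only (shared across
    channels) and redrawn per forward pass; ``keep_prob = 1`` reduces to the
    deterministic convolution.  No inverted-dropout rescaling is applied —
    the same masking runs at train and test time for MC prediction.
    """
    if not (0.0 < keep_prob <= 1.0):
        raise ValidationError("keep_prob must lie in (0, 1]")
    hb = _single_to_batch(h).copy()
    if keep_prob < 1.0:
        if mask is None:
            rng = rng or np.random.default_rng()
            mask = (rng.random(hb.shape[1:4]) < keep_prob)
        mask = np.asarray(mask).astype(hb.dtype)
        if mask.shape != hb.shape[1:4]:
            raise ValidationError("mask must cover the spatial grid")
        hb *= mask[None, ..., None]
    w = np.asarray(weights, dtype=hb.dtype)
    out = conv3d(hb, w, geom.dilation)[0]
    if bias is not None:
        out = out + np.asarray(bias, dtype=out.dtype)
    return out


# ---------------------------------------------------------------------------
# KL divergences and penalties

def kl_bernoulli(p_f, p_prior):
    """KL(Bern(p_f) || Bern(p_prior)); open-interval arguments only."""
    p = np.asarray(p_f, dtype=float)
    q = np.asarray(p_prior, dtype=float)
    if (p <= 0).any() or (p >= 1).any() or (q <= 0).any() or (q >= 1).any():
        raise ValidationError("Bernoulli KL arguments must lie in (0, 1)")
    out = p * (np.log(p) - np.log(q)) + (1 - p) * (np.log1p(-p) - np.log1p(-q))
    return out if out.shape else float(out)


def kl_gaussian(mu, sigma, prior: PriorSpec | None = None):
    """KL(N(mu, sigma^2) || N(mu_prior, sigma_prior^2)), elementwise."""
    prior = prior or PriorSpec()
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise ValidationError("sigma must be positive")
    sp = prior.sigma_prior
    out = (
        np.log(sp) - np.log(sigma)
        + (sigma ** 2 + (mu - prior.mu_prior) ** 2) / (2.0 * sp ** 2)
        - 0.5
    )
    return out if out.shape else float(out)


def layer_kl(posterior: LayerPosterior, prior: PriorSpec | None = None) -> float:
    """Total layer KL: per-filter gate KL plus per-weight Gaussian KL,
    summed over independent filters and taps."""
    prior = prior or PriorSpec()
    gate = np.sum(kl_bernoulli(posterior.p, prior.p_prior))
    slab = np.sum(kl_gaussian(posterior.mu, posterior.sigma, prior))
    return float(gate + slab)


def map_penalty(weights) -> float:
    """Negative log of a standard-normal weight prior, constants dropped:
    ``0.5 * sum(w^2)``."""
    w = np.asarray(weights, dtype=float)
    return float(0.5 * np.sum(w * w))


# ---------------------------------------------------------------------------
# trainable layer objects (batched, with manual backprop)

class _LayerBase:
    """Common bookkeeping: parameter dict, gradient dict, ReLU cache."""

    def __init__(self, geom: FilterGeometry, in_channels: int, n_filters: int,
                 relu: bool = True, dtype=np.float32):
        self.geom = geom
        self.in_channels = in_channels
        self.n_filters = n_filters
        self.relu = relu
        self.dtype = np.dtype(dtype)
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache: dict = {}

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _apply_relu(self, y):
        if self.relu:
            mask = y > 0
            self._cache["relu_mask"] = mask
            return np.where(mask, y, 0)
        return y

    def _relu_back(self, dy):
        if self.relu:
            return dy * self._cache["relu_mask"]
        return dy

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


class MapConvLayer(_LayerBase):
    """Deterministic dilated convolution with point weights (MAP variant)."""

    stochastic = False

    def __init__(self, geom, in_channels, n_filters, relu=True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__(geom, in_channels, n_filters, relu, dtype)
        rng = rng or np.random.default_rng()
        shape = geom.kernel_shape + (in_channels, n_filters)
        fan_in = in_channels * geom.n_taps
        self.params = {
            "w": (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype),
            "b": np.zeros(n_filters, dtype=dtype),
        }
        self.zero_grads()

    def forward(self, x, rng=None, sample=True):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        self._cache["x"] = x
        y = conv3d(x, self.params["w"], self.geom.dilation) + self.params["b"]
        return self._apply_relu(y)

    def backward(self, dy):
        dy = self._relu_back(dy)
        x = self._cache["x"]
        self.grads["w"] += conv3d_grad_w(x, dy, self.geom.kernel_shape,
                                         self.geom.dilation)
        self.grads["b"] += dy.sum(axis=(0, 1, 2, 3))
        return conv3d_grad_h(dy, self.params["w"], self.geom.dilation)

    # L2 penalty from the standard-normal weight prior (biases free)
    def regularizer(self, prior=None) -> float:
        return map_penalty(self.params["w"])

    def add_regularizer_grads(self, scale: float = 1.0, prior=None) -> None:
        self.grads["w"] += scale * self.params["w"]


class BernoulliDropoutConvLayer(MapConvLayer):
    """Point weights, Bernoulli mask on every spatial input element."""

    stochastic = True

    def __init__(self, geom, in_channels, n_filters, relu=True, keep_prob=0.9,
                 rng=None, dtype=np.float32):
        if not (0.0 < keep_prob <= 1.0):
            raise ValidationError("keep_prob must lie in (0, 1]")
        super().__init__(geom, in_channels, n_filters, relu, rng=rng, dtype=dtype)
        self.keep_prob = float(keep_prob)

    def forward(self, x, rng=None, sample=True):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        if sample and self.keep_prob < 1.0:
            rng = rng or np.random.default_rng()
            mask = (rng.random(x.shape[:4]) < self.keep_prob).astype(self.dtype)
            xm = x * mask[..., None]
        elif not sample and self.keep_prob < 1.0:
            mask = np.full(x.shape[:4], self.keep_prob, dtype=self.dtype)
            xm = x * self.keep_prob
        else:
            mask = None
            xm = x
        self._cache["x"] = xm
        self._cache["mask"] = mask
        y = conv3d(xm, self.params["w"], self.geom.dilation) + self.params["b"]
        return self._apply_relu(y)

    def backward(self, dy):
        dy = self._relu_back(dy)
        xm = self._cache["x"]
        self.grads["w"] += conv3d_grad_w(xm, dy, self.geom.kernel_shape,
                                         self.geom.dilation)
        self.grads["b"] += dy.sum(axis=(0, 1, 2, 3))
        dx = conv3d_grad_h(dy, self.params["w"], self.geom.dilation)
        if self._cache["mask"] is not None:
            dx *= self._cache["mask"][..., None]
        return dx


class SpikeSlabConvLayer(_LayerBase):
    """Spike-and-slab dropout conv layer with learned gates and weight scales.

    Forward (sampled): ``z = b_f * (mu* + sigma* eps) + bias`` with one gate
    draw per filter per example and fresh pre-activation noise, per the local
    reparameterization above.  Deterministic mode (``sample=False``) uses the
    posterior means: ``z = p_f * mu* + bias``.
    """

    stochastic = True

    def __init__(self, geom, in_channels, n_filters, relu=True,
                 prior: PriorSpec | None = None, temperature: float = 0.02,
                 init_p: float = 0.9, init_sigma: float = 0.01,
                 rng=None, dtype=np.float32):
        super().__init__(geom, in_channels, n_filters, relu, dtype)
        rng = rng or np.random.default_rng()
        post = LayerPosterior.initialize(
            geom, in_channels, n_filters, rng, init_p, init_sigma, dtype
        )
        self.params = {
            "mu": post.mu, "rho": post.rho,
            "p_logit": post.p_logit, "b": post.bias,
        }
        self.prior = prior or PriorSpec()
        self.concrete = ConcreteSpec(temperature)
        self.zero_grads()

    @property
    def posterior(self) -> LayerPosterior:
        return LayerPosterior(
            p_logit=self.params["p_logit"], mu=self.params["mu"],
            rho=self.params["rho"], bias=self.params["b"],
        )

    def forward(self, x, rng=None, sample=True):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        d = self.geom.dilation
        sigma = softplus(self.params["rho"]).astype(self.dtype)
        B, F = x.shape[0], self.n_filters
        if sample:
            rng = rng or np.random.default_rng()
            u = np.clip(rng.random((B, F)), _U_EPS, 1.0 - _U_EPS)
            a = (self.params["p_logit"][None, :] + logit(u)) / self.concrete.temperature
            g = sigmoid(a).astype(self.dtype)
            m, var = _conv3d_pair(x, self.params["mu"], sigma * sigma, d)
            eps = rng.standard_normal(m.shape).astype(self.dtype)
            s = np.sqrt(var + _VAR_EPS)
            A = m + s * eps
        else:
            m = conv3d(x, self.params["mu"], d)
            g = np.broadcast_to(
                sigmoid(self.params["p_logit"]).astype(self.dtype)[None, :], (B, F)
            ).copy()
            eps = None
            s = None
            A = m
        gb = g[:, None, None, None, :]
        z = gb * A + self.params["b"]
        self._cache.update(x=x, sigma=sigma, s=s, eps=eps, g=g, A=A,
                           sampled=sample)
        return self._apply_relu(z)

    def backward(self, dz):
        dz = self._relu_back(dz)
        c = self._cache
        x, g = c["x"], c["g"]
        d = self.geom.dilation
        gb = g[:, None, None, None, :]
        dm = dz * gb
        # gate gradient via the concrete relaxation (or mean-gate in
        # deterministic mode): dz/dg = A, chain through sigmoid
        dgate = np.einsum("bxyzf,bxyzf->bf", dz, c["A"])
        if c["sampled"]:
            dlogit = dgate * g * (1.0 - g) / self.concrete.temperature
        else:
            dlogit = dgate * g * (1.0 - g)
        self.grads["p_logit"] += dlogit.sum(axis=0).astype(self.dtype)
        self.grads["b"] += dz.sum(axis=(0, 1, 2, 3))
        if c["sampled"]:
            sigma = c["sigma"]
            dV = dm * (c["eps"] / (2.0 * c["s"]))
            dmu, dsig2 = _conv3d_pair_grad_w(x, dm, dV,
                                             self.geom.kernel_shape, d)
            self.grads["mu"] += dmu
            # sigma^2 = softplus(rho)^2; d sigma^2 / d rho = 2 sigma sigmoid(rho)
            self.grads["rho"] += dsig2 * 2.0 * sigma * sigmoid(
                self.params["rho"].astype(np.float64)
            ).astype(self.dtype)
            dx = conv3d_grad_h(dm, self.params["mu"], d)
            dx += 2.0 * x * conv3d_grad_h(dV, (sigma * sigma), d)
        else:
            self.grads["mu"] += conv3d_grad_w(x, dm, self.geom.kernel_shape, d)
            dx = conv3d_grad_h(dm, self.params["mu"], d)
        return dx

    def regularizer(self, prior: PriorSpec | None = None) -> float:
        return layer_kl(self.posterior, prior or self.prior)

    def add_regularizer_grads(self, scale: float = 1.0,
                              prior: PriorSpec | None = None) -> None:
        prior = prior or self.prior
        p = sigmoid(self.params["p_logit"].astype(np.float64))
        dkl_dp = (np.log(p) - np.log(prior.p_prior)
                  - np.log1p(-p) + np.log1p(-prior.p_prior))
        self.grads["p_logit"] += (scale * dkl_dp * p * (1 - p)).astype(self.dtype)
        sigma = softplus(self.params["rho"].astype(np.float64))
        sp2 = prior.sigma_prior ** 2
        dmu = (self.params["mu"].astype(np.float64) - prior.mu_prior) / sp2
        dsigma = -1.0 / sigma + sigma / sp2
        self.grads["mu"] += (scale * dmu).astype(self.dtype)
        self.grads["rho"] += (
            scale * dsigma * sigmoid(self.params["rho"].astype(np.float64))
        ).astype(self.dtype)
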