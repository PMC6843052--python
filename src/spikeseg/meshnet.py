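"""MeshNet: an 8-layer dilated-convolution segmentation network.

The architecture keeps spatial shape at every layer (padding = dilation for
3^3 kernels) and grows the receptive field through a dilation schedule of
(1, 1, 1, 2, 4, 8, 1) for the seven hidden 3^3 layers, followed by a 1^3
read-out layer over classes.  The composed receptive field is
``1 + 2 * sum(dilation_l * half_width_l) = 37`` voxels per axis.

Three variants share this one architecture definition and differ only in the
weight model of each layer: ``map`` (point weights), ``bd`` (MC Bernoulli
dropout) and ``ssd`` (spike-and-slab dropout).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .layers import (
    BernoulliDropoutConvLayer,
    FilterGeometry,
    MapConvLayer,
    PriorSpec,
    SpikeSlabConvLayer,
)
from .volumes import ValidationError

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "MeshNet",
    "build_model",
    "count_parameters",
    "receptive_field",
    "DEFAULT_LAYER_TABLE",
]

VARIANTS = ("map", "bd", "ssd")


@dataclass(frozen=True)
class LayerSpec:
    """One row of the layer table: kernel edge, dilation, activation.

    ``out_channels`` of None means "use the architecture's n_filters";
    the final row uses ``n_classes``.
    """

    kernel: int = 3
    dilation: int = 1
    relu: bool = True
    out_channels: int | None = None


# kernel, dilation per hidden layer; final 1^3 read-out is linear (softmax
# applied at prediction time; training consumes pre-softmax scores)
DEFAULT_LAYER_TABLE: tuple[LayerSpec, ...] = (
    LayerSpec(3, 1), LayerSpec(3, 1), LayerSpec(3, 1),
    LayerSpec(3, 2), LayerSpec(3, 4), LayerSpec(3, 8),
    LayerSpec(3, 1),
    LayerSpec(1, 1, relu=False),
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters defining a MeshNet variant."""

    n_filters: int = 96
    n_classes: int = 50
    in_channels: int = 1
    variant: str = "ssd"
    keep_prob: float = 0.9
    temperature: float = 0.02
    prior: PriorSpec = field(default_factory=PriorSpec)
    init_p: float = 0.9
    init_sigma: float = 0.01
    layer_table: tuple[LayerSpec, ...] = DEFAULT_LAYER_TABLE
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(
                f"unsupported variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.n_classes < 2 or self.n_filters < 1:
            raise ValidationError("need n_classes >= 2 and n_filters >= 1")
        object.__setattr__(self, "layer_table", tuple(
            ls if isinstance(ls, LayerSpec) else LayerSpec(**ls)
            for ls in self.layer_table
        ))

    def channels(self) -> list[tuple[int, int]]:
        """(in, out) channel pairs per layer."""
        pairs = []
        c_in = self.in_channels
        for i, ls in enumerate(self.layer_table):
            c_out = ls.out_channels
            if c_out is None:
                c_out = (self.n_classes if i == len(self.layer_table) - 1
                         else self.n_filters)
            pairs.append((c_in, c_out))
            c_in = c_out
        return pairs

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ArchitectureSpec":
        d = json.loads(s)
        d["prior"] = PriorSpec(**d["prior"])
        d["layer_table"] = tuple(LayerSpec(**ls) for ls in d["layer_table"])
        return cls(**d)


class MeshNet:
    """The assembled network: an ordered chain of conv layers.

    ``forward`` maps ``(B, X, Y, Z, C_in)`` activations to per-voxel class
    scores ``(B, X, Y, Z, n_classes)`` with spatial shape preserved;
    ``predict_proba`` applies the per-voxel softmax.
    """

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator | None = None):
        self.spec = spec
        rng = rng or np.random.default_rng()
        dtype = np.dtype(spec.dtype)
        self.layers = []
        for ls, (c_in, c_out) in zip(spec.layer_table, spec.channels()):
            hw = (ls.kernel - 1) // 2
            geom = FilterGeometry(hw, hw, hw, ls.dilation)
            if spec.variant == "map":
                layer = MapConvLayer(geom, c_in, c_out, ls.relu, rng=rng, dtype=dtype)
            elif spec.variant == "bd":
                layer = BernoulliDropoutConvLayer(
                    geom, c_in, c_out, ls.relu, keep_prob=spec.keep_prob,
                    rng=rng, dtype=dtype,
                )
            else:
                layer = SpikeSlabConvLayer(
                    geom, c_in, c_out, ls.relu, prior=spec.prior,
                    temperature=spec.temperature, init_p=spec.init_p,
                    init_sigma=spec.init_sigma, rng=rng, dtype=dtype,
                )
            self.layers.append(layer)

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _as_batch(x) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 4:
            x = x[..., None]
        if x.ndim != 5:
            raise ValidationError("expected input of shape (B, X, Y, Z[, C])")
        return x

    def forward(self, x, rng: np.random.Generator | None = None,
                sample: bool = True) -> np.ndarray:
        """Per-voxel class scores (pre-softmax). ``sample`` draws fresh
        weight/gate/mask noise in the stochastic variants; the MAP variant
        is deterministic regardless."""
        h = self._as_batch(x)
        if h.shape[-1] != self.spec.in_channels:
            raise ValidationError(
                f"expected {self.spec.in_channels} input channel(s), "
                f"got {h.shape[-1]}"
            )
        for layer in self.layers:
            h = layer.forward(h, rng=rng, sample=sample)
        return h

    def predict_proba(self, x, rng=None, sample: bool = True) -> np.ndarray:
        scores = self.forward(x, rng=rng, sample=sample)
        return softmax(scores)

    def backward(self, dscores: np.ndarray) -> np.ndarray:
        d = dscores
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    # -- regularization -----------------------------------------------------
    def regularizer(self) -> float:
        """KL to the prior (ssd) or the Gaussian-prior L2 penalty (map/bd)."""
        return float(sum(layer.regularizer() for layer in self.layers))

    def add_regularizer_grads(self, scale: float = 1.0) -> None:
        for layer in self.layers:
            layer.add_regularizer_grads(scale)

    # -- parameter plumbing ---------------------------------------------------
    def zero_grads(self) -> None:
        for layer in self.layers:
            layer.zero_grads()

    def parameters(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}.{name}": arr
            for i, layer in enumerate(self.layers)
            for name, arr in layer.params.items()
        }

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"layer{i}.{name}": arr
            for i, layer in enumerate(self.layers)
            for name, arr in layer.grads.items()
        }

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        for key, arr in values.items():
            if key not in own:
                raise ValidationError(f"unknown parameter {key!r} in checkpoint")
            if own[key].shape != arr.shape:
                raise ValidationError(
                    f"checkpoint/architecture mismatch for {key!r}: "
                    f"{arr.shape} vs {own[key].shape}"
                )
            own[key][...] = arr

    def copy_parameters(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.parameters().items()}

    # -- serialization --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Checkpoint: one npz with named per-layer parameter groups plus the
        architecture spec as JSON (stable, documented format)."""
        arrays = dict(self.parameters())
        arrays["__architecture__"] = np.frombuffer(
            self.spec.to_json().encode(), dtype=np.uint8
        )
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MeshNet":
        with np.load(str(path)) as data:
            try:
                spec = ArchitectureSpec.from_json(
                    bytes(data["__architecture__"]).decode()
                )
            except KeyError as exc:
                raise ValidationError(
                    f"{path} is not a spikeseg checkpoint (missing architecture)"
                ) from exc
            net = cls(spec, rng=np.random.default_rng(0))
            net.set_parameters(
                {k: data[k] for k in data.files if k != "__architecture__"}
            )
        return net


def softmax(scores: np.ndarray, axis: int = -1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_model(spec: ArchitectureSpec, seed: int | None = None,
                rng: np.random.Generator | None = None) -> MeshNet:
    """Construct a MeshNet for the given architecture spec."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return MeshNet(spec, rng=rng)


def count_parameters(model: MeshNet) -> dict[str, int]:
    """Per-kind parameter counts.

    ``weights`` counts point weights (map/bd) or Gaussian means (ssd);
    ``scales`` the per-weight sigma parameters; ``gates`` the per-filter
    inclusion logits; ``biases`` the deterministic biases.  SSD totals are
    ~2x the MAP weight count plus one gate per filter.
    """
    counts = {"weights": 0, "scales": 0, "gates": 0, "biases": 0}
    for layer in model.layers:
        for name, arr in layer.params.items():
            if name in ("w", "mu"):
                counts["weights"] += arr.size
            elif name == "rho":
                counts["scales"] += arr.size
            elif name == "p_logit":
                counts["gates"] += arr.size
            elif name == "b":
                counts["biases"] += arr.size
    counts["total"] = sum(counts.values())
    return counts


def receptive_field(spec: ArchitectureSpec) -> int:
    """Theoretical receptive-field edge length of the composed network:
    ``1 + 2 * sum(dilation * half_width)`` over layers."""
    return 1 + 2 * sum(
        ls.dilation * ((ls.kernel - 1) // 2) for ls in spec.layer_table
    )
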