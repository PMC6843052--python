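"""Monte-Carlo predictive segmentation and uncertainty.

Prediction marginalizes the posterior over weights by averaging the softmax
output of ``n_mc`` stochastic forward passes — in probability space, not in
logits — and summarizes uncertainty as the per-voxel entropy of that
averaged posterior predictive (in nats).  The volume-level uncertainty is
the mean entropy over voxels not predicted as background, which is the
scan-quality score used by the QC experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshnet import MeshNet, softmax
from .prep import TileGrid, stitch, tile
from .volumes import ValidationError, Volume

__all__ = [
    "PredictiveOutput",
    "mc_predict",
    "voxel_entropy",
    "volume_uncertainty",
    "AllBackgroundError",
]

_SIMPLEX_TOL = 1e-4


class AllBackgroundError(ValidationError):
    """The prediction contains no foreground voxels; the volume-level
    uncertainty summary is unusable for this scan."""


@dataclass
class PredictiveOutput:
    """MC-averaged posterior predictive for one volume.

    ``class_probabilities``: (X, Y, Z, C) per-voxel simplex;
    ``predicted_labels``: argmax grid (ties broken toward the lowest class
    index); ``entropy``: per-voxel entropy in nats, in [0, log C];
    ``n_mc``: number of Monte-Carlo samples averaged.
    """

    class_probabilities: np.ndarray
    predicted_labels: np.ndarray
    entropy: np.ndarray
    n_mc: int

    @property
    def n_classes(self) -> int:
        return self.class_probabilities.shape[-1]


def mc_predict(model: MeshNet, volume, n_mc: int = 10, seed: int = 0,
               tile_size: int = 32, batch_tiles: int = 8,
               return_samples: bool = False):
    """Tile, run ``n_mc`` stochastic forward passes, average, stitch.

    The volume must be cubic with each side divisible by ``tile_size`` (the
    conformed-pipeline contract).  Fresh weight/gate/mask noise is drawn per
    tile and per MC pass; the MAP variant is deterministic, so its output is
    identical for any ``n_mc``.  With ``return_samples`` the per-sample
    probability grids are also returned (memory scales with ``n_mc``).
    """
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    if data.ndim != 3:
        raise ValidationError("mc_predict expects a 3D volume")
    if len(set(data.shape)) != 1 or data.shape[0] % tile_size != 0:
        raise ValidationError(
            f"volume shape {data.shape} is not a cube divisible by "
            f"tile size {tile_size}; conform the volume first"
        )
    if n_mc < 1:
        raise ValidationError("n_mc must be >= 1")
    tiles, grid = tile(data.astype(np.float32), tile_size=tile_size)
    rng = np.random.default_rng(seed)
    n_classes = model.spec.n_classes
    side = data.shape[0]
    mean_probs = np.zeros(data.shape + (n_classes,), dtype=np.float32)
    samples = ([np.zeros_like(mean_probs) for _ in range(n_mc)]
               if return_samples else None)
    for start in range(0, len(tiles), batch_tiles):
        chunk = tiles[start:start + batch_tiles]
        xb = np.stack(chunk)[..., None]
        offsets = grid.offsets[start:start + batch_tiles]
        for s in range(n_mc):
            probs = model.predict_proba(xb, rng=rng, sample=True)
            for t, (i, j, k) in enumerate(offsets):
                block = probs[t]
                mean_probs[i:i + tile_size, j:j + tile_size,
                           k:k + tile_size, :] += block
                if return_samples:
                    samples[s][i:i + tile_size, j:j + tile_size,
                               k:k + tile_size, :] = block
    mean_probs /= n_mc
    entropy = voxel_entropy(mean_probs, validate=False)
    labels = mean_probs.argmax(axis=-1).astype(np.int32)
    out = PredictiveOutput(mean_probs, labels, entropy, n_mc)
    if return_samples:
        return out, samples
    return out


def voxel_entropy(probabilities: np.ndarray, validate: bool = True) -> np.ndarray:
    """Per-voxel entropy of a class-probability grid, in nats.

    ``H = -sum_c p_c log p_c`` with the ``0 log 0 = 0`` convention; lies in
    ``[0, log C]``.  Input must be a per-voxel simplex (within tolerance).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim < 1:
        raise ValidationError("expected an array with a trailing class axis")
    if validate:
        if (p < -_SIMPLEX_TOL).any():
            raise ValidationError("probabilities must be non-negative")
        sums = p.sum(axis=-1)
        if np.abs(sums - 1.0).max() > _SIMPLEX_TOL:
            raise ValidationError(
                "probabilities do not sum to 1 within tolerance"
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


def volume_uncertainty(output: PredictiveOutput) -> float:
    """Mean voxel entropy over voxels not predicted as background.

    Averaging is restricted to voxels whose predicted label differs from 0
    (the background/"unknown" class).  An all-background prediction has no
    usable summary and raises :class:`AllBackgroundError`.
    """
    mask = output.predicted_labels != 0
    if not mask.any():
        raise AllBackgroundError(
            "prediction is entirely background; volume uncertainty undefined"
        )
    return float(output.entropy[mask].mean())
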