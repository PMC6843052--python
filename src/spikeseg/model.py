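"""Model/Results front end.

:class:`SegmentationModel` is constructed from data (volumes plus reference
label volumes), owns the preprocessing (per-volume z-scoring, tiling) and
the architecture, and ``fit()`` returns a :class:`SegmentationResults`
carrying the trained network, the loss trace, validation diagnostics and a
``summary()`` table.  Prediction, evaluation and plotting hang off the
results object.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PredictiveOutput, mc_predict  # noqa: F401  (re-exported)
from .meshnet import ArchitectureSpec, MeshNet, build_model, count_parameters
from .prep import tile, zscore
from .training import TrainConfig, train
from .volumes import LabelVolume, ValidationError, Volume
from .evaluation import EvalReport, evaluate_volume

__all__ = ["SegmentationModel", "SegmentationResults"]


def _as_volume(v) -> Volume:
    return v if isinstance(v, Volume) else Volume(np.asarray(v, dtype=np.float32))


def _label_data(l) -> np.ndarray:
    return l.data if isinstance(l, LabelVolume) else np.asarray(l)


def _tile_pairs(volumes, labels, tile_size, normalize):
    xs, ys = [], []
    for vol, lab in zip(volumes, labels):
        vol = _as_volume(vol)
        if normalize:
            vol = zscore(vol)
        vt, _ = tile(vol.data, tile_size=tile_size)
        lt, _ = tile(_label_data(lab), tile_size=tile_size)
        xs.extend(vt)
        ys.extend(lt)
    x = np.stack(xs)[..., None].astype(np.float32)
    y = np.stack(ys).astype(np.int64)
    return x, y


class SegmentationModel:
    """A segmentation network specified jointly with its training data.

    Parameters
    ----------
    volumes, labels : sequences of (Volume | ndarray) and (LabelVolume | ndarray)
        Training pairs; each volume is z-scored individually (unless
        ``normalize=False``) and split into non-overlapping cubic tiles.
    arch : ArchitectureSpec, optional
        Defaults to the standard table with ``n_classes`` inferred from the
        labels.  Pass e.g. ``n_filters=16`` via ``arch`` for desk-scale work.
    val_volumes, val_labels : optional validation pairs for model selection.
    """

    def __init__(self, volumes, labels, arch: ArchitectureSpec | None = None,
                 tile_size: int = 32, train_tile_size: int | None = None,
                 val_volumes=None, val_labels=None, normalize: bool = True):
        volumes = list(volumes)
        labels = list(labels)
        if len(volumes) != len(labels) or not volumes:
            raise ValidationError("need matching, nonempty volume/label lists")
        self.tile_size = tile_size
        self.normalize = normalize
        if arch is None:
            n_classes = int(max(int(_label_data(l).max()) for l in labels)) + 1
            arch = ArchitectureSpec(n_classes=max(n_classes, 2))
        self.arch = arch
        # training may use smaller crops than the inference tiling (the
        # network is fully convolutional); validation/prediction tiles keep
        # the pipeline tile size
        self.x_train, self.y_train = _tile_pairs(
            volumes, labels, train_tile_size or tile_size, normalize)
        if int(self.y_train.max()) >= arch.n_classes:
            raise ValidationError(
                f"labels contain id {int(self.y_train.max())} but the "
                f"architecture has {arch.n_classes} classes"
            )
        self.val = None
        if val_volumes is not None:
            self.val = _tile_pairs(val_volumes, list(val_labels),
                                   tile_size, normalize)

    @classmethod
    def from_dataset(cls, dataset: dict, arch: ArchitectureSpec | None = None,
                     tile_size: int = 32, train_tile_size: int | None = None,
                     normalize: bool = True) -> "SegmentationModel":
        """Build from a ``make_dataset``-style dict with train/val splits."""
        train_pairs = dataset["train"]
        val_pairs = dataset.get("val") or None
        kwargs = {}
        if val_pairs:
            kwargs = {
                "val_volumes": [v for v, _ in val_pairs],
                "val_labels": [l for _, l in val_pairs],
            }
        return cls([v for v, _ in train_pairs], [l for _, l in train_pairs],
                   arch=arch, tile_size=tile_size,
                   train_tile_size=train_tile_size, normalize=normalize,
                   **kwargs)

    def fit(self, config: TrainConfig | None = None, seed: int | None = None,
            warm_start_steps: int = 0,
            **overrides) -> "SegmentationResults":
        """Train the network; returns a results object.

        ``overrides`` update individual :class:`TrainConfig` fields, e.g.
        ``model.fit(n_steps=100, learning_rate=1e-3)``.

        ``warm_start_steps`` > 0 first trains a MAP (point-estimate)
        network for that many steps and initializes the variational weight
        means (and point weights, for BD) from it before the main run —
        the usual "posterior means from a pretrained point estimate"
        initialization for variational networks.  Ignored for the MAP
        variant.
        """
        config = config or TrainConfig()
        if seed is not None:
            overrides["seed"] = seed
        if overrides:
            config = replace(config, **overrides)
        network = build_model(self.arch, seed=config.seed)
        # output bias starts at the empirical class log-priors: an
        # imbalanced segmentation otherwise spends its first many updates
        # learning base rates before any structure
        freq = np.bincount(self.y_train.ravel(),
                           minlength=self.arch.n_classes) / self.y_train.size
        log_prior = np.log(freq + 1e-8)
        network.layers[-1].params["b"][:] = log_prior
        warm_log = None
        if warm_start_steps > 0 and self.arch.variant != "map":
            warm_arch = replace(self.arch, variant="map")
            warm_net = build_model(warm_arch, seed=config.seed)
            warm_net.layers[-1].params["b"][:] = log_prior
            warm_cfg = replace(config, n_steps=warm_start_steps,
                               keep_best=False)
            warm_net, warm_log = train(warm_net,
                                       (self.x_train, self.y_train), warm_cfg)
            for lay, wlay in zip(network.layers, warm_net.layers):
                key = "mu" if "mu" in lay.params else "w"
                lay.params[key][...] = wlay.params["w"]
                lay.params["b"][...] = wlay.params["b"]
        network, log = train(network, (self.x_train, self.y_train), config,
                             val_data=self.val)
        if warm_log is not None:
            warm_log = warm_log.assign(phase="warm_start")
            log = pd.concat([warm_log, log.assign(phase="main")],
                            ignore_index=True)
        return SegmentationResults(self, network, config, log)


class SegmentationResults:
    """Fitted segmentation model: trained posterior plus diagnostics."""

    def __init__(self, model: SegmentationModel, network: MeshNet,
                 config: TrainConfig, log: pd.DataFrame):
        self.model = model
        self.network = network
        self.config = config
        self.log = log

    @property
    def best_val_dice(self) -> float:
        vals = self.log["val_dice"].dropna()
        return float(vals.max()) if len(vals) else float("nan")

    def predict(self, volume, n_mc: int = 10, seed: int = 0,
                **kwargs) -> PredictiveOutput:
        """MC-averaged posterior predictive for one (unnormalized) volume."""
        vol = _as_volume(volume)
        if self.model.normalize:
            vol = zscore(vol)
        return mc_predict(self.network, vol, n_mc=n_mc, seed=seed,
                          tile_size=self.model.tile_size, **kwargs)

    def evaluate(self, volume, labels, n_mc: int = 10, seed: int = 0,
                 metadata=None) -> EvalReport:
        output = self.predict(volume, n_mc=n_mc, seed=seed)
        return evaluate_volume(output, labels, metadata=metadata)

    def summary(self) -> str:
        """Plain-text fit summary table."""
        counts = count_parameters(self.network)
        spec = self.network.spec
        final = self.log.iloc[-1] if len(self.log) else None
        rows = [
            ("Variant", spec.variant.upper()),
            ("Filters / classes", f"{spec.n_filters} / {spec.n_classes}"),
            ("Layers", str(len(spec.layer_table))),
            ("Parameters", f"{counts['total']:,}"),
            ("Training tiles (N)", str(self.model.x_train.shape[0])),
            ("Mini-batch (M)", str(self.config.minibatch_size)),
            ("Steps", str(self.config.n_steps)),
            ("Learning rate", f"{self.config.learning_rate:g}"),
            ("Final loss", "n/a" if final is None else f"{final['loss']:.4g}"),
            ("Final data term", "n/a" if final is None else
             f"{final['data_term']:.4g}"),
            ("Final regularizer", "n/a" if final is None else
             f"{final['reg_term']:.4g}"),
            ("Best validation Dice", f"{self.best_val_dice:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Spike-and-slab segmentation fit"
                 if spec.variant == "ssd" else "Segmentation fit",
                 "=" * 40]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Loss-trace diagnostic plot (data term and regularizer)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log["step"], self.log["loss"], label="loss")
        ax.plot(self.log["step"], self.log["data_term"], label="data term",
                alpha=0.7)
        ax.set_xlabel("step")
        ax.set_ylabel("objective")
        ax.legend()
        return ax

    def save(self, path: str | Path) -> None:
        self.network.save(path)
        log_path = Path(path).with_suffix(".log.csv")
        self.log.to_csv(log_path, index=False)

    @staticmethod
    def load_network(path: str | Path) -> MeshNet:
        return MeshNet.load(path)
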