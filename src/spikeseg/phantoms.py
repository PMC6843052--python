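"""Synthetic labelled brain-like phantoms with known ground truth.

Real training corpora for whole-brain segmentation (thousands of scans plus
reference label volumes) are not redistributable, so the package ships a
phantom generator that emulates the structure such data is assumed to have:
a cubic intensity grid containing spatially coherent labelled regions
(concentric ellipsoids subdivided by octant planes, mimicking nested
cortical/subcortical topology), region-specific intensity distributions, a
smooth multiplicative bias field, and additive noise.  A degradation mode
produces artifact-laden "bad quality" volumes for the quality-control
experiments.

Everything here is a pure function of its arguments: identical specs
(including seeds) produce bit-identical output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, ValidationError, Volume

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "generate_phantom",
    "degrade",
    "split_counts",
    "make_dataset",
    "write_dataset",
    "ARTIFACT_KINDS",
]

ARTIFACT_KINDS = ("noise_burst", "motion_blur", "ringing", "intensity_clip")


def _default_means(n_classes: int) -> tuple[float, ...]:
    # Background dim, foreground classes evenly spaced in the 0-255 range.
    return tuple(np.linspace(20.0, 235.0, n_classes))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic labelled volume.

    ``intensity_means`` gives the per-class mean intensity (class 0 =
    background first); ``intensity_sd`` the additive Gaussian noise scale
    (scalar or per-class); ``bias_field_amplitude`` the relative amplitude
    of the smooth multiplicative bias field (0.05 = +-5% low-frequency
    modulation, a mild residual-inhomogeneity level).
    """

    side_length: int = 64
    n_classes: int = 8
    intensity_means: tuple[float, ...] | None = None
    intensity_sd: float | tuple[float, ...] = 8.0
    bias_field_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        if self.side_length < 4:
            raise ValidationError("side_length must be >= 4")
        if self.intensity_means is None:
            object.__setattr__(
                self, "intensity_means", _default_means(self.n_classes)
            )
        if len(self.intensity_means) != self.n_classes:
            raise ValidationError("need one intensity mean per class")
        sds = np.atleast_1d(np.asarray(self.intensity_sd, dtype=float))
        if (sds < 0).any():
            raise ValidationError("intensity_sd must be non-negative")
        if self.bias_field_amplitude < 0:
            raise ValidationError("bias_field_amplitude must be non-negative")

    @property
    def per_class_sd(self) -> np.ndarray:
        sds = np.atleast_1d(np.asarray(self.intensity_sd, dtype=float))
        if sds.size == 1:
            sds = np.full(self.n_classes, float(sds[0]))
        if sds.size != self.n_classes:
            raise ValidationError("intensity_sd must be scalar or per-class")
        return sds


@dataclass(frozen=True)
class DegradationSpec:
    """Severity-controlled artifact recipe for "bad quality" phantoms."""

    severity: float = 0.8
    artifact_kinds: tuple[str, ...] = ARTIFACT_KINDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise ValidationError("severity must lie in [0, 1]")
        for kind in self.artifact_kinds:
            if kind not in ARTIFACT_KINDS:
                raise ValidationError(f"unknown artifact kind {kind!r}")


def _label_geometry(side: int, n_classes: int) -> np.ndarray:
    """Concentric ellipsoids subdivided by octant planes.

    Region cells (shell, octant) are mapped cyclically onto foreground class
    ids so every class id appears at least once even for small phantoms.
    """
    coords = np.stack(
        np.meshgrid(*([np.arange(side)] * 3), indexing="ij"), axis=-1
    ).astype(np.float64)
    centre = (side - 1) / 2.0
    x = coords - centre
    semi = np.array([0.45, 0.40, 0.35]) * side  # anisotropic: breaks symmetry
    r = np.sqrt(((x / semi) ** 2).sum(axis=-1))

    n_fg = n_classes - 1
    n_shells = max(2, int(np.ceil(n_fg / 8)) + 1)
    edges = np.linspace(0.0, 1.0, n_shells + 1)[1:]
    shell = np.searchsorted(edges, r, side="left")  # n_shells inside, outside > last
    octant = (
        (x[..., 0] >= 0).astype(np.int32) * 4
        + (x[..., 1] >= 0).astype(np.int32) * 2
        + (x[..., 2] >= 0).astype(np.int32)
    )
    cell = shell * 8 + octant
    labels = np.where(r <= 1.0, cell % n_fg + 1, 0).astype(np.int32)
    # guarantee coverage of every foreground id even when rounding starves one
    present = np.bincount(labels.ravel(), minlength=n_classes) > 0
    missing = np.flatnonzero(~present[1:]) + 1
    if missing.size:
        inner = np.flatnonzero((r <= 1.0).ravel())
        chunks = np.array_split(inner[: 8 * missing.size], missing.size)
        flat = labels.ravel()
        for cls, chunk in zip(missing, chunks):
            flat[chunk] = cls
        labels = flat.reshape(labels.shape)
    return labels


def _bias_field(side: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """1 + amplitude * (sum of 3 random low-order cosine modes in [-1, 1])."""
    if amplitude == 0:
        return np.ones((side,) * 3)
    ax = np.arange(side) / side
    modes = np.zeros((side,) * 3)
    for _ in range(3):
        freq = rng.integers(1, 3, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        modes += (
            np.cos(2 * np.pi * freq[0] * ax + phase[0])[:, None, None]
            * np.cos(2 * np.pi * freq[1] * ax + phase[1])[None, :, None]
            * np.cos(2 * np.pi * freq[2] * ax + phase[2])[None, None, :]
        )
    peak = np.abs(modes).max()
    if peak > 0:
        modes /= peak
    return 1.0 + amplitude * modes


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Generate one (intensity, label) phantom pair.

    Intensity = class mean x smooth bias field + additive Gaussian noise.
    Both grids share shape and 1 mm isotropic spacing.  Deterministic in
    ``spec`` (including the seed).
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.side_length
    labels = _label_geometry(side, spec.n_classes)
    means = np.asarray(spec.intensity_means, dtype=np.float64)
    sds = spec.per_class_sd
    bias = _bias_field(side, spec.bias_field_amplitude, rng)
    data = means[labels] * bias
    noise_sd = sds[labels]
    if (noise_sd > 0).any():
        data = data + noise_sd * rng.standard_normal(labels.shape)
    affine = np.eye(4)
    return (
        Volume(data.astype(np.float32), affine),
        LabelVolume(labels, spec.n_classes, affine.copy()),
    )


def _apply_artifact(data, kind, severity, rng):
    side = data.shape[0]
    if kind == "noise_burst":
        # heavy noise confined to a random slab of slices
        axis = int(rng.integers(0, 3))
        width = max(1, int(round(severity * side / 2)))
        start = int(rng.integers(0, max(side - width, 1)))
        sl = [slice(None)] * 3
        sl[axis] = slice(start, start + width)
        burst = severity * 60.0 * rng.standard_normal(data[tuple(sl)].shape)
        data[tuple(sl)] += burst
    elif kind == "motion_blur":
        size = 1 + 2 * int(round(severity * 3))  # odd, identity at severity 0
        if size > 1:
            axis = int(rng.integers(0, 3))
            data[...] = ndimage.uniform_filter1d(data, size=size, axis=axis)
    elif kind == "ringing":
        axis = int(rng.integers(0, 3))
        freq = int(rng.integers(3, 8))
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * freq * np.arange(side) / side + phase)
        shape = [1, 1, 1]
        shape[axis] = side
        data += severity * 30.0 * wave.reshape(shape)
    elif kind == "intensity_clip":
        q = 1.0 - 0.4 * severity
        hi = np.quantile(data, q)
        np.clip(data, None, hi, out=data)
    return data


def degrade(volume: Volume, spec: DegradationSpec) -> Volume:
    """Apply severity-scaled artifacts; severity 0 returns the input unchanged.

    For a fixed seed the mean absolute change grows with severity (each
    artifact amplitude is linear or monotone in severity).
    """
    if not (0.0 <= spec.severity <= 1.0):
        raise ValidationError("severity must lie in [0, 1]")
    data = volume.data.astype(np.float64).copy()
    if spec.severity > 0:
        rng = np.random.default_rng(spec.seed)
        for kind in spec.artifact_kinds:
            data = _apply_artifact(data, kind, spec.severity, rng)
    return Volume(data.astype(np.float32), volume.affine.copy())


def split_counts(n: int, fractions=(0.8, 0.1, 0.1)) -> tuple[int, ...]:
    """Deterministic split sizes: floor(n*fraction), remainder to the first
    (training) split.  E.g. 11,480 at 80-10-10 -> (9184, 1148, 1148)."""
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    if any(f < 0 for f in fractions):
        raise ValidationError("split fractions must be non-negative")
    counts = [int(np.floor(n * f)) for f in fractions]
    counts[0] += n - sum(counts)
    return tuple(counts)


def make_dataset(
    n: int,
    spec_template: PhantomSpec | None = None,
    split=(0.8, 0.1, 0.1),
) -> dict[str, list[tuple[Volume, LabelVolume]]]:
    """Generate ``n`` phantoms and partition them train/val/test.

    Per-volume seeds derive deterministically from the template seed; the
    partition is a seeded shuffle, so the same call always returns the same
    dataset and no volume appears in two splits.
    """
    if spec_template is None:
        spec_template = PhantomSpec()
    counts = split_counts(n, split)
    if sum(f > 0 for f in split) > n:
        raise ValidationError(
            f"cannot fill {sum(f > 0 for f in split)} nonempty splits with {n} volumes"
        )
    pairs = [
        generate_phantom(replace(spec_template, seed=spec_template.seed + 1000 * i))
        for i in range(n)
    ]
    order = np.random.default_rng(spec_template.seed).permutation(n)
    names = ("train", "val", "test")
    out: dict[str, list[tuple[Volume, LabelVolume]]] = {}
    start = 0
    for name, c in zip(names, counts):
        out[name] = [pairs[i] for i in order[start:start + c]]
        start += c
    return out


def write_dataset(dataset, out_dir: str | Path, qc_scores=None) -> None:
    """Write phantom pairs as NIfTI (.nii.gz) plus an optional QC-score CSV.

    Files: ``<split>_<idx>_t1.nii.gz`` / ``<split>_<idx>_labels.nii.gz``;
    ``qc_scores.csv`` has columns volume_id, rater1, rater2[, rater3].
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for split, pairs in dataset.items():
        for i, (vol, lab) in enumerate(pairs):
            vol.save(out_dir / f"{split}_{i:03d}_t1.nii.gz")
            lab.save(out_dir / f"{split}_{i:03d}_labels.nii.gz")
    if qc_scores:
        with open(out_dir / "qc_scores.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            n_raters = max(len(s) for _, s in qc_scores)
            writer.writerow(
                ["volume_id"] + [f"rater{i + 1}" for i in range(n_raters)]
            )
            for vid, scores in qc_scores:
                writer.writerow([vid] + list(scores))
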