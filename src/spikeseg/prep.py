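"""Volume preprocessing: conform, z-score, tile/stitch, label mapping.

The preprocessing contract mirrors the common neuroimaging segmentation
pipeline: every scan is resampled ("conformed") to a 1 mm isotropic cube,
intensity-rescaled to the 0-255 range, individually z-scored across all
voxels, and split into non-overlapping cubic tiles that the network consumes
independently.  ``stitch`` is the exact inverse of ``tile``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, ValidationError, Volume

__all__ = [
    "TileGrid",
    "conform",
    "conform_labels",
    "zscore",
    "tile",
    "stitch",
    "map_labels",
    "load_label_map",
    "default_label_map",
]

DEFAULT_SIDE = 256
DEFAULT_TILE = 32


def _conform_geometry(volume_shape, affine, side: int):
    """Output affine (1 mm isotropic, axis-aligned, centred on the input FOV)
    and the output->input voxel map used by ``ndimage.affine_transform``."""
    affine = np.asarray(affine, dtype=float)
    out_affine = np.eye(4)
    centre_vox = (np.asarray(volume_shape, dtype=float) - 1.0) / 2.0
    centre_world = affine[:3, :3] @ centre_vox + affine[:3, 3]
    out_affine[:3, 3] = centre_world - (side - 1.0) / 2.0
    # output voxel index -> input voxel index
    m = np.linalg.inv(affine) @ out_affine
    return out_affine, m[:3, :3], m[:3, 3]


def conform(volume: Volume, side: int = DEFAULT_SIDE) -> Volume:
    """Resample to a 1 mm isotropic cube of ``side`` voxels per edge.

    Trilinear interpolation, then min-max rescale of the intensities to
    [0, 255].  Degenerate (non-positive) voxel spacing is rejected.
    """
    if side < 1:
        raise ValidationError("side must be positive")
    if min(volume.spacing) <= 0 or not np.isfinite(volume.spacing).all():
        raise ValidationError(f"degenerate voxel spacing {volume.spacing}")
    out_affine, matrix, offset = _conform_geometry(volume.shape, volume.affine, side)
    data = ndimage.affine_transform(
        volume.data.astype(np.float32),
        matrix,
        offset=offset,
        output_shape=(side, side, side),
        order=1,
        mode="constant",
        cval=float(volume.data.min()),
    )
    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        data = (data - lo) * (255.0 / (hi - lo))
    else:
        data = np.zeros_like(data)
    return Volume(data.astype(np.float32), out_affine)


def conform_labels(labels: LabelVolume, side: int = DEFAULT_SIDE) -> LabelVolume:
    """Conform a label volume with nearest-neighbour interpolation.

    Class ids are categorical and must not be averaged; voxels falling
    outside the input field of view become background (0).
    """
    if min(np.linalg.norm(labels.affine[:3, :3], axis=0)) <= 0:
        raise ValidationError("degenerate voxel spacing")
    out_affine, matrix, offset = _conform_geometry(labels.shape, labels.affine, side)
    data = ndimage.affine_transform(
        labels.data,
        matrix,
        offset=offset,
        output_shape=(side, side, side),
        order=0,
        mode="constant",
        cval=0,
    )
    return LabelVolume(data.astype(np.int32), labels.n_classes, out_affine)


def zscore(volume: Volume) -> Volume:
    """Z-score intensities across all voxels (population SD, no masking)."""
    data = volume.data.astype(np.float64)
    if data.size < 2:
        raise ValidationError("z-score needs more than one voxel")
    sd = data.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("z-score undefined for a constant volume")
    out = (data - data.mean()) / sd
    return Volume(out.astype(np.float32), volume.affine.copy())


@dataclass(frozen=True)
class TileGrid:
    """Disjoint cubic tiling of a conformed volume.

    Offsets are tile corner coordinates, half-open intervals
    ``[offset, offset + tile_size)``, ordered lexicographically by axis.
    """

    tile_size: int = DEFAULT_TILE
    offsets: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)

    @classmethod
    def for_shape(cls, shape, tile_size: int = DEFAULT_TILE) -> "TileGrid":
        shape = tuple(int(s) for s in shape)
        if tile_size < 1:
            raise ValidationError("tile_size must be positive")
        for s in shape:
            if s % tile_size != 0:
                raise ValidationError(
                    f"volume side {s} is not divisible by tile size {tile_size}"
                )
        offsets = tuple(
            product(*(range(0, s, tile_size) for s in shape))
        )
        return cls(tile_size=tile_size, offsets=offsets)

    @property
    def n_tiles(self) -> int:
        return len(self.offsets)

    def permuted(self, order) -> "TileGrid":
        """Grid with offsets re-ordered by ``order`` (for bookkeeping tests)."""
        return TileGrid(self.tile_size, tuple(self.offsets[i] for i in order))


def tile(data: np.ndarray | Volume, grid: TileGrid | None = None,
         tile_size: int = DEFAULT_TILE) -> tuple[list[np.ndarray], TileGrid]:
    """Split a volume into the grid's non-overlapping cubic sub-volumes.

    Returns the ordered tile list and the grid (built from the volume shape
    when not supplied).  A conformed 256^3 volume with 32^3 tiles yields 512
    sub-volumes.
    """
    arr = data.data if isinstance(data, (Volume, LabelVolume)) else np.asarray(data)
    if arr.ndim != 3:
        raise ValidationError("tile expects a 3D volume")
    if grid is None:
        grid = TileGrid.for_shape(arr.shape, tile_size)
    ts = grid.tile_size
    tiles = []
    for (i, j, k) in grid.offsets:
        if i + ts > arr.shape[0] or j + ts > arr.shape[1] or k + ts > arr.shape[2]:
            raise ValidationError(f"tile offset {(i, j, k)} exceeds volume shape")
        tiles.append(arr[i:i + ts, j:j + ts, k:k + ts].copy())
    return tiles, grid


def stitch(tiles, grid: TileGrid) -> np.ndarray:
    """Reassemble tiles into a full volume; exact inverse of :func:`tile`.

    Placement is governed by the grid's offsets, not list position, so a
    consistently permuted (tiles, offsets) pair reconstructs identically.
    """
    tiles = list(tiles)
    if len(tiles) != grid.n_tiles:
        raise ValidationError(
            f"got {len(tiles)} tiles for a grid of {grid.n_tiles}"
        )
    ts = grid.tile_size
    extent = [0, 0, 0]
    for off in grid.offsets:
        for ax in range(3):
            extent[ax] = max(extent[ax], off[ax] + ts)
    first = np.asarray(tiles[0])
    out = np.zeros(tuple(extent) + first.shape[3:], dtype=first.dtype)
    seen = np.zeros(tuple(extent), dtype=bool)
    for t, (i, j, k) in zip(tiles, grid.offsets):
        t = np.asarray(t)
        if t.shape[:3] != (ts, ts, ts):
            raise ValidationError(f"tile shape {t.shape[:3]} != {(ts, ts, ts)}")
        if seen[i:i + ts, j:j + ts, k:k + ts].any():
            raise ValidationError(f"overlapping tile at offset {(i, j, k)}")
        out[i:i + ts, j:j + ts, k:k + ts] = t
        seen[i:i + ts, j:j + ts, k:k + ts] = True
    if not seen.all():
        raise ValidationError("tiles do not cover the volume")
    return out


def map_labels(raw_labels: LabelVolume, lookup: dict[int, int]) -> LabelVolume:
    """Collapse raw label ids to a compact class set.

    ``lookup`` maps raw id -> class id; raw ids absent from the lookup map to
    background (0), making the mapping total.  The output ``n_classes`` is
    ``max(target ids) + 1``.
    """
    if not lookup:
        raise ValidationError("empty label lookup")
    targets = np.asarray(list(lookup.values()), dtype=np.int32)
    if targets.min() < 0:
        raise ValidationError("target class ids must be non-negative")
    n_classes = max(int(targets.max()) + 1, 2)
    max_raw = max(int(max(lookup.keys())), int(raw_labels.data.max()))
    lut = np.zeros(max_raw + 1, dtype=np.int32)
    for raw, cls in lookup.items():
        if raw < 0:
            raise ValidationError("raw label ids must be non-negative")
        lut[raw] = cls
    data = lut[raw_labels.data]
    return LabelVolume(data, n_classes, raw_labels.affine.copy())


def load_label_map(path: str | Path) -> dict[int, int]:
    """Read a two-column delimited text label map (raw_id, class_id).

    Lines starting with '#' are comments; whitespace or tab delimited.
    """
    lookup: dict[int, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValidationError(f"malformed label-map line: {line!r}")
        lookup[int(parts[0])] = int(parts[1])
    return lookup


def default_label_map() -> dict[int, int]:
    """The shipped FreeSurfer-aseg-derived 50-class lookup table."""
    return load_label_map(Path(__file__).parent / "data" / "fs_aseg_50class.tsv")
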