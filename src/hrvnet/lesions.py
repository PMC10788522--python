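"""Lesion-map combination, thresholding, cluster filtering and atlas overlay.

Maps live in voxel-index space and are assumed co-registered; spatial
normalisation happens upstream.  Cluster extent filtering uses
26-connectivity by default (configurable), and the extent rule is
strict: clusters must have *more than* ``min_voxels`` voxels to survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionMap",
    "AtlasLabels",
    "combine_maps",
    "threshold_cluster",
    "atlas_overlay",
]


@dataclass
class LesionMap:
    """A 3-D lesion probability/statistic volume."""

    values: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("lesion map must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("lesion map contains non-finite values")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path, space_tag: str = "unknown") -> "LesionMap":
        img = nib.load(str(path))
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            values=np.asanyarray(img.dataobj, dtype=float),
            voxel_size=voxel_size,
            space_tag=space_tag,
        )


@dataclass
class AtlasLabels:
    """Integer label volume (0 = background) with a label->name table."""

    labels: np.ndarray
    names: dict
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def roi_labels(self) -> list:
        return sorted(set(np.unique(self.labels)) - {0})

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), affine), str(path))


def _check_same_grid(a_shape, b_shape) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"grid mismatch: {tuple(a_shape)} vs {tuple(b_shape)}")


def combine_maps(maps: list, mode: str = "sum") -> LesionMap:
    """Voxelwise combination of co-registered lesion maps.

    ``mode="sum"`` (default) adds the maps, so overlapping binary lesions
    accumulate counts; ``mode="max"`` takes the voxelwise maximum.
    """
    if not maps:
        raise ValueError("no maps to combine")
    first = maps[0]
    for m in maps[1:]:
        _check_same_grid(first.values.shape, m.values.shape)
    stack = np.stack([m.values for m in maps])
    if mode == "sum":
        combined = stack.sum(axis=0)
    elif mode == "max":
        combined = stack.max(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LesionMap(
        values=combined, voxel_size=first.voxel_size, space_tag=first.space_tag
    )


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


def threshold_cluster(
    lesion: LesionMap,
    t_thresh: float = 3.0,
    min_voxels: int = 10,
    connectivity: int = 26,
) -> LesionMap:
    """Keep suprathreshold voxels in clusters of more than ``min_voxels``.

    Voxels with value > ``t_thresh`` are retained, then connected
    components with extent <= ``min_voxels`` are removed (a 10-voxel
    cluster is removed under the default strict >10 rule; an 11-voxel
    cluster survives).  Idempotent.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    mask = lesion.values > t_thresh
    labelled, n_clusters = ndimage.label(mask, structure=_structure(connectivity))
    out = np.zeros_like(lesion.values)
    if n_clusters:
        sizes = np.bincount(labelled.ravel())
        keep = np.zeros(sizes.size, dtype=bool)
        keep[1:] = sizes[1:] > min_voxels
        survivors = keep[labelled]
        out[survivors] = lesion.values[survivors]
    return LesionMap(
        values=out, voxel_size=lesion.voxel_size, space_tag=lesion.space_tag
    )


def atlas_overlay(
    lesion: LesionMap, atlas: AtlasLabels, min_voxels: int = 10
) -> pd.DataFrame:
    """Per-ROI lesion volume and overlay percentage.

    The overlay percentage is each ROI's share of the total
    suprathreshold (nonzero) lesion volume; ROIs with fewer than
    ``min_voxels`` lesioned voxels are omitted, so the reported
    percentages may sum to less than 100.
    """
    _check_same_grid(lesion.values.shape, atlas.labels.shape)
    active = lesion.values != 0
    total_voxels = int(active.sum())
    voxvol = lesion.voxel_volume_mm3
    rows = []
    if total_voxels:
        for label in atlas.roi_labels:
            n = int(np.count_nonzero(active & (atlas.labels == label)))
            if n < min_voxels or n == 0:
                continue
            rows.append(
                {
                    "roi_name": atlas.names[label],
                    "lesion_volume_mm3": n * voxvol,
                    "overlay_percent": 100.0 * n / total_voxels,
                }
            )
    report = pd.DataFrame(rows, columns=["roi_name", "lesion_volume_mm3", "overlay_percent"])
    return report.sort_values("lesion_volume_mm3", ascending=False, ignore_index=True)
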