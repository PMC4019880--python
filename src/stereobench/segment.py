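"""Baseline automated 3D cell detector: threshold, connected components, size filter.

This is the simplest workable model of cell appearance — a single global
intensity threshold separates foreground from background, each connected
foreground region is declared a cell, and regions much smaller than a typical
cell are discarded.  Its known failure modes (one threshold cannot follow
staining variation; nearby cells merge into one component) are exactly what
the evaluation layer is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .chroma import SmoothingSpec
from .core import GeometryError, ImageStack, MarkerSet, Spacing

#: mapping from the common 3D connectivity names to scipy structuring elements
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LabeledVolume:
    """Integer-labeled segmentation of a stack; label 0 is background.

    Labels are consecutive positive integers ordered by the raster-scan
    position of each region's first voxel, so labeling is deterministic.
    """

    labels: np.ndarray
    spacing: Spacing
    connectivity: Optional[int] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def sizes(self) -> np.ndarray:
        """Voxel count per label, index 0 holding label 1."""
        counts = np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)
        return counts[1:]

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.labels.shape


@dataclass
class DetectorParams:
    """Parameters of the baseline detector.

    ``threshold`` is inclusive (a voxel at exactly the threshold is
    foreground, the common ImageJ convention).  ``min_voxels`` removes regions
    strictly smaller than itself; the boundary case is kept.
    """

    threshold: float
    connectivity: int = 26
    min_voxels: int = 0
    smoothing: Optional[SmoothingSpec] = None

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.min_voxels < 0:
            raise ValueError("min_voxels must be non-negative")


def threshold_stack(stack: ImageStack, level: float) -> np.ndarray:
    """Binary foreground mask: voxel is foreground iff intensity >= level."""
    if stack.data.ndim != 3:
        raise GeometryError("threshold_stack expects a single-channel stack")
    return stack.data >= level


def _raster_compact(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive integers ordered by first raster-scan voxel."""
    n = int(labels.max(initial=0))
    if n == 0:
        return labels.astype(np.int32)
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    np.minimum.at(first, flat, np.arange(flat.size, dtype=np.int64))
    present = np.flatnonzero(first[1:] < flat.size) + 1
    order = present[np.argsort(first[present], kind="stable")]
    lut = np.zeros(n + 1, dtype=np.int32)
    lut[order] = np.arange(1, len(order) + 1, dtype=np.int32)
    return lut[labels]


def connected_components_3d(
    mask: np.ndarray,
    connectivity: int = 26,
    spacing: Spacing = (1.0, 1.0, 1.0),
) -> LabeledVolume:
    """Partition a binary mask into connected foreground regions.

    Two foreground voxels share a label iff they are connected under the
    declared 6/18/26 neighborhood.  Labels are compacted and ordered by each
    region's first voxel in raster-scan order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise GeometryError("mask must be 3D")
    raw, _ = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    return LabeledVolume(_raster_compact(raw), spacing, connectivity)


def size_filter(vol: LabeledVolume, min_voxels: int) -> LabeledVolume:
    """Remove regions strictly smaller than ``min_voxels`` voxels.

    Removed voxels become background; surviving labels are compacted while
    preserving their order.
    """
    if min_voxels <= 0:
        return LabeledVolume(vol.labels.copy(), vol.spacing, vol.connectivity)
    sizes = np.bincount(vol.labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    lut = np.zeros(len(sizes), dtype=np.int32)
    lut[keep] = np.arange(1, int(keep.sum()) + 1, dtype=np.int32)
    return LabeledVolume(lut[vol.labels], vol.spacing, vol.connectivity)


def min_voxels_volume(min_voxels: int, spacing: Spacing) -> float:
    """Physical volume (um^3) corresponding to a voxel-count size filter."""
    dx, dy, dz = spacing
    return min_voxels * dx * dy * dz


def detect(stack: ImageStack, params: DetectorParams) -> Tuple[LabeledVolume, MarkerSet]:
    """Run the full baseline detector and extract one marker per region.

    Optional Gaussian pre-smoothing (sigmas in voxels, independent of optical
    resolution) -> inclusive global threshold -> 3D connected components ->
    size filter -> region centroids.
    """
    from . import chroma, regionstats

    work = stack
    if params.smoothing is not None:
        work = chroma.gaussian_smooth_3d(stack, params.smoothing)
    mask = threshold_stack(work, params.threshold)
    vol = connected_components_3d(mask, params.connectivity, stack.spacing)
    vol = size_filter(vol, params.min_voxels)
    markers = regionstats.markers_from_volume(vol)
    return vol, markers
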