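"""Per-region statistics of labeled volumes.

The centroid of a region k with voxel set Omega_k is the plain voxel-index
mean, C_k = (sum x, sum y, sum z) / |Omega_k|, mirrored into physical
coordinates as index * spacing.  This intentionally matches what automated
detectors report; the manual ground-truth convention of placing z at the
median in-focus plane differs by at most about half a nucleus height and is
absorbed by the axial matching tolerance downstream.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd

from .core import MarkerSet
from .segment import LabeledVolume


def boundary_touch_flags(vol: LabeledVolume) -> np.ndarray:
    """Per-label flag (index 0 = label 1): region has a voxel on a stack face."""
    n = vol.n_labels
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    lab = vol.labels
    faces = [lab[0], lab[-1], lab[:, 0], lab[:, -1], lab[:, :, 0], lab[:, :, -1]]
    touching = np.unique(np.concatenate([f.ravel() for f in faces]))
    touching = touching[touching > 0]
    flags[touching - 1] = True
    return flags


def region_centroids(vol: LabeledVolume) -> pd.DataFrame:
    """Centroids, sizes and boundary flags of every labeled region.

    Returns a DataFrame with columns ``label, x_vox, y_vox, z_vox, x_um,
    y_um, z_um, n_voxels, boundary`` ordered by label.
    """
    zz, yy, xx = np.nonzero(vol.labels)
    lab = vol.labels[zz, yy, xx]
    n = vol.n_labels
    sizes = np.bincount(lab, minlength=n + 1)[1:]
    if np.any(sizes == 0):
        raise ValueError("labels are not consecutive: empty label present")
    cx = np.bincount(lab, weights=xx, minlength=n + 1)[1:] / np.maximum(sizes, 1)
    cy = np.bincount(lab, weights=yy, minlength=n + 1)[1:] / np.maximum(sizes, 1)
    cz = np.bincount(lab, weights=zz, minlength=n + 1)[1:] / np.maximum(sizes, 1)
    dx, dy, dz = vol.spacing
    return pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "x_vox": cx,
            "y_vox": cy,
            "z_vox": cz,
            "x_um": cx * dx,
            "y_um": cy * dy,
            "z_um": cz * dz,
            "n_voxels": sizes,
            "boundary": boundary_touch_flags(vol),
        }
    )


def markers_from_volume(vol: LabeledVolume) -> MarkerSet:
    """One marker per labeled region at its centroid, with size attached."""
    if vol.n_labels == 0:
        return MarkerSet.empty(spacing=vol.spacing)
    stats = region_centroids(vol)
    return MarkerSet(
        ids=stats["label"].to_numpy(),
        xyz=stats[["x_um", "y_um", "z_um"]].to_numpy(),
        boundary=stats["boundary"].to_numpy(),
        sizes=stats["n_voxels"].to_numpy(),
        spacing=vol.spacing,
    )


def plane_boundaries(vol: LabeledVolume, plane: int) -> pd.DataFrame:
    """Contour voxels of every region within one XY plane.

    A foreground voxel belongs to the contour of its region if at least one
    of its 4-neighbors (within the plane; off-image counts as different) has a
    different label.  Intended for visualization overlays only.

    Returns a DataFrame with columns ``label, y, x``.
    """
    if not 0 <= plane < vol.labels.shape[0]:
        raise IndexError(f"plane {plane} out of range")
    pl = vol.labels[plane]
    padded = np.pad(pl, 1, constant_values=-1)
    center = padded[1:-1, 1:-1]
    differs = (
        (padded[:-2, 1:-1] != center)
        | (padded[2:, 1:-1] != center)
        | (padded[1:-1, :-2] != center)
        | (padded[1:-1, 2:] != center)
    )
    yy, xx = np.nonzero((center > 0) & differs)
    return pd.DataFrame({"label": center[yy, xx], "y": yy, "x": xx}).sort_values(
        ["label", "y", "x"], ignore_index=True
    )
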