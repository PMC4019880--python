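"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (BFS flood fill, explicit loops,
direct summation, optimal assignment) and shares no code with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
from scipy.optimize import linear_sum_assignment

_OFFSETS = {
    6: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
        if abs(dz) + abs(dy) + abs(dx) == 1],
    18: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if 0 < abs(dz) + abs(dy) + abs(dx) <= 2],
    26: [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
         if (dz, dy, dx) != (0, 0, 0)],
}


def flood_fill_labels(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Label connected components by BFS flood fill in raster-scan order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offsets = _OFFSETS[connectivity]
    nz, ny, nx = mask.shape
    next_label = 0
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or labels[z, y, x]:
                    continue
                next_label += 1
                queue = deque([(z, y, x)])
                labels[z, y, x] = next_label
                while queue:
                    cz, cy, cx = queue.popleft()
                    for dz, dy, dx in offsets:
                        tz, ty, tx = cz + dz, cy + dy, cx + dx
                        if (0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx
                                and mask[tz, ty, tx] and not labels[tz, ty, tx]):
                            labels[tz, ty, tx] = next_label
                            queue.append((tz, ty, tx))
    return labels


def partition_of(labels: np.ndarray):
    """Set of frozensets of flat voxel indices, one per label."""
    flat = labels.ravel()
    out = {}
    for idx, lab in enumerate(flat):
        if lab > 0:
            out.setdefault(lab, []).append(idx)
    return {frozenset(v) for v in out.values()}


def explicit_centroid(labels: np.ndarray, label: int):
    """Explicit-loop voxel-index mean of one region, as (x, y, z)."""
    sx = sy = sz = n = 0
    nz, ny, nx = labels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if labels[z, y, x] == label:
                    sx += x
                    sy += y
                    sz += z
                    n += 1
    return sx / n, sy / n, sz / n


def face_scan_flags(labels: np.ndarray) -> dict:
    """Per-label boundary flag by scanning every voxel of the six faces."""
    nz, ny, nx = labels.shape
    flags = {int(k): False for k in np.unique(labels) if k > 0}
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if z in (0, nz - 1) or y in (0, ny - 1) or x in (0, nx - 1):
                    lab = int(labels[z, y, x])
                    if lab > 0:
                        flags[lab] = True
    return flags


def direct_gaussian_3d(data: np.ndarray, sigmas_xyz, truncate: float = 4.0):
    """Direct-summation separable Gaussian convolution (zero boundary).

    Only valid where the kernel support does not leave the array; the caller
    is responsible for comparing interior voxels only.
    """
    sx, sy, sz = sigmas_xyz

    def kernel(sigma):
        if sigma == 0:
            return np.array([1.0]), 0
        radius = int(truncate * sigma + 0.5)
        offs = np.arange(-radius, radius + 1)
        w = np.exp(-(offs**2) / (2 * sigma**2))
        return w / w.sum(), radius

    kx, rx = kernel(sx)
    ky, ry = kernel(sy)
    kz, rz = kernel(sz)
    nz, ny, nx = data.shape
    out = np.zeros_like(data, dtype=float)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                acc = 0.0
                for iz in range(-rz, rz + 1):
                    for iy in range(-ry, ry + 1):
                        for ix in range(-rx, rx + 1):
                            tz, ty, tx = z + iz, y + iy, x + ix
                            if 0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx:
                                acc += (data[tz, ty, tx] * kz[iz + rz]
                                        * ky[iy + ry] * kx[ix + rx])
                out[z, y, x] = acc
    return out


def optimal_match_count(gt_xyz: np.ndarray, det_xyz: np.ndarray,
                        r_xy: float, r_z: float) -> int:
    """Maximum number of gt-detection pairs under the cylinder rule
    (optimal bipartite assignment via the Hungarian algorithm)."""
    if len(gt_xyz) == 0 or len(det_xyz) == 0:
        return 0
    d = gt_xyz[:, None, :] - det_xyz[None, :, :]
    dxy = np.hypot(d[..., 0], d[..., 1])
    dz = np.abs(d[..., 2])
    eligible = (dxy <= r_xy) & (dz <= r_z)
    cost = np.where(eligible, -1.0, 0.0)
    rows, cols = linear_sum_assignment(cost)
    return int(eligible[rows, cols].sum())


def random_ellipsoid_region(shape, rng, max_size=250):
    """A random connected blob-ish region as a set of voxel indices."""
    nz, ny, nx = shape
    cz = rng.uniform(2, nz - 3)
    cy = rng.uniform(2, ny - 3)
    cx = rng.uniform(2, nx - 3)
    rz = rng.uniform(1, nz / 3)
    ry = rng.uniform(1, ny / 3)
    rx = rng.uniform(1, nx / 3)
    voxels = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1:
                    voxels.append((z, y, x))
    return voxels[:max_size]
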