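"""Shared containers and coordinate conventions.

Conventions used throughout the package:

* Image arrays are indexed ``[z, y, x]`` (plane-major, the order in which the
  planes of a multi-page TIFF are stored); RGB or multi-channel stacks carry a
  trailing channel axis.
* Voxel indices are 0-based and the physical position of a voxel is
  ``index * spacing`` in micrometres, with no half-voxel offset.
* ``spacing`` is always ``(dx, dy, dz)`` in um/voxel (lateral x, lateral y,
  axial z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

Spacing = Tuple[float, float, float]

RGB_CHANNELS = ("R", "G", "B")


class GeometryError(ValueError):
    """Raised when stacks or marker sets with incompatible geometry meet."""


@dataclass
class ImageStack:
    """A 3D voxel grid (optionally multi-channel) with anisotropic spacing.

    ``data`` has shape ``(nz, ny, nx)`` for single-channel stacks or
    ``(nz, ny, nx, c)`` for multi-channel ones.  ``channel_names`` names the
    trailing axis; 3-channel stacks default to ``("R", "G", "B")``.
    """

    data: np.ndarray
    spacing: Spacing
    channel_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise GeometryError(
                f"stack data must be 3D or 3D+channel, got shape {self.data.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.ndim == 4:
            if self.channel_names is None:
                if self.data.shape[-1] == 3:
                    self.channel_names = RGB_CHANNELS
                else:
                    raise GeometryError("multi-channel stack needs channel_names")
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != self.data.shape[-1]:
                raise GeometryError(
                    f"{self.data.shape[-1]} channels but names {self.channel_names}"
                )

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def nz(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nx(self) -> int:
        return self.data.shape[2]

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def is_rgb(self) -> bool:
        return self.data.ndim == 4 and self.channel_names == RGB_CHANNELS

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[-1]

    @property
    def bit_depth(self) -> Optional[int]:
        """Bit depth for integer stacks, None for real-valued ones."""
        if self.data.dtype == np.uint8:
            return 8
        if self.data.dtype == np.uint16:
            return 16
        return None

    def extent_um(self) -> Tuple[float, float, float]:
        """Physical coordinate of the last voxel along each axis (x, y, z)."""
        dx, dy, dz = self.spacing
        return ((self.nx - 1) * dx, (self.ny - 1) * dy, (self.nz - 1) * dz)

    def same_geometry(self, other: "ImageStack") -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(
            self.spacing, other.spacing
        )

    def with_data(self, data: np.ndarray, channel_names=None) -> "ImageStack":
        return ImageStack(data, self.spacing, channel_names)


@dataclass
class MarkerSet:
    """Point annotations (ground truth or detections) in physical coordinates.

    ``xyz`` is an ``(n, 3)`` array of (x, y, z) positions in um.  ``boundary``
    flags cells whose support intersects the image boundary; ``sizes`` is the
    voxel count of the originating region where known.  ``spacing`` declares
    the coordinate frame (the voxel spacing of the stack the markers refer to)
    and is used to refuse comparisons across frames.
    """

    ids: np.ndarray
    xyz: np.ndarray
    boundary: np.ndarray
    sizes: Optional[np.ndarray] = None
    spacing: Optional[Spacing] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.boundary = np.asarray(self.boundary, dtype=bool)
        if self.sizes is not None:
            self.sizes = np.asarray(self.sizes, dtype=np.int64)
        n = len(self.ids)
        if self.xyz.shape[0] != n or self.boundary.shape[0] != n:
            raise ValueError("ids, xyz and boundary must have equal length")
        if self.sizes is not None and self.sizes.shape[0] != n:
            raise ValueError("sizes length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_interior(self) -> int:
        return int((~self.boundary).sum())

    @classmethod
    def empty(cls, spacing: Optional[Spacing] = None) -> "MarkerSet":
        return cls(
            ids=np.zeros(0, dtype=np.int64),
            xyz=np.zeros((0, 3)),
            boundary=np.zeros(0, dtype=bool),
            spacing=spacing,
        )

    @classmethod
    def from_arrays(cls, xyz, boundary=None, ids=None, sizes=None, spacing=None):
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        n = xyz.shape[0]
        if ids is None:
            ids = np.arange(1, n + 1)
        if boundary is None:
            boundary = np.zeros(n, dtype=bool)
        return cls(ids=ids, xyz=xyz, boundary=boundary, sizes=sizes, spacing=spacing)

    def to_dataframe(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "id": self.ids,
                "x_um": self.xyz[:, 0],
                "y_um": self.xyz[:, 1],
                "z_um": self.xyz[:, 2],
                "boundary": self.boundary.astype(int),
            }
        )
        if self.sizes is not None:
            frame["n_voxels"] = self.sizes
        return frame

    def translated(self, delta) -> "MarkerSet":
        delta = np.asarray(delta, dtype=float).reshape(1, 3)
        return MarkerSet(
            ids=self.ids.copy(),
            xyz=self.xyz + delta,
            boundary=self.boundary.copy(),
            sizes=None if self.sizes is None else self.sizes.copy(),
            spacing=self.spacing,
        )


def quantize(values: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Scale real values in [0, 1] to an unsigned integer range.

    Rounds half away from zero (all values are non-negative after clipping, so
    this is floor(x + 0.5)).
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    vmax = 2**bit_depth - 1
    clipped = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
    out = np.floor(clipped * vmax + 0.5)
    return out.astype(np.uint8 if bit_depth == 8 else np.uint16)
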