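"""Channel extraction and color/intensity preprocessing.

Every detector in this package expects a single-channel stack in which cells
are bright on a dark background, as in fluorescence imaging.  Brightfield
DAB-stained material is the opposite (dark brown cells on a bright neutral
background), so two conversions are provided: inverting the red channel, and
the red chromaticity r = R / (R + G + B) of the Lrg color-ratio space, in
which stained regions come out brighter than the background.  Both operate on
each voxel independently and therefore change contrast but not resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import GeometryError, ImageStack, RGB_CHANNELS


@dataclass
class SmoothingSpec:
    """Per-axis Gaussian standard deviations in *voxel* units.

    Voxel units are deliberate: the smoothing is a camera-noise reduction
    step whose scale is independent of the optical resolution.
    """

    sigma_x: float = 0.0
    sigma_y: float = 0.0
    sigma_z: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_x, self.sigma_y, self.sigma_z) < 0:
            raise ValueError("smoothing sigmas must be non-negative")


def _require_rgb(stack: ImageStack) -> None:
    if not stack.is_rgb:
        raise GeometryError("operation requires an RGB stack")


def invert_red_channel(stack: ImageStack) -> ImageStack:
    """Invert the red channel of an RGB stack: out = (2^d - 1) - R."""
    _require_rgb(stack)
    depth = stack.bit_depth
    if depth is None:
        raise ValueError("invert_red_channel requires an integer-typed stack")
    vmax = 2**depth - 1
    red = stack.data[..., 0]
    return ImageStack((vmax - red.astype(np.int64)).astype(red.dtype), stack.spacing)


def red_chromaticity(stack: ImageStack) -> ImageStack:
    """Per-voxel red chromaticity r = R / (R + G + B), in [0, 1].

    Pure black voxels (R = G = B = 0) are defined to have r = 0; in the
    brightfield context they are background.
    """
    _require_rgb(stack)
    rgb = stack.data.astype(np.float64)
    total = rgb.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, rgb[..., 0] / np.where(total > 0, total, 1.0), 0.0)
    return ImageStack(r, stack.spacing)


def gaussian_smooth_3d(stack: ImageStack, spec: SmoothingSpec) -> ImageStack:
    """Separable 3D Gaussian convolution with per-axis sigmas in voxels.

    Reflect (half-sample symmetric) boundary handling, kernel truncated at
    4 sigma.  Output is real-valued with unchanged geometry.
    """
    if stack.data.ndim != 3:
        raise GeometryError("gaussian_smooth_3d expects a single-channel stack")
    sigma = (spec.sigma_z, spec.sigma_y, spec.sigma_x)  # array axes are (z, y, x)
    data = stack.data.astype(np.float64)
    if max(sigma) == 0:
        return ImageStack(data, stack.spacing)
    out = ndimage.gaussian_filter(data, sigma=sigma, mode="reflect", truncate=4.0)
    return ImageStack(out, stack.spacing)


def extract_channel(stack: ImageStack, channel: str) -> ImageStack:
    """Extract a named channel as a grayscale stack with unchanged geometry.

    RGB stacks are addressed by "R"/"G"/"B"; fluorescence multi-channel
    stacks by the role labels they were merged with (e.g. "nuclear").
    """
    if stack.data.ndim != 4:
        raise GeometryError("extract_channel expects a multi-channel stack")
    names = stack.channel_names
    if channel not in names:
        raise KeyError(f"unknown channel {channel!r}; stack has {names}")
    return ImageStack(stack.data[..., names.index(channel)], stack.spacing)


def merge_channels(stacks, names) -> ImageStack:
    """Merge single-channel stacks of identical geometry into one stack."""
    names = tuple(names)
    if len(stacks) != len(names) or not stacks:
        raise ValueError("need one name per stack")
    base = stacks[0]
    for s in stacks[1:]:
        if not base.same_geometry(s):
            raise GeometryError("channel geometry mismatch")
    data = np.stack([s.data for s in stacks], axis=-1)
    channel_names = RGB_CHANNELS if names == RGB_CHANNELS else names
    return ImageStack(data, base.spacing, channel_names)
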