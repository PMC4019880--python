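"""Synthetic 3D microscopy stacks with exactly known ground truth.

The generator emulates the statistical structure of thick-section widefield /
confocal acquisitions: ellipsoidal nuclei or somata (4-5 um diameter in XY)
placed by hard-core rejection sampling (optionally with Thomas-process
clustering), rendered as an indicator volume convolved with an anisotropic
Gaussian that stands in for the axial point-spread blur, on top of additive
Gaussian (and optionally Poisson) noise.  Fluorescent stacks are bright cells
on a dark background; brightfield stacks are RGB with DAB-brown cells darker
than a bright neutral background in the red channel.

Four acquisition presets reproduce the published benchmark geometries
(voxel spacings, plane counts and modalities of stacks 3A-3D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import GeometryError, ImageStack, MarkerSet, Spacing, quantize
from .regionstats import markers_from_volume
from .segment import LabeledVolume


class PlacementError(RuntimeError):
    """Raised when hard-core rejection sampling cannot place all cells."""


@dataclass(frozen=True)
class AcquisitionProfile:
    """Geometry and modality of one acquisition condition."""

    name: str
    lateral_spacing_x: float  # um/voxel
    lateral_spacing_y: float
    axial_spacing: float  # um/plane
    width: int  # voxels
    height: int
    n_planes: int
    modality: str = "fluorescence"  # or "brightfield_rgb"
    label_target: str = "nucleus"  # or "cytoplasm"

    def __post_init__(self) -> None:
        if min(self.lateral_spacing_x, self.lateral_spacing_y, self.axial_spacing) <= 0:
            raise ValueError("all spacings must be positive")
        if self.n_planes < 1 or self.width < 1 or self.height < 1:
            raise ValueError("stack dimensions must be at least 1")
        if self.modality not in ("fluorescence", "brightfield_rgb"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def spacing(self) -> Spacing:
        return (self.lateral_spacing_x, self.lateral_spacing_y, self.axial_spacing)

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return (self.n_planes, self.height, self.width)

    def scaled(self, width: int, height: int, n_planes: int) -> "AcquisitionProfile":
        """Same spacings and modality on a smaller (or larger) voxel grid."""
        return replace(self, width=width, height=height, n_planes=n_planes)


def preset_profiles() -> List[AcquisitionProfile]:
    """The four benchmark acquisition conditions (stacks 3A-3D)."""
    return [
        AcquisitionProfile("3A", 0.102134, 0.101507, 0.5, 1388, 1040, 45,
                           "fluorescence", "nucleus"),
        AcquisitionProfile("3B", 0.46056, 0.46056, 1.0, 512, 512, 51,
                           "fluorescence", "nucleus"),
        AcquisitionProfile("3C", 0.102134, 0.101507, 0.5, 1344, 1024, 26,
                           "fluorescence", "cytoplasm"),
        AcquisitionProfile("3D", 0.075173, 0.074300, 0.5, 1600, 1200, 45,
                           "brightfield_rgb", "cytoplasm"),
    ]


def preset_profile(name: str) -> AcquisitionProfile:
    for p in preset_profiles():
        if p.name == name:
            return p
    raise KeyError(f"unknown acquisition preset {name!r}")


@dataclass
class CellPopulationSpec:
    """Population to place in a stack.

    Radii are in um; the defaults correspond to nuclei with a 4-5 um XY
    diameter.  ``clustering`` is the offspring dispersion (um) of a Thomas
    process (None = homogeneous placement).  ``min_separation`` is a hard-core
    center-to-center distance in um.
    """

    n_cells: int = 50
    radius_xy_range: Tuple[float, float] = (2.0, 2.5)
    radius_z_range: Tuple[float, float] = (2.0, 2.5)
    clustering: Optional[float] = None
    min_separation: float = 5.5
    intensity_range: Tuple[float, float] = (0.6, 1.0)
    allow_boundary_cut: bool = True

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        for lo, hi in (self.radius_xy_range, self.radius_z_range):
            if lo <= 0 or hi < lo:
                raise ValueError("radius ranges must be positive intervals")
        lo, hi = self.intensity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("intensity_range must lie in [0, 1]")
        if self.min_separation < 0:
            raise ValueError("min_separation must be non-negative")


@dataclass
class NoiseModel:
    """Noise and blur applied during rendering.

    ``background_level`` and ``gaussian_sd`` are on the normalized [0, 1]
    intensity scale; ``poisson_scale`` is photons per unit intensity (0
    disables shot noise); blur sigmas are in um, with the axial sigma larger
    by default to emulate out-of-focus axial blur.
    """

    background_level: float = 0.08
    gaussian_sd: float = 0.02
    poisson_scale: float = 0.0
    axial_blur_sd: float = 1.0
    lateral_blur_sd: float = 0.3

    def __post_init__(self) -> None:
        vals = (self.background_level, self.gaussian_sd, self.poisson_scale,
                self.axial_blur_sd, self.lateral_blur_sd)
        if min(vals) < 0:
            raise ValueError("noise parameters must be non-negative")


_MAX_TRIES_PER_CELL = 2000

# DAB-stained brightfield rendering: bright near-neutral background, brown
# cells whose red value is below the background red (and whose chromaticity
# r = R/(R+G+B) is above it).
_BF_BACKGROUND = np.array([0.90, 0.88, 0.86])
_BF_STAIN = np.array([0.45, 0.28, 0.14])


def _sample_centers(
    profile: AcquisitionProfile,
    pop: CellPopulationSpec,
    radii: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hard-core (optionally Thomas-clustered) center placement in um."""
    ex, ey, ez = (
        (profile.width - 1) * profile.lateral_spacing_x,
        (profile.height - 1) * profile.lateral_spacing_y,
        (profile.n_planes - 1) * profile.axial_spacing,
    )
    spacing = np.array(profile.spacing)
    extent = np.array([ex, ey, ez])

    parents = None
    if pop.clustering is not None and pop.n_cells > 0:
        n_parents = max(1, math.ceil(pop.n_cells / 5))
        parents = rng.uniform(0, 1, size=(n_parents, 3)) * extent

    centers: List[np.ndarray] = []
    for i in range(pop.n_cells):
        r_xyz = np.array([radii[i, 0], radii[i, 0], radii[i, 1]])
        if pop.allow_boundary_cut:
            lo = np.zeros(3)
            hi = extent.copy()
        else:
            # margin keeps the rasterized support strictly off the faces
            lo = r_xyz + 0.51 * spacing
            hi = extent - r_xyz - 0.51 * spacing
        if np.any(hi < lo):
            raise PlacementError(
                f"cell radius {r_xyz} does not fit interior of stack extent {extent}"
            )
        placed = False
        for _ in range(_MAX_TRIES_PER_CELL):
            if parents is None:
                cand = rng.uniform(lo, hi)
            else:
                parent = parents[rng.integers(len(parents))]
                cand = parent + rng.normal(0.0, pop.clustering, size=3)
                if np.any(cand < lo) or np.any(cand > hi):
                    continue
            if centers and pop.min_separation > 0:
                d = np.linalg.norm(np.array(centers) - cand, axis=1)
                if d.min() < pop.min_separation:
                    continue
            centers.append(cand)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1}/{pop.n_cells} with "
                f"min_separation={pop.min_separation} um after "
                f"{_MAX_TRIES_PER_CELL} attempts"
            )
    return np.array(centers).reshape(-1, 3)


def _paint_cells(
    profile: AcquisitionProfile,
    centers: np.ndarray,
    radii: np.ndarray,
    intensities: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Rasterize ellipsoids into a label volume and an intensity volume."""
    nz, ny, nx = profile.grid_shape
    dx, dy, dz = profile.spacing
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    intensity = np.zeros((nz, ny, nx), dtype=np.float64)
    for k, (c, r, amp) in enumerate(zip(centers, radii, intensities), start=1):
        cx, cy, cz = c
        rxy, rz = r
        ix0 = max(0, math.ceil((cx - rxy) / dx))
        ix1 = min(nx - 1, math.floor((cx + rxy) / dx))
        iy0 = max(0, math.ceil((cy - rxy) / dy))
        iy1 = min(ny - 1, math.floor((cy + rxy) / dy))
        iz0 = max(0, math.ceil((cz - rz) / dz))
        iz1 = min(nz - 1, math.floor((cz + rz) / dz))
        if ix1 < ix0 or iy1 < iy0 or iz1 < iz0:
            continue
        xs = (np.arange(ix0, ix1 + 1) * dx - cx) / rxy
        ys = (np.arange(iy0, iy1 + 1) * dy - cy) / rxy
        zs = (np.arange(iz0, iz1 + 1) * dz - cz) / rz
        mask = (
            zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2
        ) <= 1.0
        box_lab = labels[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1]
        box_int = intensity[iz0 : iz1 + 1, iy0 : iy1 + 1, ix0 : ix1 + 1]
        paint = mask & (box_lab == 0)
        box_lab[paint] = k
        np.maximum(box_int, np.where(mask, amp, 0.0), out=box_int)
    return labels, intensity


def _compact_labels(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Drop labels with no surviving voxels; return (labels, kept original ids)."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max(initial=0) + 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels], present


def _blur(intensity: np.ndarray, noise: NoiseModel, spacing: Spacing) -> np.ndarray:
    dx, dy, dz = spacing
    sigma = (noise.axial_blur_sd / dz, noise.lateral_blur_sd / dy,
             noise.lateral_blur_sd / dx)
    if max(sigma) == 0:
        return intensity
    return ndimage.gaussian_filter(intensity, sigma=sigma, mode="reflect", truncate=4.0)


def render_brightfield(
    labels: LabeledVolume,
    intensity_stack: ImageStack,
    seed: int,
    noise_sd: float = 0.02,
    background_rgb: np.ndarray = _BF_BACKGROUND,
    stain_rgb: np.ndarray = _BF_STAIN,
) -> ImageStack:
    """Render a stain-intensity field as an 8-bit brightfield RGB stack.

    The background is bright and approximately neutral; voxels blend toward a
    DAB-brown stain color in proportion to the (blurred) stain intensity, so
    cells are darker than the background in the red channel but brighter in
    the red chromaticity channel.
    """
    if labels.grid_shape != intensity_stack.grid_shape:
        raise GeometryError("labels and intensity stack geometry mismatch")
    if intensity_stack.data.ndim != 3:
        raise GeometryError("intensity stack must be single-channel")
    rng = np.random.default_rng(seed)
    alpha = np.clip(intensity_stack.data.astype(np.float64), 0.0, 1.0)[..., None]
    rgb = background_rgb * (1.0 - alpha) + stain_rgb * alpha
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, size=rgb.shape)
    return ImageStack(quantize(rgb, 8), intensity_stack.spacing)


def sample_population(
    profile: AcquisitionProfile, pop: CellPopulationSpec, seed: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the analytic cell population for a given master seed.

    Returns ``(centers, radii, intensities)`` with centers in um and radii as
    ``(r_xy, r_z)`` pairs.  This is exactly the population ``generate_stack``
    rasterizes for the same arguments: the master seed is split into fixed
    per-stage streams (placement, cell geometry, pixel noise, brightfield
    rendering), so individual stages can be re-run independently.
    """
    ss = np.random.SeedSequence(seed)
    place_ss, cell_ss, _, _ = ss.spawn(4)
    cell_rng = np.random.default_rng(cell_ss)
    place_rng = np.random.default_rng(place_ss)
    n = pop.n_cells
    radii = np.column_stack(
        [
            cell_rng.uniform(*pop.radius_xy_range, size=n),
            cell_rng.uniform(*pop.radius_z_range, size=n),
        ]
    ).reshape(-1, 2)
    intensities = cell_rng.uniform(*pop.intensity_range, size=n)
    centers = _sample_centers(profile, pop, radii, place_rng)
    return centers, radii, intensities


def generate_stack(
    profile: AcquisitionProfile,
    pop: CellPopulationSpec,
    noise: NoiseModel,
    seed: int,
    bit_depth: int = 8,
) -> Tuple[ImageStack, MarkerSet, LabeledVolume]:
    """Generate one synthetic stack plus its exact ground truth.

    Returns ``(stack, markers, labels)``: the rendered image stack (grayscale
    for fluorescence, RGB for brightfield), one ground-truth marker per placed
    cell at the voxel-mean centroid of its true support (boundary flag set
    when the support touches any stack face), and the true label volume.

    All randomness derives from ``seed`` through a fixed splitting scheme
    (see :func:`sample_population`), so identical inputs reproduce
    bit-identical outputs.
    """
    ss = np.random.SeedSequence(seed)
    _, _, noise_ss, bf_ss = ss.spawn(4)
    noise_rng = np.random.default_rng(noise_ss)
    bf_seed = int(bf_ss.generate_state(1)[0] % (2**31))

    centers, radii, intensities = sample_population(profile, pop, seed)

    raw_labels, stain = _paint_cells(profile, centers, radii, intensities)
    raw_labels, _ = _compact_labels(raw_labels)
    vol = LabeledVolume(raw_labels, profile.spacing)
    markers = markers_from_volume(vol)

    blurred = _blur(stain, noise, profile.spacing)
    if profile.modality == "brightfield_rgb":
        stack = render_brightfield(
            vol,
            ImageStack(blurred, profile.spacing),
            seed=bf_seed,
            noise_sd=noise.gaussian_sd,
        )
    else:
        img = noise.background_level + blurred
        if noise.poisson_scale > 0:
            img = noise_rng.poisson(np.clip(img, 0, None) * noise.poisson_scale)
            img = img / noise.poisson_scale
        if noise.gaussian_sd > 0:
            img = img + noise_rng.normal(0.0, noise.gaussian_sd, size=img.shape)
        stack = ImageStack(quantize(img, bit_depth), profile.spacing)
    return stack, markers, vol


def contrast_to_noise(stack: ImageStack, labels: LabeledVolume) -> float:
    """(mean foreground - mean background) / background standard deviation.

    Defined on single-channel stacks; the statistic the noise-monotonicity
    property is stated on.
    """
    if stack.data.ndim != 3:
        raise GeometryError("contrast_to_noise expects a single-channel stack")
    fg = labels.labels > 0
    if not fg.any() or fg.all():
        raise ValueError("need both foreground and background voxels")
    data = stack.data.astype(np.float64)
    bg = data[~fg]
    sd = bg.std()
    if sd == 0:
        raise ValueError("background has zero variance")
    return float((data[fg].mean() - bg.mean()) / sd)
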