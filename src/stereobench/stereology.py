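"""3D stereologic counting rules: unbiased counting frame, UVCS, fractionator.

The unbiased counting frame (Sterio's rule) is a 2D rectangle with two
inclusion edges (top and right) and two exclusion edges (left and bottom,
extended beyond the frame: the left edge infinitely upward from the top-left
corner and the right edge infinitely downward from the bottom-right corner).
A cell profile is counted iff part of it lies inside the frame and it touches
no exclusion line.  The unbiased virtual counting space (UVCS) extends the
frame into the section thickness: a cell is counted only if it additionally
has its unique "top" (the Z position where it first comes into focus) inside
the UVCS depth interval.  Together these rules count every cell exactly once
regardless of size, shape or orientation, which is what 2D profile counting
cannot do.

Cells are represented by circular XY footprints and a top-z coordinate; the
rules are stated on profiles and tops, so these proxies keep them exactly
testable.  Z increases downward into the section (z = 0 at the section top).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class UVCSGeometry:
    """Counting frame plus depth interval within the section.

    ``frame_origin`` is the lower-left (minimum-x, minimum-y) corner of the
    frame in um; exclusion edges are the left and bottom edges plus their
    extensions (the classic convention); ``z_top < z_bottom`` bound the
    counting depth, leaving guard zones against sectioning artifacts.
    """

    frame_origin: Tuple[float, float]
    frame_size: Tuple[float, float]
    z_top: float
    z_bottom: float

    def __post_init__(self) -> None:
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise ValueError("frame dimensions must be positive")
        if not self.z_top < self.z_bottom:
            raise ValueError("z_top must be above (less than) z_bottom")

    @property
    def x0(self) -> float:
        return self.frame_origin[0]

    @property
    def y0(self) -> float:
        return self.frame_origin[1]

    @property
    def x1(self) -> float:
        return self.frame_origin[0] + self.frame_size[0]

    @property
    def y1(self) -> float:
        return self.frame_origin[1] + self.frame_size[1]


@dataclass(frozen=True)
class CellRecord:
    """A cell as seen by the counting rules.

    ``centroid`` is (x, y, z) in um, ``radius`` the circular XY footprint
    radius, and ``top_z`` the depth at which the cell first comes into focus.
    A cell cut off at the section top has its top in the section above; such
    cells carry ``top_z = None``.
    """

    centroid: Tuple[float, float, float]
    radius: float
    top_z: Optional[float]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("footprint radius must be positive")
        if self.top_z is not None and self.top_z > self.centroid[2]:
            raise ValueError("top_z must not be below the centroid")


def _dist_point_segment(
    px: float, py: float, ax: float, ay: float, bx: float, by: float
) -> float:
    abx, aby = bx - ax, by - ay
    denom = abx * abx + aby * aby
    t = 0.0 if denom == 0 else max(0.0, min(1.0, ((px - ax) * abx + (py - ay) * aby) / denom))
    return math.hypot(px - (ax + t * abx), py - (ay + t * aby))


def _dist_point_vertical_ray(px, py, x, y_start, upward: bool) -> float:
    """Distance to the ray x = const, y >= y_start (upward) or y <= y_start."""
    if (py >= y_start) if upward else (py <= y_start):
        return abs(px - x)
    return math.hypot(px - x, py - y_start)


def _touches_exclusion(cell: CellRecord, frame: UVCSGeometry) -> bool:
    cx, cy, _ = cell.centroid
    r = cell.radius
    dists = (
        # left edge and its extension above the frame: x = x0, y in [y0, +inf)
        _dist_point_vertical_ray(cx, cy, frame.x0, frame.y0, upward=True),
        # bottom edge
        _dist_point_segment(cx, cy, frame.x0, frame.y0, frame.x1, frame.y0),
        # extension of the exclusion line below the bottom-right corner
        _dist_point_vertical_ray(cx, cy, frame.x1, frame.y0, upward=False),
    )
    return min(dists) <= r


def _intersects_frame(cell: CellRecord, frame: UVCSGeometry) -> bool:
    cx, cy, _ = cell.centroid
    nx = min(max(cx, frame.x0), frame.x1)
    ny = min(max(cy, frame.y0), frame.y1)
    return math.hypot(cx - nx, cy - ny) < cell.radius


def frame_classify(cell: CellRecord, frame: UVCSGeometry) -> str:
    """Apply the 2D unbiased counting frame rule.

    Returns "counted" if the footprint lies inside the frame or intersects
    only inclusion edges, "excluded" if it touches any exclusion line (or its
    extensions) or misses the frame entirely.
    """
    if not _intersects_frame(cell, frame):
        return "excluded"
    return "excluded" if _touches_exclusion(cell, frame) else "counted"


def top_in_uvcs(cell: CellRecord, frame: UVCSGeometry) -> bool:
    """True iff the cell's top lies inside this section and within the UVCS depth."""
    if cell.top_z is None:  # top is in the section above
        return False
    return frame.z_top <= cell.top_z <= frame.z_bottom


def uvcs_count(
    cells: Iterable[CellRecord], frame: UVCSGeometry
) -> Tuple[int, List[str]]:
    """Count cells satisfying all 3D counting rules.

    A cell is counted iff the frame rule accepts its profile AND its top lies
    within the UVCS.  Returns the count and a per-cell classification
    ("counted", "frame_excluded", or "top_outside").
    """
    classes: List[str] = []
    count = 0
    for cell in cells:
        if frame_classify(cell, frame) != "counted":
            classes.append("frame_excluded")
        elif not top_in_uvcs(cell, frame):
            classes.append("top_outside")
        else:
            classes.append("counted")
            count += 1
    return count, classes


@dataclass(frozen=True)
class SamplingDesign:
    """Known sampling fractions of a fractionator design.

    ``section_fraction`` = sampled sections / all sections, ``area_fraction``
    = frame area / grid tile area, ``height_fraction`` = UVCS depth / section
    thickness; each in (0, 1].
    """

    section_fraction: float = 1.0
    area_fraction: float = 1.0
    height_fraction: float = 1.0

    def __post_init__(self) -> None:
        for f in (self.section_fraction, self.area_fraction, self.height_fraction):
            if not 0 < f <= 1:
                raise ValueError("sampling fractions must be in (0, 1]")


def estimate_total(counted: float, design: SamplingDesign) -> float:
    """Fractionator estimate: total = Q / (ssf * asf * hsf)."""
    return counted / (
        design.section_fraction * design.area_fraction * design.height_fraction
    )


def fractionator_simulation(
    n_points: int,
    seed: int,
    block_xy: float = 200.0,
    section_thickness: float = 20.0,
    n_sections: int = 10,
    section_period: int = 2,
    tile: float = 40.0,
    frame: float = 20.0,
    uvcs_height: float = 10.0,
    guard: float = 5.0,
) -> float:
    """One fractionator estimate of a known uniform point population.

    ``n_points`` points (point-like cells: the top coincides with the point)
    are scattered uniformly in a block of ``block_xy`` x ``block_xy`` x
    ``n_sections * section_thickness`` um, sectioned exhaustively; every
    ``section_period``-th section is sampled from a random start, frames of
    side ``frame`` are placed on a systematically random grid with tile side
    ``tile``, and points are counted when they fall in a sampled frame (the
    half-open frame realizes the counting-frame rule for points) with local
    depth inside ``(guard, guard + uvcs_height]``.  Returns the fractionator
    estimate of the total; averaging over seeds demonstrates unbiasedness.
    """
    rng = np.random.default_rng(seed)
    depth = n_sections * section_thickness
    pts = rng.uniform(0.0, 1.0, size=(n_points, 3)) * (block_xy, block_xy, depth)

    sec = np.floor(pts[:, 2] / section_thickness).astype(int)
    sec_start = rng.integers(section_period)
    in_section = (sec % section_period) == sec_start

    ux, uy = rng.uniform(0, tile, size=2)
    fx = np.mod(pts[:, 0] - ux, tile)
    fy = np.mod(pts[:, 1] - uy, tile)
    in_frame = (fx > 0) & (fx <= frame) & (fy > 0) & (fy <= frame)

    zeta = pts[:, 2] - sec * section_thickness
    in_height = (zeta > guard) & (zeta <= guard + uvcs_height)

    q = int(np.count_nonzero(in_section & in_frame & in_height))
    design = SamplingDesign(
        section_fraction=1.0 / section_period,
        area_fraction=(frame / tile) ** 2,
        height_fraction=uvcs_height / section_thickness,
    )
    return estimate_total(q, design)


def profile_count_bias_demo(
    populations: Sequence[Tuple[str, int, float]],
    section_thickness: float,
    seed: int,
    block: float = 200.0,
    uvcs_height: float = 10.0,
) -> pd.DataFrame:
    """Demonstrate the size bias of 2D profile counting vs UVCS counting.

    Each population is ``(name, n_cells, radius_um)``: spherical cells with
    centers uniform in a ``block``-sided cube.  A thin section of the given
    thickness is cut at a common random depth; a cell contributes a profile
    iff the section slab intersects its sphere, so the expected profile count
    grows with cell diameter ((d + t) / block per cell).  UVCS counting uses
    only the cell tops inside a disector of height ``uvcs_height`` at the
    same depth and is size-independent.

    Returns a DataFrame with columns ``population, true_count,
    profile_count, uvcs_count, uvcs_estimate``.
    """
    rng = np.random.default_rng(seed)
    max_r = max((r for _, _, r in populations), default=0.0)
    z_sec = rng.uniform(max_r + uvcs_height, block - max_r - section_thickness)
    rows = []
    for name, n, radius in populations:
        centers = rng.uniform(0.0, block, size=(n, 3))
        cz = centers[:, 2]
        profiles = int(np.count_nonzero((cz + radius >= z_sec) & (cz - radius <= z_sec + section_thickness)))
        tops = cz - radius
        uvcs = int(np.count_nonzero((tops > z_sec) & (tops <= z_sec + uvcs_height)))
        rows.append(
            {
                "population": name,
                "true_count": n,
                "profile_count": profiles,
                "uvcs_count": uvcs,
                "uvcs_estimate": uvcs * block / uvcs_height,
            }
        )
    return pd.DataFrame(rows)
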