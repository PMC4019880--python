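"""Centroid matching, TP/FN/FP classification, rates, and method combination.

Detections are matched to ground-truth markers by a single greedy pass over
the ground truth: a cylindrical search region (lateral radius r_xy, axial
half-height r_z) centered on each ground-truth centroid is inspected for the
nearest not-yet-consumed detection.  A hit marks the ground-truth cell as a
true-positive and consumes the detection; a miss marks it as a
false-negative; detections left over at the end are false-positives.  The
cylinder reflects the anisotropic precision of light microscopy: XY positions
are known more precisely than Z.

Rates: R_tp = N_tp / N_gt, R_fp = N_fp / N_s, where N_s is the number of
detected objects.  Stratified true-positive rates split the ground truth into
cells fully interior to the stack (R_tpi) and cells touching its boundary
(R_tpb); boundary cells are matched like any others, the split is post hoc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import GeometryError, MarkerSet


@dataclass(frozen=True)
class ToleranceSpec:
    """Cylindrical matching tolerance: lateral radius and axial half-height, um."""

    r_xy: float = 3.0
    r_z: float = 1.5

    def __post_init__(self) -> None:
        if self.r_xy <= 0 or self.r_z <= 0:
            raise ValueError("tolerances must be positive")


def default_tolerance(profile_name: str) -> ToleranceSpec:
    """Benchmark tolerances: 3 um lateral; 2 um axial for the low-NA
    condition (3B), 1.5 um for the rest."""
    return ToleranceSpec(3.0, 2.0 if profile_name == "3B" else 1.5)


@dataclass
class MatchResult:
    """TP/FN/FP assignment between a ground-truth and a detection set.

    ``assignments`` has one row per ground-truth marker (class TP or FN, with
    the matched detection id or <NA>) followed by one row per unmatched
    detection (class FP).
    """

    assignments: pd.DataFrame
    n_gt: int
    n_gti: int
    n_s: int
    n_tp: int
    n_fn: int
    n_fp: int
    r_tp: float
    r_tpi: float
    r_tpb: float
    r_fp: float
    tp_gt_ids: FrozenSet[int]
    fp_xyz: np.ndarray
    fp_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_tp + self.n_fn != self.n_gt:
            raise ValueError("count identity N_tp + N_fn = N_gt violated")
        if self.n_tp + self.n_fp != self.n_s:
            raise ValueError("count identity N_tp + N_fp = N_s violated")


def rates(
    n_tp: int, n_fn: int, n_fp: int, n_gt: int, n_s: int
) -> Tuple[float, float]:
    """True-positive and false-positive rates from the raw counts.

    R_tp = N_tp / N_gt and R_fp = N_fp / N_s.  Zero denominators yield a rate
    of 0 with a warning; violated count identities also warn (some published
    rows are internally inconsistent and are handled upstream).
    """
    if n_tp + n_fn != n_gt or n_tp + n_fp != n_s:
        warnings.warn(
            f"count identities violated: tp={n_tp} fn={n_fn} fp={n_fp} "
            f"gt={n_gt} s={n_s}",
            stacklevel=2,
        )
    if n_gt > 0:
        r_tp = n_tp / n_gt
    else:
        warnings.warn("N_gt = 0; defining R_tp = 0", stacklevel=2)
        r_tp = 0.0
    if n_s > 0:
        r_fp = n_fp / n_s
    else:
        if n_fp:
            warnings.warn("N_s = 0; defining R_fp = 0", stacklevel=2)
        r_fp = 0.0
    return r_tp, r_fp


def _stratified(tp_gt_ids: Iterable[int], gt: MarkerSet) -> Tuple[float, float]:
    tp_gt_ids = set(tp_gt_ids)
    interior = ~gt.boundary
    n_int = int(interior.sum())
    n_bnd = len(gt) - n_int
    tp_int = sum(1 for i, b in zip(gt.ids, gt.boundary) if not b and int(i) in tp_gt_ids)
    tp_bnd = len(tp_gt_ids) - tp_int
    if n_int > 0:
        r_tpi = tp_int / n_int
    else:
        warnings.warn("interior stratum empty; R_tpi = 0", stacklevel=2)
        r_tpi = 0.0
    if n_bnd > 0:
        r_tpb = tp_bnd / n_bnd
    else:
        warnings.warn("boundary stratum empty; R_tpb = 0", stacklevel=2)
        r_tpb = 0.0
    return r_tpi, r_tpb


def stratified_rates(result: MatchResult, gt: MarkerSet) -> Tuple[float, float]:
    """Interior and boundary true-positive rates of an existing result."""
    return _stratified(result.tp_gt_ids, gt)


def _check_frames(a: MarkerSet, b: MarkerSet) -> None:
    if a.spacing is not None and b.spacing is not None:
        if not np.allclose(a.spacing, b.spacing):
            raise GeometryError(
                f"marker sets declare different coordinate frames: "
                f"{a.spacing} vs {b.spacing}"
            )


def match(
    gt: MarkerSet,
    det: MarkerSet,
    tol: ToleranceSpec,
    metric: str = "normalized",
    order: str = "file",
) -> MatchResult:
    """Greedily match detections to ground-truth markers within a cylinder.

    A detection is eligible for a ground-truth marker iff its lateral
    Euclidean distance is <= r_xy and its axial offset is <= r_z.  Among
    eligible detections the nearest is chosen by the normalized elliptic
    distance sqrt((dxy/r_xy)^2 + (dz/r_z)^2) (``metric="euclidean"`` uses the
    plain 3D distance instead); ties go to the lowest detection id.  Each
    matched detection is removed from further consideration.

    ``order`` is "file" (input order; greedy results can depend on it) or
    "sorted" (canonical lexicographic order by coordinates).
    """
    if metric not in ("normalized", "euclidean"):
        raise ValueError("metric must be 'normalized' or 'euclidean'")
    if order not in ("file", "sorted"):
        raise ValueError("order must be 'file' or 'sorted'")
    _check_frames(gt, det)

    gt_idx = np.arange(len(gt))
    if order == "sorted":
        gt_idx = gt_idx[np.lexsort((gt.xyz[:, 2], gt.xyz[:, 1], gt.xyz[:, 0]))]

    consumed = np.zeros(len(det), dtype=bool)
    matched_det = np.full(len(gt), -1, dtype=np.int64)  # det array index per gt
    for i in gt_idx:
        dxyz = det.xyz - gt.xyz[i]
        dxy = np.hypot(dxyz[:, 0], dxyz[:, 1])
        dz = np.abs(dxyz[:, 2])
        eligible = (~consumed) & (dxy <= tol.r_xy) & (dz <= tol.r_z)
        if not eligible.any():
            continue
        if metric == "normalized":
            dist = np.sqrt((dxy / tol.r_xy) ** 2 + (dz / tol.r_z) ** 2)
        else:
            dist = np.sqrt(dxy**2 + dz**2)
        cand = np.flatnonzero(eligible)
        # nearest; ties broken by lowest detection id
        key = np.lexsort((det.ids[cand], dist[cand]))
        best = cand[key[0]]
        matched_det[i] = best
        consumed[best] = True

    rows = []
    for i in range(len(gt)):
        j = matched_det[i]
        rows.append(
            {
                "gt_id": int(gt.ids[i]),
                "det_id": str(int(det.ids[j])) if j >= 0 else pd.NA,
                "class": "TP" if j >= 0 else "FN",
            }
        )
    fp_mask = ~consumed
    for j in np.flatnonzero(fp_mask):
        rows.append({"gt_id": pd.NA, "det_id": str(int(det.ids[j])), "class": "FP"})
    assignments = pd.DataFrame(rows, columns=["gt_id", "det_id", "class"])

    n_tp = int((matched_det >= 0).sum())
    n_gt = len(gt)
    n_s = len(det)
    n_fp = int(fp_mask.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_tp, r_fp = rates(n_tp, n_gt - n_tp, n_fp, n_gt, n_s)
        tp_ids = frozenset(int(gt.ids[i]) for i in np.flatnonzero(matched_det >= 0))
        r_tpi, r_tpb = _stratified(tp_ids, gt)
    return MatchResult(
        assignments=assignments,
        n_gt=n_gt,
        n_gti=gt.n_interior,
        n_s=n_s,
        n_tp=n_tp,
        n_fn=n_gt - n_tp,
        n_fp=n_fp,
        r_tp=r_tp,
        r_tpi=r_tpi,
        r_tpb=r_tpb,
        r_fp=r_fp,
        tp_gt_ids=tp_ids,
        fp_xyz=det.xyz[fp_mask].copy(),
        fp_ids=tuple(str(int(i)) for i in det.ids[fp_mask]),
    )


def _cylinder_pairs(
    xyz_a: np.ndarray, xyz_b: np.ndarray, tol: ToleranceSpec
) -> List[Tuple[int, int]]:
    """Greedy nearest pairing of two point sets under the cylinder rule."""
    used_b = np.zeros(len(xyz_b), dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for i in range(len(xyz_a)):
        d = xyz_b - xyz_a[i]
        dxy = np.hypot(d[:, 0], d[:, 1])
        dz = np.abs(d[:, 2])
        eligible = (~used_b) & (dxy <= tol.r_xy) & (dz <= tol.r_z)
        if not eligible.any():
            continue
        ndist = np.sqrt((dxy / tol.r_xy) ** 2 + (dz / tol.r_z) ** 2)
        cand = np.flatnonzero(eligible)
        j = cand[np.argmin(ndist[cand])]
        used_b[j] = True
        pairs.append((i, j))
    return pairs


def _check_same_gt(a: MatchResult, b: MatchResult, gt: MarkerSet) -> None:
    gt_ids = sorted(int(i) for i in gt.ids)
    for res in (a, b):
        ids = sorted(
            int(v) for v in res.assignments.loc[res.assignments["class"] != "FP", "gt_id"]
        )
        if ids != gt_ids:
            raise ValueError("results were not evaluated against the same ground truth")


def _combined_result(
    tp_ids: FrozenSet[int],
    fp_xyz: np.ndarray,
    fp_ids: Tuple[str, ...],
    gt: MarkerSet,
) -> MatchResult:
    n_tp = len(tp_ids)
    n_gt = len(gt)
    n_fp = len(fp_xyz)
    n_s = n_tp + n_fp  # combined N_s defined to preserve the count identity
    rows = [
        {
            "gt_id": int(i),
            "det_id": "combined" if int(i) in tp_ids else pd.NA,
            "class": "TP" if int(i) in tp_ids else "FN",
        }
        for i in gt.ids
    ]
    rows += [{"gt_id": pd.NA, "det_id": d, "class": "FP"} for d in fp_ids]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_tp, r_fp = rates(n_tp, n_gt - n_tp, n_fp, n_gt, n_s)
        r_tpi, r_tpb = _stratified(tp_ids, gt)
    return MatchResult(
        assignments=pd.DataFrame(rows, columns=["gt_id", "det_id", "class"]),
        n_gt=n_gt,
        n_gti=gt.n_interior,
        n_s=n_s,
        n_tp=n_tp,
        n_fn=n_gt - n_tp,
        n_fp=n_fp,
        r_tp=r_tp,
        r_tpi=r_tpi,
        r_tpb=r_tpb,
        r_fp=r_fp,
        tp_gt_ids=tp_ids,
        fp_xyz=np.asarray(fp_xyz, dtype=float).reshape(-1, 3),
        fp_ids=tuple(fp_ids),
    )


def combine_union(
    a: MatchResult,
    b: MatchResult,
    gt: MarkerSet,
    tol: ToleranceSpec,
    dedup: bool = True,
) -> MatchResult:
    """Result of running two detectors simultaneously (union of detections).

    A ground-truth marker is a TP iff it is a TP in either result.  The
    false-positive pool is the two FP sets together; with ``dedup`` (default)
    mutually-close FPs (within the cylinder tolerance, greedy nearest
    pairing) are merged and count once.
    """
    _check_same_gt(a, b, gt)
    tp_ids = frozenset(a.tp_gt_ids | b.tp_gt_ids)
    if dedup and len(a.fp_xyz) and len(b.fp_xyz):
        pairs = _cylinder_pairs(a.fp_xyz, b.fp_xyz, tol)
        paired_b = {j for _, j in pairs}
        fp_xyz = np.vstack(
            [a.fp_xyz, b.fp_xyz[[j for j in range(len(b.fp_xyz)) if j not in paired_b]]]
        )
        fp_ids = tuple(f"a:{i}" for i in a.fp_ids) + tuple(
            f"b:{b.fp_ids[j]}" for j in range(len(b.fp_ids)) if j not in paired_b
        )
    else:
        fp_xyz = (
            np.vstack([a.fp_xyz, b.fp_xyz])
            if len(a.fp_xyz) or len(b.fp_xyz)
            else np.zeros((0, 3))
        )
        fp_ids = tuple(f"a:{i}" for i in a.fp_ids) + tuple(f"b:{i}" for i in b.fp_ids)
    return _combined_result(tp_ids, fp_xyz, fp_ids, gt)


def combine_intersection(
    a: MatchResult,
    b: MatchResult,
    gt: MarkerSet,
    tol: ToleranceSpec,
) -> MatchResult:
    """Result of requiring both detectors to find an object.

    A ground-truth marker is a TP iff it is a TP in both results; a
    false-positive is a mutually-close pair (one from each result, within the
    cylinder tolerance, greedy nearest pairing), counted once per pair.
    """
    _check_same_gt(a, b, gt)
    tp_ids = frozenset(a.tp_gt_ids & b.tp_gt_ids)
    if len(a.fp_xyz) and len(b.fp_xyz):
        pairs = _cylinder_pairs(a.fp_xyz, b.fp_xyz, tol)
        fp_xyz = np.array([(a.fp_xyz[i] + b.fp_xyz[j]) / 2 for i, j in pairs]).reshape(
            -1, 3
        )
        fp_ids = tuple(f"a:{a.fp_ids[i]}&b:{b.fp_ids[j]}" for i, j in pairs)
    else:
        fp_xyz = np.zeros((0, 3))
        fp_ids = ()
    return _combined_result(tp_ids, fp_xyz, fp_ids, gt)
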