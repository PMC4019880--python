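"""Evaluation core: greedy cylindrical matching, rates, combination."""

import warnings

import numpy as np
import pytest

import stereobench as sb
from conftest import perturbed_detector, random_markers
from oracles import optimal_match_count

TOL = sb.ToleranceSpec(3.0, 1.5)


def markers(points, boundary=None, ids=None):
    return sb.MarkerSet.from_arrays(np.asarray(points, dtype=float),
                                    boundary=boundary, ids=ids)


class TestMatch:
    def test_no_detections_all_false_negative(self):
        gt = markers(np.random.default_rng(0).uniform(0, 30, (7, 3)))
        res = sb.match(gt, sb.MarkerSet.empty(), TOL)
        assert (res.n_tp, res.n_fn, res.n_fp) == (0, 7, 0)
        assert res.r_tp == 0.0

    def test_identical_sets_match_perfectly(self):
        gt = markers(np.random.default_rng(1).uniform(0, 30, (9, 3)))
        res = sb.match(gt, markers(gt.xyz), TOL)
        assert res.r_tp == 1.0 and res.r_fp == 0.0
        assert res.n_tp == 9

    def test_cylinder_membership(self):
        gt = markers([[10, 10, 5]])
        inside = markers([[10 + 2.9, 10, 5 + 1.4]])
        outside = markers([[10 + 3.1, 10, 5]])
        assert sb.match(gt, inside, TOL).n_tp == 1
        assert sb.match(gt, outside, TOL).n_tp == 0

    def test_axial_overflow_rejected_despite_small_lateral_distance(self):
        gt = markers([[10, 10, 5]])
        det = markers([[10, 10, 5 + 1.6]])
        assert sb.match(gt, det, TOL).n_tp == 0

    def test_shared_detection_consumed_once_in_either_order(self):
        det = markers([[12, 10, 5]])
        for order in ([[10, 10, 5], [14, 10, 5]], [[14, 10, 5], [10, 10, 5]]):
            res = sb.match(markers(order), det, TOL)
            assert (res.n_tp, res.n_fn, res.n_fp) == (1, 1, 0)

    def test_nearest_by_normalized_distance(self):
        # detection A: dxy=2.0, dz=0 -> 2/3; detection B: dxy=0, dz=1.2 -> 0.8
        gt = markers([[10, 10, 5]])
        det = markers([[12.0, 10, 5], [10, 10, 6.2]], ids=[1, 2])
        res = sb.match(gt, det, TOL)
        assert res.assignments.iloc[0]["det_id"] == "1"
        # plain euclidean picks B (1.2 < 2.0)
        res2 = sb.match(gt, det, TOL, metric="euclidean")
        assert res2.assignments.iloc[0]["det_id"] == "2"

    def test_equidistant_tie_goes_to_lowest_id(self):
        gt = markers([[10, 10, 5]])
        det = markers([[12, 10, 5], [8, 10, 5]], ids=[7, 3])
        res = sb.match(gt, det, TOL)
        assert res.assignments.iloc[0]["det_id"] == "3"

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        gt = random_markers(rng, 30)
        det = perturbed_detector(gt, rng)
        base = sb.match(gt, det, TOL)
        shifted = sb.match(gt.translated([5, -3, 2]), det.translated([5, -3, 2]), TOL)
        assert (base.n_tp, base.n_fp) == (shifted.n_tp, shifted.n_fp)

    def test_shrinking_tolerance_never_gains_matches(self):
        rng = np.random.default_rng(3)
        gt = random_markers(rng, 40)
        det = perturbed_detector(gt, rng, jitter_xy=1.5, jitter_z=0.8)
        tps = [
            sb.match(gt, det, sb.ToleranceSpec(rxy, rz)).n_tp
            for rxy, rz in [(4.0, 2.0), (3.0, 1.5), (2.0, 1.0), (1.0, 0.5)]
        ]
        assert all(a >= b for a, b in zip(tps, tps[1:]))

    def test_count_identities_always_hold(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            gt = random_markers(rng, int(rng.integers(0, 50)))
            det = perturbed_detector(gt, rng, n_spurious=int(rng.integers(0, 10)))
            res = sb.match(gt, det, TOL)
            assert res.n_tp + res.n_fn == res.n_gt
            assert res.n_tp + res.n_fp == res.n_s

    def test_greedy_bounded_by_optimal_assignment(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            gt = random_markers(rng, int(rng.integers(5, 60)))
            det = perturbed_detector(gt, rng, jitter_xy=2.0, jitter_z=1.0,
                                     n_spurious=8)
            res = sb.match(gt, det, TOL)
            assert res.n_tp <= optimal_match_count(gt.xyz, det.xyz, TOL.r_xy, TOL.r_z)

    def test_mismatched_coordinate_frames_rejected(self):
        gt = sb.MarkerSet.from_arrays([[1, 1, 1]], spacing=(0.1, 0.1, 0.5))
        det = sb.MarkerSet.from_arrays([[1, 1, 1]], spacing=(0.46, 0.46, 1.0))
        with pytest.raises(sb.GeometryError):
            sb.match(gt, det, TOL)

    def test_sorted_order_is_canonical(self):
        rng = np.random.default_rng(6)
        gt = random_markers(rng, 25)
        det = perturbed_detector(gt, rng)
        perm = rng.permutation(len(gt))
        gt_perm = sb.MarkerSet(ids=gt.ids[perm], xyz=gt.xyz[perm],
                               boundary=gt.boundary[perm])
        a = sb.match(gt, det, TOL, order="sorted")
        b = sb.match(gt_perm, det, TOL, order="sorted")
        assert a.n_tp == b.n_tp and a.tp_gt_ids == b.tp_gt_ids


class TestRates:
    @pytest.mark.parametrize(
        "n_tp,n_fn,n_fp,n_gt,n_s,r_tp_2dp,r_fp_2dp",
        [
            (153, 2, 1191, 155, 1344, "0.99", "0.89"),
            (133, 22, 5, 155, 138, "0.86", "0.04"),
            (56, 4, 13, 60, 69, "0.93", "0.19"),
            (22, 36, 98, 58, 120, "0.38", "0.82"),
        ],
    )
    def test_published_count_arithmetic(self, n_tp, n_fn, n_fp, n_gt, n_s,
                                        r_tp_2dp, r_fp_2dp):
        r_tp, r_fp = sb.rates(n_tp, n_fn, n_fp, n_gt, n_s)
        assert sb.format_rate(r_tp) == r_tp_2dp
        assert sb.format_rate(r_fp) == r_fp_2dp

    def test_three_decimal_rendering(self):
        _, r_fp = sb.rates(133, 22, 5, 155, 138)
        assert sb.format_rate(r_fp, 3) == "0.036"

    def test_zero_ground_truth_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            r_tp, r_fp = sb.rates(0, 0, 0, 0, 0)
        assert (r_tp, r_fp) == (0.0, 0.0)

    def test_identity_violation_warns(self):
        with pytest.warns(UserWarning):
            sb.rates(54, 95, 36, 155, 96)


class TestStratifiedRates:
    def test_interior_perfect_boundary_partial(self):
        # 155 ground truth, 56 interior all matched, 97 of 99 boundary matched
        n_bnd, n_int = 99, 56
        xyz = np.column_stack([np.linspace(0, 1540, 155), np.zeros(155), np.zeros(155)])
        boundary = np.array([True] * n_bnd + [False] * n_int)
        gt = markers(xyz, boundary=boundary)
        matched = list(range(2, n_bnd)) + list(range(n_bnd, 155))
        det = markers(xyz[matched])
        res = sb.match(gt, det, TOL)
        assert (res.n_tp, res.n_gt, res.n_gti) == (153, 155, 56)
        assert sb.format_rate(res.r_tpi) == "1.00"
        assert sb.format_rate(res.r_tpb) == "0.98"

    def test_all_interior_collapses_to_overall_rate(self):
        gt = markers(np.random.default_rng(7).uniform(0, 99, (10, 3)))
        det = markers(gt.xyz[:6])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sb.match(gt, det, TOL)
        assert res.r_tpi == res.r_tp

    def test_opposite_strata(self):
        gt = markers([[0, 0, 0], [50, 0, 0]], boundary=[False, True])
        det = markers([[50, 0, 0]])
        res = sb.match(gt, det, TOL)
        assert (res.r_tpi, res.r_tpb) == (0.0, 1.0)


class TestCombination:
    def _two_results(self, seed, n=40):
        rng = np.random.default_rng(seed)
        gt = random_markers(rng, n)
        det_a = perturbed_detector(gt, rng, miss_rate=0.25, n_spurious=6)
        det_b = perturbed_detector(gt, rng, miss_rate=0.25, n_spurious=6)
        res_a = sb.match(gt, det_a, TOL)
        res_b = sb.match(gt, det_b, TOL)
        return gt, res_a, res_b

    def test_union_with_itself_is_identity(self):
        gt, res_a, _ = self._two_results(8)
        union = sb.combine_union(res_a, res_a, gt, TOL)
        assert (union.n_tp, union.n_fp, union.n_s) == (res_a.n_tp, res_a.n_fp, res_a.n_s)

    def test_intersection_with_itself_is_identity(self):
        gt, res_a, _ = self._two_results(9)
        inter = sb.combine_intersection(res_a, res_a, gt, TOL)
        assert (inter.n_tp, inter.n_fp) == (res_a.n_tp, res_a.n_fp)

    def test_union_true_positives_are_set_union(self):
        gt = markers([[0, 0, 0], [20, 0, 0], [40, 0, 0]])
        res_a = sb.match(gt, markers([[0, 0, 0], [20, 0, 0]]), TOL)
        res_b = sb.match(gt, markers([[20, 0, 0], [40, 0, 0]]), TOL)
        union = sb.combine_union(res_a, res_b, gt, TOL)
        assert union.tp_gt_ids == {1, 2, 3}
        assert union.n_tp == 3

    def test_intersection_of_disjoint_results_is_empty(self):
        gt = markers([[0, 0, 0], [20, 0, 0]])
        res_a = sb.match(gt, markers([[0, 0, 0]]), TOL)
        res_b = sb.match(gt, markers([[20, 0, 0]]), TOL)
        inter = sb.combine_intersection(res_a, res_b, gt, TOL)
        assert inter.n_tp == 0

    def test_union_improves_tp_and_worsens_fp(self):
        for seed in range(20):
            gt, res_a, res_b = self._two_results(100 + seed)
            union = sb.combine_union(res_a, res_b, gt, TOL)
            assert union.r_tp >= max(res_a.r_tp, res_b.r_tp)
            assert union.n_fp >= max(res_a.n_fp, res_b.n_fp)
            assert union.n_tp + union.n_fn == union.n_gt
            assert union.n_tp + union.n_fp == union.n_s

    def test_intersection_lowers_tp(self):
        for seed in range(20):
            gt, res_a, res_b = self._two_results(200 + seed)
            inter = sb.combine_intersection(res_a, res_b, gt, TOL)
            assert inter.r_tp <= min(res_a.r_tp, res_b.r_tp)
            assert inter.n_fp <= min(res_a.n_fp, res_b.n_fp)

    def test_union_without_dedup_pools_all_false_positives(self):
        gt, res_a, res_b = self._two_results(10)
        pooled = sb.combine_union(res_a, res_b, gt, TOL, dedup=False)
        assert pooled.n_fp == res_a.n_fp + res_b.n_fp

    def test_differing_ground_truth_rejected(self):
        gt1, res_a, _ = self._two_results(11)
        gt2, res_c, _ = self._two_results(12, n=30)
        with pytest.raises(ValueError):
            sb.combine_union(res_a, res_c, gt1, TOL)

    def test_default_tolerances_per_condition(self):
        assert sb.default_tolerance("3B") == sb.ToleranceSpec(3.0, 2.0)
        for name in ("3A", "3C", "3D"):
            assert sb.default_tolerance(name) == sb.ToleranceSpec(3.0, 1.5)
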