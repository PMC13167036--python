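"""Prediction dialect normalization, anchor conversions, postprocessing."""

import json

import numpy as np
import pytest

from filasim.dataset_io import InstanceMaskStack
from filasim.predictions import (AnchorChain, GtThresholds, PredictionSet,
                                 anchor_length, anchors_to_mask_lines,
                                 anchors_to_mask_spline, compute_gt_thresholds,
                                 normalize_predictions, preprocess_image,
                                 read_anchor_csv, read_anchor_json,
                                 unified_postprocess)
from filasim.rendering import rasterize_polyline
from filasim.geometry import Polyline
from filasim.seg_metrics import skeletonize


def bar(shape, r0, r1, c0, c1):
    m = np.zeros(shape, bool)
    m[r0:r1, c0:c1] = True
    return m


class TestAnchorChain:
    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            AnchorChain(np.array([[1.0, 2.0]]))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            AnchorChain(np.array([[0.0, 0.0], [np.inf, 1.0]]))

    def test_all_duplicate_chain_errors_on_conversion(self):
        chain = AnchorChain(np.array([[3.0, 3.0], [3.0, 3.0], [3.0, 3.0]]))
        with pytest.raises(ValueError, match="single point"):
            anchors_to_mask_spline(chain, 10, 10)

    def test_three_four_five_triangle_length(self):
        assert anchor_length(AnchorChain(np.array([[0.0, 0.0], [3.0, 4.0]]))) == 5.0

    def test_length_matches_pairwise_oracle(self, rng):
        pts = rng.uniform(0, 50, size=(7, 2))
        oracle = sum(float(np.linalg.norm(pts[i + 1] - pts[i])) for i in range(6))
        assert anchor_length(AnchorChain(pts)) == pytest.approx(oracle, abs=1e-12)


class TestAnchorConversion:
    def test_two_anchor_chain_spline_equals_lines(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            chain = AnchorChain(r.uniform(1, 30, (2, 2)))
            a = anchors_to_mask_spline(chain, 32, 32)
            b = anchors_to_mask_lines(chain, 32, 32)
            assert np.array_equal(a, b)

    def test_collinear_anchors_stay_within_half_pixel_of_line(self):
        chain = AnchorChain(np.array([[2.0, 2.0], [10.0, 6.0], [18.0, 10.0],
                                      [26.0, 14.0]]))
        mask = anchors_to_mask_spline(chain, 32, 32)
        p0, p1 = np.array([2.0, 2.0]), np.array([26.0, 14.0])
        d = p1 - p0
        for r, c in zip(*np.nonzero(mask)):
            p = np.array([c, r], float)
            dist = abs(d[0] * (p - p0)[1] - d[1] * (p - p0)[0]) / np.linalg.norm(d)
            assert dist <= 0.5 + 1e-9

    def test_l_shape_lines_equals_union_of_segment_oracles(self):
        chain = AnchorChain(np.array([[2.0, 2.0], [2.0, 12.0], [12.0, 12.0]]))
        mask = anchors_to_mask_lines(chain, 16, 16)
        seg1 = rasterize_polyline(Polyline(np.array([[2.0, 2.0], [2.0, 12.0]])), 16, 16)
        seg2 = rasterize_polyline(Polyline(np.array([[2.0, 12.0], [12.0, 12.0]])), 16, 16)
        assert np.array_equal(mask, seg1 | seg2)

    def test_closed_loop_chain_allowed(self):
        chain = AnchorChain(np.array([[2.0, 2.0], [12.0, 2.0], [12.0, 12.0],
                                      [2.0, 12.0], [2.0, 2.0]]))
        mask = anchors_to_mask_lines(chain, 16, 16)
        assert mask.sum() > 0

    def test_random_in_bounds_chains_give_nonempty_in_canvas_masks(self, rng):
        for _ in range(20):
            chain = AnchorChain(rng.uniform(2, 29, (rng.integers(2, 7), 2)))
            mask = anchors_to_mask_spline(chain, 32, 32)
            assert mask.sum() > 0


class TestNormalize:
    def test_stack_passes_through_identically(self):
        stack = InstanceMaskStack([bar((8, 8), 1, 3, 1, 7)], (8, 8))
        ps = PredictionSet(dialect="stack", shape=(8, 8), stack=stack)
        assert normalize_predictions(ps) is stack

    def test_labeled_map_splits_to_slices(self):
        labels = np.zeros((8, 8), int)
        labels[1, 1] = 1
        labels[5, 5] = 2
        ps = PredictionSet(dialect="labels", shape=(8, 8), labels=labels)
        assert len(normalize_predictions(ps)) == 2

    def test_chains_keep_count_and_order(self):
        chains = [AnchorChain(np.array([[1.0, 1.0], [1.0, 6.0]])),
                  AnchorChain(np.array([[5.0, 1.0], [5.0, 6.0]])),
                  AnchorChain(np.array([[1.0, 4.0], [6.0, 4.0]]))]
        ps = PredictionSet(dialect="anchors", shape=(8, 8), chains=chains)
        stack = normalize_predictions(ps)
        assert len(stack) == 3
        assert stack[0][1, 1] and stack[1][1, 5]

    def test_dialect_payload_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PredictionSet(dialect="stack", shape=(8, 8), labels=np.zeros((8, 8)))


class TestThresholdsAndPostprocess:
    def test_single_instance_bounds_before_margin(self):
        m = bar((20, 20), 10, 11, 2, 12)   # 10-px line
        gt = InstanceMaskStack([m], (20, 20))
        th = compute_gt_thresholds(gt, margin=0.0)
        assert th.min_length == th.max_length == 10
        assert th.min_area == th.max_area == 10

    def test_known_lengths_bounds(self):
        masks = [bar((40, 40), 2 + 4 * i, 3 + 4 * i, 0, n) for i, n in
                 enumerate([10, 20, 30])]
        gt = InstanceMaskStack(masks, (40, 40))
        th = compute_gt_thresholds(gt, margin=0.0)
        assert (th.min_length, th.max_length) == (10, 30)

    def test_bounds_match_exhaustive_scan_oracle(self, rng):
        masks = [rng.random((16, 16)) > 0.7 for _ in range(5)]
        masks = [m for m in masks if m.any()]
        gt = InstanceMaskStack(masks, (16, 16))
        th = compute_gt_thresholds(gt, margin=0.0)
        lengths = [skeletonize(m).sum() for m in masks]
        areas = [m.sum() for m in masks]
        assert th.min_length == min(lengths) and th.max_length == max(lengths)
        assert th.min_area == min(areas) and th.max_area == max(areas)

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            compute_gt_thresholds(InstanceMaskStack([], (8, 8)))

    def test_all_within_bounds_unchanged(self):
        masks = [bar((20, 20), 2, 5, 1, 15), bar((20, 20), 10, 13, 1, 15)]
        stack = InstanceMaskStack(masks, (20, 20))
        ps = PredictionSet(dialect="stack", shape=(20, 20), stack=stack)
        th = compute_gt_thresholds(stack, margin=0.1)
        out = unified_postprocess(ps, th)
        assert len(out.stack) == 2

    def test_out_of_bounds_instances_dropped(self):
        keep = [bar((40, 40), 2, 3, 0, 20), bar((40, 40), 6, 7, 0, 22),
                bar((40, 40), 10, 11, 0, 18)]
        tiny = bar((40, 40), 20, 21, 0, 2)        # length 2, too short
        huge = bar((40, 40), 25, 39, 0, 39)       # area way too big
        stack = InstanceMaskStack(keep + [tiny, huge], (40, 40))
        th = GtThresholds(min_length=15, max_length=25, min_area=15, max_area=25)
        out = unified_postprocess(
            PredictionSet(dialect="stack", shape=(40, 40), stack=stack), th)
        assert len(out.stack) == 3

    def test_anchor_dialect_ignores_area(self):
        chain = AnchorChain(np.array([[0.0, 0.0], [20.0, 0.0]]))   # length 20
        ps = PredictionSet(dialect="anchors", shape=(32, 32), chains=[chain])
        th = GtThresholds(min_length=15, max_length=25, min_area=1e6, max_area=2e6)
        out = unified_postprocess(ps, th)
        assert len(out.chains) == 1

    def test_postprocess_is_idempotent_subset(self, rng):
        masks = [rng.random((16, 16)) > 0.7 for _ in range(6)]
        stack = InstanceMaskStack([m for m in masks if m.any()], (16, 16))
        ps = PredictionSet(dialect="stack", shape=(16, 16), stack=stack)
        th = GtThresholds(min_length=2, max_length=30, min_area=3, max_area=100)
        once = unified_postprocess(ps, th)
        twice = unified_postprocess(once, th)
        assert len(once.stack) <= len(stack)
        assert len(twice.stack) == len(once.stack)
        for a, b in zip(once.stack, twice.stack):
            assert np.array_equal(a, b)


class TestPreprocess:
    def test_empty_config_is_bit_identical(self, rng):
        img = rng.random((16, 16))
        assert preprocess_image(img, []) is img

    def test_minmax_maps_to_unit_range(self, rng):
        img = rng.uniform(0.2, 0.7, (16, 16))
        out = preprocess_image(img, [{"name": "minmax"}])
        assert out.min() == 0.0 and out.max() == 1.0

    def test_double_inversion_is_identity(self, rng):
        img = rng.random((16, 16))
        out = preprocess_image(img, [{"name": "invert"}, {"name": "invert"}])
        assert np.allclose(out, img)

    def test_to_rgb_replicates_channels(self, rng):
        out = preprocess_image(rng.random((8, 8)), [{"name": "to_rgb"}])
        assert out.shape == (8, 8, 3)
        assert np.array_equal(out[:, :, 0], out[:, :, 2])

    def test_unknown_step_rejected(self, rng):
        with pytest.raises(ValueError, match="mystery"):
            preprocess_image(rng.random((8, 8)), [{"name": "mystery"}])


class TestAnchorFiles:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "chains.csv"
        path.write_text(
            "instance_id,point_index,x,y\n"
            "0,0,1.5,2.5\n0,1,8.0,2.5\n"
            "1,1,9.0,9.0\n1,0,4.0,4.0\n")   # out-of-order points
        chains = read_anchor_csv(path)
        assert len(chains) == 2
        assert np.allclose(chains[1].points, [[4.0, 4.0], [9.0, 9.0]])

    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "chains.json"
        path.write_text(json.dumps([[[1, 2], [3, 4]], [[5, 6], [7, 8], [9, 10]]]))
        chains = read_anchor_json(path)
        assert len(chains) == 2 and len(chains[1].points) == 3
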