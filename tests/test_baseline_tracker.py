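"""Baseline tracker: confidence split, 8-dim Kalman oracle, assignment
optimality against exhaustive permutation search, and track lifecycle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spermtrack.baseline_tracker import (
    BaselineTracker,
    TrackerConfig,
    associate,
    kf8_predict,
    kf8_update,
    split_by_confidence,
    _init_track,
    _measurement_noise,
    _process_noise,
    _F,
    _H8,
)
from spermtrack.core_io import BBox, Detection


def det(frame, left, top, w=10.0, h=10.0, conf=0.9):
    return Detection(frame, BBox(left, top, w, h), conf)


class TestSplitByConfidence:
    def test_definition(self):
        cfg = TrackerConfig(tau_high=0.5, eta_low=0.1)
        dets = [det(1, 0, 0, conf=c) for c in (0.9, 0.3, 0.05)]
        high, low = split_by_confidence(dets, cfg)
        assert [d.confidence for d in high] == [0.9]
        assert [d.confidence for d in low] == [0.3]

    def test_boundary_score_goes_low(self):
        cfg = TrackerConfig(tau_high=0.5, eta_low=0.1)
        high, low = split_by_confidence([det(1, 0, 0, conf=0.5)], cfg)
        assert not high and len(low) == 1

    @given(scores=st.lists(st.floats(0, 1), max_size=30))
    def test_partition_property(self, scores):
        cfg = TrackerConfig()
        dets = [det(1, 0, 0, conf=c) for c in scores]
        high, low = split_by_confidence(dets, cfg)
        dropped = [d for d in dets if d.confidence <= cfg.eta_low]
        assert len(high) + len(low) + len(dropped) == len(dets)


class TestKF8:
    def test_zero_velocity_prediction(self):
        cfg = TrackerConfig()
        t = _init_track(1, det(1, 0, 0), cfg, 1)
        mean_before = t.kf_mean[:4].copy()
        kf8_predict(t, cfg)
        assert np.allclose(t.kf_mean[:4], mean_before)

    def test_constant_velocity_step(self):
        cfg = TrackerConfig()
        t = _init_track(1, det(1, 0, 0), cfg, 1)
        t.kf_mean[4] = 2.0  # xc velocity
        xc = t.kf_mean[0]
        kf8_predict(t, cfg)
        assert t.kf_mean[0] == pytest.approx(xc + 2.0)

    def test_predict_matches_dense_oracle(self, rng):
        cfg = TrackerConfig()
        for _ in range(100):
            t = _init_track(1, det(1, *rng.uniform(0, 500, 2), *rng.uniform(5, 40, 2)), cfg, 1)
            t.kf_mean[4:] = rng.normal(0, 3, 4)
            A = rng.normal(size=(8, 8))
            t.kf_cov = A @ A.T + 0.1 * np.eye(8)
            exp_mean = _F @ t.kf_mean
            exp_cov = _F @ t.kf_cov @ _F.T + _process_noise(float(t.kf_mean[3]), 1.0)
            kf8_predict(t, cfg)
            assert np.allclose(t.kf_mean, exp_mean, atol=1e-12)
            assert np.allclose(t.kf_cov, exp_cov, atol=1e-12)

    def test_update_matches_dense_oracle(self, rng):
        cfg = TrackerConfig()
        for _ in range(100):
            t = _init_track(1, det(1, *rng.uniform(0, 500, 2), *rng.uniform(5, 40, 2)), cfg, 1)
            A = rng.normal(size=(8, 8))
            t.kf_cov = A @ A.T + 0.1 * np.eye(8)
            d = det(2, *rng.uniform(0, 500, 2), *rng.uniform(5, 40, 2))
            z = np.array(d.box.to_cxcywh())
            R = _measurement_noise(float(t.kf_mean[3]), 1.0)
            S = _H8 @ t.kf_cov @ _H8.T + R
            K = t.kf_cov @ _H8.T @ np.linalg.inv(S)
            exp_mean = t.kf_mean + K @ (z - _H8 @ t.kf_mean)
            exp_cov = (np.eye(8) - K @ _H8) @ t.kf_cov
            exp_cov = (exp_cov + exp_cov.T) / 2
            # the tracker floors box size at a tiny positive value
            exp_mean[2] = max(exp_mean[2], 1e-6)
            exp_mean[3] = max(exp_mean[3], 1e-6)
            kf8_update(t, d, cfg, 2)
            assert np.allclose(t.kf_mean, exp_mean, atol=1e-10)
            assert np.allclose(t.kf_cov, exp_cov, atol=1e-10)

    def test_zero_measurement_noise_limit(self):
        cfg = TrackerConfig(measurement_noise_scale=1e-9)
        t = _init_track(1, det(1, 0, 0), cfg, 1)
        target = det(2, 30, 40, 12, 14)
        kf8_update(t, target, cfg, 2)
        assert np.allclose(t.kf_mean[:4], target.box.to_cxcywh(), atol=1e-5)

    def test_zero_prior_covariance_keeps_mean(self):
        cfg = TrackerConfig()
        t = _init_track(1, det(1, 0, 0), cfg, 1)
        t.kf_cov = np.zeros((8, 8))
        before = t.kf_mean.copy()
        kf8_update(t, det(2, 50, 50), cfg, 2)
        assert np.allclose(t.kf_mean, before, atol=1e-12)


def brute_force_min_cost(cost):
    """Minimum summed cost over all maximal injective assignments."""
    n, m = cost.shape
    if n <= m:
        return min(
            sum(cost[i, p[i]] for i in range(n))
            for p in itertools.permutations(range(m), n)
        )
    return min(
        sum(cost[p[j], j] for j in range(m))
        for p in itertools.permutations(range(n), m)
    )


class TestAssociate:
    def _tracks_from_boxes(self, boxes):
        cfg = TrackerConfig()
        out = []
        for i, b in enumerate(boxes):
            t = _init_track(i + 1, Detection(1, b, 0.9), cfg, 1)
            out.append(t)
        return out

    def test_single_pair_above_threshold(self):
        tr = self._tracks_from_boxes([BBox(0, 0, 10, 10)])
        m, ut, ud = associate(tr, [det(1, 1, 1)], 0.3)
        assert m == [(0, 0)] and not ut and not ud

    def test_below_threshold_unmatched(self):
        tr = self._tracks_from_boxes([BBox(0, 0, 10, 10)])
        m, ut, ud = associate(tr, [det(1, 9, 9)], 0.3)
        assert not m and ut == [0] and ud == [0]

    def test_diagonal_optimum(self):
        tr = self._tracks_from_boxes([BBox(0, 0, 10, 10), BBox(100, 100, 10, 10)])
        dets = [det(1, 1, 0), det(1, 101, 100)]
        m, _, _ = associate(tr, dets, 0.1)
        assert m == [(0, 0), (1, 1)]

    def test_empty_inputs(self):
        assert associate([], [], 0.3) == ([], [], [])
        tr = self._tracks_from_boxes([BBox(0, 0, 10, 10)])
        assert associate(tr, [], 0.3) == ([], [0], [])

    def test_optimality_against_brute_force(self, rng):
        """Assignment total cost equals the exhaustive-permutation
        minimum on random instances up to 6x6."""
        from scipy.optimize import linear_sum_assignment

        for _ in range(200):
            n, m = rng.integers(1, 7, 2)
            # random boxes in a small arena so IoUs are non-trivial
            tboxes = [BBox(*rng.uniform(0, 40, 2), *rng.uniform(5, 25, 2)) for _ in range(n)]
            dboxes = [BBox(*rng.uniform(0, 40, 2), *rng.uniform(5, 25, 2)) for _ in range(m)]
            from spermtrack.core_io import iou_matrix

            cost = 1.0 - iou_matrix(tboxes, dboxes)
            rows, cols = linear_sum_assignment(cost)
            total = cost[rows, cols].sum()
            assert total == pytest.approx(brute_force_min_cost(cost), abs=1e-9)


class TestLifecycle:
    def test_single_object_confirmed_after_n_init(self):
        tracker = BaselineTracker(TrackerConfig(n_init=3))
        outputs = {}
        for f in range(1, 6):
            outputs[f] = tracker.step(f, [det(f, 2.0 * f, 0.0)])
        assert outputs[1] == [] and outputs[2] == []
        for f in range(3, 6):
            assert len(outputs[f]) == 1
            assert outputs[f][0][0] == 1

    def test_long_absence_issues_new_id(self):
        cfg = TrackerConfig(n_init=1, max_lost=5)
        tracker = BaselineTracker(cfg)
        ids = set()
        for f in range(1, 4):
            for tid, _ in tracker.step(f, [det(f, 0.0, 0.0)]):
                ids.add(tid)
        for f in range(4, 11):  # gap of 7 > max_lost
            tracker.step(f, [])
        for f in range(11, 14):
            for tid, _ in tracker.step(f, [det(f, 0.0, 0.0)]):
                ids.add(tid)
        assert len(ids) == 2  # the baseline fragments; the EKF layer's job

    def test_ids_strictly_increase_never_reused(self):
        tracker = BaselineTracker(TrackerConfig(n_init=1, max_lost=2))
        seen = []
        rng = np.random.default_rng(0)
        for f in range(1, 40):
            dets = [det(f, float(rng.uniform(0, 300)), float(rng.uniform(0, 300)))
                    for _ in range(rng.integers(0, 4))]
            for tid, _ in tracker.step(f, dets):
                seen.append(tid)
        # each id's occurrences are contiguous in first-seen order and
        # ids grow monotonically by first appearance
        firsts = {}
        for k, tid in enumerate(seen):
            firsts.setdefault(tid, k)
        order = sorted(firsts, key=firsts.get)
        assert order == sorted(order)

    def test_matching_is_partial_bijection(self):
        tracker = BaselineTracker(TrackerConfig(n_init=1))
        for f in range(1, 10):
            out = tracker.step(
                f, [det(f, 0.0 + f, 0.0), det(f, 100.0 + f, 100.0), det(f, 200.0, 200.0 + f)]
            )
            ids = [tid for tid, _ in out]
            assert len(ids) == len(set(ids))

    def test_all_high_confidence_reduces_to_single_stage(self):
        """With every score above tau the low-confidence stage is empty,
        so results equal a tracker run with the second stage disabled."""
        cfg = TrackerConfig()
        dets_by_frame = {
            f: [det(f, 3.0 * f, 0.0, conf=0.95), det(f, 100.0, 3.0 * f, conf=0.8)]
            for f in range(1, 15)
        }
        high, low = split_by_confidence(dets_by_frame[1], cfg)
        assert len(high) == 2 and not low
        a = BaselineTracker(cfg)
        b = BaselineTracker(TrackerConfig(iou_min_second=0.999999))
        for f in range(1, 15):
            out_a = a.step(f, dets_by_frame[f])
            out_b = b.step(f, dets_by_frame[f])
            assert [(tid, bx.left) for tid, bx in out_a] == [(tid, bx.left) for tid, bx in out_b]

    def test_duplicate_tracks_suppressed(self):
        cfg = TrackerConfig(n_init=1, duplicate_iou=0.85)
        tracker = BaselineTracker(cfg)
        # two co-located detections every frame sustain duplicate tracks
        for f in range(1, 6):
            out = tracker.step(f, [det(f, 0.0, 0.0), det(f, 0.2, 0.0)])
        assert len(out) == 1

    def test_out_of_order_frame_rejected(self):
        tracker = BaselineTracker()
        tracker.step(1, [])
        with pytest.raises(ValueError):
            tracker.step(1, [])
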