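"""Relative distance errors, center outlier accounting, report aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinemark import center_report, landmark_report, rd_lumbar, rd_sacrum
from spinemark.metrics import lumbar_normalizers
from spinemark.phantom import LUMBAR_LABELS, VERTEBRA_LABELS


class TestRdLumbar:
    def test_worked_example(self):
        # gt Lt=(10,10), Rt=(30,10), Lb=(10,30) -> h=v=20; pred (13,14)
        assert rd_lumbar((13, 14), (10, 10), h=20, v=20) == pytest.approx(25.0)

    def test_zero_at_exact_prediction(self):
        assert rd_lumbar((5, 5), (5, 5), 10, 10) == 0.0

    def test_scale_invariance(self):
        a = rd_lumbar((13, 14), (10, 10), 20, 20)
        b = rd_lumbar((26, 28), (20, 20), 40, 40)
        assert a == pytest.approx(b)

    def test_zero_edge_rejected(self):
        with pytest.raises(ValueError):
            rd_lumbar((1, 1), (0, 0), 0, 10)


class TestRdSacrum:
    def test_worked_example(self):
        assert rd_sacrum((3, 4), (0, 0), l=50) == pytest.approx(10.0)

    def test_zero_at_exact(self):
        assert rd_sacrum((7, 7), (7, 7), 30) == 0.0

    def test_rotation_invariance(self, rng):
        for _ in range(20):
            gt = rng.uniform(0, 100, 2)
            delta = rng.uniform(-5, 5, 2)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
            assert rd_sacrum(gt + delta, gt, 40) == pytest.approx(
                rd_sacrum(gt + rot @ delta, gt, 40)
            )


@given(
    s=st.floats(0.2, 5.0),
    tx=st.floats(-100, 100),
    ty=st.floats(-100, 100),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_rd_similarity_invariance(s, tx, ty):
    """Scaling pred, gt, and the normalizers together leaves RD unchanged."""
    pred, gt = np.array([13.0, 14.0]), np.array([10.0, 10.0])
    shift = np.array([tx, ty])
    a = rd_lumbar(pred, gt, 20, 25)
    b = rd_lumbar(s * pred + shift, s * gt + shift, s * 20, s * 25)
    assert a == pytest.approx(b, rel=1e-9)
    c = rd_sacrum(pred, gt, 50)
    d = rd_sacrum(s * pred + shift, s * gt + shift, s * 50)
    assert c == pytest.approx(d, rel=1e-9)


def test_lumbar_normalizers_use_incident_edges():
    corners = np.array([[0, 0], [20, 0], [0, 30], [20, 30]], dtype=float)
    norms = lumbar_normalizers(corners)
    assert norms[0] == (20.0, 30.0)  # Lt: top edge, left edge
    assert norms[3] == (20.0, 30.0)  # Rb: bottom edge, right edge


def _fake_annotations(n, rng, spacing=70.0):
    """Simple stacked-box annotations for report tests."""
    gts = []
    for _ in range(n):
        y0 = rng.uniform(80, 120)
        centers = np.stack([np.full(6, 250.0), y0 + spacing * np.arange(6)], axis=1)
        landmarks = {}
        for i, lab in enumerate(LUMBAR_LABELS):
            cx, cy = centers[i]
            landmarks[lab] = np.array(
                [[cx - 40, cy - 20], [cx + 40, cy - 20], [cx - 40, cy + 20], [cx + 40, cy + 20]]
            )
        cx, cy = centers[5]
        landmarks["S1"] = np.array([[cx - 35, cy - 20], [cx + 35, cy - 20]])
        gts.append({"centers": centers, "landmarks": landmarks})
    return gts


class TestCenterReport:
    def test_perfect_predictions(self, rng):
        gts = _fake_annotations(5, rng)
        rep = center_report(
            [g["centers"] for g in gts],
            [g["centers"] for g in gts],
            [g["landmarks"] for g in gts],
        )
        assert rep["outlier_ratio_percent"] == 0.0
        assert rep["all"]["total"][0] == 0.0
        assert rep["inlier"]["total"][0] == 0.0

    def test_crop_missing_a_landmark_is_outlier_regardless_of_distance(self, rng):
        gts = _fake_annotations(4, rng)
        preds = [g["centers"].copy() for g in gts]
        # shift one image's L1 center far enough that its crop misses Lt
        preds[2][0] += np.array([80.0, 0.0])
        rep = center_report(preds, [g["centers"] for g in gts], [g["landmarks"] for g in gts])
        assert rep["n_outliers"] == 1
        assert rep["outlier_ratio_percent"] == pytest.approx(25.0)

    def test_ratio_counting(self, rng):
        gts = _fake_annotations(100, rng)
        preds = [g["centers"].copy() for g in gts]
        for i in (3, 30, 60):
            preds[i][0] += np.array([200.0, 0.0])
        rep = center_report(preds, [g["centers"] for g in gts], [g["landmarks"] for g in gts])
        assert rep["outlier_ratio_percent"] == pytest.approx(3.0)

    def test_inlier_excludes_outlier_distances(self, rng):
        gts = _fake_annotations(3, rng)
        preds = [g["centers"] + np.array([1.0, 0.0]) for g in gts]
        preds[0][0] += np.array([300.0, 0.0])
        rep = center_report(preds, [g["centers"] for g in gts], [g["landmarks"] for g in gts])
        assert rep["inlier"]["total"][0] == pytest.approx(1.0)
        assert rep["all"]["total"][0] > 1.0


class TestLandmarkReport:
    def test_perfect_predictions(self, rng):
        gts = _fake_annotations(3, rng)
        rep = landmark_report([g["landmarks"] for g in gts], [g["landmarks"] for g in gts])
        assert rep.total_rd_mean == 0.0
        assert rep.outlier_ratio == 0.0
        assert rep.accuracy == 100.0

    def test_vertebra_at_25_percent_rd_flagged(self, rng):
        gts = _fake_annotations(1, rng)
        pred = {k: v.copy() for k, v in gts[0]["landmarks"].items()}
        # move all 4 L2 corners by 25% of (h, v) = (80, 40) -> RD = 25*sqrt(2) > 20
        pred["L2"] = pred["L2"] + np.array([20.0, 10.0])
        rep = landmark_report([pred], [gts[0]["landmarks"]])
        assert rep.per_vertebra["L2"]["outlier_ratio"] == 100.0
        assert rep.per_vertebra["L1"]["outlier_ratio"] == 0.0

    def test_aggregate_mean_matches_hand_computation(self, rng):
        gts = _fake_annotations(1, rng)
        gt = gts[0]["landmarks"]
        pred = {k: v.copy() for k, v in gt.items()}
        pred["L1"] = pred["L1"] + np.array([8.0, 0.0])  # h=80 -> rd 10% each corner
        pred["S1"] = pred["S1"] + np.array([0.0, 7.0])  # l=70 -> rd 10% each point
        rep = landmark_report([pred], [gt])
        assert rep.per_vertebra["L1"]["rd_mean"] == pytest.approx(10.0)
        assert rep.per_vertebra["S1"]["rd_mean"] == pytest.approx(10.0)
        # total over 22 landmarks: 4 at 10%, 2 at 10%, 16 at 0
        assert rep.total_rd_mean == pytest.approx((4 * 10 + 2 * 10) / 22)

    def test_missing_label_skipped(self, rng):
        gts = _fake_annotations(2, rng)
        preds = [dict(g["landmarks"]) for g in gts]
        del preds[0]["L3"]
        rep = landmark_report(preds, [g["landmarks"] for g in gts])
        assert rep.per_vertebra["L3"]["n_cases"] == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            landmark_report([], [])
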