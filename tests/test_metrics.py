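import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octeb.metrics import (
    MatchResult,
    acc,
    adjusted_metrics,
    evaluate,
    fom,
    fpr,
    fpr_classical,
    match_adjusted,
    match_exact,
    mld,
    tpr,
)
from octeb.phantom import GroundTruth


def _truth(edge, roi=None):
    edge = np.asarray(edge, dtype=bool)
    roi = np.ones_like(edge) if roi is None else np.asarray(roi, dtype=bool)
    return GroundTruth.from_masks(edge, roi)


def _mask(shape, pixels):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return m


class TestMatchExact:
    def test_perfect_detection(self):
        edge = _mask((10, 10), [(3, c) for c in range(10)])
        m = match_exact(edge, _truth(edge))
        assert m.fp == 0 and m.fn == 0 and m.tp == m.n_ideal == 10
        assert np.all(m.distances == 0)

    def test_empty_detection(self):
        edge = _mask((10, 10), [(3, c) for c in range(10)])
        m = match_exact(np.zeros((10, 10), dtype=bool), _truth(edge))
        assert m.tp == 0 and m.fp == 0 and m.fn == 10

    def test_single_offset_pixel(self):
        truth = _truth(_mask((10, 10), [(5, 5)]))
        m = match_exact(_mask((10, 10), [(5, 8)]), truth)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)
        np.testing.assert_allclose(m.distances, [3.0])

    def test_shape_mismatch(self):
        truth = _truth(np.zeros((5, 5), dtype=bool))
        with pytest.raises(ValueError, match="shape"):
            match_exact(np.zeros((6, 5), dtype=bool), truth)

    def test_detections_outside_roi_ignored(self):
        roi = np.zeros((10, 10), dtype=bool)
        roi[3:7] = True
        truth = _truth(_mask((10, 10), [(4, 4)]), roi)
        det = _mask((10, 10), [(4, 4), (0, 0), (9, 9)])
        m = match_exact(det, truth)
        assert m.n_actual == 1 and m.tp == 1 and m.fp == 0


class TestRates:
    def test_perfect(self):
        edge = _mask((8, 8), [(2, c) for c in range(8)])
        m = match_exact(edge, _truth(edge))
        assert tpr(m) == 1.0 and fpr(m) == 0.0 and acc(m) == 1.0

    def test_tpr_ratio(self):
        m = MatchResult(tp=41, fp=0, tn=0, fn=59, n_roi=100, n_ideal=100,
                        n_actual=41, distances=np.zeros(41))
        assert tpr(m) == pytest.approx(0.41)

    def test_redefined_fpr_uses_detected_count(self):
        m = MatchResult(tp=3, fp=7, tn=80, fn=10, n_roi=100, n_ideal=13,
                        n_actual=10, distances=np.zeros(10))
        assert fpr(m) == pytest.approx(0.7)
        # the classical form divides by N - N_I instead
        assert fpr_classical(m) == pytest.approx(7 / 87)

    def test_fpr_of_empty_detection_is_zero(self):
        m = MatchResult(tp=0, fp=0, tn=90, fn=10, n_roi=100, n_ideal=10,
                        n_actual=0, distances=np.zeros(0))
        assert fpr(m) == 0.0

    def test_no_ground_truth_error(self):
        m = MatchResult(tp=0, fp=0, tn=100, fn=0, n_roi=100, n_ideal=0,
                        n_actual=0, distances=np.zeros(0))
        with pytest.raises(ValueError, match="undefined"):
            tpr(m)


class TestFom:
    def test_perfect_is_one(self):
        edge = _mask((10, 10), [(4, c) for c in range(10)])
        assert fom(match_exact(edge, _truth(edge))) == 1.0

    def test_single_pixel_distance_three(self):
        truth = _truth(_mask((10, 10), [(5, 5)]))
        m = match_exact(_mask((10, 10), [(5, 8)]), truth)
        assert fom(m, alpha=1 / 9) == pytest.approx(0.5)

    def test_far_spurious_half(self):
        # truth: 10 pixels; detection: those 10 plus 10 far-away pixels
        truth_px = [(5, c) for c in range(10)]
        spurious = [(95, c) for c in range(10)]
        truth = _truth(_mask((100, 10), truth_px))
        m = match_exact(_mask((100, 10), truth_px + spurious), truth)
        assert fom(m) == pytest.approx(0.5, abs=1e-2)

    def test_empty_detection_is_zero(self):
        truth = _truth(_mask((10, 10), [(5, 5)]))
        m = match_exact(np.zeros((10, 10), dtype=bool), truth)
        assert fom(m) == 0.0

    def test_negative_alpha_rejected(self):
        truth = _truth(_mask((5, 5), [(2, 2)]))
        with pytest.raises(ValueError):
            fom(match_exact(np.zeros((5, 5), dtype=bool), truth), alpha=-1)


class TestMld:
    def test_perfect_is_zero(self):
        edge = _mask((20, 10), [(8, c) for c in range(10)])
        assert mld(edge, _truth(edge)) == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_uniform_shift_law(self, k):
        edge = _mask((20, 10), [(8, c) for c in range(10)])
        shifted = np.zeros_like(edge)
        shifted[8 + k] = True
        assert mld(shifted, _truth(edge), max_dist=3) == pytest.approx(float(k))

    def test_shift_beyond_window_undefined(self):
        edge = _mask((20, 10), [(8, c) for c in range(10)])
        shifted = np.zeros_like(edge)
        shifted[12] = True
        assert np.isnan(mld(shifted, _truth(edge), max_dist=3))


class TestAdjusted:
    def test_radius_zero_matches_exact(self):
        rng = np.random.default_rng(3)
        det, edge = rng.random((12, 12)) < 0.2, rng.random((12, 12)) < 0.1
        edge[6, 6] = True
        truth = _truth(edge)
        m0 = match_adjusted(det, truth, radius=0)
        me = match_exact(det, truth)
        assert (m0.tp, m0.fp, m0.tn, m0.fn) == (me.tp, me.fp, me.tn, me.fn)

    def test_shift_two_within_radius(self):
        edge = _mask((20, 10), [(8, c) for c in range(10)])
        shifted = np.zeros_like(edge)
        shifted[10] = True
        m = match_adjusted(shifted, _truth(edge), radius=2)
        assert m.tp == m.n_ideal == 10 and m.fp == 0

    def test_shift_three_outside_radius(self):
        edge = _mask((20, 10), [(8, c) for c in range(10)])
        shifted = np.zeros_like(edge)
        shifted[11] = True
        m = match_adjusted(shifted, _truth(edge), radius=2)
        assert m.tp == 0 and m.fp == 10

    def test_adjusted_metric_values(self):
        edge = _mask((20, 10), [(8, c) for c in range(10)])
        shifted = np.zeros_like(edge)
        shifted[10] = True
        truth = _truth(edge)
        fom_adj, tpr_adj, fpr_adj, acc_adj = adjusted_metrics(
            match_adjusted(shifted, truth, radius=2)
        )
        assert tpr_adj == 1.0 and fpr_adj == 0.0
        assert fom_adj == pytest.approx(9 / 13)

    def test_nothing_near_truth(self):
        edge = _mask((30, 10), [(5, c) for c in range(10)])
        det = _mask((30, 10), [(25, c) for c in range(10)])
        m = match_adjusted(det, _truth(edge), radius=2)
        _, tpr_adj, fpr_adj, _ = adjusted_metrics(m)
        assert tpr_adj == 0.0
        assert fpr_adj == pytest.approx(m.n_actual / m.n_ideal)

    def test_perfect_detection_adjusted_equals_exact(self):
        edge = _mask((10, 10), [(4, c) for c in range(10)])
        report = evaluate(edge, _truth(edge))
        assert (report.fom_adj, report.tpr_adj, report.fpr_adj, report.acc_adj) == (1, 1, 0, 1)


class TestAgainstNaiveOracle:
    """The vectorized suite must agree with the brute-force double-loop
    reference on arbitrary small masks (shared definitions, no shared code)."""

    def test_random_masks(self):
        from _naive import naive_metrics, random_mask_pair

        rng = np.random.default_rng(42)
        for _ in range(40):
            det, gt, roi = random_mask_pair(rng)
            expected = naive_metrics(det, gt, roi)
            report = evaluate(det, GroundTruth.from_masks(gt, roi))
            got = report.to_dict()
            for key, val in expected.items():
                assert np.isclose(got[key], val, atol=1e-12, equal_nan=True), key


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_flip_invariance_and_bounds(seed):
    """Metrics are invariant under simultaneous horizontal flips, and the
    universally guaranteed orderings between adjusted and exact metrics hold."""
    from _naive import random_mask_pair

    rng = np.random.default_rng(seed)
    det, gt, roi = random_mask_pair(rng, shape=(12, 12))
    a = evaluate(det, GroundTruth.from_masks(gt, roi))
    b = evaluate(det[:, ::-1], GroundTruth.from_masks(gt[:, ::-1], roi[:, ::-1]))
    for key in ("fom", "tpr", "fpr", "acc", "fom_adj", "tpr_adj", "fpr_adj", "acc_adj", "mld"):
        assert np.isclose(a.to_dict()[key], b.to_dict()[key], atol=1e-12, equal_nan=True), key
    assert 0 <= a.fom <= 1 and 0 <= a.fom_adj <= 1
    assert a.fom_adj >= a.fom - 1e-12
    assert a.tpr_adj >= a.tpr
    assert a.acc_adj >= a.acc
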