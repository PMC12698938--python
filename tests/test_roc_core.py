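"""Curve construction and the weighted/unweighted threshold statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uniroc import (
    EvalDataset,
    InvalidDatasetError,
    build_roc,
    mann_whitney_auc,
    sensitivity_star,
    trapezoidal_auc,
    weighted_auc,
)

from .conftest import brute_se_star, pair_auc, random_dataset


class TestBuildRoc:
    def test_worked_example_is_a_staircase(self, t1):
        curve = build_roc(t1)
        assert len(curve) == 21  # origin + one vertex per unique score
        assert curve.thresholds[0] == np.inf
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        dx = np.diff(curve.fpr)
        dy = np.diff(curve.tpr)
        # no mixed-class ties: every segment is purely horizontal or vertical
        assert np.all((dx == 0) | (dy == 0))
        assert np.all(dx >= 0) and np.all(dy >= 0)

    def test_perfect_separation_vertices(self, toy_perfect):
        curve = build_roc(toy_perfect)
        np.testing.assert_allclose(curve.fpr, [0, 0, 0, 0.5, 1])
        np.testing.assert_allclose(curve.tpr, [0, 0.5, 1, 1, 1])

    def test_tied_scores_collapse_into_diagonal_segment(self, t1_tied):
        curve = build_roc(t1_tied)
        assert len(curve) == 17  # 5 cases share the 0.3 threshold
        dx = np.diff(curve.fpr)
        dy = np.diff(curve.tpr)
        diagonal = (dx > 0) & (dy > 0)
        assert diagonal.sum() == 1
        k = np.flatnonzero(diagonal)[0]
        assert curve.thresholds[k + 1] == 0.3
        # 2 presences and 3 absences are tied at 0.3
        assert dy[k] == pytest.approx(2 / 11)
        assert dx[k] == pytest.approx(3 / 9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(hs=[0.1, 0.2], sp=[1, 1]),                      # no absences
            dict(hs=[0.1, 0.2], sp=[0, 0]),                      # no presences
            dict(hs=[0.1, 0.2], sp=[0, 1], w=[1.0, 0.0]),        # non-positive weight
            dict(hs=[0.1, 1.2], sp=[0, 1]),                      # score out of range
            dict(hs=[0.1, 0.2], sp=[0, 2]),                      # label not binary
            dict(hs=[0.1], sp=[1]),                              # too short
            dict(hs=[0.1, 0.2], sp=[0, 1], w=[1.0]),             # length mismatch
        ],
    )
    def test_invalid_datasets_are_hard_errors(self, kwargs):
        with pytest.raises(InvalidDatasetError):
            EvalDataset(**kwargs)


class TestAuc:
    def test_worked_example_value(self, t1):
        assert round(trapezoidal_auc(build_roc(t1)).estimate, 3) == 0.667
        assert round(mann_whitney_auc(t1).estimate, 3) == 0.667

    def test_perfect_and_degenerate_curves(self, toy_perfect):
        assert trapezoidal_auc(build_roc(toy_perfect)).estimate == 1.0
        flat = EvalDataset([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert trapezoidal_auc(build_roc(flat)).estimate == 0.5

    def test_reversed_labels_complement_auc(self, toy_perfect, t1):
        for data in (toy_perfect, t1):
            flipped = EvalDataset(data.hs, 1 - data.sp)
            a = trapezoidal_auc(build_roc(data)).estimate
            b = trapezoidal_auc(build_roc(flipped)).estimate
            assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_tied_curve_matches_pair_enumeration(self, t1_tied):
        expected = pair_auc(t1_tied.hs, t1_tied.sp)
        assert trapezoidal_auc(build_roc(t1_tied)).estimate == pytest.approx(
            expected, abs=1e-12
        )
        assert mann_whitney_auc(t1_tied).estimate == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_trapezoidal_equals_mann_whitney(self, seed):
        data = random_dataset(np.random.default_rng(seed))
        trap = trapezoidal_auc(build_roc(data)).estimate
        mw = mann_whitney_auc(data).estimate
        assert abs(trap - mw) < 1e-12


class TestWeightedAuc:
    @pytest.mark.parametrize(
        "column, expected",
        [("w.a", 0.667), ("w.b", 0.634), ("w.c", 0.732),
         ("w.d", 0.661), ("w.e", 0.649), ("w.f", 0.649)],
    )
    def test_worked_example_weightings(self, t1, t1_weights, column, expected):
        assert round(weighted_auc(t1.with_weights(t1_weights[column])).estimate, 3) == expected

    def test_downweighting_absences_shifts_wauc_directionally(self, t1, t1_weights):
        auc = trapezoidal_auc(build_roc(t1)).estimate
        low_abs = weighted_auc(t1.with_weights(t1_weights["w.b"])).estimate
        high_abs = weighted_auc(t1.with_weights(t1_weights["w.c"])).estimate
        # a discounted low-scored absence hurts, a discounted high-scored one helps
        assert low_abs < auc < high_abs

    def test_class_constant_weights_leave_auc_unchanged(self, t1):
        auc = trapezoidal_auc(build_roc(t1)).estimate
        w = np.where(t1.sp == 1, 3.7, 0.013)
        assert weighted_auc(t1.with_weights(w)).estimate == pytest.approx(auc, abs=1e-12)

    def test_global_rescaling_is_a_no_op(self, t1, t1_weights):
        base = weighted_auc(t1.with_weights(t1_weights["w.e"])).estimate
        scaled = weighted_auc(t1.with_weights(t1_weights["w.e"] * 123.0)).estimate
        assert scaled == pytest.approx(base, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_weighted_pair_enumeration(self, seed):
        data = random_dataset(np.random.default_rng(seed), weighted=True)
        expected = pair_auc(data.hs, data.sp, data.w)
        assert abs(weighted_auc(data).estimate - expected) < 1e-12


class TestSensitivityStar:
    def test_perfect_separation_reaches_one(self, toy_perfect):
        res = sensitivity_star(toy_perfect)
        assert res.estimate == 1.0
        curve = build_roc(toy_perfect)
        k = np.flatnonzero(curve.thresholds == res.threshold)[0]
        assert (curve.fpr[k], curve.tpr[k]) == (0.0, 1.0)

    def test_single_threshold_data_gives_half(self):
        flat = EvalDataset([0.4, 0.4, 0.4], [1, 0, 1])
        assert sensitivity_star(flat).estimate == 0.5

    def test_worked_example_matches_exhaustive_scan(self, t1, t1_weights):
        value, threshold = brute_se_star(t1.hs, t1.sp)
        res = sensitivity_star(t1)
        assert res.estimate == pytest.approx(value, abs=1e-12)
        assert res.threshold == threshold
        wv, _ = brute_se_star(t1.hs, t1.sp, t1_weights["w.b"])
        wres = sensitivity_star(t1.with_weights(t1_weights["w.b"]), weighted=True)
        assert wres.estimate == pytest.approx(wv, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_scan_on_random_data(self, seed):
        data = random_dataset(np.random.default_rng(seed), weighted=True)
        value, _ = brute_se_star(data.hs, data.sp, data.w)
        res = sensitivity_star(data, weighted=True)
        assert res.estimate == pytest.approx(value, abs=1e-12)
        assert 0.0 <= res.estimate <= 1.0
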