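"""Spatially constrained sampling, label extraction and classification metrics."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from shapely.geometry import box

from vigormap import build_report, extract_labels, sample_points
from vigormap.raster import CRS, FieldBoundary, GridTransform
from vigormap.validation import (SamplingError, complete_confusion,
                                 labels_from_confusion, report_to_frame)
from vigormap.vigor import NODATA_LABEL, VigorClassRaster


def rect_47ha():
    # ~47 ha: 686.5 m × 686.5 m
    return FieldBoundary(box(0, 0, 686.5, 686.5), crs=CRS(epsg=2180))


class TestSampling:
    def test_spacing_and_count(self):
        pts = sample_points(rect_47ha(), n=100, min_spacing_m=15.0, seed=45)
        assert pts.shape == (100, 2)
        assert pdist(pts).min() >= 15.0

    def test_deterministic_bit_for_bit(self):
        a = sample_points(rect_47ha(), n=50, min_spacing_m=15.0, seed=45)
        b = sample_points(rect_47ha(), n=50, min_spacing_m=15.0, seed=45)
        np.testing.assert_array_equal(a, b)

    def test_all_points_inside_polygon(self):
        import shapely
        b = rect_47ha()
        pts = sample_points(b, n=60, min_spacing_m=15.0, seed=2)
        assert shapely.contains_xy(b.geometry, pts[:, 0], pts[:, 1]).all()

    def test_two_points_zero_spacing(self):
        pts = sample_points(rect_47ha(), n=2, min_spacing_m=0.0, seed=1)
        assert pts.shape == (2, 2)

    def test_infeasible_spacing_errors_with_achieved_count(self):
        with pytest.raises(SamplingError, match=r"could only place \d+ of 100"):
            sample_points(rect_47ha(), n=100, min_spacing_m=10_000.0, seed=1,
                          max_attempts=20_000)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            sample_points(rect_47ha(), n=0)
        with pytest.raises(ValueError):
            sample_points(rect_47ha(), n=5, min_spacing_m=-1)


class TestExtractLabels:
    def _checkerboard(self, n=10):
        labels = np.add.outer(np.arange(n), np.arange(n)) % 2
        return VigorClassRaster(labels=labels.astype(np.int16),
                                class_mean_composite=np.linspace(1, 0, 5))

    def test_pixel_center_label(self):
        vcr = self._checkerboard()
        t = GridTransform(0.0, 10.0, 1.0, 1.0)
        labels, kept = extract_labels(vcr, t, np.array([[2.5, 6.5]]))  # row 3, col 2
        assert kept.all() and labels[0] == (3 + 2) % 2

    def test_checkerboard_formula(self):
        vcr = self._checkerboard()
        t = GridTransform(0.0, 10.0, 1.0, 1.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.01, 9.99, size=(100, 2))
        labels, kept = extract_labels(vcr, t, pts)
        rows = np.floor(10.0 - pts[:, 1]).astype(int)
        cols = np.floor(pts[:, 0]).astype(int)
        np.testing.assert_array_equal(labels, (rows + cols) % 2)

    def test_nodata_point_excluded_with_warning(self, caplog):
        vcr = self._checkerboard()
        vcr.labels[0, 0] = NODATA_LABEL
        t = GridTransform(0.0, 10.0, 1.0, 1.0)
        with caplog.at_level("WARNING", logger="vigormap.validation"):
            labels, kept = extract_labels(vcr, t, np.array([[0.5, 9.5], [1.5, 9.5]]))
        assert not kept[0] and kept[1]
        assert len(labels) == 1
        assert "excluded" in caplog.text


class TestBuildReport:
    def test_perfect_predictions(self):
        y = np.repeat(np.arange(5), 4)
        rep = build_report(y, y)
        np.testing.assert_array_equal(rep.confusion, np.diag([4] * 5))
        assert rep.overall_accuracy == 1.0
        assert np.all(rep.f1 == 1.0)

    def test_survey_matrix_metrics(self):
        """Published accuracy table: OA 0.81 and the per-class F1 scores."""
        supports = [8, 34, 31, 22, 5]
        diagonal = [7, 28, 29, 14, 3]
        col_sums = [9, 30, 41, 17, 3]
        cm = complete_confusion(diagonal, supports, col_sums)
        assert cm.sum(axis=1).tolist() == supports
        assert cm.sum(axis=0).tolist() == col_sums
        rep = build_report(*labels_from_confusion(cm))
        assert rep.overall_accuracy == pytest.approx(0.81)
        assert rep.f1.round(3).tolist() == [0.824, 0.875, 0.806, 0.718, 0.750]
        assert rep.precision.round(3).tolist() == [0.778, 0.933, 0.707, 0.824, 1.000]
        assert rep.recall.round(3).tolist() == [0.875, 0.824, 0.935, 0.636, 0.600]

    @pytest.mark.parametrize("precision, recall, f1", [
        (0.778, 0.875, 0.824),   # harmonic mean, Very Good row
        (1.000, 0.600, 0.750),   # Very Poor row
    ])
    def test_f1_harmonic_identity(self, precision, recall, f1):
        assert 2 * precision * recall / (precision + recall) == pytest.approx(
            f1, abs=5e-4)

    def test_metric_identities_on_random_labels(self):
        """1000 random label sets: marginals, weighted recall = OA, F1 identity."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = rng.integers(5, 60)
            ref = rng.integers(0, 5, n)
            pred = rng.integers(0, 5, n)
            rep = build_report(ref, pred)
            cm = rep.confusion
            assert cm.sum() == n
            np.testing.assert_array_equal(cm.sum(axis=1), np.bincount(ref, minlength=5))
            np.testing.assert_array_equal(cm.sum(axis=0), np.bincount(pred, minlength=5))
            np.testing.assert_array_equal(cm.sum(axis=1), rep.support)
            assert rep.weighted_avg["recall"] == pytest.approx(rep.overall_accuracy)
            for p, r, f in zip(rep.precision, rep.recall, rep.f1):
                expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
                assert f == pytest.approx(expected)

    def test_absent_class_zero_division_flagged(self):
        ref = np.array([0, 0, 1, 1])
        pred = np.array([0, 0, 1, 1])
        rep = build_report(ref, pred)
        assert rep.precision[4] == 0.0 and rep.recall[4] == 0.0
        assert rep.undefined_precision[4] and rep.undefined_recall[4]
        # macro averages include the zeros
        assert rep.macro_avg["precision"] == pytest.approx(2 / 5)

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="empty"):
            build_report([], [])
        with pytest.raises(ValueError, match="outside"):
            build_report([0, 1], [0, 7])
        with pytest.raises(ValueError, match="equal-length"):
            build_report([0, 1], [0])

    def test_report_frame_has_summary_rows(self):
        y = np.repeat(np.arange(5), 4)
        df = report_to_frame(build_report(y, y))
        assert list(df["class"])[-3:] == ["Overall Accuracy", "Macro Avg",
                                          "Weighted Avg"]


class TestCompleteConfusion:
    def test_infeasible_marginals_rejected(self):
        with pytest.raises(ValueError):
            complete_confusion([5], [3], [5])
        with pytest.raises(ValueError):
            complete_confusion([1, 1], [3, 1], [1, 2])
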