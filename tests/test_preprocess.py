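"""Preprocessing chain: alignment, baseline, exclusion, scaling, glog."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmrfield import (PreprocessConfig, baseline_correct, exclude_regions,
                      glog, glog_inverse, glog_transform, mean_center,
                      preprocess_pipeline, reference_align, segmental_align,
                      total_area_normalize)
from nmrfield.preprocess import _shift_row


def lorentz(ppm, center, hw=0.003, height=1.0):
    return height * hw**2 / ((ppm - center) ** 2 + hw**2)


class TestReferenceAlign:
    def test_offset_apex_moved_to_zero(self, grid_2048, make_spectrum_set):
        ppm = grid_2048.values
        row = lorentz(ppm, 0.02) + lorentz(ppm, 5.0)
        sset = make_spectrum_set([row], ppm)
        out = reference_align(sset)
        win = np.abs(out.ppm) <= 0.25
        apex = out.ppm[np.flatnonzero(win)[np.argmax(out.intensities[0, win])]]
        assert abs(apex - 0.0) <= grid_2048.spacing / 2

    def test_already_aligned_is_identity(self, grid_2048, make_spectrum_set):
        ppm = grid_2048.values
        j = np.argmin(np.abs(ppm))
        row = lorentz(ppm, ppm[j]) + lorentz(ppm, 4.0)
        sset = make_spectrum_set([row], ppm)
        out = reference_align(sset)
        assert out.processing_log[-1]["shifts"] == [0]
        np.testing.assert_array_equal(out.intensities, sset.intensities)

    def test_known_point_offset_restored(self, grid_2048, make_spectrum_set):
        ppm = grid_2048.values
        base = lorentz(ppm, 0.0) + lorentz(ppm, 3.0)
        k = 4
        shifted = _shift_row(base, k)
        out = reference_align(make_spectrum_set([base, shifted], ppm))
        # identical away from the edge-filled k points
        np.testing.assert_allclose(out.intensities[0, k:-k],
                                   out.intensities[1, k:-k], atol=1e-12)

    def test_flat_window_warns_and_keeps_data(self, grid_2048,
                                              make_spectrum_set):
        ppm = grid_2048.values
        row = lorentz(ppm, 5.0)     # nothing near 0 ppm
        row[np.abs(ppm) <= 0.25] = 0.0
        sset = make_spectrum_set([row], ppm)
        with pytest.warns(UserWarning, match="flat TSP"):
            out = reference_align(sset)
        np.testing.assert_array_equal(out.intensities, sset.intensities)


class TestBaselineCorrect:
    def test_zero_baseline_untouched(self, grid_2048, make_spectrum_set):
        # compact-support peaks: a zero baseline must stay zero
        ppm = grid_2048.values
        row = np.exp(-((ppm - 3.0) / 0.004) ** 2) \
            + np.exp(-((ppm - 7.0) / 0.004) ** 2)
        out = baseline_correct(make_spectrum_set([row], ppm))
        assert np.max(np.abs(out.intensities[0] - row)) < 1e-6 * row.max()

    def test_known_curve_removed(self, grid_2048, make_spectrum_set):
        ppm = grid_2048.values
        peaks = lorentz(ppm, 3.0, height=5.0) + lorentz(ppm, 7.0, height=3.0)
        curve = 0.4 * np.cos(2 * np.pi * (ppm - ppm[0]) / 21.0) \
            + 0.2 * np.sin(2 * np.pi * (ppm - ppm[0]) / 10.5)
        out = baseline_correct(make_spectrum_set([peaks + curve], ppm))
        free = (np.abs(ppm - 3.0) > 0.5) & (np.abs(ppm - 7.0) > 0.5)
        resid = out.intensities[0] - peaks
        rms_resid = np.sqrt(np.mean(resid[free] ** 2))
        rms_curve = np.sqrt(np.mean(curve[free] ** 2))
        assert rms_resid < 0.05 * rms_curve

    def test_constant_offset_removed_from_noise(self, grid_2048,
                                                make_spectrum_set):
        """A pure-noise spectrum riding on a large constant offset comes back
        centered near zero; min-based anchors leave at most a small
        noise-scale bias."""
        rng = np.random.default_rng(0)
        sd = 0.02
        row = 50 * sd + rng.normal(0, sd, grid_2048.n_points)
        out = baseline_correct(make_spectrum_set([row], grid_2048.values))
        assert abs(out.intensities[0].mean()) < 2.0 * sd

    def test_bad_knot_spacing_rejected(self, grid_2048, make_spectrum_set):
        sset = make_spectrum_set([np.ones(grid_2048.n_points)],
                                 grid_2048.values)
        with pytest.raises(ValueError):
            baseline_correct(sset, knot_spacing=grid_2048.spacing)
        with pytest.raises(ValueError):
            baseline_correct(sset, knot_spacing=100.0)


class TestExcludeRegions:
    def test_default_removes_water_and_tsp(self, grid_2048,
                                           make_spectrum_set):
        sset = make_spectrum_set([np.ones(grid_2048.n_points)],
                                 grid_2048.values)
        out = exclude_regions(sset)
        assert not np.any((out.ppm >= 4.49) & (out.ppm <= 5.89))
        assert not np.any(out.ppm < 0.14)

    def test_empty_exclusion_is_identity(self, grid_2048, make_spectrum_set):
        sset = make_spectrum_set([np.ones(grid_2048.n_points)],
                                 grid_2048.values)
        out = exclude_regions(sset, PreprocessConfig(exclusion_regions=()))
        assert out.n_points == sset.n_points

    def test_surviving_count_matches_independent_mask(self, grid_2048,
                                                      make_spectrum_set):
        ppm = grid_2048.values
        sset = make_spectrum_set([np.ones(ppm.size)], ppm)
        out = exclude_regions(sset)
        mask = ((ppm >= 4.49) & (ppm <= 5.89)) | (ppm <= 0.14)
        assert out.n_points == ppm.size - int(mask.sum())

    def test_all_columns_excluded_rejected(self, grid_2048,
                                           make_spectrum_set):
        sset = make_spectrum_set([np.ones(grid_2048.n_points)],
                                 grid_2048.values)
        cfg = PreprocessConfig(exclusion_regions=((-np.inf, np.inf),))
        with pytest.raises(ValueError, match="every column"):
            exclude_regions(sset, cfg)


class TestSegmentalAlign:
    def _cohort(self, ppm, n=4):
        base = lorentz(ppm, 1.3) + lorentz(ppm, 3.2) + lorentz(ppm, 8.4)
        return np.tile(base, (n, 1))

    def test_identical_spectra_zero_shifts(self, grid_2048,
                                           make_spectrum_set):
        ppm = grid_2048.values
        out = segmental_align(make_spectrum_set(self._cohort(ppm), ppm))
        for seg in out.processing_log[-1]["segments"]:
            assert all(s == 0 for s in seg["shifts"])

    def test_displacement_recovered(self, grid_2048, make_spectrum_set):
        ppm = grid_2048.values
        rows = self._cohort(ppm, n=5)
        seg_mask = (ppm >= 1.10) & (ppm <= 1.55)
        idx = np.flatnonzero(seg_mask)
        rows[0, idx] = _shift_row(rows[0, idx], 3)
        out = segmental_align(make_spectrum_set(rows, ppm))
        seg_log = next(s for s in out.processing_log[-1]["segments"]
                       if s["segment"] == [1.10, 1.55])
        assert seg_log["shifts"][0] == -3
        np.testing.assert_allclose(out.intensities[0, idx][3:-3],
                                   rows[1, idx][3:-3], atol=1e-9)

    def test_correlation_never_decreases(self, grid_2048, make_spectrum_set):
        rng = np.random.default_rng(1)
        ppm = grid_2048.values
        rows = self._cohort(ppm, n=6)
        rows += rng.normal(0, 0.02, rows.shape)
        sset = make_spectrum_set(rows, ppm)
        target = rows.mean(axis=0)
        out = segmental_align(sset)
        for lo, hi in ((1.10, 1.55), (2.95, 3.50)):
            m = (ppm >= lo) & (ppm <= hi)
            for i in range(rows.shape[0]):
                before = np.corrcoef(rows[i, m], target[m])[0, 1]
                after = np.corrcoef(out.intensities[i, m], target[m])[0, 1]
                assert after >= before - 1e-12

    def test_short_segment_rejected(self, grid_2048, make_spectrum_set):
        ppm = grid_2048.values
        sset = make_spectrum_set(self._cohort(ppm), ppm)
        cfg = PreprocessConfig(
            alignment_segments=((3.0, 3.0 + 1.5 * grid_2048.spacing),))
        with pytest.raises(ValueError, match="shorter than 3"):
            segmental_align(sset, cfg)


class TestNormalizeAndGlog:
    def test_total_area_arithmetic(self, make_spectrum_set):
        sset = make_spectrum_set([[1.0, 2.0, 3.0]], [0.0, 1.0, 2.0])
        out = total_area_normalize(sset)
        np.testing.assert_allclose(out.intensities[0],
                                   [1 / 6, 2 / 6, 3 / 6], atol=1e-15)

    def test_rows_sum_to_one_and_idempotent(self, make_spectrum_set):
        rng = np.random.default_rng(2)
        sset = make_spectrum_set(rng.uniform(0.1, 1, (5, 64)), np.arange(64.0))
        out = total_area_normalize(sset)
        np.testing.assert_allclose(out.intensities.sum(axis=1), 1.0,
                                   atol=1e-12)
        again = total_area_normalize(out)
        np.testing.assert_allclose(again.intensities, out.intensities,
                                   atol=1e-12)

    def test_zero_row_rejected_with_sample_name(self, make_spectrum_set):
        sset = make_spectrum_set([[1.0, 1.0], [0.0, 0.0]], [0.0, 1.0])
        with pytest.raises(ValueError, match="sample1"):
            total_area_normalize(sset)

    def test_glog_value_at_y0(self):
        # g(y0) = ln(sqrt(lambda)/2)
        assert glog(1e-7, y0=1e-7, lam=5e-4) == \
            pytest.approx(np.log(np.sqrt(5e-4) / 2.0), abs=1e-12)
        assert glog(1e-7, y0=1e-7, lam=5e-4) == pytest.approx(-4.4936, abs=5e-4)

    def test_glog_limit_is_natural_log(self):
        assert abs(glog(1.0, y0=0.0, lam=1e-18) - 0.0) < 1e-6
        assert abs(glog(2.5, y0=0.0, lam=1e-18) - np.log(2.5)) < 1e-6

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(-10, 10), st.floats(1e-8, 10))
    def test_glog_strictly_monotone(self, y, dy):
        assert glog(y + dy) > glog(y)

    def test_glog_roundtrip_including_negatives(self):
        y = np.array([-0.5, -1e-4, 0.0, 1e-7, 3e-3, 0.7])
        back = glog_inverse(glog(y))
        np.testing.assert_allclose(back, y, atol=1e-9)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            glog(1.0, lam=0.0)
        with pytest.raises(ValueError):
            glog_inverse(1.0, lam=-1.0)


class TestMeanCenter:
    def test_basic_and_idempotent(self):
        X = np.array([[1.0, 5.0], [3.0, 7.0]])
        Xc, means = mean_center(X)
        np.testing.assert_allclose(Xc[:, 0], [-1.0, 1.0])
        np.testing.assert_allclose(means, [2.0, 6.0])
        Xcc, _ = mean_center(Xc)
        np.testing.assert_allclose(Xcc, Xc, atol=1e-12)
        assert np.abs(Xc.mean(axis=0)).max() < 1e-12

    def test_heldout_uses_training_means(self):
        X = np.array([[0.0, 0.0], [2.0, 4.0]])
        _, means = mean_center(X)
        held = np.array([10.0, 10.0])
        np.testing.assert_allclose(held - means, [9.0, 8.0])

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            mean_center(np.ones((1, 3)))


class TestPipeline:
    def test_order_logged_and_rerun_bit_identical(self, grid_1024):
        from nmrfield import CohortDesign, simulate_cohort
        sset = simulate_cohort(CohortDesign(class_sizes={1: 3, 6: 3}, seed=4),
                               grid=grid_1024)
        a = preprocess_pipeline(sset)
        b = preprocess_pipeline(sset)
        steps = [e["step"] for e in a.processing_log if e["step"] != "simulate"]
        assert steps == ["reference_align", "baseline_correct",
                         "exclude_regions", "segmental_align",
                         "total_area_normalize", "glog_transform"]
        assert np.array_equal(a.intensities, b.intensities)

    def test_normalize_glog_roundtrip_identity(self, make_spectrum_set):
        rng = np.random.default_rng(3)
        sset = make_spectrum_set(rng.uniform(0.05, 1, (4, 128)),
                                 np.arange(128.0))
        norm = total_area_normalize(sset)
        g = glog_transform(norm)
        back = norm.replace(intensities=glog_inverse(g.intensities))
        renorm = total_area_normalize(back)
        np.testing.assert_allclose(renorm.intensities, norm.intensities,
                                   atol=1e-9)
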