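import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import porkfresh as pf
from porkfresh.errors import CalibrationError, DomainError
from porkfresh.preprocess import PreprocessingTag


def _scan(sample, dark=None, white=None):
    sample = np.asarray(sample, float)
    dark = np.zeros_like(sample) if dark is None else np.asarray(dark, float)
    white = (
        np.full_like(sample, 100.0) if white is None else np.asarray(white, float)
    )
    return pf.RawScan(sample, dark, white)


def _dataset(refl, wl=None):
    refl = np.atleast_2d(np.asarray(refl, float))
    wl = np.arange(refl.shape[1], dtype=float) if wl is None else np.asarray(wl, float)
    meta = pd.DataFrame(
        {"day": 1, "replicate": 1, "observation": 1},
        index=pd.Index([f"s{i}" for i in range(refl.shape[0])], name="sample_id"),
    )
    return pf.SpectralDataset(wl, refl, meta)


class TestCalibration:
    def test_sample_equals_white_gives_one(self):
        scan = _scan(np.full((2, 4), 100.0))
        np.testing.assert_allclose(pf.calibrate_reflectance(scan), 1.0)

    def test_sample_equals_dark_gives_zero(self):
        scan = _scan(np.zeros((2, 4)))
        np.testing.assert_allclose(pf.calibrate_reflectance(scan), 0.0)

    def test_midpoint_gives_half(self):
        scan = _scan(np.full((2, 4), 50.0))
        np.testing.assert_allclose(pf.calibrate_reflectance(scan), 0.5)

    def test_white_not_above_dark_names_index(self):
        white = np.full((2, 3), 100.0)
        white[1, 2] = 0.0
        scan = pf.RawScan(np.ones((2, 3)), np.zeros((2, 3)), white)
        with pytest.raises(CalibrationError, match=r"\(1, 2\)"):
            pf.calibrate_reflectance(scan)

    def test_out_of_range_values_warned_not_clipped(self):
        scan = _scan(
            np.array([[170.0, 70.0, 10.0]]),
            dark=np.full((1, 3), 20.0),
            white=np.full((1, 3), 120.0),
        )
        with pytest.warns(UserWarning, match="2 calibrated"):
            refl = pf.calibrate_reflectance(scan)
        np.testing.assert_allclose(refl, [[1.5, 0.5, -0.1]])


class TestTrim:
    def test_boundary_inclusion(self):
        ds = _dataset([[1.0, 2.0, 3.0, 4.0]], wl=[300, 400, 1600, 1700])
        out = pf.trim_wavelengths(ds, 400, 1600)
        np.testing.assert_array_equal(out.wavelengths_nm, [400, 1600])
        np.testing.assert_array_equal(out.reflectance, [[2.0, 3.0]])

    def test_full_range_is_identity(self):
        ds = _dataset(np.random.default_rng(0).random((3, 8)))
        out = pf.trim_wavelengths(
            ds, ds.wavelengths_nm[0], ds.wavelengths_nm[-1]
        )
        np.testing.assert_array_equal(out.reflectance, ds.reflectance)

    def test_640_band_grid_count_matches_membership_oracle(self):
        wl = np.linspace(278, 1724, 640)
        ds = _dataset(np.zeros((1, 640)), wl=wl)
        out = pf.trim_wavelengths(ds, 400, 1600)
        expected = sum(1 for w in wl if 400 <= w <= 1600)
        assert out.n_bands == expected

    def test_empty_range_raises(self):
        ds = _dataset([[1.0, 2.0]], wl=[100, 200])
        with pytest.raises(DomainError):
            pf.trim_wavelengths(ds, 300, 400)
        with pytest.raises(DomainError):
            pf.trim_wavelengths(ds, 200, 100)


class TestRoiMean:
    def test_constant_cube(self):
        cube = np.full((5, 4), 3.25)
        mask = np.array([True, False, True, True, False])
        np.testing.assert_allclose(pf.roi_mean_spectrum(cube, mask), 3.25)

    def test_two_pixel_average(self):
        cube = np.array([[0.0, 0.0], [1.0, 1.0]])
        np.testing.assert_allclose(
            pf.roi_mean_spectrum(cube, np.array([True, True])), 0.5
        )

    def test_matches_loop_oracle(self, rng):
        cube = rng.random((10, 6))
        mask = rng.random(10) > 0.4
        expected = np.array(
            [np.mean([cube[i, b] for i in range(10) if mask[i]])
             for b in range(6)]
        )
        np.testing.assert_allclose(
            pf.roi_mean_spectrum(cube, mask), expected
        )

    def test_empty_mask_raises(self):
        with pytest.raises(DomainError):
            pf.roi_mean_spectrum(np.ones((3, 2)), np.zeros(3, bool))


class TestSnv:
    def test_hand_example(self):
        np.testing.assert_allclose(
            pf.snv(np.array([[1.0, 2.0, 3.0]])), [[-1.0, 0.0, 1.0]]
        )

    def test_idempotent(self, rng):
        x = rng.random((4, 20))
        once = pf.snv(x)
        np.testing.assert_allclose(pf.snv(once), once, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.random((3, 15))
        np.testing.assert_allclose(pf.snv(5 * x + 2), pf.snv(x), atol=1e-10)

    def test_constant_row_identified(self):
        x = np.vstack([np.arange(4.0), np.full(4, 2.0)])
        with pytest.raises(DomainError, match="row 1"):
            pf.snv(x)

    @settings(deadline=None, max_examples=25)
    @given(
        arrays(
            np.float64,
            (3, 12),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_rows_standardized(self, x):
        if np.any(x.std(axis=1, ddof=1) < 1e-9):
            return
        out = pf.snv(x)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)


class TestMsc:
    def test_affine_distortion_inverted(self, rng):
        ref = rng.random(30) + 0.5
        x = 2.0 * ref + 1.0
        np.testing.assert_allclose(pf.msc(x, ref), [ref], atol=1e-10)

    def test_reference_itself_unchanged(self, rng):
        ref = rng.random(30)
        np.testing.assert_allclose(pf.msc(ref, ref), [ref], atol=1e-10)

    def test_refit_oracle_gives_unit_gain_zero_offset(self, rng):
        x = rng.random((6, 40)) + np.linspace(0, 1, 40)
        out = pf.msc(x, "mean")
        ref = x.mean(axis=0)
        ref_c = ref - ref.mean()
        for row in out:
            b = (row - row.mean()) @ ref_c / (ref_c @ ref_c)
            a = row.mean() - b * ref.mean()
            assert b == pytest.approx(1.0, abs=1e-8)
            assert a == pytest.approx(0.0, abs=1e-8)

    def test_distortion_roundtrip(self, rng):
        ref = rng.random(25)
        x = rng.random((4, 25))
        out = pf.msc(x, ref)
        ref_c = ref - ref.mean()
        for xi, oi in zip(x, out):
            b = (xi - xi.mean()) @ ref_c / (ref_c @ ref_c)
            a = xi.mean() - b * ref.mean()
            np.testing.assert_allclose(a + b * oi, xi, atol=1e-9)

    def test_degenerate_gain_flagged(self, rng):
        ref = rng.random(10)
        flat = np.full((1, 10), 3.0)
        with pytest.warns(UserWarning, match="MSC gain"):
            out = pf.msc(flat, ref)
        assert np.all(np.isfinite(out))

    def test_reference_band_mismatch(self, rng):
        with pytest.raises(DomainError):
            pf.msc(rng.random((2, 10)), rng.random(9))


class TestL2Normalize:
    def test_three_four_five(self):
        np.testing.assert_allclose(
            pf.l2_normalize(np.array([[3.0, 4.0]])), [[0.6, 0.8]]
        )

    def test_unit_row_unchanged(self):
        row = np.array([[1.0, 0.0, 0.0]])
        np.testing.assert_allclose(pf.l2_normalize(row), row)

    def test_scale_invariance(self, rng):
        x = rng.random((3, 9)) + 0.1
        np.testing.assert_allclose(
            pf.l2_normalize(7.3 * x), pf.l2_normalize(x), atol=1e-12
        )

    def test_zero_row_raises(self):
        with pytest.raises(DomainError, match="row 0"):
            pf.l2_normalize(np.zeros((1, 4)))

    def test_unit_norm_property(self, rng):
        out = pf.l2_normalize(rng.random((8, 30)) + 0.01)
        np.testing.assert_allclose(
            np.linalg.norm(out, axis=1), 1.0, atol=1e-12
        )


class TestApplyPreprocessing:
    def test_raw_is_identity(self, rng):
        ds = _dataset(rng.random((3, 10)))
        out = pf.apply_preprocessing(ds, "raw")
        np.testing.assert_array_equal(out.reflectance, ds.reflectance)
        assert out.preprocessing.name == "raw"

    def test_snv_dispatch_matches_direct_call(self, rng):
        ds = _dataset(rng.random((3, 10)))
        out = pf.apply_preprocessing(ds, "snv")
        np.testing.assert_allclose(out.reflectance, pf.snv(ds.reflectance))

    def test_msc_prediction_uses_stored_reference(self, rng):
        cal = _dataset(rng.random((6, 12)))
        pred = _dataset(rng.random((4, 12)))
        cal_out = pf.apply_preprocessing(cal, "msc")
        pred_out = pf.apply_preprocessing(pred, cal_out.preprocessing)
        # stored calibration reference, not the prediction-set mean
        expected = pf.msc(pred.reflectance, cal.reflectance.mean(axis=0))
        np.testing.assert_allclose(pred_out.reflectance, expected)
        naive = pf.msc(pred.reflectance, "mean")
        assert not np.allclose(pred_out.reflectance, naive)

    def test_unknown_tag_rejected(self, rng):
        ds = _dataset(rng.random((2, 5)))
        with pytest.raises(Exception, match="savgol"):
            pf.apply_preprocessing(ds, "savgol")

    def test_tag_reference_consistency_enforced(self):
        with pytest.raises(Exception):
            PreprocessingTag("snv", msc_reference=np.ones(3))
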