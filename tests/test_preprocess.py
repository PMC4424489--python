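"""Flat/dark normalisation, outlier repair, monitor scaling, negative log
and the single-distance phase filter."""

import numpy as np
import pytest

import tomopipe as tp
from tomopipe.framework import DataBlock, Space, TomoError
from tomopipe.preprocess import PaganinParams, paganin_transfer


def _block(values, space=Space.DETECTOR):
    values = np.asarray(values, dtype=float)
    angles = np.zeros(values.shape[0])
    return DataBlock(values, space, ("angle", "vertical", "horizontal"), angles)


class TestFlatDark:
    def test_intensity_equal_to_flat_gives_unity(self):
        frames = np.full((2, 4, 4), 500.0)
        out = tp.flat_dark_correct(
            _block(frames), flats=np.full((1, 4, 4), 500.0), darks=np.zeros((1, 4, 4))
        )
        np.testing.assert_allclose(out.values, 1.0)
        assert out.space is Space.PROJECTION

    def test_intensity_equal_to_dark_clamps_to_eps(self):
        frames = np.full((1, 4, 4), 20.0)
        out = tp.flat_dark_correct(
            _block(frames),
            flats=np.full((1, 4, 4), 500.0),
            darks=np.full((1, 4, 4), 20.0),
        )
        np.testing.assert_allclose(out.values, 1e-6)

    def test_noiseless_scan_recovers_exp_of_analytic_sinogram(
        self, shepp, noiseless_scan
    ):
        block, flats, darks, truth = noiseless_scan
        out = tp.flat_dark_correct(block)
        ref = np.exp(
            -tp.analytic_sinogram(shepp, block.angles_deg, 64, truth["det_spacing"])
        )
        np.testing.assert_allclose(out.values[:, 2, :], ref, atol=1e-10)

    def test_degenerate_pixels_repaired_and_counted(self):
        flats = np.full((1, 4, 4), 500.0)
        flats[0, 1, 1] = 0.0  # flat <= dark at this pixel
        frames = np.full((1, 4, 4), 250.0)
        out = tp.flat_dark_correct(
            _block(frames), flats=flats, darks=np.full((1, 4, 4), 10.0)
        )
        assert out.meta["n_degenerate_pixels"] == 1
        assert np.isfinite(out.values).all()
        np.testing.assert_allclose(out.values[0, 1, 1], 0.48979, atol=1e-4)

    def test_all_degenerate_is_an_error(self):
        with pytest.raises(TomoError, match="degenerate"):
            tp.flat_dark_correct(
                _block(np.ones((1, 3, 3))),
                flats=np.zeros((1, 3, 3)),
                darks=np.ones((1, 3, 3)),
            )

    def test_missing_flats_rejected(self):
        with pytest.raises(TomoError, match="flat"):
            tp.flat_dark_correct(_block(np.ones((1, 3, 3))), darks=0.0)


class TestOutlierRemoval:
    def test_constant_frame_untouched(self):
        frames = np.full((1, 8, 8), 3.0)
        out, mask = tp.remove_outlier_pixels(frames)
        np.testing.assert_array_equal(out, frames)
        assert not mask.any()

    def test_single_hot_pixel_flagged_and_replaced_by_median(self):
        frame = np.ones((1, 9, 9))
        frame[0, 4, 4] = 100.0
        out, mask = tp.remove_outlier_pixels(frame)
        assert mask[0, 4, 4]
        assert mask.sum() == 1
        assert out[0, 4, 4] == 1.0

    def test_unflagged_pixels_bit_identical(self):
        rng = np.random.default_rng(0)
        frames = 1000 + 50 * rng.standard_normal((2, 16, 16))
        out, mask = tp.remove_outlier_pixels(frames)
        np.testing.assert_array_equal(out[~mask], frames[~mask])

    def test_seeded_zingers_detected_without_false_positives(self, shepp):
        scan = tp.ScanConfig(
            n_angles=20, n_det=128, n_rows=16, noise_on=False,
            include_final_180=False,
        )
        block, _, _, _ = tp.simulate_scan(shepp, scan)
        art = tp.ArtefactConfig(zinger_rate=1e-4, zinger_amp=10.0)
        corrupted, truth = tp.inject_artefacts(block.values, art, seed=5)
        repaired, mask = tp.remove_outlier_pixels(corrupted)
        zingers = {tuple(p) for p in truth["zinger_pixels"]}
        flagged = {tuple(p) for p in np.argwhere(mask)}
        assert zingers, "fixture must inject at least one zinger"
        assert len(zingers & flagged) / len(zingers) >= 0.99
        assert len(flagged - zingers) / mask.size <= 1e-3

    def test_idempotent_on_own_output(self, shepp):
        scan = tp.ScanConfig(n_angles=8, n_det=64, n_rows=8, noise_on=False)
        block, _, _, _ = tp.simulate_scan(shepp, scan)
        corrupted, _ = tp.inject_artefacts(
            block.values, tp.ArtefactConfig(zinger_rate=5e-4), seed=3
        )
        once, _ = tp.remove_outlier_pixels(corrupted)
        twice, mask2 = tp.remove_outlier_pixels(once)
        np.testing.assert_array_equal(once, twice)

    def test_non_finite_input_rejected(self):
        frames = np.ones((1, 4, 4))
        frames[0, 0, 0] = np.nan
        with pytest.raises(TomoError, match="finite"):
            tp.remove_outlier_pixels(frames)


class TestMonitorNormalize:
    def test_equal_readings_are_identity(self):
        block = _block(np.random.default_rng(0).random((4, 3, 3)), Space.PROJECTION)
        out = tp.monitor_normalize(block, np.full(4, 7.0))
        np.testing.assert_array_equal(out.values, block.values)

    def test_double_reading_halves_frame(self):
        block = _block(np.ones((2, 2, 2)), Space.PROJECTION)
        out = tp.monitor_normalize(block, np.array([1.0, 3.0]))  # mean 2
        np.testing.assert_allclose(out.values[0], 2.0)
        np.testing.assert_allclose(out.values[1], 2.0 / 3.0)

    def test_seeded_drift_equalised(self):
        rng = np.random.default_rng(4)
        monitor = 1.0 + 0.05 * rng.standard_normal(16)
        frames = np.ones((16, 4, 4)) * monitor[:, None, None]
        out = tp.monitor_normalize(_block(frames, Space.PROJECTION), monitor)
        means = out.values.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0], atol=1e-12)

    def test_non_positive_reading_names_frame(self):
        block = _block(np.ones((3, 2, 2)), Space.PROJECTION)
        with pytest.raises(TomoError, match="frame 1"):
            tp.monitor_normalize(block, np.array([1.0, 0.0, 1.0]))


class TestNegLog:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.0, 0.0), (np.exp(-2.0), 2.0), (1e-6, -np.log(1e-6))],
    )
    def test_pointwise_values(self, value, expected):
        block = _block(np.full((1, 2, 2), value), Space.PROJECTION)
        out = tp.neg_log(block)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert np.isfinite(out.values).all()

    def test_non_positive_transmission_rejected(self):
        block = _block(np.zeros((1, 2, 2)), Space.PROJECTION)
        with pytest.raises(TomoError, match="clamp"):
            tp.neg_log(block)

    def test_strictly_decreasing_in_transmission(self):
        t = np.linspace(0.01, 1.0, 50).reshape(1, 5, 10)
        out = tp.neg_log(_block(t, Space.PROJECTION)).values.ravel()
        assert np.all(np.diff(out) < 0)


class TestPaganin:
    def _params(self, **kw):
        defaults = dict(
            delta_beta=100.0, distance_z=50.0, wavelength=0.1, pixel_size=1.0
        )
        defaults.update(kw)
        return PaganinParams(**defaults)

    def test_zero_distance_is_identity(self):
        frames = np.random.default_rng(1).random((2, 16, 16)) + 1
        block = _block(frames, Space.PROJECTION)
        out = tp.paganin_filter(block, self._params(distance_z=0.0))
        np.testing.assert_allclose(out.values, frames, atol=1e-12)

    def test_constant_frame_unchanged(self):
        block = _block(np.full((1, 16, 16), 3.7), Space.PROJECTION)
        out = tp.paganin_filter(block, self._params())
        np.testing.assert_allclose(out.values, 3.7, atol=1e-12)

    def test_sinusoid_amplitude_matches_transfer_function(self):
        n = 64
        u0 = 4.0 / n  # exact FFT-grid frequency, cycles per unit length
        x = np.arange(n)
        frame = 1.0 + 0.1 * np.cos(2 * np.pi * u0 * x)[None, :] * np.ones((n, 1))
        block = _block(frame[None], Space.PROJECTION)
        params = self._params(pad=0)
        out = tp.paganin_filter(block, params).values[0]
        expected_gain = 1.0 / (
            1.0 + np.pi * params.wavelength * params.distance_z
            * params.delta_beta * u0**2
        )
        got = np.ptp(out) / np.ptp(frame)
        assert abs(got - expected_gain) < 1e-6

    def test_mean_preserved_and_no_magnitude_amplified(self):
        rng = np.random.default_rng(2)
        frame = rng.random((32, 32)) + 1
        block = DataBlock(frame, Space.PROJECTION, ("vertical", "horizontal"))
        params = self._params(pad=0)
        out = tp.paganin_filter(block, params).values
        assert abs(out.mean() - frame.mean()) < 1e-10
        mags_in = np.abs(np.fft.fft2(frame))
        mags_out = np.abs(np.fft.fft2(out))
        assert np.all(mags_out <= mags_in + 1e-9)
        assert np.all(paganin_transfer((32, 32), params) <= 1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            self._params(delta_beta=-1.0)
        with pytest.raises(ValueError):
            self._params(distance_z=-5.0)
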