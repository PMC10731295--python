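"""Black/white correction, band cropping, and ROI spectrum extraction."""

import numpy as np
import pytest

import mycospec as ms
from mycospec.calibration import CalibrationError, default_crop


def _cube(data, wl=None):
    data = np.asarray(data, dtype=float)
    wl = np.arange(data.shape[2], dtype=float) + 1 if wl is None else wl
    return ms.RawCube(data, wl)


def _refs(white, dark):
    return ms.ReferencePair(np.asarray(white, float), np.asarray(dark, float))


def test_white_input_gives_unit_transmittance(rng):
    white = rng.uniform(100, 200, (4, 5, 3))
    dark = rng.uniform(0, 10, (4, 5, 3))
    out = ms.calibrate(_cube(white), _refs(white, dark))
    assert np.allclose(out.transmittance, 1.0)


def test_dark_input_gives_zero_transmittance(rng):
    white = rng.uniform(100, 200, (4, 5, 3))
    dark = rng.uniform(0, 10, (4, 5, 3))
    out = ms.calibrate(_cube(dark), _refs(white, dark))
    assert np.allclose(out.transmittance, 0.0)


def test_scalar_cell_value():
    """raw 80, dark 20, white 120 -> (80-20)/(120-20) = 0.6."""
    shape = (1, 1, 1)
    out = ms.calibrate(
        _cube(np.full(shape, 80.0)), _refs(np.full(shape, 120.0), np.full(shape, 20.0))
    )
    assert out.transmittance[0, 0, 0] == pytest.approx(0.6, abs=1e-12)


def test_shape_mismatch_rejected(rng):
    raw = _cube(rng.random((4, 4, 3)))
    with pytest.raises(ValueError, match="shape"):
        ms.calibrate(raw, _refs(np.ones((4, 5, 3)), np.zeros((4, 5, 3))))


def test_degenerate_denominators_flagged_and_counted(rng):
    white = np.ones((4, 4, 2))
    dark = np.zeros((4, 4, 2))
    white[:, :, 0] = 0.0  # half of all cells degenerate
    raw = _cube(rng.random((4, 4, 2)))
    with pytest.raises(CalibrationError, match="16 of 32"):
        ms.calibrate(raw, _refs(white, dark))
    # below the tolerated fraction: degenerate cells are zeroed
    white = np.ones((10, 10, 10))
    white[0, 0, 0] = 0.0
    raw = _cube(np.full((10, 10, 10), 0.5))
    out = ms.calibrate(raw, ms.ReferencePair(white, np.zeros((10, 10, 10))), max_degenerate_frac=0.01)
    assert out.transmittance[0, 0, 0] == 0.0
    assert np.allclose(out.transmittance.ravel()[1:], 0.5)


def test_calibration_monotone_in_raw(rng):
    white = rng.uniform(100, 200, (3, 3, 4))
    dark = rng.uniform(0, 10, (3, 3, 4))
    lo = rng.uniform(20, 80, (3, 3, 4))
    hi = lo + rng.uniform(0, 30, (3, 3, 4))
    r_lo = ms.calibrate(_cube(lo), _refs(white, dark)).transmittance
    r_hi = ms.calibrate(_cube(hi), _refs(white, dark)).transmittance
    assert np.all(r_hi >= r_lo)


def test_clipping_bounds(rng):
    white = np.ones((2, 2, 2))
    dark = np.zeros((2, 2, 2))
    raw = _cube(np.array([[[-1.0, 5.0]] * 2] * 2))
    out = ms.calibrate(raw, _refs(white, dark), clip_max=2.0)
    assert out.transmittance.min() >= 0.0
    assert out.transmittance.max() <= 2.0


class TestCropBands:
    def test_full_window_is_noop(self):
        wl = np.linspace(401, 1046, 360)
        cube = ms.TransmittanceCube(np.zeros((2, 2, 360)), wl)
        out = ms.crop_bands(cube, 401, 1046)
        assert out.shape[2] == 360

    def test_default_crop_keeps_336_bands(self):
        """The analysis window drops the 24 noisy reddest bands of 360."""
        wl = np.linspace(401, 1046, 360)
        cube = ms.TransmittanceCube(np.zeros((2, 2, 360)), wl)
        out = default_crop(cube)
        assert out.shape[2] == 336
        assert out.wavelengths_nm[0] >= 400.0

    def test_empty_window_rejected(self):
        wl = np.linspace(401, 1046, 360)
        cube = ms.TransmittanceCube(np.zeros((2, 2, 360)), wl)
        with pytest.raises(ValueError):
            ms.crop_bands(cube, 500.0, 500.5)

    def test_crop_spectrumset(self, mini_spectra):
        out = ms.crop_bands(mini_spectra, 500, 900)
        assert out.n_samples == mini_spectra.n_samples
        assert np.all((out.wavelengths_nm >= 500) & (out.wavelengths_nm <= 900))


class TestRoiMeanSpectrum:
    def test_single_pixel(self, rng):
        cube = ms.TransmittanceCube(rng.random((4, 4, 5)), np.arange(5.0) + 1)
        mask = np.zeros((4, 4), bool)
        mask[2, 1] = True
        assert np.array_equal(ms.roi_mean_spectrum(cube, mask), cube.transmittance[2, 1])

    def test_uniform_cube(self):
        cube = ms.TransmittanceCube(np.full((3, 3, 4), 0.7), np.arange(4.0) + 1)
        mask = np.ones((3, 3), bool)
        assert np.allclose(ms.roi_mean_spectrum(cube, mask), 0.7)

    def test_two_pixel_hand_mean(self, rng):
        cube = ms.TransmittanceCube(rng.random((2, 2, 6)), np.arange(6.0) + 1)
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = mask[1, 1] = True
        expected = (cube.transmittance[0, 0] + cube.transmittance[1, 1]) / 2
        assert np.allclose(ms.roi_mean_spectrum(cube, mask), expected)

    def test_empty_mask_rejected(self):
        cube = ms.TransmittanceCube(np.zeros((2, 2, 2)), np.arange(2.0) + 1)
        with pytest.raises(ValueError, match="empty"):
            ms.roi_mean_spectrum(cube, np.zeros((2, 2), bool))

    def test_permutation_invariance(self, rng):
        data = rng.random((4, 4, 3))
        wl = np.arange(3.0) + 1
        mask = rng.random((4, 4)) > 0.4
        mask[0, 0] = True
        base = ms.roi_mean_spectrum(ms.TransmittanceCube(data, wl), mask)
        perm = rng.permutation(16).reshape(4, 4)
        shuffled = data.reshape(16, 3)[perm.ravel()].reshape(4, 4, 3)
        shuffled_mask = mask.ravel()[perm.ravel()].reshape(4, 4)
        out = ms.roi_mean_spectrum(ms.TransmittanceCube(shuffled, wl), shuffled_mask)
        assert np.allclose(out, base)


def test_spectrumset_row_and_band_subsets(mini_spectra):
    rows = mini_spectra.subset_rows(np.array([0, 3, 5]))
    assert rows.n_samples == 3
    assert list(rows.labels) == list(mini_spectra.labels[[0, 3, 5]])
    bands = mini_spectra.subset_bands([4, 1])
    assert bands.wavelengths_nm[0] == mini_spectra.wavelengths_nm[4]
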