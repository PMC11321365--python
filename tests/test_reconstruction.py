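import numpy as np
import pytest

from snapcube.formats_io import Hypercube, RawMosaicFrame
from snapcube.reconstruction import (
    CalibrationError,
    CalibrationPair,
    calibrate,
    clip_glare,
    reconstruct_hypercube,
    roi_mean_spectrum,
    temporal_average,
)
from snapcube.sensor_model import preset
from snapcube.srda_sim import make_tile_scene, simulate_mosaic_frame, tile_spectrum


def frame_of(pixels, cam):
    return RawMosaicFrame(np.asarray(pixels, dtype=float), cam)


class TestReconstruct:
    def test_constant_frame_gives_constant_cube(self, vis_cam):
        cube = reconstruct_hypercube(frame_of(np.full((16, 16), 7.0), vis_cam))
        assert cube.data.shape == (4, 4, 16)
        assert np.all(cube.data == 7.0)

    def test_index_bookkeeping_maps_cells_to_bands(self, vis_cam):
        # pixel value at tile cell (r, c) equals that cell's band index
        tile = vis_cam.layout.cell_band.astype(float)
        frame = frame_of(np.tile(tile, (2, 2)), vis_cam)
        cube = reconstruct_hypercube(frame)
        for b in range(16):
            assert np.all(cube.data[:, :, b] == b)

    def test_vis_frame_yields_16_bands(self, vis_cam, noise_free_model, grid):
        scene = make_tile_scene(tile_spectrum("red", grid), (32, 32))
        cube = reconstruct_hypercube(simulate_mosaic_frame(scene, vis_cam, noise_free_model))
        assert cube.n_bands == 16 and cube.data.shape == (8, 8, 16)

    def test_inactive_cells_never_read(self, grid):
        cam = preset("rnir")  # 15 bands, one inactive cell
        px = np.tile(cam.layout.cell_band.astype(float), (2, 2))
        px[px == -1] = 9999.0
        cube = reconstruct_hypercube(frame_of(px, cam))
        assert cube.data.max() == 14

    def test_non_divisible_frame_rejected(self, vis_cam):
        with pytest.raises(ValueError):
            reconstruct_hypercube(frame_of(np.zeros((15, 16)), vis_cam))


class TestTemporalAverage:
    def test_single_element_identity(self, vis_cam):
        f = frame_of(np.random.default_rng(0).uniform(size=(8, 8)), vis_cam)
        avg = temporal_average([f])
        np.testing.assert_array_equal(avg.pixels, f.pixels)

    def test_two_frames_mean(self, vis_cam):
        avg = temporal_average(
            [frame_of(np.full((8, 8), 2.0), vis_cam), frame_of(np.full((8, 8), 4.0), vis_cam)]
        )
        assert np.all(avg.pixels == 3.0)

    def test_shape_mismatch_rejected(self, vis_cam):
        with pytest.raises(ValueError):
            temporal_average(
                [frame_of(np.zeros((8, 8)), vis_cam), frame_of(np.zeros((12, 8)), vis_cam)]
            )

    def test_noise_shrinks_as_inverse_sqrt_n(self):
        # Monte-Carlo: the standard error of a 30-frame average is ~1/sqrt(30)
        # of the single-frame noise.
        rng = np.random.default_rng(11)
        sigma, n = 5.0, 30
        frames = [100.0 + rng.normal(0, sigma, (64, 64)) for _ in range(n)]
        avg = temporal_average(frames)
        se = np.std(avg - 100.0)
        assert se == pytest.approx(sigma / np.sqrt(n), rel=0.15)

    def test_commutes_with_reconstruction(self, vis_cam):
        rng = np.random.default_rng(3)
        frames = [frame_of(rng.uniform(0, 100, (16, 16)), vis_cam) for _ in range(5)]
        a = reconstruct_hypercube(temporal_average(frames))
        b = temporal_average([reconstruct_hypercube(f) for f in frames])
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)


def cubes(vals, bands=2):
    data = np.broadcast_to(np.asarray(vals, dtype=float), (4, 4, bands)).copy()
    return Hypercube(data, np.linspace(500, 600, bands), "raw_intensity")


class TestCalibrate:
    def test_white_maps_to_tile_reflectance(self):
        pair = CalibrationPair(cubes(9.0), cubes(1.0))
        out, _ = calibrate(cubes(9.0), pair)
        np.testing.assert_allclose(out.data, 0.95)

    def test_dark_maps_to_zero(self):
        pair = CalibrationPair(cubes(9.0), cubes(1.0))
        out, _ = calibrate(cubes(1.0), pair)
        np.testing.assert_allclose(out.data, 0.0)

    def test_closed_form_midpoint(self):
        # R = 0.95 * (5 - 1) / (9 - 1) = 0.475
        pair = CalibrationPair(cubes(9.0), cubes(1.0))
        out, _ = calibrate(cubes(5.0), pair)
        np.testing.assert_allclose(out.data, 0.475)

    def test_invariant_to_global_illumination_gain(self):
        rng = np.random.default_rng(5)
        I = Hypercube(rng.uniform(10, 50, (4, 4, 2)), [500.0, 600.0])
        W = Hypercube(rng.uniform(60, 90, (4, 4, 2)), [500.0, 600.0])
        D = Hypercube(np.full((4, 4, 2), 4.0), [500.0, 600.0])
        base, _ = calibrate(I, CalibrationPair(W, D))
        k = 3.7  # same lamp brightening scales scene and white signal alike
        I2 = Hypercube(D.data + k * (I.data - D.data), I.band_centers_nm)
        W2 = Hypercube(D.data + k * (W.data - D.data), W.band_centers_nm)
        scaled, _ = calibrate(I2, CalibrationPair(W2, D))
        np.testing.assert_allclose(scaled.data, base.data, rtol=1e-12)

    def test_degenerate_pixels_flagged_and_counted(self):
        W = cubes(9.0)
        W.data[0, 0, 0] = 1.0  # equals dark: invalid
        pair = CalibrationPair(W, cubes(1.0))
        out, report = calibrate(cubes(5.0), pair)
        assert report["n_invalid"] == 1
        assert np.isnan(out.data[0, 0, 0])
        assert np.isfinite(out.data[1:, :, :]).all()

    def test_all_invalid_is_calibration_error(self):
        with pytest.raises(CalibrationError):
            calibrate(cubes(5.0), CalibrationPair(cubes(1.0), cubes(1.0)))


class TestClipGlare:
    def test_no_clipping_below_threshold(self):
        cube = Hypercube(np.full((4, 4, 2), 0.5), [500.0, 600.0], "reflectance")
        out, n = clip_glare(cube)
        assert n == 0
        np.testing.assert_array_equal(out.data, cube.data)

    def test_single_glare_pixel_clipped(self):
        data = np.full((4, 4, 2), 0.5)
        data[2, 2, 1] = 1.7
        out, n = clip_glare(Hypercube(data, [500.0, 600.0], "reflectance"))
        assert n == 1
        assert out.data[2, 2, 1] == 1.0

    def test_higher_threshold_is_identity(self):
        data = np.random.default_rng(0).uniform(0, 1, (4, 4, 2))
        cube = Hypercube(data, [500.0, 600.0], "reflectance")
        out, n = clip_glare(cube, max_value=2.0)
        assert n == 0
        np.testing.assert_array_equal(out.data, data)


class TestRoiMeanSpectrum:
    def test_uniform_cube_any_mask(self):
        cube = Hypercube(np.full((4, 4, 3), 0.4), [500.0, 550.0, 600.0], "reflectance")
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 3] = True
        curve = roi_mean_spectrum(cube, mask)
        np.testing.assert_allclose(curve.values, 0.4)

    def test_two_pixel_average(self):
        data = np.zeros((2, 2, 2))
        data[0, 0] = [0.2, 0.4]
        data[1, 1] = [0.6, 0.8]
        cube = Hypercube(data, [500.0, 600.0], "reflectance")
        mask = np.eye(2, dtype=bool)
        np.testing.assert_allclose(roi_mean_spectrum(cube, mask).values, [0.4, 0.6])

    def test_clipped_glare_raises_roi_mean(self):
        # 3 pixels, one saturated: clipping to 1.0 then including it raises
        # the band mean versus excluding the glare pixel.
        data = np.full((1, 3, 1), 0.5)
        data[0, 2, 0] = 1.9
        cube = Hypercube(data, [500.0], "reflectance")
        clipped, _ = clip_glare(cube)
        incl = roi_mean_spectrum(clipped, np.array([[True, True, True]]))
        excl = roi_mean_spectrum(clipped, np.array([[True, True, False]]))
        assert incl.values[0] > excl.values[0]

    def test_invalid_pixels_excluded(self):
        data = np.full((1, 3, 1), 0.5)
        data[0, 1, 0] = np.nan
        cube = Hypercube(data, [500.0], "reflectance")
        curve = roi_mean_spectrum(cube, np.ones((1, 3), bool))
        assert curve.values[0] == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        cube = Hypercube(np.zeros((2, 2, 1)), [500.0], "reflectance")
        with pytest.raises(ValueError):
            roi_mean_spectrum(cube, np.zeros((2, 2), bool))
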