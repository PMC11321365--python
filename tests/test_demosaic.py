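import numpy as np
import pytest

from snapcube.demosaic import (
    UnsharpParams,
    demosaic_fc,
    demosaic_lpf,
    demosaic_wrc,
    form_fc_kernel,
    unsharp,
)
from snapcube.formats_io import RawMosaicFrame
from snapcube.resolution import fit_sine_profile
from snapcube.srda_sim import (
    AcquisitionModel,
    make_sine_scene,
    make_tile_scene,
    simulate_mosaic_frame,
    tile_spectrum,
)


def frame_of(pixels, cam):
    return RawMosaicFrame(np.asarray(pixels, dtype=float), cam)


@pytest.fixture(scope="module")
def flat_mosaic(vis_cam, noise_free_model, grid):
    """Flat white-tile scene seen through the mosaic: pure periodic
    per-cell gain modulation, no spatial structure."""
    scene = make_tile_scene(tile_spectrum("white", grid), (128, 128))
    return simulate_mosaic_frame(scene, vis_cam, noise_free_model)


class TestWRC:
    def test_raw_equals_white_gives_flat_zero_image(self, flat_mosaic):
        res = demosaic_wrc(flat_mosaic, flat_mosaic)
        # constant ratio: display normalization maps the degenerate constant
        # image to all zeros; physical ratio is exactly flat
        assert np.all(res.image == 0.0)
        assert np.nanstd(res.raw_image) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_the_ratio(self, vis_cam, flat_mosaic):
        half = frame_of(0.5 * flat_mosaic.pixels, vis_cam)
        res = demosaic_wrc(half, flat_mosaic)
        np.testing.assert_allclose(res.raw_image, 0.5, rtol=1e-12)
        assert np.all(res.image == 0.0)

    def test_removes_white_pattern_keeps_scene_feature(self, vis_cam, flat_mosaic):
        # double one tile cell of the scene relative to the white: the ratio
        # must be flat except that cell at exactly twice the rest
        px = flat_mosaic.pixels.copy()
        px[1::4, 2::4] *= 2.0
        res = demosaic_wrc(frame_of(px, vis_cam), flat_mosaic)
        ratio = res.raw_image
        assert np.allclose(ratio[1::4, 2::4], 2.0 * ratio[0::4, 0::4], rtol=1e-9)
        others = np.delete(ratio.ravel(), np.ravel_multi_index(
            np.meshgrid(np.arange(1, 128, 4), np.arange(2, 128, 4), indexing="ij"),
            (128, 128)).ravel())
        assert np.std(others) < 1e-9

    def test_per_cell_gain_absorbed_by_white(self, vis_cam, flat_mosaic):
        rng = np.random.default_rng(2)
        gain = np.tile(rng.uniform(0.5, 2.0, (4, 4)), (32, 32))
        raw = frame_of(flat_mosaic.pixels * gain, vis_cam)
        white = frame_of(flat_mosaic.pixels * gain, vis_cam)
        base = demosaic_wrc(flat_mosaic, flat_mosaic)
        gained = demosaic_wrc(raw, white)
        np.testing.assert_allclose(gained.raw_image, base.raw_image, rtol=1e-9)

    def test_degenerate_white_rejected(self, vis_cam):
        z = frame_of(np.zeros((16, 16)), vis_cam)
        with pytest.raises(ValueError):
            demosaic_wrc(z, z)


class TestLPF:
    def test_constant_image_unchanged(self, vis_cam):
        res = demosaic_lpf(frame_of(np.full((64, 64), 5.0), vis_cam))
        np.testing.assert_allclose(res.raw_image, 5.0, atol=1e-9)
        assert np.all(res.image == 0.0)  # constant maps to zeros on display

    def test_flattens_pure_mosaic_modulation(self, flat_mosaic):
        res = demosaic_lpf(flat_mosaic)
        out = res.raw_image
        assert out.std() / out.mean() < 0.01

    def test_low_frequency_sinusoid_preserved(self, vis_cam, illuminant):
        # a scene sinusoid far below the mosaic harmonics must survive with
        # <2% relative amplitude error
        model = AcquisitionModel(illuminant=illuminant, dark_level=0.0, seed=1).with_noise_off()
        scene = make_sine_scene(1.0 / 32.0, 0.25, 0.5, extent=(128, 128))
        raw = simulate_mosaic_frame(scene, vis_cam, model)
        out = demosaic_lpf(raw).raw_image
        fit = fit_sine_profile(out.mean(axis=1), expected_freq=1.0 / 32.0)
        ratio = fit.amplitude / fit.offset
        assert ratio == pytest.approx(0.25 / 0.5, rel=0.02)

    def test_parameter_validation(self, flat_mosaic):
        with pytest.raises(ValueError):
            demosaic_lpf(flat_mosaic, keep_radius_frac=0.9)
        with pytest.raises(ValueError):
            demosaic_lpf(flat_mosaic, notch_threshold=-0.1)


class TestFCKernel:
    def test_constant_raw_gives_unit_kernels(self, vis_cam):
        pair = form_fc_kernel(frame_of(np.full((16, 16), 3.0), vis_cam))
        np.testing.assert_allclose(pair.H, 1.0)
        np.testing.assert_allclose(pair.H_inv, 1.0)

    def test_single_tile_sum_proportional_to_cell_values(self, vis_cam):
        rng = np.random.default_rng(0)
        tile = rng.uniform(1, 5, (4, 4))
        pair = form_fc_kernel(frame_of(tile, vis_cam))
        np.testing.assert_allclose(pair.H, tile / tile.mean(), rtol=1e-12)
        np.testing.assert_allclose(pair.H * pair.H_inv, 1.0, rtol=1e-12)

    @pytest.mark.parametrize("name, size", [("vis", 4), ("nir", 5)])
    def test_kernel_matches_mosaic_period(self, name, size, grid, illuminant):
        from snapcube.sensor_model import preset

        cam = preset(name)
        model = AcquisitionModel(illuminant=illuminant, seed=0).with_noise_off()
        raw = simulate_mosaic_frame(
            make_tile_scene(tile_spectrum("white", grid), (40, 40)), cam, model
        )
        pair = form_fc_kernel(raw)
        assert pair.H.shape == (size, size)

    def test_zero_cell_sum_rejected(self, vis_cam):
        px = np.ones((16, 16))
        px[0::4, 0::4] = 0.0
        with pytest.raises(ValueError):
            form_fc_kernel(frame_of(px, vis_cam))


class TestFC:
    def test_constant_raw_gives_constant_output(self, vis_cam):
        res = demosaic_fc(frame_of(np.full((32, 32), 4.0), vis_cam))
        assert np.ptp(res.raw_image) < 1e-9
        assert np.all(res.image == 0.0)

    def test_flattens_pure_mosaic_modulation(self, flat_mosaic):
        out = demosaic_fc(flat_mosaic).raw_image
        assert out.std() / out.mean() < 0.02

    def test_invariant_to_global_intensity_scaling(self, vis_cam, flat_mosaic):
        base = demosaic_fc(flat_mosaic)
        scaled = demosaic_fc(frame_of(flat_mosaic.pixels * 7.3, vis_cam))
        np.testing.assert_allclose(scaled.raw_image, base.raw_image, rtol=1e-9)

    def test_step_edge_stays_sharp(self, vis_cam, illuminant, grid):
        # 10-90% rise of a reflectance step after FC must be <= 2 * period
        model = AcquisitionModel(illuminant=illuminant, seed=0).with_noise_off()
        spatial = np.full((64, 64), 0.3)
        spatial[:, 32:] = 0.9
        from snapcube.srda_sim import SceneSpec, _flat_spectrum

        raw = simulate_mosaic_frame(
            SceneSpec(spatial, _flat_spectrum()), vis_cam, model
        )
        out = demosaic_fc(raw).raw_image.mean(axis=0)
        lo, hi = out[:16].mean(), out[48:].mean()
        above10 = np.flatnonzero(out > lo + 0.1 * (hi - lo))
        above90 = np.flatnonzero(out > lo + 0.9 * (hi - lo))
        rise = above90[0] - above10[0]
        assert rise <= 2 * vis_cam.layout.period

    def test_deterministic(self, flat_mosaic):
        a = demosaic_fc(flat_mosaic)
        b = demosaic_fc(flat_mosaic)
        np.testing.assert_array_equal(a.image, b.image)


class TestUnsharp:
    def test_zero_amount_is_identity(self):
        img = np.random.default_rng(0).uniform(0, 1, (32, 32))
        np.testing.assert_array_equal(unsharp(img, 1.0, 0.0), img)

    def test_constant_unchanged(self):
        img = np.full((32, 32), 0.5)
        np.testing.assert_allclose(unsharp(img, 1.0, 0.5), img, atol=1e-12)

    def test_sinusoid_amplitude_increases_by_gaussian_factor(self):
        # blur multiplies a sinusoid by g = exp(-2 pi^2 sigma^2 f^2); the
        # unsharp output amplitude is (1 + amount*(1 - g)) times the input
        f, sigma, amount = 1.0 / 8.0, 1.0, 0.5
        x = np.arange(128)
        img = 0.5 + 0.2 * np.sin(2 * np.pi * f * x)[None, :] * np.ones((16, 1))
        out = unsharp(img, sigma, amount)
        g = np.exp(-2 * np.pi**2 * sigma**2 * f**2)
        expected = 0.2 * (1 + amount * (1 - g))
        amp = 0.5 * np.ptp(out[8, 16:-16])
        assert amp > 0.2  # strictly increased
        assert amp == pytest.approx(expected, rel=0.02)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            unsharp(np.zeros((8, 8)), sigma=0.0)
        with pytest.raises(ValueError):
            unsharp(np.zeros((8, 8)), amount=-1.0)
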