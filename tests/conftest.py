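import numpy as np
import pytest
from hypothesis import settings

from snapcube.formats_io import SpectralCurve

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from snapcube.reconstruction import (
    calibrate,
    reconstruct_hypercube,
    roi_mean_spectrum,
    temporal_average,
)
from snapcube.sensor_model import preset
from snapcube.spectral_validation import resample_reference, spectral_rmse
from snapcube.srda_sim import (
    AcquisitionModel,
    halogen_illuminant,
    make_reference_pair,
    make_tile_scene,
    simulate_sequence,
    tile_spectrum,
)


@pytest.fixture(scope="session")
def grid():
    return np.arange(360.0, 1101.0)


@pytest.fixture(scope="session")
def illuminant(grid):
    return halogen_illuminant(grid)


@pytest.fixture(scope="session")
def vis_cam():
    return preset("vis")


@pytest.fixture(scope="session")
def noise_free_model(illuminant):
    return AcquisitionModel(illuminant=illuminant, seed=1).with_noise_off()


@pytest.fixture(scope="session")
def noisy_model(illuminant):
    return AcquisitionModel(illuminant=illuminant, seed=7)


@pytest.fixture(scope="session")
def tile_rmse_pipeline():
    """simulate -> average -> reconstruct -> calibrate -> ROI spectrum -> RMSE
    against the generating tile spectrum (percent)."""
    return _tile_rmse_pipeline


def _tile_rmse_pipeline(tile_name, camera, model, grid, extent=(64, 64), n_frames=1,
                        cal=None):
    spectrum = tile_spectrum(tile_name, grid)
    scene = make_tile_scene(spectrum, extent)
    if cal is None:
        cal = make_reference_pair(camera, model, extent, n_frames=n_frames)
    frames = simulate_sequence(scene, camera, model, n_frames)
    cube = reconstruct_hypercube(temporal_average(frames))
    refl, _ = calibrate(cube, cal)
    curve = roi_mean_spectrum(refl, np.ones(refl.spatial_shape, bool), tile_name)
    rr = resample_reference(spectrum, camera.band_centers_nm)
    measured = SpectralCurve(
        curve.wavelengths_nm[rr.kept], curve.values[rr.kept], tile_name
    )
    return spectral_rmse(measured, rr.curve)
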