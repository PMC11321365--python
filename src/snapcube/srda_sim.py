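"""Forward model of snapshot-mosaic (SRDA) acquisition.

The simulator turns a ground-truth reflectance scene into the raw mosaic
frames the camera would record, so the entire processing stack can be
exercised without hardware.  The sensor model is linear: for a pixel whose
tile cell carries band ``b``,

    counts = dark_level + gain * sum_lambda L(l) * R(x, y, l) * T_b(l) * dl
             + shot noise + read noise,

clipped to the sensor's digital range.  ``L`` is the illuminant (a smooth
halogen-like curve by default, dim at short visible wavelengths), ``T_b``
the Gaussian transmission of band ``b``'s filter, and ``R`` the scene
reflectance.  Inactive mosaic cells record dark level plus read noise only.

Scenes are separable, ``R(x, y, l) = spatial(x, y) * spectrum(l)``, which
covers everything the validation protocol needs: flat reflectance tiles,
wavelength-flat USAF three-bar targets, and sinusoidal test patterns.
Shot noise is modeled as Gaussian with variance equal to the signal in
counts, adequate at the >100-count levels simulated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .formats_io import RawMosaicFrame, SpectralCurve
from .reconstruction import CalibrationPair, temporal_average
from .resolution import ElementProbe, UsafElement, usaf_linewidth_mm
from .sensor_model import CameraSpec, gaussian_filter_bank

__all__ = [
    "SceneSpec",
    "AcquisitionModel",
    "halogen_illuminant",
    "tile_spectrum",
    "TILE_NAMES",
    "simulate_mosaic_frame",
    "simulate_sequence",
    "make_reference_pair",
    "make_tile_scene",
    "make_usaf_scene",
    "make_sine_scene",
]


@dataclass
class SceneSpec:
    """Separable ground-truth reflectance scene.

    ``spatial`` scales the per-wavelength ``spectrum``; the product must lie
    in [0, 1] everywhere.  ``mm_per_pixel`` gives physical scale for bar
    targets.
    """

    spatial: np.ndarray  # (H, W) in [0, 1]
    spectrum: SpectralCurve  # values in [0, 1]
    mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        sp = np.asarray(self.spatial, dtype=np.float64)
        if sp.ndim != 2:
            raise ValueError("scene spatial field must be 2D")
        if np.nanmin(sp) < 0 or np.nanmax(sp) * np.max(self.spectrum.values) > 1 + 1e-12:
            raise ValueError("scene reflectance must lie in [0, 1]")
        if np.any(self.spectrum.values < 0):
            raise ValueError("scene spectrum must be nonnegative")
        self.spatial = sp

    @property
    def extent(self) -> tuple[int, int]:
        return self.spatial.shape


@dataclass
class AcquisitionModel:
    """Illumination, gain and noise description of one acquisition.

    ``gain`` in counts per unit band-integrated radiance; ``None`` picks a
    gain that puts a unit-reflectance scene at 90% of full scale in the
    brightest band.  ``dark_level`` and ``read_noise_sd`` are in counts.
    """

    illuminant: SpectralCurve
    dark_level: float = 64.0
    gain: float | None = None
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_noise_off(self) -> "AcquisitionModel":
        return replace(self, read_noise_sd=0.0, shot_noise=False)


def halogen_illuminant(
    grid_nm: np.ndarray, temperature_k: float = 3200.0
) -> SpectralCurve:
    """Relative spectral power of a halogen lamp (Planck curve at ~3200 K).

    Rises steadily from the blue toward the red/NIR, so short visible bands
    are light-starved, as with a real fiber-coupled halogen source.
    """
    lam_m = np.asarray(grid_nm, dtype=float) * 1e-9
    h, c, kB = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    power = 1.0 / (lam_m**5 * (np.exp(h * c / (lam_m * kB * temperature_k)) - 1.0))
    return SpectralCurve(grid_nm, power / power.max(), f"halogen_{temperature_k:.0f}K")


# ---------------------------------------------------------------------------
# Tile spectra: smooth synthetic analogues of colored Spectralon tiles.
# Transitions are kept broad (>= 25 nm scales) so the band-integrated and
# center-sampled reflectance agree to well under one percent.
# ---------------------------------------------------------------------------


def _logistic(lam: np.ndarray, center: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(lam - center) / scale))


def _bump(lam: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - center) / width) ** 2))


_TILES = {
    "red": lambda l: 0.08 + 0.80 * _logistic(l, 600, 25),
    "green": lambda l: 0.08 + 0.50 * _bump(l, 540, 60) + 0.40 * _logistic(l, 710, 30),
    "blue": lambda l: 0.08 + 0.55 * _bump(l, 465, 55) + 0.45 * _logistic(l, 760, 40),
    "yellow": lambda l: 0.08 + 0.75 * _logistic(l, 550, 25),
    "violet": lambda l: 0.15 + 0.30 * _bump(l, 430, 55) + 0.55 * _logistic(l, 640, 35),
    "cyan": lambda l: 0.08 + 0.50 * _bump(l, 500, 65) + 0.45 * _logistic(l, 740, 40),
    "orange": lambda l: 0.07 + 0.78 * _logistic(l, 585, 25),
    "purple": lambda l: 0.12 + 0.25 * _bump(l, 440, 55) + 0.60 * _logistic(l, 620, 40),
    "nir": lambda l: 0.10 + 0.70 * _logistic(l, 800, 60),
    "white": lambda l: np.full_like(l, 0.95),
}

TILE_NAMES = tuple(n for n in _TILES if n != "white")


def tile_spectrum(name: str, grid_nm: np.ndarray) -> SpectralCurve:
    """Synthetic reference-tile reflectance evaluated on ``grid_nm``."""
    if name not in _TILES:
        raise ValueError(f"unknown tile {name!r}; choose from {tuple(_TILES)}")
    grid = np.asarray(grid_nm, dtype=float)
    vals = np.clip(_TILES[name](grid), 0.02, 0.98)
    if name == "white":
        vals = np.full_like(grid, 0.95)
    return SpectralCurve(grid, vals, name)


# ---------------------------------------------------------------------------
# Core forward model
# ---------------------------------------------------------------------------


def _spectral_grid(camera: CameraSpec) -> np.ndarray:
    """1-nm quadrature grid covering all filters out to +/- 3 FWHM."""
    lo = float(camera.band_centers_nm.min() - 3 * camera.filter_fwhm_nm.max())
    hi = float(camera.band_centers_nm.max() + 3 * camera.filter_fwhm_nm.max())
    return np.arange(np.floor(lo), np.ceil(hi) + 1.0)


def _band_weights(camera: CameraSpec, model: AcquisitionModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-band illuminant-weighted filter responses on the 1-nm grid.

    Returns (grid, weights) with ``weights[b, g] = L(g) * T_b(g)``; the
    rectangular-quadrature band signal for a spectrum R is ``weights @ R``.
    """
    grid = _spectral_grid(camera)
    ill = model.illuminant
    if grid[0] < ill.wavelengths_nm[0] - 1e-9 or grid[-1] > ill.wavelengths_nm[-1] + 1e-9:
        raise ValueError(
            f"illuminant range [{ill.wavelengths_nm[0]}, {ill.wavelengths_nm[-1]}] nm "
            f"does not cover the filter support [{grid[0]}, {grid[-1]}] nm"
        )
    L = np.interp(grid, ill.wavelengths_nm, ill.values)
    T = gaussian_filter_bank(camera, grid).transmission
    return grid, L[None, :] * T


def _resolve_gain(camera: CameraSpec, model: AcquisitionModel) -> float:
    if model.gain is not None:
        return float(model.gain)
    _, w = _band_weights(camera, model)
    max_signal = float(w.sum(axis=1).max())  # unit reflectance, brightest band
    return (0.9 * camera.full_scale - model.dark_level) / max_signal


def band_signals(
    spectrum: SpectralCurve, camera: CameraSpec, model: AcquisitionModel
) -> np.ndarray:
    """Noise-free per-band signal (counts above dark) for a unit spatial field."""
    grid, w = _band_weights(camera, model)
    R = np.interp(grid, spectrum.wavelengths_nm, spectrum.values)
    return _resolve_gain(camera, model) * (w @ R)


def simulate_mosaic_frame(
    scene: SceneSpec,
    camera: CameraSpec,
    model: AcquisitionModel,
    rng: np.random.Generator | None = None,
    dark_only: bool = False,
) -> RawMosaicFrame:
    """Record one raw mosaic frame of ``scene`` with ``camera``.

    ``dark_only=True`` simulates a blocked light path (dark reference).
    Noise uses ``rng`` if given, else a fresh generator from ``model.seed``.
    """
    H, W = scene.extent
    p = camera.layout.period
    if H % p or W % p:
        raise ValueError(f"scene extent {scene.extent} not divisible by period {p}")
    if rng is None:
        rng = model.rng()
    signal = np.zeros((H, W), dtype=np.float64)
    if not dark_only:
        s_b = band_signals(scene.spectrum, camera, model)
        cell_band = camera.layout.cell_band
        band_map = np.tile(cell_band, (H // p, W // p))
        active = band_map >= 0
        signal[active] = s_b[band_map[active]] * scene.spatial[active]
    counts = model.dark_level + signal
    if model.shot_noise:
        counts = counts + rng.normal(0.0, np.sqrt(np.maximum(signal, 0.0)))
    if model.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, model.read_noise_sd, size=counts.shape)
    counts = np.clip(counts, 0.0, camera.full_scale)
    return RawMosaicFrame(counts, camera, {"simulated": True, "dark_only": dark_only})


def simulate_sequence(
    scene: SceneSpec,
    camera: CameraSpec,
    model: AcquisitionModel,
    n_frames: int,
    dark_only: bool = False,
) -> list[RawMosaicFrame]:
    """Repeated exposures of the same scene with independent noise draws."""
    rng = model.rng()
    return [
        simulate_mosaic_frame(scene, camera, model, rng=rng, dark_only=dark_only)
        for _ in range(n_frames)
    ]


def make_reference_pair(
    camera: CameraSpec,
    model: AcquisitionModel,
    extent: tuple[int, int],
    n_frames: int = 30,
    white_reflectance: float = 0.95,
) -> CalibrationPair:
    """Temporally averaged white (95% tile) and dark reference frames."""
    grid = _spectral_grid(camera)
    white_scene = make_tile_scene(
        SpectralCurve(grid, np.full_like(grid, white_reflectance), "white"), extent
    )
    white = temporal_average(simulate_sequence(white_scene, camera, model, n_frames))
    dark = temporal_average(
        simulate_sequence(white_scene, camera, model, n_frames, dark_only=True)
    )
    return CalibrationPair(white=white, dark=dark, white_reflectance=white_reflectance)


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------


def make_tile_scene(spectrum: SpectralCurve, extent: tuple[int, int]) -> SceneSpec:
    """Spatially uniform scene of one reflectance tile."""
    if np.any(spectrum.values < 0) or np.any(spectrum.values > 1):
        raise ValueError("tile spectrum must lie in [0, 1]")
    return SceneSpec(np.ones(extent), spectrum)


def _flat_spectrum() -> SpectralCurve:
    grid = np.arange(300.0, 1101.0)
    return SpectralCurve(grid, np.ones_like(grid), "flat")


def _bar_coverage(length: int, start: float, width: float, n_bars: int = 3) -> np.ndarray:
    """Exact per-pixel area coverage of ``n_bars`` bars of ``width`` px
    separated by equal gaps, along one axis."""
    edges = [(start + k * 2.0 * width, start + k * 2.0 * width + width) for k in range(n_bars)]
    idx = np.arange(length, dtype=np.float64)
    cov = np.zeros(length)
    for a, b in edges:
        cov += np.clip(np.minimum(idx + 1.0, b) - np.maximum(idx, a), 0.0, 1.0)
    return cov


def make_usaf_scene(
    elements: list[UsafElement],
    mm_per_pixel: float,
    bar_reflectance: float = 0.10,
    background_reflectance: float = 0.90,
    margin_px: int = 16,
) -> tuple[SceneSpec, list[ElementProbe]]:
    """Wavelength-flat three-bar chart with both bar orientations.

    Each element is drawn twice: horizontal bars (probed along a vertical
    line; this measures vertical resolution) and vertical bars (probed
    horizontally).  Bar widths follow the exact USAF-1951 geometry at the
    given scale; sub-pixel bar edges are rendered with exact area coverage.
    Returns the scene and coarse-to-fine probes ready for
    :func:`snapcube.resolution.resolution_limit`.
    """
    if not elements:
        return SceneSpec(
            np.full((margin_px * 2, margin_px * 2), background_reflectance),
            _flat_spectrum(),
            mm_per_pixel,
        ), []
    widths = [usaf_linewidth_mm(e) / mm_per_pixel for e in elements]
    if min(widths) < 2.0:
        raise ValueError(
            f"element {elements[int(np.argmin(widths))]} has bar width "
            f"{min(widths):.2f} px < 2 px at {mm_per_pixel} mm/px"
        )
    order = np.argsort(widths)[::-1]  # coarse -> fine
    elements = [elements[i] for i in order]
    widths = [widths[i] for i in order]

    slot_h = [int(np.ceil(5 * w)) + margin_px for w in widths]
    patch_w = [int(np.ceil(5 * w)) for w in widths]
    H = margin_px + sum(slot_h)
    Wd = 2 * margin_px + 2 * max(patch_w) + margin_px
    field_img = np.full((H, Wd), background_reflectance)
    probes: list[ElementProbe] = []
    y = margin_px
    for e, w, ph, pw in zip(elements, widths, slot_h, patch_w):
        length = pw  # bar length = 5 * width, per the chart geometry
        # horizontal bars at (rows y..y+5w, cols x0..x0+length)
        x0 = margin_px
        cov = _bar_coverage(int(np.ceil(5 * w)), 0.0, w)
        patch = background_reflectance + (bar_reflectance - background_reflectance) * cov
        field_img[y : y + cov.size, x0 : x0 + length] = patch[:, None]
        mid = x0 + length / 2.0
        probes.append(
            ElementProbe(e, ((float(y), mid), (float(y + cov.size - 1), mid)), "vertical")
        )
        # vertical bars to the right
        x1 = margin_px + max(patch_w) + margin_px
        field_img[y : y + length, x1 : x1 + cov.size] = patch[None, :]
        midr = y + length / 2.0
        probes.append(
            ElementProbe(e, ((midr, float(x1)), (midr, float(x1 + cov.size - 1))), "horizontal")
        )
        y += ph
    # pad to a multiple of common mosaic periods (4 and 5 -> 20)
    H2 = int(np.ceil(field_img.shape[0] / 20) * 20)
    W2 = int(np.ceil(field_img.shape[1] / 20) * 20)
    padded = np.full((H2, W2), background_reflectance)
    padded[: field_img.shape[0], : field_img.shape[1]] = field_img
    return SceneSpec(padded, _flat_spectrum(), mm_per_pixel), probes


def make_sine_scene(
    frequency: float,
    amplitude: float,
    offset: float,
    orientation: str = "vertical",
    extent: tuple[int, int] = (128, 128),
) -> SceneSpec:
    """Wavelength-flat sinusoidal reflectance field.

    ``frequency`` is in cycles/pixel along the modulated axis;
    ``orientation='vertical'`` modulates along rows.  The analytic Michelson
    contrast of the pattern is ``amplitude / offset``.
    """
    if amplitude < 0 or offset - amplitude < 0 or offset + amplitude > 1:
        raise ValueError("offset +/- amplitude must stay within [0, 1]")
    H, W = extent
    if orientation == "vertical":
        axis = np.arange(H, dtype=np.float64)[:, None]
    elif orientation == "horizontal":
        axis = np.arange(W, dtype=np.float64)[None, :]
    else:
        raise ValueError("orientation must be 'vertical' or 'horizontal'")
    spatial = offset + amplitude * np.sin(2.0 * np.pi * frequency * axis)
    return SceneSpec(np.broadcast_to(spatial, (H, W)).copy(), _flat_spectrum())
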