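"""Declarative snapshot hyperspectral camera descriptions.

A snapshot-mosaic camera (spectrally resolved detector array, SRDA) carries a
periodic p x p tile of micro-optical bandpass filters over its sensor.  Each
cell of the tile samples one spectral band; one full-resolution raw frame
therefore encodes a complete (if spatially subsampled) hypercube.

This module holds the camera geometry (:class:`MosaicLayout`,
:class:`CameraSpec`), JSON (de)serialization, factory presets for the three
supported cameras (VIS 16-band 4x4, red/NIR 15-band 4x4, NIR 24-band 5x5),
and a Gaussian :class:`FilterBank` used by the forward simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "INACTIVE",
    "MosaicLayout",
    "CameraSpec",
    "FilterBank",
    "ConfigError",
    "load_camera_spec",
    "save_camera_spec",
    "gaussian_filter_bank",
    "preset",
    "PRESET_NAMES",
]

#: Sentinel band index marking a mosaic cell with no assigned band.
INACTIVE = -1


class ConfigError(ValueError):
    """Raised when a camera description violates its schema or invariants."""


@dataclass(frozen=True)
class MosaicLayout:
    """Periodic band-to-cell map of a multispectral filter array.

    Parameters
    ----------
    period:
        Edge length of the repeating mosaic tile in pixels (4 or 5 for the
        supported cameras, but any positive integer is accepted).
    cell_band:
        ``period x period`` integer grid.  Entry ``(r, c)`` is the band index
        sampled at tile cell ``(r, c)``; :data:`INACTIVE` marks an unused cell.
    """

    period: int
    cell_band: np.ndarray

    def __post_init__(self) -> None:
        cb = np.asarray(self.cell_band, dtype=int)
        object.__setattr__(self, "cell_band", cb)
        if cb.shape != (self.period, self.period):
            raise ConfigError(
                f"cell_band shape {cb.shape} does not match period {self.period}"
            )
        bands = cb[cb != INACTIVE]
        expected = np.arange(bands.size)
        if bands.size == 0 or not np.array_equal(np.sort(bands), expected):
            raise ConfigError(
                "cell_band must contain each band index 0..B-1 exactly once "
                f"(got active cells {np.sort(bands).tolist()})"
            )

    @property
    def n_bands(self) -> int:
        return int(np.count_nonzero(self.cell_band != INACTIVE))

    def band_cells(self) -> np.ndarray:
        """(B, 2) array of (row, col) tile coordinates, indexed by band."""
        cells = np.empty((self.n_bands, 2), dtype=int)
        for r in range(self.period):
            for c in range(self.period):
                b = self.cell_band[r, c]
                if b != INACTIVE:
                    cells[b] = (r, c)
        return cells

    def active_mask(self) -> np.ndarray:
        return self.cell_band != INACTIVE

    @staticmethod
    def row_major(period: int, n_bands: int) -> "MosaicLayout":
        """Default layout: bands 0..B-1 row-major within the tile, remaining
        cells (bottom-right first missing) inactive."""
        if not 0 < n_bands <= period * period:
            raise ConfigError(f"{n_bands} bands do not fit a {period}x{period} tile")
        flat = np.full(period * period, INACTIVE, dtype=int)
        flat[:n_bands] = np.arange(n_bands)
        return MosaicLayout(period, flat.reshape(period, period))


@dataclass(frozen=True)
class CameraSpec:
    """Complete static description of one snapshot hyperspectral camera."""

    name: str
    band_centers_nm: np.ndarray
    layout: MosaicLayout
    bit_depth: int = 10
    #: Filter full width at half maximum, scalar or per-band; simulation only.
    filter_fwhm_nm: np.ndarray = field(default_factory=lambda: np.array(15.0))

    def __post_init__(self) -> None:
        centers = np.asarray(self.band_centers_nm, dtype=float)
        fwhm = np.broadcast_to(
            np.asarray(self.filter_fwhm_nm, dtype=float), centers.shape
        ).copy()
        object.__setattr__(self, "band_centers_nm", centers)
        object.__setattr__(self, "filter_fwhm_nm", fwhm)
        if centers.ndim != 1 or centers.size < 1:
            raise ConfigError("band_centers_nm must be a non-empty 1D sequence")
        if np.any(np.diff(centers) <= 0):
            raise ConfigError("band_centers_nm must be strictly ascending")
        if centers.size != self.layout.n_bands:
            raise ConfigError(
                f"{centers.size} band centers declared but layout has "
                f"{self.layout.n_bands} active cells"
            )
        if self.bit_depth < 1:
            raise ConfigError("bit_depth must be positive")
        if np.any(fwhm <= 0):
            raise ConfigError("filter_fwhm_nm must be positive")

    @property
    def n_bands(self) -> int:
        return int(self.band_centers_nm.size)

    @property
    def full_scale(self) -> float:
        return float(2**self.bit_depth - 1)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "band_centers_nm": self.band_centers_nm.tolist(),
            "period": self.layout.period,
            "cell_band": self.layout.cell_band.tolist(),
            "bit_depth": self.bit_depth,
            "filter_fwhm_nm": self.filter_fwhm_nm.tolist(),
        }

    @staticmethod
    def from_dict(d: dict) -> "CameraSpec":
        try:
            name = str(d["name"])
            centers = np.asarray(d["band_centers_nm"], dtype=float)
            period = int(d["period"])
        except KeyError as exc:
            raise ConfigError(f"camera config missing required field {exc}") from exc
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"malformed camera config field: {exc}") from exc
        if "cell_band" in d and d["cell_band"] is not None:
            layout = MosaicLayout(period, np.asarray(d["cell_band"], dtype=int))
        else:
            layout = MosaicLayout.row_major(period, centers.size)
        return CameraSpec(
            name=name,
            band_centers_nm=centers,
            layout=layout,
            bit_depth=int(d.get("bit_depth", 10)),
            filter_fwhm_nm=np.asarray(d.get("filter_fwhm_nm", 15.0), dtype=float),
        )


def save_camera_spec(spec: CameraSpec, path: str | Path) -> None:
    Path(path).write_text(json.dumps(spec.to_dict(), indent=2, sort_keys=True))


def load_camera_spec(path: str | Path) -> CameraSpec:
    """Load and validate a camera description from its JSON file."""
    path = Path(path)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: camera config must be a JSON object")
    return CameraSpec.from_dict(d)


@dataclass(frozen=True)
class FilterBank:
    """Per-band filter transmission sampled on a common wavelength grid."""

    wavelength_grid_nm: np.ndarray
    transmission: np.ndarray  # (B, G), values in [0, 1]

    def __post_init__(self) -> None:
        grid = np.asarray(self.wavelength_grid_nm, dtype=float)
        t = np.asarray(self.transmission, dtype=float)
        object.__setattr__(self, "wavelength_grid_nm", grid)
        object.__setattr__(self, "transmission", t)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if t.ndim != 2 or t.shape[1] != grid.size:
            raise ValueError("transmission must be (B, len(grid))")
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("transmission values must lie in [0, 1]")


def gaussian_filter_bank(spec: CameraSpec, grid_nm: np.ndarray) -> FilterBank:
    """Idealized Gaussian transmission curves for each band of ``spec``.

    Band ``b`` transmits ``exp(-4 ln2 (lam - center_b)^2 / FWHM_b^2)`` with a
    unit peak, i.e. a Gaussian whose full width at half maximum equals the
    declared filter FWHM.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if grid.min() > spec.band_centers_nm.min() or grid.max() < spec.band_centers_nm.max():
        raise ValueError(
            f"wavelength grid [{grid.min()}, {grid.max()}] nm does not cover the "
            f"band centers of camera {spec.name!r}"
        )
    centers = spec.band_centers_nm[:, None]
    fwhm = spec.filter_fwhm_nm[:, None]
    t = np.exp(-4.0 * np.log(2.0) * (grid[None, :] - centers) ** 2 / fwhm**2)
    return FilterBank(grid, t)


# ---------------------------------------------------------------------------
# Presets.  Band centers are placed uniformly over the realized spectral
# endpoints of each camera; the vendor does not publish the exact centers.
# FWHM scales roughly with wavelength, matching the ~10-20 nm passbands
# typical of Fabry-Perot mosaic filters.
# ---------------------------------------------------------------------------

_PRESETS = {
    "vis": dict(lo=461.0, hi=597.0, n=16, period=4, fwhm=12.0),
    "rnir": dict(lo=614.0, hi=853.0, n=15, period=4, fwhm=16.0),
    "nir": dict(lo=669.0, hi=949.0, n=24, period=5, fwhm=18.0),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> CameraSpec:
    """Factory for the built-in camera presets ``vis``, ``rnir``, ``nir``."""
    key = name.lower()
    if key not in _PRESETS:
        raise ConfigError(f"unknown camera preset {name!r}; choose from {PRESET_NAMES}")
    p = _PRESETS[key]
    centers = np.linspace(p["lo"], p["hi"], p["n"])
    return CameraSpec(
        name=key.upper(),
        band_centers_nm=centers,
        layout=MosaicLayout.row_major(p["period"], p["n"]),
        bit_depth=10,
        filter_fwhm_nm=np.asarray(p["fwhm"]),
    )
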