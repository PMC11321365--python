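"""Raw mosaic frames -> calibrated reflectance hypercubes.

The processing chain is: temporally average repeated raw frames, sample each
mosaic tile cell into its band plane (``reconstruct_hypercube``), convert
counts to reflectance against white/dark references (``calibrate``), clip
specular glare, and extract region-of-interest mean spectra.

Calibration follows the standard flat-field identity

    R = rho_white * (I - D) / (W - D)

where ``rho_white`` is the reflectance of the white reference tile
(0.95 for Spectralon).  Pixels where ``W - D`` falls below an epsilon guard
are flagged invalid (NaN) and excluded from downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .formats_io import Hypercube, RawMosaicFrame, SpectralCurve

__all__ = [
    "CalibrationPair",
    "CalibrationError",
    "reconstruct_hypercube",
    "temporal_average",
    "calibrate",
    "clip_glare",
    "roi_mean_spectrum",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when white/dark references cannot calibrate anything."""


@dataclass
class CalibrationPair:
    """Averaged white (95% tile) and dark (blocked light) references.

    ``white`` and ``dark`` may be raw mosaic frames or already-reconstructed
    cubes; they must match each other and the data they calibrate.
    """

    white: RawMosaicFrame | Hypercube
    dark: RawMosaicFrame | Hypercube
    white_reflectance: float = 0.95

    def as_cubes(self) -> tuple[Hypercube, Hypercube]:
        w, d = self.white, self.dark
        if isinstance(w, RawMosaicFrame):
            w = reconstruct_hypercube(w)
        if isinstance(d, RawMosaicFrame):
            d = reconstruct_hypercube(d)
        return w, d


def reconstruct_hypercube(frame: RawMosaicFrame) -> Hypercube:
    """Sample each mosaic cell into its band plane.

    The output has spatial size ``(H/p, W/p)`` and one plane per band:
    ``cube[i, j, b] = frame[i*p + r_b, j*p + c_b]`` where ``(r_b, c_b)`` is
    band ``b``'s cell within the tile.  Inactive cells are never read.
    """
    p = frame.camera.layout.period
    H, W = frame.pixels.shape
    if H % p or W % p:
        raise ValueError(f"frame shape {H}x{W} not divisible by mosaic period {p}")
    cells = frame.camera.layout.band_cells()
    planes = [frame.pixels[r::p, c::p] for r, c in cells]
    data = np.stack(planes, axis=2).astype(np.float64, copy=False)
    return Hypercube(data, frame.camera.band_centers_nm, "raw_intensity")


def temporal_average(items: Sequence[RawMosaicFrame | Hypercube | np.ndarray]):
    """Element-wise arithmetic mean of same-shape frames, cubes or arrays.

    Averaging raw frames before reconstruction is equivalent to averaging
    reconstructed cubes, since tile sampling is linear.
    """
    if len(items) == 0:
        raise ValueError("temporal_average needs at least one element")
    first = items[0]
    if isinstance(first, RawMosaicFrame):
        arrays = [np.asarray(f.pixels, dtype=np.float64) for f in items]
    elif isinstance(first, Hypercube):
        arrays = [np.asarray(c.data, dtype=np.float64) for c in items]
    else:
        arrays = [np.asarray(a, dtype=np.float64) for a in items]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("temporal_average requires homogeneous shapes")
    mean = np.mean(arrays, axis=0)
    if isinstance(first, RawMosaicFrame):
        return RawMosaicFrame(mean, first.camera, dict(first.meta, averaged=len(items)))
    if isinstance(first, Hypercube):
        return Hypercube(mean, first.band_centers_nm, first.kind)
    return mean


def calibrate(
    raw: Hypercube,
    cal: CalibrationPair,
    eps_frac: float = 1e-6,
    full_scale: float | None = None,
) -> tuple[Hypercube, dict]:
    """Convert raw counts to reflectance using white/dark references.

    Pixels where ``white - dark <= eps_frac * full_scale`` receive NaN and
    are counted in the returned report.  ``full_scale`` defaults to the
    maximum of the white reference (a conservative stand-in when the camera
    bit depth is unknown at this point in the pipeline).
    """
    white, dark = cal.as_cubes()
    if white.data.shape != raw.data.shape or dark.data.shape != raw.data.shape:
        raise ValueError("calibration references must match the raw cube shape")
    W = white.data.astype(np.float64)
    D = dark.data.astype(np.float64)
    I = raw.data.astype(np.float64)
    if full_scale is None:
        full_scale = float(np.nanmax(W)) or 1.0
    denom = W - D
    invalid = ~(denom > eps_frac * full_scale)
    if invalid.all():
        raise CalibrationError("white - dark is degenerate everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        R = cal.white_reflectance * (I - D) / denom
    R[invalid] = np.nan
    n_bad = int(invalid.sum())
    if n_bad:
        log.warning("calibrate: %d pixel-bands flagged invalid (W-D <= eps)", n_bad)
    report = {"n_invalid": n_bad, "eps": eps_frac * full_scale}
    return Hypercube(R, raw.band_centers_nm, "reflectance"), report


def clip_glare(cube: Hypercube, max_value: float = 1.0) -> tuple[Hypercube, int]:
    """Threshold glare: replace reflectance above ``max_value`` by it.

    Returns the clipped cube and the number of clipped pixel-bands.  Glare
    pixels are clipped rather than dropped so that camera and spectrometer
    regions of interest stay comparable.
    """
    if cube.kind != "reflectance":
        raise ValueError("clip_glare expects a reflectance cube")
    over = cube.data > max_value
    n = int(np.count_nonzero(over))
    data = np.where(over, max_value, cube.data)
    return Hypercube(data, cube.band_centers_nm, cube.kind), n


def roi_mean_spectrum(cube: Hypercube, mask: np.ndarray, label: str = "roi") -> SpectralCurve:
    """Per-band mean reflectance over a boolean region of interest.

    Invalid (NaN) pixels are excluded band-wise; the curve's wavelengths are
    the camera band centers.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.spatial_shape:
        raise ValueError("mask shape must match the cube's spatial shape")
    if not mask.any():
        raise ValueError("empty ROI mask")
    sel = cube.data[mask]  # (n_pixels, B)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(sel, axis=0)
    return SpectralCurve(cube.band_centers_nm, values, label)
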