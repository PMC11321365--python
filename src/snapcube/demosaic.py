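"""Mosaic-pattern removal from full-resolution raw frames.

A snapshot-mosaic sensor modulates the scene with the periodic per-cell gain
of its filter array.  Demosaicing here means producing a single spatially
smooth grayscale image at full sensor resolution (not a per-band
interpolation).  Three methods are provided:

* **WRC** (white-reference calibration): element-wise division by the raw
  mosaic image of a white tile, which carries the same per-cell gains.
* **LPF** (low-pass filtering): the mosaic appears as harmonics at multiples
  of 1/period in the 2D Fourier plane; bins outside a protected low-frequency
  disk whose magnitude is large are notched out.
* **FC** (filter convolution): a period-sized kernel of per-cell response
  sums and its reciprocal are each convolved over the image; the two
  normalized results are averaged, then unsharp-masked.

Every :class:`DemosaicResult` carries two rasters: ``raw_image``, the
demosaiced field on its physical intensity scale (use this for quantitative
residual/contrast work), and ``image``, the min-max normalized [0, 1]
version for display and cross-method comparison.  A constant field
normalizes to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .formats_io import RawMosaicFrame

__all__ = [
    "FCKernelPair",
    "DemosaicResult",
    "UnsharpParams",
    "demosaic_wrc",
    "demosaic_lpf",
    "form_fc_kernel",
    "demosaic_fc",
    "unsharp",
]


@dataclass(frozen=True)
class FCKernelPair:
    """Per-cell response kernel H (mean 1 over active cells) and 1/H."""

    H: np.ndarray
    H_inv: np.ndarray


@dataclass
class DemosaicResult:
    image: np.ndarray  # (H, W), min-max normalized to [0, 1]
    method: str  # WRC | LPF | FC
    params: dict = field(default_factory=dict)
    raw_image: np.ndarray | None = None  # physical-scale field


@dataclass(frozen=True)
class UnsharpParams:
    sigma: float = 1.0
    amount: float = 0.5


def _minmax(img: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a (numerically) constant image maps to
    zeros."""
    finite = img[np.isfinite(img)]
    if finite.size == 0:
        return np.zeros_like(img, dtype=np.float64)
    lo, hi = float(finite.min()), float(finite.max())
    if hi - lo <= 1e-9 * max(abs(hi), abs(lo), 1e-300):
        return np.zeros_like(img, dtype=np.float64)
    return (img - lo) / (hi - lo)


def demosaic_wrc(
    raw: RawMosaicFrame, white_mosaic: RawMosaicFrame, eps_frac: float = 1e-6
) -> DemosaicResult:
    """Divide the raw image by the (averaged) white-reference mosaic.

    The white mosaic carries the same per-cell filter gains as the scene
    image, so the ratio cancels the pattern.  Pixels where the white image
    is at or below the epsilon guard become invalid (NaN).
    """
    a = np.asarray(raw.pixels, dtype=np.float64)
    w = np.asarray(white_mosaic.pixels, dtype=np.float64)
    if a.shape != w.shape:
        raise ValueError("raw and white mosaics must have identical shape")
    eps = eps_frac * max(float(np.nanmax(w)), 1.0)
    valid = w > eps
    if not valid.any():
        raise ValueError("white mosaic is degenerate everywhere")
    ratio = np.full_like(a, np.nan)
    ratio[valid] = a[valid] / w[valid]
    return DemosaicResult(_minmax(ratio), "WRC", {"eps_frac": eps_frac}, ratio)


def demosaic_lpf(
    raw: RawMosaicFrame,
    keep_radius_frac: float | None = None,
    notch_threshold: float = 0.1,
) -> DemosaicResult:
    """Notch out strong high-frequency Fourier bins carrying the mosaic.

    ``keep_radius_frac`` protects a central disk of that fraction of the
    Nyquist frequency (default ``1/(2*period)``, half way to the first
    mosaic harmonic).  Outside the disk, bins whose magnitude exceeds
    ``notch_threshold`` times the largest non-DC magnitude are zeroed
    (magnitude and phase together).  Both parameters are tuning starting
    points to be adapted per dataset, as the notch threshold is inherently
    data-dependent.
    """
    p = raw.camera.layout.period
    if keep_radius_frac is None:
        keep_radius_frac = 1.0 / (2.0 * p)
    if not 0 < keep_radius_frac <= 0.5:
        raise ValueError("keep_radius_frac must lie in (0, 0.5]")
    if notch_threshold < 0:
        raise ValueError("notch_threshold must be nonnegative")
    img = np.asarray(raw.pixels, dtype=np.float64)
    F = np.fft.fft2(img)
    fy = np.fft.fftfreq(img.shape[0])[:, None]
    fx = np.fft.fftfreq(img.shape[1])[None, :]
    radius = np.hypot(fy, fx)  # cycles/pixel; Nyquist = 0.5 c/px
    protected = radius <= keep_radius_frac * 0.5
    mag = np.abs(F)
    mag_no_dc = mag.copy()
    mag_no_dc[0, 0] = 0.0
    cutoff = notch_threshold * mag_no_dc.max()
    F[(~protected) & (mag > cutoff)] = 0.0
    out = np.real(np.fft.ifft2(F))
    return DemosaicResult(
        _minmax(out),
        "LPF",
        {"keep_radius_frac": keep_radius_frac, "notch_threshold": notch_threshold},
        out,
    )


def form_fc_kernel(raw: RawMosaicFrame) -> FCKernelPair:
    """Sum the image cell-wise into a period-sized response kernel.

    ``H[r, c]`` is the sum of all samples taken at tile cell ``(r, c)``,
    normalized so the active-cell mean is 1; ``H_inv`` is its element-wise
    reciprocal.  Inactive cells are set to the active mean (1) so they are
    neutral under convolution.
    """
    p = raw.camera.layout.period
    img = np.asarray(raw.pixels, dtype=np.float64)
    H_px, W_px = img.shape
    if H_px % p or W_px % p:
        raise ValueError(f"frame shape {img.shape} not divisible by period {p}")
    tiles = img.reshape(H_px // p, p, W_px // p, p)
    sums = tiles.sum(axis=(0, 2))  # (p, p) per-cell sums
    active = raw.camera.layout.active_mask()
    if np.any(sums[active] <= 0):
        raise ValueError("zero or negative cell sum; cannot form FC kernel")
    H = sums / sums[active].mean()
    H = np.where(active, H, 1.0)
    return FCKernelPair(H=H, H_inv=1.0 / H)


def _tile_pad(img: np.ndarray, period: int, pad: int) -> np.ndarray:
    """Pad by periodically replicating the outermost tile strips.

    Unlike plain reflection this preserves the mosaic phase of the pattern
    right up to the border, so the kernel cancellation does not break down
    in a period-wide edge band.
    """
    H, W = img.shape
    rows = np.concatenate(
        [np.arange(-pad, 0) % period, np.arange(H), H - period + (np.arange(pad) % period)]
    )
    cols = np.concatenate(
        [np.arange(-pad, 0) % period, np.arange(W), W - period + (np.arange(pad) % period)]
    )
    return img[np.ix_(rows, cols)]


def _unsharp_raw(img: np.ndarray, sigma: float, amount: float) -> np.ndarray:
    if amount == 0:
        return img.copy()
    return img + amount * (img - ndimage.gaussian_filter(img, sigma, mode="reflect"))


def demosaic_fc(
    raw: RawMosaicFrame, unsharp_params: UnsharpParams = UnsharpParams()
) -> DemosaicResult:
    """Convolve with the response kernel and its reciprocal, average, sharpen.

    The H branch weights bright cells up and the 1/H branch weights them
    down; each branch is normalized to unit mean, so their residual mosaic
    patterns are (to second order in the gain variation) equal and opposite
    and cancel in the average.  An unsharp mask then restores edge sharpness
    lost to the period-sized convolution.  ``raw_image`` holds the sharpened
    field around its natural unit mean; ``image`` is its min-max display
    normalization.
    """
    kern = form_fc_kernel(raw)
    p = raw.camera.layout.period
    img = np.asarray(raw.pixels, dtype=np.float64)
    big = _tile_pad(img, p, p)
    A = ndimage.convolve(big, kern.H, mode="nearest")[p:-p, p:-p]
    B = ndimage.convolve(big, kern.H_inv, mode="nearest")[p:-p, p:-p]
    mean_a, mean_b = A.mean(), B.mean()
    if mean_a <= 0 or mean_b <= 0:
        raise ValueError("degenerate FC branches (nonpositive mean)")
    combined = 0.5 * (A / mean_a + B / mean_b)
    sharp = _unsharp_raw(combined, unsharp_params.sigma, unsharp_params.amount)
    return DemosaicResult(
        _minmax(sharp),
        "FC",
        {"sigma": unsharp_params.sigma, "amount": unsharp_params.amount},
        sharp,
    )


def unsharp(image: np.ndarray, sigma: float = 1.0, amount: float = 0.5) -> np.ndarray:
    """Unsharp mask: ``img + amount * (img - gaussian(img, sigma))``, clipped
    to [0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    img = np.asarray(image, dtype=np.float64)
    return np.clip(_unsharp_raw(img, sigma, amount), 0.0, 1.0)
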