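"""Spectral fidelity assessment against reference reflectance curves.

Camera spectra (per-band reflectance at the band centers) are compared with
spectrophotometer reference curves: the reference is linearly resampled onto
the camera band centers (bands outside the reference's wavelength range are
excluded, never extrapolated), optionally a single least-squares gain aligns
the scales, and the disagreement is summarized as a percent RMSE with
reflectance on the 0-1 scale.  Per-tile RMSEs aggregate to mean +/- sample
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import SpectralCurve

__all__ = [
    "ResampledReference",
    "RmseSummary",
    "resample_reference",
    "scale_align",
    "spectral_rmse",
    "rmse_table",
]


@dataclass
class ResampledReference:
    curve: SpectralCurve  # reference values at the retained band centers
    kept: np.ndarray  # indices of band centers inside the reference range
    excluded: np.ndarray  # indices outside the reference range


def resample_reference(ref: SpectralCurve, band_centers_nm: np.ndarray) -> ResampledReference:
    """Linearly interpolate a reference curve at the camera band centers.

    Band centers outside the reference's wavelength span are excluded from
    quantitative comparison rather than extrapolated; their indices are
    reported so the measured curve can be trimmed identically.
    """
    if len(ref) < 2:
        raise ValueError("reference curve needs at least 2 samples")
    centers = np.asarray(band_centers_nm, dtype=float)
    inside = (centers >= ref.wavelengths_nm[0]) & (centers <= ref.wavelengths_nm[-1])
    kept = np.flatnonzero(inside)
    excluded = np.flatnonzero(~inside)
    if kept.size == 0:
        raise ValueError(
            "no band centers fall inside the reference curve's wavelength range"
        )
    values = np.interp(centers[kept], ref.wavelengths_nm, ref.values)
    return ResampledReference(
        SpectralCurve(centers[kept], values, ref.label), kept, excluded
    )


def _common(measured: SpectralCurve, ref: SpectralCurve) -> tuple[np.ndarray, np.ndarray]:
    if len(measured) != len(ref) or not np.allclose(
        measured.wavelengths_nm, ref.wavelengths_nm
    ):
        raise ValueError("curves must share a common wavelength sampling")
    return measured.values, ref.values


def scale_align(measured: SpectralCurve, ref: SpectralCurve) -> float:
    """Least-squares gain ``g`` minimizing ``sum((measured - g*ref)^2)``.

    The closed form is ``<measured, ref> / <ref, ref>``.  The gain is
    returned, not applied: relative-reflectance systems apply one gain,
    fitted on a single tissue or tile, to every curve.
    """
    m, r = _common(measured, ref)
    denom = float(np.dot(r, r))
    if denom == 0.0:
        raise ValueError("cannot align against an identically zero reference")
    return float(np.dot(m, r) / denom)


def spectral_rmse(measured: SpectralCurve, ref: SpectralCurve) -> float:
    """Percent RMSE between two curves on common wavelengths.

    Reflectance on the 0-1 scale; a constant difference of 0.02 at every
    band gives 2.00%.
    """
    m, r = _common(measured, ref)
    return float(100.0 * np.sqrt(np.mean((m - r) ** 2)))


@dataclass
class RmseSummary:
    mean: float
    sd: float
    n: int
    sd_defined: bool  # False when n == 1 (SD reported as 0 with this flag)

    def rounded(self) -> tuple[float, float]:
        return float(np.round(self.mean, 2)), float(np.round(self.sd, 2))


def rmse_table(per_tile_rmse: np.ndarray) -> RmseSummary:
    """Mean and sample standard deviation (n-1 denominator) of per-tile RMSEs."""
    x = np.asarray(per_tile_rmse, dtype=float)
    if x.size == 0:
        raise ValueError("rmse_table needs at least one value")
    if x.size == 1:
        return RmseSummary(float(x[0]), 0.0, 1, sd_defined=False)
    return RmseSummary(float(x.mean()), float(x.std(ddof=1)), int(x.size), True)
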