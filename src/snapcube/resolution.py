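"""Spatial-resolution metrology on USAF-1951 bar targets.

An intensity profile is taken across a three-bar element, a sinusoid
``offset + amplitude * sin(2*pi*f*x + phi)`` is fitted, and the Michelson
contrast ``(Smax - Smin) / (Smax + Smin)`` of the fit decides whether the
element counts as resolved (contrast >= 20% by default, inclusive).  The
smallest resolved element, converted to a line width in millimeters via the
standard USAF-1951 geometry, is the reported resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.measure import profile_line

__all__ = [
    "SineFitResult",
    "UsafElement",
    "ElementProbe",
    "ResolutionReport",
    "FitError",
    "michelson_contrast",
    "fit_sine_profile",
    "usaf_linewidth_mm",
    "usaf_lp_per_mm",
    "resolution_limit",
]


class FitError(RuntimeError):
    """Sine fit failed to converge; carries the offending profile stats."""


@dataclass(frozen=True)
class SineFitResult:
    amplitude: float
    offset: float
    frequency: float  # cycles / pixel
    phase: float
    rms_residual: float

    @property
    def smax(self) -> float:
        return self.offset + self.amplitude

    @property
    def smin(self) -> float:
        return self.offset - self.amplitude

    @property
    def contrast(self) -> float:
        return michelson_contrast(self.smax, self.smin)


@dataclass(frozen=True, order=True)
class UsafElement:
    """One element of the USAF-1951 chart: (group, element 1..6)."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if not 1 <= self.element <= 6:
            raise ValueError("USAF element index must be in 1..6")

    def __str__(self) -> str:
        return f"g{self.group}e{self.element}"


def michelson_contrast(smax: float, smin: float) -> float:
    """Modulation depth ``(Smax - Smin) / (Smax + Smin)``."""
    if smax < smin:
        raise ValueError("smax must be >= smin")
    total = smax + smin
    if total <= 0:
        raise ValueError("smax + smin must be positive")
    return (smax - smin) / total


def usaf_lp_per_mm(e: UsafElement) -> float:
    """Spatial resolution of a USAF element in line pairs per millimeter:
    ``2^(group + (element - 1) / 6)``."""
    return 2.0 ** (e.group + (e.element - 1) / 6.0)


def usaf_linewidth_mm(e: UsafElement) -> float:
    """Bar width in mm: half the line-pair pitch, ``1 / (2 * lp_per_mm)``.

    Full precision is returned; reports round to 3 decimals (half-even).
    """
    return 1.0 / (2.0 * usaf_lp_per_mm(e))


def _sine(x, offset, amplitude, freq, phase):
    return offset + amplitude * np.sin(2.0 * np.pi * freq * x + phase)


def fit_sine_profile(profile: np.ndarray, expected_freq: float) -> SineFitResult:
    """Nonlinear least-squares sinusoid fit to a bar-profile intensity trace.

    Initialized at the geometric bar frequency with amplitude
    ``(max - min) / 2`` and offset at the mean; the amplitude is constrained
    nonnegative.  The frequency is left free so small scale errors in the
    assumed geometry do not bias the contrast.
    """
    y = np.asarray(profile, dtype=np.float64)
    if y.ndim != 1 or y.size < 8:
        raise ValueError("profile must be a 1D vector of length >= 8")
    if not 0 < expected_freq < 0.5:
        raise ValueError("expected_freq must be in (0, 0.5) cycles/pixel")
    x = np.arange(y.size, dtype=np.float64)
    amp0 = 0.5 * (y.max() - y.min())
    off0 = float(y.mean())
    if amp0 == 0.0:  # constant profile: the zero-amplitude fit is exact
        return SineFitResult(0.0, off0, expected_freq, 0.0, 0.0)
    # Coarse phase search keeps the optimizer out of the phase-flipped
    # local minimum.
    phases = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    trial_resid = [
        np.sum((y - _sine(x, off0, amp0, expected_freq, ph)) ** 2) for ph in phases
    ]
    ph0 = float(phases[int(np.argmin(trial_resid))])
    try:
        popt, _ = curve_fit(
            _sine,
            x,
            y,
            p0=[off0, amp0, expected_freq, ph0],
            bounds=(
                [-np.inf, 0.0, expected_freq / 3.0, -np.inf],
                [np.inf, np.inf, min(3.0 * expected_freq, 0.5), np.inf],
            ),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(
            f"sine fit did not converge (n={y.size}, f0={expected_freq:.4f}, "
            f"range=[{y.min():.4g}, {y.max():.4g}])"
        ) from exc
    offset, amplitude, freq, phase = popt
    resid = y - _sine(x, *popt)
    return SineFitResult(
        amplitude=float(amplitude),
        offset=float(offset),
        frequency=float(freq),
        phase=float(phase % (2 * np.pi)),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass(frozen=True)
class ElementProbe:
    """Where and how to measure one USAF element in an image.

    ``segment`` is ``((r0, c0), (r1, c1))`` in pixel coordinates, running
    perpendicular to the bars; ``orientation`` labels the bar direction
    ('horizontal' bars are probed vertically and vice versa).
    """

    element: UsafElement
    segment: tuple[tuple[float, float], tuple[float, float]]
    orientation: str  # "horizontal" | "vertical"


@dataclass
class ResolutionReport:
    """Per-orientation resolution-limit search outcome."""

    limit: dict[str, UsafElement | None]
    limit_mm: dict[str, float | None]
    contrasts: dict[str, list[tuple[UsafElement, float]]]
    threshold: float

    def resolved(self, orientation: str) -> bool:
        return self.limit.get(orientation) is not None


def _round3(x: float) -> float:
    # round-half-even at 3 decimals, matching report formatting
    return float(np.round(x, 3))


def resolution_limit(
    image: np.ndarray,
    probes: list[ElementProbe],
    mm_per_pixel: float,
    threshold: float = 0.20,
) -> ResolutionReport:
    """Find the finest USAF element with fitted contrast >= ``threshold``.

    Probes must be ordered coarse -> fine per orientation.  For each probe
    the pixel profile along its segment is extracted, a sinusoid is fitted
    at the element's geometric frequency, and its Michelson contrast is
    compared with the cutoff (inclusive).  Orientations are searched
    independently; an orientation where no element passes reports ``None``
    (unresolved at the coarsest element).
    """
    img = np.asarray(image, dtype=np.float64)
    limit: dict[str, UsafElement | None] = {}
    limit_mm: dict[str, float | None] = {}
    contrasts: dict[str, list[tuple[UsafElement, float]]] = {}
    for probe in probes:
        ori = probe.orientation
        contrasts.setdefault(ori, [])
        width_px = usaf_linewidth_mm(probe.element) / mm_per_pixel
        freq = 1.0 / (2.0 * width_px)  # one line pair spans two bar widths
        (r0, c0), (r1, c1) = probe.segment
        prof = profile_line(img, (r0, c0), (r1, c1), mode="reflect", order=1)
        fit = fit_sine_profile(prof, expected_freq=freq)
        # Fitted Smin below zero (sine overshoot on square-wave bars) is
        # unphysical for intensities; clamp the contrast into [0, 1].
        c = min(fit.contrast, 1.0) if fit.smax + fit.smin > 0 else 0.0
        contrasts[ori].append((probe.element, c))
        if c >= threshold:
            limit[ori] = probe.element
            limit_mm[ori] = _round3(usaf_linewidth_mm(probe.element))
    for ori in contrasts:
        limit.setdefault(ori, None)
        limit_mm.setdefault(ori, None)
    return ResolutionReport(limit, limit_mm, contrasts, threshold)
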