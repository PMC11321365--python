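"""Pseudo-RGB rendering from reflectance hypercubes.

The three output channels are the hyperspectral bands nearest to the CIE
primary wavelengths 700.0 nm (R), 546.1 nm (G) and 435.8 nm (B).  Cameras
whose range does not reach a target simply use their nearest band (e.g. a
visible camera ending at 597 nm renders "red" from its longest band).
"""

from __future__ import annotations

import numpy as np

from .formats_io import Hypercube

__all__ = ["RGB_TARGETS_NM", "nearest_band", "pseudo_rgb"]

RGB_TARGETS_NM: tuple[float, float, float] = (700.0, 546.1, 435.8)


def nearest_band(band_centers_nm: np.ndarray, target_nm: float) -> int:
    """Index of the band center closest to ``target_nm``; ties pick the
    lower index."""
    centers = np.asarray(band_centers_nm, dtype=float)
    if centers.size < 1:
        raise ValueError("need at least one band")
    return int(np.argmin(np.abs(centers - target_nm)))


def pseudo_rgb(
    cube: Hypercube,
    targets_nm: tuple[float, float, float] = RGB_TARGETS_NM,
    stretch: bool = False,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Build an (h, w, 3) image from the bands nearest the RGB targets.

    Channels are clipped to [0, 1]; no white balance or gamma is applied.
    ``stretch=True`` applies a 1st-99th percentile contrast stretch for
    display.  Returns the image and the selected band indices (R, G, B).
    """
    if cube.kind != "reflectance":
        raise ValueError("pseudo_rgb expects a reflectance cube")
    idx = tuple(nearest_band(cube.band_centers_nm, t) for t in targets_nm)
    img = np.stack([cube.data[:, :, i] for i in idx], axis=2)
    img = np.clip(np.nan_to_num(img, nan=0.0), 0.0, 1.0)
    if stretch:
        lo, hi = np.percentile(img, [1.0, 99.0])
        if hi > lo:
            img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    return img, idx  # type: ignore[return-value]
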