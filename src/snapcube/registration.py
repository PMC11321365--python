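"""Dual-camera alignment.

Two snapshot cameras behind a dichroic mirror see the same field through
slightly different optics.  Alignment proceeds by collapsing each hypercube
to a grayscale spectral-mean image, binarizing at a user-chosen threshold to
form masks, picking paired control points, estimating a 2D affine transform
by least squares, and warping every band of the source (red/NIR) cube onto
the destination (VIS) cube's grid.

Coordinates are 0-based (row, col) pixel centers; the transform maps source
coordinates to destination coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .formats_io import Hypercube

__all__ = [
    "AffineTransform",
    "EstimationError",
    "spectral_mean_image",
    "binarize",
    "estimate_affine",
    "apply_affine",
]


class EstimationError(ValueError):
    """Raised when control points cannot determine an affine transform."""


@dataclass(frozen=True)
class AffineTransform:
    """2D affine map ``dst = A @ src + t`` stored as a 2x3 matrix [A | t]."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform(
            np.hstack([Ainv, (-Ainv @ self.translation)[:, None]])
        )

    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.hstack([np.eye(2), np.zeros((2, 1))]))


def spectral_mean_image(cube: Hypercube) -> np.ndarray:
    """Per-pixel mean over bands; invalid (NaN) bands excluded pixel-wise."""
    if cube.n_bands < 1:
        raise ValueError("cube has no bands")
    data = np.asarray(cube.data, dtype=np.float64)
    valid = np.isfinite(data)
    counts = valid.sum(axis=2)
    sums = np.where(valid, data, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground mask ``image >= threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(image) >= threshold


def estimate_affine(src_points: np.ndarray, dst_points: np.ndarray) -> AffineTransform:
    """Least-squares affine fit ``dst ~= A @ src + t`` from paired points.

    Exact for 3 non-collinear pairs; with more pairs the residual is
    minimized in the least-squares sense.  Collinear or insufficient points
    raise :class:`EstimationError`.
    """
    src = np.atleast_2d(np.asarray(src_points, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_points, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise EstimationError("need matching (N, 2) source and destination points")
    if src.shape[0] < 3:
        raise EstimationError("need at least 3 control-point pairs")
    X = np.hstack([src, np.ones((src.shape[0], 1))])  # (N, 3)
    if np.linalg.matrix_rank(X) < 3:
        raise EstimationError("control points are collinear/degenerate")
    coeffs, *_ = np.linalg.lstsq(X, dst, rcond=None)  # (3, 2)
    return AffineTransform(coeffs.T)


def apply_affine(
    cube: Hypercube,
    transform: AffineTransform,
    out_shape: tuple[int, int] | None = None,
    order: int = 1,
) -> Hypercube:
    """Warp every band of a cube with the same source->destination affine.

    Each destination pixel is pulled from the source via the inverse map
    with bilinear interpolation (``order=1``; use 0 for nearest-neighbor
    masks).  Destination pixels that map outside the source domain are
    invalid (NaN).
    """
    if out_shape is None:
        out_shape = cube.spatial_shape
    inv = transform.inverse()
    rr, cc = np.meshgrid(
        np.arange(out_shape[0], dtype=float),
        np.arange(out_shape[1], dtype=float),
        indexing="ij",
    )
    src_coords = inv.apply_points(np.column_stack([rr.ravel(), cc.ravel()]))
    coords = [src_coords[:, 0].reshape(out_shape), src_coords[:, 1].reshape(out_shape)]
    out = np.empty(out_shape + (cube.n_bands,), dtype=np.float64)
    for b in range(cube.n_bands):
        out[:, :, b] = ndimage.map_coordinates(
            np.asarray(cube.data[:, :, b], dtype=np.float64),
            coords,
            order=order,
            mode="constant",
            cval=np.nan,
        )
    return Hypercube(out, cube.band_centers_nm, cube.kind)
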