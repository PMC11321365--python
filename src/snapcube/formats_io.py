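"""Raster and spectrum I/O.

Conventions used throughout the toolkit:

* pixel coordinates are 0-based ``(row, col)`` with the origin top-left;
* raw frames whose dimensions are not divisible by the mosaic period are
  cropped by dropping trailing rows/columns, preserving the mosaic phase
  anchored at (0, 0);
* hypercubes serialize either as a multi-page TIFF (one band per page,
  ascending wavelength, float32 for reflectance / uint16 for raw counts)
  with a JSON sidecar for band metadata, or as an ENVI BSQ pair
  (plain-text ``.hdr`` + raw ``.dat``);
* spectra are two-column CSV (wavelength nm, reflectance).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from .sensor_model import CameraSpec

__all__ = [
    "RawMosaicFrame",
    "Hypercube",
    "SpectralCurve",
    "FormatError",
    "read_frame_sequence",
    "write_frame_sequence",
    "write_hypercube",
    "read_hypercube",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk inputs."""


@dataclass
class RawMosaicFrame:
    """Full-resolution 2D sensor raster carrying the mosaic pattern."""

    pixels: np.ndarray  # (H, W), nonnegative
    camera: CameraSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise FormatError(f"raw frame must be 2D, got shape {px.shape}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Hypercube:
    """(rows x cols x bands) spectral image volume."""

    data: np.ndarray
    band_centers_nm: np.ndarray
    kind: str = "raw_intensity"  # or "reflectance"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        centers = np.asarray(self.band_centers_nm, dtype=float)
        if data.ndim != 3:
            raise FormatError(f"hypercube must be 3D, got shape {data.shape}")
        if data.shape[2] != centers.size:
            raise FormatError(
                f"{data.shape[2]} bands in volume but {centers.size} band centers"
            )
        if self.kind not in ("raw_intensity", "reflectance"):
            raise FormatError(f"unknown hypercube kind {self.kind!r}")
        self.data = data
        self.band_centers_nm = centers

    @property
    def n_bands(self) -> int:
        return int(self.band_centers_nm.size)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class SpectralCurve:
    """Wavelength-indexed reflectance vector (camera or spectrometer)."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or w.shape != v.shape:
            raise FormatError("wavelengths and values must be equal-length 1D vectors")
        if np.any(np.diff(w) <= 0):
            raise FormatError("wavelengths must be strictly ascending")
        self.wavelengths_nm = w
        self.values = v

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


# ---------------------------------------------------------------------------
# Raw frame sequences
# ---------------------------------------------------------------------------


def _crop_to_period(pixels: np.ndarray, period: int, origin: str) -> np.ndarray:
    h, w = pixels.shape
    h2, w2 = h - h % period, w - w % period
    if (h2, w2) != (h, w):
        log.warning(
            "%s: %dx%d raster not divisible by mosaic period %d; cropping to %dx%d",
            origin, h, w, period, h2, w2,
        )
    return pixels[:h2, :w2]


def read_frame_sequence(
    path: str | Path | Sequence[str | Path], camera: CameraSpec
) -> list[RawMosaicFrame]:
    """Read raw mosaic frames from one multi-page TIFF or a list of TIFFs.

    Frames are returned in page order (and filename order across files).
    Rasters not divisible by the mosaic period are cropped to the nearest
    multiple, keeping the top-left origin, with a logged warning.
    """
    paths = [Path(path)] if isinstance(path, (str, Path)) else [Path(p) for p in path]
    frames: list[RawMosaicFrame] = []
    for p in paths:
        if not p.exists():
            raise FormatError(f"frame file not found: {p}")
        stack = tifffile.imread(p)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise FormatError(f"{p}: expected single-channel grayscale pages")
        # A trailing length-3/4 axis means RGB(A) pages, which a mosaic
        # sensor never produces.
        if stack.shape[-1] in (3, 4) and stack.shape[-1] < min(stack.shape[:-1]):
            raise FormatError(f"{p}: multi-channel (color) input is not a mosaic frame")
        for i, page in enumerate(stack):
            px = _crop_to_period(np.asarray(page), camera.layout.period, f"{p}[{i}]")
            frames.append(RawMosaicFrame(px, camera, {"source": f"{p}", "page": i}))
    if not frames:
        raise FormatError("empty frame sequence")
    return frames


def write_frame_sequence(
    frames: Iterable[RawMosaicFrame], path: str | Path, dtype=np.uint16
) -> None:
    stack = np.stack([np.asarray(f.pixels) for f in frames])
    if np.issubdtype(np.dtype(dtype), np.integer):
        stack = np.clip(np.rint(stack), 0, np.iinfo(dtype).max)
    tifffile.imwrite(Path(path), stack.astype(dtype))


# ---------------------------------------------------------------------------
# Hypercubes: TIFF stack + JSON sidecar, or ENVI BSQ
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_hypercube(cube: Hypercube, path: str | Path, dialect: str = "tiff_stack") -> None:
    """Serialize a cube; ``dialect`` is ``tiff_stack`` or ``envi``."""
    path = Path(path)
    data = cube.data
    if cube.kind == "reflectance":
        data = data.astype(np.float32)
    elif not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    if dialect == "tiff_stack":
        tifffile.imwrite(path, np.moveaxis(data, 2, 0))
        _sidecar(path).write_text(
            json.dumps(
                {
                    "band_centers_nm": cube.band_centers_nm.tolist(),
                    "kind": cube.kind,
                },
                indent=2,
                sort_keys=True,
            )
        )
    elif dialect == "envi":
        hdr = path.with_suffix(".hdr")
        dat = path.with_suffix(".dat")
        h, w, b = data.shape
        code = _ENVI_CODES[data.dtype]
        hdr.write_text(
            "ENVI\n"
            f"description = {{snapcube {cube.kind} cube}}\n"
            f"samples = {w}\nlines = {h}\nbands = {b}\n"
            "header offset = 0\nfile type = ENVI Standard\n"
            f"data type = {code}\ninterleave = bsq\nbyte order = 0\n"
            "wavelength units = nm\n"
            "wavelength = {" + ", ".join(f"{c:.10g}" for c in cube.band_centers_nm) + "}\n"
        )
        np.moveaxis(data, 2, 0).tofile(dat)  # BSQ: band, line, sample
    else:
        raise FormatError(f"unknown hypercube dialect {dialect!r}")


def _parse_envi_header(text: str) -> dict:
    # Collapse {...} groups onto one line, then read key = value pairs.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip().lower()] = v.strip()
    return fields


def read_hypercube(path: str | Path) -> Hypercube:
    """Read a cube written by :func:`write_hypercube` (either dialect)."""
    path = Path(path)
    if path.suffix.lower() in (".hdr", ".dat") or path.with_suffix(".hdr").exists():
        hdr = path.with_suffix(".hdr")
        dat = path.with_suffix(".dat")
        if not hdr.exists():
            raise FormatError(f"missing ENVI header {hdr}")
        f = _parse_envi_header(hdr.read_text())
        try:
            h, w, b = int(f["lines"]), int(f["samples"]), int(f["bands"])
            dtype = _ENVI_DTYPES[int(f["data type"])]
        except KeyError as exc:
            raise FormatError(f"{hdr}: incomplete ENVI header ({exc})") from exc
        if f.get("interleave", "bsq").lower() != "bsq":
            raise FormatError(f"{hdr}: only BSQ interleave is supported")
        wl_m = re.search(r"\{([^}]*)\}", f.get("wavelength", ""))
        centers = (
            np.array([float(x) for x in wl_m.group(1).split(",")])
            if wl_m
            else np.arange(b, dtype=float)
        )
        data = np.fromfile(dat, dtype=dtype)
        if data.size != h * w * b:
            raise FormatError(f"{dat}: size does not match header dimensions")
        data = np.moveaxis(data.reshape(b, h, w), 0, 2)
        desc = f.get("description", "")
        kind = "reflectance" if "reflectance" in desc else "raw_intensity"
        return Hypercube(data, centers, kind)
    # TIFF stack
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        centers = np.asarray(meta["band_centers_nm"], dtype=float)
        kind = meta.get("kind", "raw_intensity")
    else:
        centers = np.arange(pages.shape[0], dtype=float)
        kind = "raw_intensity"
    return Hypercube(np.moveaxis(pages, 0, 2), centers, kind)


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def read_spectrum_csv(path: str | Path, label: str | None = None) -> SpectralCurve:
    """Read a two-column (wavelength nm, reflectance) CSV; header optional.

    Rows are sorted ascending by wavelength; duplicate wavelengths are an
    error because they make the curve ambiguous.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = re.split(r"[,;\t]\s*|\s+", line)
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            if ln == 1:
                continue  # header row
            raise FormatError(f"{path}:{ln}: non-numeric spectrum row {line!r}")
    if len(rows) < 2:
        raise FormatError(f"{path}: a spectrum needs at least 2 samples")
    arr = np.array(sorted(rows))
    if np.any(np.diff(arr[:, 0]) == 0):
        raise FormatError(f"{path}: duplicate wavelengths in spectrum")
    return SpectralCurve(arr[:, 0], arr[:, 1], label or path.stem)


def write_spectrum_csv(curve: SpectralCurve, path: str | Path) -> None:
    lines = ["wavelength_nm,reflectance"]
    lines += [f"{w:.6g},{v:.8g}" for w, v in zip(curve.wavelengths_nm, curve.values)]
    Path(path).write_text("\n".join(lines) + "\n")
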