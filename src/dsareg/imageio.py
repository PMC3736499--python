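"""Image containers, raster I/O and normalization primitives.

Images are plain 2-D ``float64`` numpy arrays throughout the package
("GrayImage"): single channel, value range [0, 255] at I/O boundaries,
0-based pixel-centered coordinates with ``(x, y) = (column, row)``.
Quantization to 8 bits happens only on write; all processing is floating
point.  A cine sequence is a 3-D ``(K, H, W)`` array of frames.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image
import tifffile

__all__ = [
    "read_image",
    "write_image",
    "normalize01",
    "as_gray_image",
    "read_sequence",
    "write_sequence",
]

#: ITU-R 601 luminance weights used by Pillow's "L" conversion.
_LUMA = (0.299, 0.587, 0.114)


def as_gray_image(arr) -> np.ndarray:
    """Validate and coerce ``arr`` into a 2-D float64 image array."""
    img = np.asarray(arr, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have positive width and height")
    return img


def read_image(path) -> np.ndarray:
    """Read a raster image as a grayscale float array in [0, 255].

    PNG and TIFF (and anything Pillow decodes) are supported; multi-channel
    inputs are converted by standard luminance weighting.  DICOM files
    (``.dcm``) are read through :mod:`pydicom` when it is installed.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() == ".dcm":
        return _read_dicom(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "I;16", "I", "F"):
                im = im.convert("L")
            img = np.asarray(im, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001 - normalize decoder errors
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if img.ndim != 2 or img.size == 0:
        raise IOError(f"{path}: not a non-empty single-channel raster")
    return img


def _read_dicom(path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise IOError("reading DICOM requires the optional pydicom dependency") from exc
    ds = pydicom.dcmread(path)
    img = np.asarray(ds.pixel_array, dtype=np.float64)
    if img.ndim == 3:
        img = img @ np.asarray(_LUMA)
    lo, hi = img.min(), img.max()
    if hi > 255 or lo < 0:  # rescale deeper bit depths into the 8-bit range
        img = np.zeros_like(img) if hi == lo else (img - lo) * (255.0 / (hi - lo))
    return img


def write_image(img, path) -> None:
    """Write ``img`` as an 8-bit grayscale PNG/TIFF, clamping to [0, 255].

    Integer-valued arrays round-trip bit exactly through
    :func:`read_image`.
    """
    img = as_gray_image(img)
    data = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    path = Path(path)
    try:
        Image.fromarray(data, mode="L").save(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot write image {path}: {exc}") from exc


def normalize01(img) -> np.ndarray:
    """Affinely map an image onto [0, 1]; constant images map to all zeros.

    The degenerate all-zero convention means a featureless map produces no
    candidate control points downstream.
    """
    img = as_gray_image(img)
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def read_sequence(path) -> np.ndarray:
    """Read a cine sequence from a multi-page TIFF or a directory of frames.

    Returns a ``(K, H, W)`` float array; all frames must share dimensions.
    """
    path = Path(path)
    if path.is_dir():
        names = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not names:
            raise IOError(f"no frames found in {path}")
        frames = [read_image(p) for p in names]
    else:
        stack = tifffile.imread(os.fspath(path))
        if stack.ndim == 2:
            stack = stack[None]
        frames = [np.asarray(f, dtype=np.float64) for f in stack]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"frames have inconsistent shapes: {sorted(shapes)}")
    return np.stack(frames)


def write_sequence(frames, path) -> None:
    """Write a ``(K, H, W)`` sequence as an 8-bit multi-page TIFF."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("sequence must be a non-empty (K, H, W) stack")
    data = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(os.fspath(path), data)
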