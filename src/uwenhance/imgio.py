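"""Raster I/O and colour-space conversions.

Every stage of the enhancement pipeline consumes and produces ``ImageRGB``:
an ``H x W x 3`` float array with intensities in ``[0, 1]``.  This module is
the only place where files and integer pixel formats are touched.

Conventions (fixed so that downstream metric values are reproducible):

* sRGB primaries, D65 white point for CIELab,
* HSV hue stored as a fraction of a turn in ``[0, 1)``,
* 8-bit quantization on write uses round-half-up.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
from skimage import color


class ImageFormatError(ValueError):
    """Raised when a file cannot be decoded as a supported raster image."""


_SUPPORTED_EXT = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def validate_image(img: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Check ImageRGB invariants: H x W x 3, finite, within [0, 1]."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name}: expected H x W x 3 array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name}: empty image")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name}: non-finite pixel values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name}: values outside [0, 1]")
    return arr


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file into an ImageRGB.

    8-bit data is scaled by 1/255, 16-bit by 1/65535.  Grayscale files are
    replicated to three channels; an alpha channel is silently dropped
    (the pipeline is RGB-only).
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise ImageFormatError(f"unsupported image format: {path!r}")
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # codec-level failure
        raise ImageFormatError(f"cannot decode {path!r}: {exc}") from exc

    if raw.dtype == np.uint8:
        arr = raw.astype(float) / 255.0
    elif raw.dtype == np.uint16:
        arr = raw.astype(float) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        arr = np.clip(raw.astype(float), 0.0, 1.0)
    else:
        raise ImageFormatError(f"unsupported pixel dtype {raw.dtype} in {path!r}")

    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = np.repeat(arr[:, :, :1], 3, axis=2)
    return validate_image(arr, name=path)


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize [0, 1] intensities to 8 bits, rounding half up."""
    arr = np.asarray(img, dtype=float)
    return np.clip(np.floor(arr * 255.0 + 0.5), 0, 255).astype(np.uint8)


def write_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an ImageRGB to disk as an 8-bit file (format from extension)."""
    arr = validate_image(img)
    iio.imwrite(os.fspath(path), to_uint8(arr))


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """RGB -> HSV with hue in [0, 1) as a fraction of a turn; S, V in [0, 1]."""
    return color.rgb2hsv(validate_image(img))


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv`; round-trip error is below 1e-6."""
    return np.clip(color.hsv2rgb(np.asarray(hsv, dtype=float)), 0.0, 1.0)


def luminance(img: np.ndarray) -> np.ndarray:
    """Luminance channel L: the plain per-pixel mean of R, G and B."""
    return validate_image(img).mean(axis=2)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """RGB -> CIELab (sRGB/D65). L* in [0, 100]; neutral grays map to a*=b*=0."""
    return color.rgb2lab(validate_image(img))
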