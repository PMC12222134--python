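"""Multi-weight pyramid fusion.

The final stage blends the Retinex-recovered image with the
contrast-enhanced image.  Three per-pixel weight maps are computed for
each input:

* contrast weight — absolute 3x3 Laplacian response of the luminance
  (edges and texture),
* brightness weight — RMS deviation of the R, G, B channels from the
  luminance (well-exposed colourful pixels score high),
* saliency weight — absolute difference between the Gaussian-smoothed
  luminance and its global mean (regions that stand out from the scene).

The weights are summed per input and normalized across inputs (with a
small delta so flat regions still get a defined 50/50 split).  Blending
happens per level of a Laplacian pyramid of the inputs against a Gaussian
pyramid of the weights, which avoids seams that direct per-pixel blending
would produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgio import luminance, validate_image

# 5-tap binomial kernel, the standard pyramid generator
_BINOMIAL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

DELTA = 1e-3  # weight regularizer


@dataclass(frozen=True)
class WeightStack:
    """Per-input weight maps and their cross-input normalization.

    Each attribute is a list with one H x W map per input image; the
    normalized maps sum to 1 at every pixel.
    """

    contrast: list[np.ndarray]
    brightness: list[np.ndarray]
    saliency: list[np.ndarray]
    combined: list[np.ndarray]
    normalized: list[np.ndarray]


def contrast_weight(img: np.ndarray) -> np.ndarray:
    """Absolute response of a 3x3 Laplacian on the luminance (reflect borders)."""
    lum = luminance(img)
    lap = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
    return np.abs(ndimage.correlate(lum, lap, mode="reflect"))


def brightness_weight(img: np.ndarray) -> np.ndarray:
    """RMS deviation of R, G, B from the luminance channel."""
    arr = validate_image(img)
    lum = arr.mean(axis=2)
    dev = arr - lum[:, :, None]
    return np.sqrt((dev**2).mean(axis=2))


def saliency_weight(img: np.ndarray, sigma: float = 5.0) -> np.ndarray:
    """|Gaussian-smoothed luminance - global mean luminance|."""
    lum = luminance(img)
    smooth = ndimage.gaussian_filter(lum, sigma, mode="reflect", radius=math.ceil(3 * sigma))
    return np.abs(smooth - lum.mean())


def normalize_weight_stack(inputs: list[np.ndarray]) -> WeightStack:
    """Compute and cross-normalize the combined weight maps of the inputs."""
    if len(inputs) < 2:
        raise ValueError("at least two inputs required for fusion weights")
    shapes = {np.asarray(x).shape for x in inputs}
    if len(shapes) != 1:
        raise ValueError(f"input shape mismatch: {shapes}")
    wc = [contrast_weight(x) for x in inputs]
    wl = [brightness_weight(x) for x in inputs]
    ws = [saliency_weight(x) for x in inputs]
    combined = [c + l + s for c, l, s in zip(wc, wl, ws)]
    denom = sum(combined) + len(inputs) * DELTA
    normalized = [(w + DELTA) / denom for w in combined]
    return WeightStack(wc, wl, ws, combined, normalized)


def max_pyramid_depth(shape: tuple[int, int]) -> int:
    return int(math.floor(math.log2(min(shape[:2])))) + 1


def _smooth(x: np.ndarray) -> np.ndarray:
    out = ndimage.correlate1d(x, _BINOMIAL, axis=0, mode="reflect")
    return ndimage.correlate1d(out, _BINOMIAL, axis=1, mode="reflect")


def _down(x: np.ndarray) -> np.ndarray:
    return _smooth(x)[::2, ::2]


def _up(x: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    # mirror (edge-centred) extension: with zero-stuffed input, symmetric
    # padding would duplicate the interleaved zeros at the border and
    # break the constant-image identity
    out = np.zeros(shape + x.shape[2:], dtype=float)
    out[::2, ::2] = x
    out = ndimage.correlate1d(out, 2.0 * _BINOMIAL, axis=0, mode="mirror")
    return ndimage.correlate1d(out, 2.0 * _BINOMIAL, axis=1, mode="mirror")


def _check_depth(shape, depth):
    if depth < 1:
        raise ValueError("depth must be >= 1")
    feasible = max_pyramid_depth(shape)
    if depth > feasible:
        raise ValueError(f"image {shape[:2]} supports a pyramid depth of at most {feasible}, got {depth}")


def gaussian_pyramid(raster: np.ndarray, depth: int = 5) -> list[np.ndarray]:
    """Smooth-then-decimate pyramid; level l has shape ceil(level_{l-1} / 2)."""
    x = np.asarray(raster, dtype=float)
    _check_depth(x.shape, depth)
    levels = [x]
    for _ in range(depth - 1):
        levels.append(_down(levels[-1]))
    return levels


def laplacian_pyramid(raster: np.ndarray, depth: int = 5) -> list[np.ndarray]:
    """Band-pass pyramid: level l = G_l - upsample(G_{l+1}); last level is G_last."""
    g = gaussian_pyramid(raster, depth)
    levels = [g[i] - _up(g[i + 1], g[i].shape[:2]) for i in range(depth - 1)]
    levels.append(g[-1])
    return levels


def collapse_pyramid(levels: list[np.ndarray]) -> np.ndarray:
    """Invert :func:`laplacian_pyramid` exactly (up to float rounding)."""
    out = levels[-1]
    for lev in reversed(levels[:-1]):
        out = lev + _up(out, lev.shape[:2])
    return out


def pyramid_fuse(inputs: list[np.ndarray], stack: WeightStack | None = None, depth: int = 5) -> np.ndarray:
    """Blend the inputs level-by-level under their normalized weight maps.

    Fused Laplacian level l = sum_k L_l(input_k) * G_l(weight_k); the
    result is collapsed and clipped to [0, 1].  A single input is
    returned unchanged (degenerate mode: its weight renormalizes to 1).
    """
    if len(inputs) == 1:
        return np.clip(np.asarray(inputs[0], dtype=float), 0.0, 1.0)
    stack = stack or normalize_weight_stack(inputs)
    if len(stack.normalized) != len(inputs):
        raise ValueError("weight stack does not match inputs")
    fused = None
    for img, wmap in zip(inputs, stack.normalized):
        lap = laplacian_pyramid(np.asarray(img, dtype=float), depth)
        wpyr = gaussian_pyramid(wmap, depth)
        contrib = [l * w[:, :, None] for l, w in zip(lap, wpyr)]
        fused = contrib if fused is None else [f + c for f, c in zip(fused, contrib)]
    return np.clip(collapse_pyramid(fused), 0.0, 1.0)
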