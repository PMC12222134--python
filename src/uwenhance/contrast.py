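"""Contrast enhancement: CLAHE followed by adaptive gamma correction.

Operates on the V channel of HSV (hue and saturation are never touched).
CLAHE equalizes clipped per-tile histograms with bilinear blending between
tile mappings; the adaptive gamma correction then applies

    T(l) = l_max * (l / l_max) ** (1 - cdf_w(l))

where cdf_w is the cumulative form of a weighted histogram distribution

    pdf_w(l) = pdf_max * ((pdf(l) - pdf_min) / (pdf_max - pdf_min)) ** alpha

so that frequent low intensities are raised gradually while high
intensities are not crushed.  ``alpha`` (default 0.5) softens the
weighting; a uniform histogram (pdf_max == pdf_min) degenerates to the
ordinary cdf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imgio import hsv_to_rgb, rgb_to_hsv, validate_image


@dataclass(frozen=True)
class ClaheParams:
    """Tile grid (rows x cols), clip limit (multiple of the uniform bin
    height) and histogram bin count."""

    tiles: tuple[int, int] = (8, 8)
    clip_limit: float = 2.0
    bins: int = 256

    def __post_init__(self):
        if self.tiles[0] < 1 or self.tiles[1] < 1:
            raise ValueError("tile grid must be at least 1 x 1")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


@dataclass(frozen=True)
class AgcCurve:
    """Adaptive gamma correction curve data for levels 0 .. l_max."""

    l_max: int
    pdf: np.ndarray
    pdf_w: np.ndarray
    cdf_w: np.ndarray
    alpha: float
    sum_pdf_w: float


def clip_redistribute(hist: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clip histogram bins and spread the excised mass uniformly.

    The cap is ``ceil(clip_limit * total / bins)``.  Redistribution can
    push bins back over the cap, so the cap-and-spread step is iterated
    while the residual excess exceeds one count.  Total mass is conserved
    exactly.
    """
    h = np.asarray(hist, dtype=float).copy()
    if (h < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    total = h.sum()
    if total == 0:
        return h
    raw_cap = clip_limit * total / h.size
    if not np.isfinite(raw_cap):  # infinite clip limit: nothing to excise
        return h
    cap = math.ceil(raw_cap)
    excess = float(np.maximum(h - cap, 0.0).sum())
    prev = np.inf
    # a cap below the mean bin height can never be satisfied; stop when the
    # excess no longer shrinks (mass is conserved at every step regardless)
    while excess > 1.0 and excess < prev - 1e-9:
        prev = excess
        np.minimum(h, cap, out=h)
        h += excess / h.size
        excess = float(np.maximum(h - cap, 0.0).sum())
    return h


def _tile_edges(n: int, parts: int) -> np.ndarray:
    """Split length n into `parts` near-equal contiguous spans; edge array of len parts+1."""
    return np.round(np.linspace(0, n, parts + 1)).astype(int)


def clahe(channel: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one channel.

    The channel is split into non-overlapping tiles; each tile's clipped
    histogram yields an equalization mapping (its cdf), and every pixel is
    remapped by bilinear interpolation between the four surrounding tile
    mappings (edge and corner pixels use the tiles that exist).
    """
    params = params or ClaheParams()
    ch = np.asarray(channel, dtype=float)
    if ch.ndim != 2:
        raise ValueError("clahe expects a single channel")
    h, w = ch.shape
    rows, cols = params.tiles
    bins = params.bins
    if h // rows < 2 or w // cols < 2:
        raise ValueError(f"tiles of {h}x{w} image on a {rows}x{cols} grid are smaller than 2x2")

    ye = _tile_edges(h, rows)
    xe = _tile_edges(w, cols)
    idx = np.clip((ch * bins).astype(int), 0, bins - 1)

    # per-tile equalization LUTs: level bin -> cdf in [0, 1]
    luts = np.empty((rows, cols, bins))
    centers_y = np.empty(rows)
    centers_x = np.empty(cols)
    for r in range(rows):
        centers_y[r] = 0.5 * (ye[r] + ye[r + 1] - 1)
        for c in range(cols):
            if r == 0:
                centers_x[c] = 0.5 * (xe[c] + xe[c + 1] - 1)
            tile = idx[ye[r] : ye[r + 1], xe[c] : xe[c + 1]]
            hist = np.bincount(tile.ravel(), minlength=bins).astype(float)
            hist = clip_redistribute(hist, params.clip_limit)
            luts[r, c] = np.cumsum(hist) / hist.sum()

    # fractional tile coordinates of every pixel (relative to tile centers)
    yy = np.arange(h, dtype=float)
    xx = np.arange(w, dtype=float)
    fy = np.interp(yy, centers_y, np.arange(rows, dtype=float))
    fx = np.interp(xx, centers_x, np.arange(cols, dtype=float))
    r0 = np.clip(np.floor(fy).astype(int), 0, rows - 1)
    r1 = np.minimum(r0 + 1, rows - 1)
    wy = (fy - r0)[:, None]
    c0 = np.clip(np.floor(fx).astype(int), 0, cols - 1)
    c1 = np.minimum(c0 + 1, cols - 1)
    wx = (fx - c0)[None, :]

    r0g = r0[:, None]
    r1g = r1[:, None]
    c0g = c0[None, :]
    c1g = c1[None, :]
    v00 = luts[np.broadcast_to(r0g, idx.shape), np.broadcast_to(c0g, idx.shape), idx]
    v01 = luts[np.broadcast_to(r0g, idx.shape), np.broadcast_to(c1g, idx.shape), idx]
    v10 = luts[np.broadcast_to(r1g, idx.shape), np.broadcast_to(c0g, idx.shape), idx]
    v11 = luts[np.broadcast_to(r1g, idx.shape), np.broadcast_to(c1g, idx.shape), idx]
    out = (1 - wy) * ((1 - wx) * v00 + wx * v01) + wy * ((1 - wx) * v10 + wx * v11)
    return np.clip(out, 0.0, 1.0)


def agc_curve_from_counts(counts: np.ndarray, alpha: float = 0.5) -> AgcCurve:
    """Build the weighted-distribution gamma curve from raw level counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    pdf = counts / total
    pmax = pdf.max()
    pmin = pdf.min()
    if pmax == pmin:  # uniform histogram: Eq. for pdf_w is 0/0
        pdf_w = pdf.copy()
    else:
        pdf_w = pmax * ((pdf - pmin) / (pmax - pmin)) ** alpha
    s = pdf_w.sum()
    cdf_w = np.cumsum(pdf_w) / s
    return AgcCurve(l_max=counts.size - 1, pdf=pdf, pdf_w=pdf_w, cdf_w=cdf_w, alpha=alpha, sum_pdf_w=float(s))


def agc_curve(channel: np.ndarray, alpha: float = 0.5, bins: int = 256) -> AgcCurve:
    """Adaptive gamma curve of a [0, 1] channel from its 256-bin histogram."""
    ch = np.asarray(channel, dtype=float)
    levels = np.clip(np.round(ch * (bins - 1)).astype(int), 0, bins - 1)
    counts = np.bincount(levels.ravel(), minlength=bins)
    return agc_curve_from_counts(counts, alpha)


def agc_transform(curve: AgcCurve) -> np.ndarray:
    """Level mapping T(l) = l_max * (l / l_max) ** (1 - cdf_w(l)).

    T(0) = 0 by the convention 0**e = 0, including when cdf_w(0) = 1.
    Returned in level units (T[l] for l = 0 .. l_max).
    """
    lmax = curve.l_max
    levels = np.arange(lmax + 1, dtype=float)
    expo = 1.0 - curve.cdf_w
    with np.errstate(divide="ignore"):
        t = lmax * (levels / lmax) ** expo
    t[0] = 0.0
    return t


def apply_agc(channel: np.ndarray, curve: AgcCurve) -> np.ndarray:
    """Apply the gamma curve to a [0, 1] channel via its quantized level."""
    t = agc_transform(curve) / curve.l_max
    levels = np.clip(np.round(np.asarray(channel, dtype=float) * curve.l_max).astype(int), 0, curve.l_max)
    return t[levels]


def enhance_contrast(
    img: np.ndarray, clahe_params: ClaheParams | None = None, alpha: float = 0.5
) -> np.ndarray:
    """CLAHE then adaptive gamma correction on the V channel of HSV.

    Hue and saturation are passed through untouched; the gamma curve is
    built from the CLAHE'd V channel itself.  Returns the image I_ACG.
    """
    arr = validate_image(img)
    hsv = rgb_to_hsv(arr)
    v = clahe(hsv[:, :, 2], clahe_params)
    v = apply_agc(v, agc_curve(v, alpha))
    out = hsv.copy()
    out[:, :, 2] = np.clip(v, 0.0, 1.0)
    return hsv_to_rgb(out)
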