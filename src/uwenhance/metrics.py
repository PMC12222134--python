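"""No-reference underwater image quality metrics: UCIQE, UIQM, AG, entropy.

These four scores quantify what underwater degradation destroys —
colourfulness, sharpness, contrast and information content — without
needing a reference image.  Conventions are fixed here because several
dialects circulate in the literature:

* **entropy** — Shannon entropy (bits) of the 256-bin histogram of the
  8-bit-quantized luminance.
* **AG** — average gradient on the 0-255 scale: per channel, the mean over
  interior pixels of sqrt((Gx^2 + Gy^2) / 2) with forward differences,
  then averaged over channels.
* **UCIQE** = 0.4680 * sigma_chroma + 0.2745 * con_lum + 0.2576 * mu_sat in
  CIELab: chroma std, (99th - 1st percentile of L*)/100 and mean
  saturation chroma / sqrt(chroma^2 + L*^2).
* **UIQM** = 0.0282 * UICM + 0.2953 * UISM + 3.5753 * UIConM, computed on
  the 0-255 scale: UICM from alpha-trimmed (alpha = 0.1) statistics of the
  opponent channels RG = R - G and YB = (R + G)/2 - B; UISM as the EME of
  Sobel-magnitude-weighted channels over 8x8 blocks with BT.601 channel
  weights; UIConM as a PLIP-free logAMEE over 8x8 blocks.  Blocks with
  zero dynamic range (or zero sum) contribute 0.

The weighting coefficients are the community-standard constants from the
metrics' source publications.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgio import luminance, read_image, rgb_to_lab, to_uint8, validate_image

UCIQE_COEFFS = (0.4680, 0.2745, 0.2576)
UIQM_COEFFS = (0.0282, 0.2953, 3.5753)
UICM_COEFFS = (-0.0268, 0.1586)
_BLOCK = 8


@dataclass(frozen=True)
class QualityReport:
    """All four scores plus the UIQM sub-scores for one image."""

    uciqe: float
    uiqm: float
    uicm: float
    uism: float
    uiconm: float
    ag: float
    entropy: float


def entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 8-bit luminance histogram."""
    gray = to_uint8(luminance(img)[..., None])[:, :, 0]
    counts = np.bincount(gray.ravel(), minlength=256).astype(float)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def average_gradient(img: np.ndarray) -> float:
    """Mean local gradient magnitude on the 0-255 scale (sharpness proxy)."""
    arr = validate_image(img) * 255.0
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("average_gradient needs at least a 2x2 image")
    vals = []
    for c in range(3):
        ch = arr[:, :, c]
        gx = ch[:-1, 1:] - ch[:-1, :-1]
        gy = ch[1:, :-1] - ch[:-1, :-1]
        vals.append(np.sqrt((gx**2 + gy**2) / 2.0).mean())
    return float(np.mean(vals))


def uciqe(img: np.ndarray) -> float:
    """Chroma-dispersion / luminance-contrast / saturation combination."""
    lab = rgb_to_lab(img)
    lstar = lab[:, :, 0]
    chroma = np.sqrt(lab[:, :, 1] ** 2 + lab[:, :, 2] ** 2)
    sigma_c = float(chroma.std())
    p1, p99 = np.percentile(lstar, [1, 99])
    con_l = float(p99 - p1) / 100.0
    denom = np.sqrt(chroma**2 + lstar**2)
    sat = np.divide(chroma, denom, out=np.zeros_like(chroma), where=denom > 0)
    mu_s = float(sat.mean())
    c1, c2, c3 = UCIQE_COEFFS
    return c1 * sigma_c + c2 * con_l + c3 * mu_s


def _alpha_trimmed_stats(x: np.ndarray, alpha: float = 0.1) -> tuple[float, float]:
    """Mean and variance after trimming an alpha fraction from each tail."""
    v = np.sort(x.ravel())
    n = v.size
    t = int(np.floor(alpha * n))
    core = v[t : n - t] if n - 2 * t > 0 else v
    mu = float(core.mean())
    var = float(((core - mu) ** 2).mean())
    return mu, var


def _uicm(arr255: np.ndarray) -> float:
    rg = arr255[:, :, 0] - arr255[:, :, 1]
    yb = (arr255[:, :, 0] + arr255[:, :, 1]) / 2.0 - arr255[:, :, 2]
    mu_rg, var_rg = _alpha_trimmed_stats(rg)
    mu_yb, var_yb = _alpha_trimmed_stats(yb)
    k1, k2 = UICM_COEFFS
    return k1 * np.sqrt(mu_rg**2 + mu_yb**2) + k2 * np.sqrt(var_rg + var_yb)


def _block_view(x: np.ndarray, block: int = _BLOCK) -> np.ndarray:
    """Trim to a whole number of blocks and reshape to (by, bx, block, block)."""
    h = (x.shape[0] // block) * block
    w = (x.shape[1] // block) * block
    if h == 0 or w == 0:
        raise ValueError(f"image too small for {block}x{block} blocks")
    v = x[:h, :w].reshape(h // block, block, w // block, block)
    return v.transpose(0, 2, 1, 3)


def _eme(x: np.ndarray) -> float:
    """EME: 2/(k1 k2) * sum ln(max/min) over blocks; zero-range or zero-min blocks contribute 0."""
    b = _block_view(x)
    bmax = b.max(axis=(2, 3))
    bmin = b.min(axis=(2, 3))
    ok = (bmin > 0) & (bmax > bmin)
    vals = np.zeros_like(bmax)
    vals[ok] = np.log(bmax[ok] / bmin[ok])
    return float(2.0 * vals.mean())


def _uism(arr255: np.ndarray) -> float:
    weights = (0.299, 0.587, 0.114)  # BT.601
    total = 0.0
    for c, w in enumerate(weights):
        ch = arr255[:, :, c]
        edge = np.hypot(ndimage.sobel(ch, axis=0, mode="reflect"), ndimage.sobel(ch, axis=1, mode="reflect"))
        total += w * _eme(edge * ch)
    return total


def _uiconm(arr255: np.ndarray) -> float:
    """PLIP-free logAMEE: mean over blocks of -w * ln(w), w = (max-min)/(max+min)."""
    gray = arr255.mean(axis=2)
    b = _block_view(gray)
    bmax = b.max(axis=(2, 3))
    bmin = b.min(axis=(2, 3))
    s = bmax + bmin
    ok = (bmax > bmin) & (s > 0)
    w = np.zeros_like(bmax)
    w[ok] = (bmax[ok] - bmin[ok]) / s[ok]
    vals = np.zeros_like(w)
    pos = w > 0
    vals[pos] = -w[pos] * np.log(w[pos])
    return float(vals.mean())


def uiqm(img: np.ndarray) -> tuple[float, float, float, float]:
    """Return (uiqm, uicm, uism, uiconm) on the 0-255 scale."""
    arr = validate_image(img) * 255.0
    c_uicm = _uicm(arr)
    c_uism = _uism(arr)
    c_uiconm = _uiconm(arr)
    w1, w2, w3 = UIQM_COEFFS
    return (w1 * c_uicm + w2 * c_uism + w3 * c_uiconm, c_uicm, c_uism, c_uiconm)


def quality_report(img: np.ndarray) -> QualityReport:
    """All four no-reference scores for one image."""
    q, uicm_, uism_, uiconm_ = uiqm(img)
    return QualityReport(
        uciqe=uciqe(img),
        uiqm=q,
        uicm=uicm_,
        uism=uism_,
        uiconm=uiconm_,
        ag=average_gradient(img),
        entropy=entropy(img),
    )


def score_images(paths: list[str | os.PathLike]) -> pd.DataFrame:
    """Score a batch of image files; one row per image."""
    rows = []
    for p in paths:
        rep = quality_report(read_image(p))
        rows.append(
            {
                "file": os.fspath(p),
                "uciqe": rep.uciqe,
                "uiqm": rep.uiqm,
                "uicm": rep.uicm,
                "uism": rep.uism,
                "uiconm": rep.uiconm,
                "ag": rep.ag,
                "entropy": rep.entropy,
            }
        )
    return pd.DataFrame(rows)
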