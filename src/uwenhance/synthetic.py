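"""Seeded synthetic scenes and physically motivated underwater degradation.

Real underwater footage degrades through wavelength-dependent attenuation
(red dies first, hence blue/green casts), backscatter haze from suspended
particles, contrast loss, sensor noise and occasionally motion blur.  The
generator reproduces these with the standard attenuation-backscatter
image-formation model::

    t_c = exp(-beta_c * d)
    out_c = img_c * t_c + B_c * (1 - t_c)

followed by an optional normalized line-kernel motion blur and clipped
additive Gaussian noise.  Clean scenes are procedural — high-chroma discs
and star shapes (urchin/starfish-like), a texture field and a smooth
illumination gradient — so contrast, saliency and chroma statistics are
all exercised without any external dataset.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DegradationParams:
    """Attenuation-backscatter degradation settings.

    beta : per-channel attenuation coefficients (1/depth-unit); red
        attenuates fastest in water, so beta_R > beta_G >= beta_B
    depth : scene distance in depth-units
    background_light : veiling light colour (blue-green dominant)
    noise_sigma : additive Gaussian noise level
    blur_len, blur_angle : optional linear motion-blur kernel (pixels, degrees)
    seed : RNG seed for the noise
    """

    beta: tuple[float, float, float] = (0.8, 0.3, 0.1)
    depth: float = 1.0
    background_light: tuple[float, float, float] = (0.08, 0.45, 0.55)
    noise_sigma: float = 0.0
    blur_len: int = 0
    blur_angle: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(b < 0 for b in self.beta) or self.depth < 0 or self.noise_sigma < 0:
            raise ValueError("beta, depth and noise_sigma must be nonnegative")
        if any(not 0 <= b <= 1 for b in self.background_light):
            raise ValueError("background_light must be within [0, 1]")


def generate_scene(seed: int, height: int = 160, width: int = 120) -> np.ndarray:
    """Procedural clean scene, deterministic for a fixed seed.

    Contains a smooth illumination gradient, a band-limited texture field
    and 6-10 high-chroma blobs (discs and 5-pointed stars).
    """
    if height < 32 or width < 32:
        raise ValueError("scene must be at least 32 x 32")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)

    # smooth background gradient in a sandy/rocky hue
    gdir = rng.uniform(0, 2 * math.pi)
    ramp = (np.cos(gdir) * xx / width + np.sin(gdir) * yy / height + 1.0) / 2.0
    base = rng.uniform(0.25, 0.55, size=3)
    tilt = rng.uniform(-0.2, 0.2, size=3)
    img = base[None, None, :] + tilt[None, None, :] * ramp[:, :, None]

    # band-limited texture (filtered white noise), shared across channels
    tex = ndimage.gaussian_filter(rng.standard_normal((height, width)), 2.0, mode="reflect")
    tex /= max(np.abs(tex).max(), 1e-12)
    img += 0.1 * tex[:, :, None]

    # high-chroma discs and stars
    n_blobs = rng.integers(6, 11)
    for _ in range(n_blobs):
        cy = rng.uniform(0.1, 0.9) * height
        cx = rng.uniform(0.1, 0.9) * width
        r = rng.uniform(0.04, 0.12) * min(height, width)
        colour = rng.uniform(0.0, 1.0, size=3)
        colour[rng.integers(0, 3)] = rng.uniform(0.7, 1.0)  # force one strong channel
        dy, dx = yy - cy, xx - cx
        rad = np.hypot(dy, dx)
        if rng.random() < 0.5:
            mask = rad <= r  # disc (urchin-like)
        else:
            ang = np.arctan2(dy, dx)
            mask = rad <= r * (0.55 + 0.45 * np.cos(5 * (ang + rng.uniform(0, math.pi))))
        img[mask] = 0.65 * colour[None, :] + 0.35 * img[mask]

    return np.clip(img, 0.0, 1.0)


def motion_blur_kernel(length: int, angle_deg: float) -> np.ndarray:
    """Normalized line kernel of the given length and orientation."""
    if length < 1:
        raise ValueError("length must be >= 1")
    size = length if length % 2 == 1 else length + 1
    k = np.zeros((size, size))
    c = size // 2
    theta = math.radians(angle_deg)
    for i in range(length):
        t = i - (length - 1) / 2.0
        y = int(round(c + t * math.sin(theta)))
        x = int(round(c + t * math.cos(theta)))
        k[y, x] += 1.0
    return k / k.sum()


def degrade(img: np.ndarray, params: DegradationParams) -> np.ndarray:
    """Apply attenuation, backscatter, optional blur and noise."""
    arr = np.asarray(img, dtype=float)
    t = np.exp(-np.asarray(params.beta) * params.depth)
    out = arr * t[None, None, :] + np.asarray(params.background_light)[None, None, :] * (1.0 - t[None, None, :])
    if params.blur_len > 1:
        k = motion_blur_kernel(params.blur_len, params.blur_angle)
        for c in range(3):
            out[:, :, c] = ndimage.correlate(out[:, :, c], k, mode="reflect")
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.seed)
        out = out + rng.normal(0.0, params.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)


# the degradation grid the fixture set cycles through: mild and strong
# casts, haze-dominant, noisy and motion-blurred conditions
_GRID = [
    dict(beta=(0.35, 0.15, 0.08), depth=1.0, noise_sigma=0.0, blur_len=0, tag="mild_cast"),
    dict(beta=(0.9, 0.35, 0.12), depth=2.0, noise_sigma=0.0, blur_len=0, tag="strong_cast"),
    dict(beta=(0.5, 0.25, 0.12), depth=2.5, noise_sigma=0.0, blur_len=0, tag="haze"),
    dict(beta=(0.6, 0.25, 0.1), depth=1.5, noise_sigma=0.01, blur_len=0, tag="noisy"),
    dict(beta=(0.9, 0.35, 0.12), depth=2.0, noise_sigma=0.0, blur_len=5, tag="strong_cast_blur"),
]


def make_fixture_set(
    n: int, seed: int, height: int = 160, width: int = 120
) -> list[tuple[np.ndarray, np.ndarray, DegradationParams, str]]:
    """n seeded (clean, degraded, params, tag) tuples spanning the grid."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        grid = _GRID[i % len(_GRID)]
        scene_seed = seed * 100_003 + i
        clean = generate_scene(scene_seed, height, width)
        params = DegradationParams(
            beta=grid["beta"],
            depth=grid["depth"],
            background_light=(0.08, 0.45, 0.55),
            noise_sigma=grid["noise_sigma"],
            blur_len=grid["blur_len"],
            blur_angle=30.0,
            seed=scene_seed + 1,
        )
        out.append((clean, degrade(clean, params), params, grid["tag"]))
    return out


def write_fixture_set(directory: str | os.PathLike, n: int, seed: int, height: int = 160, width: int = 120) -> str:
    """Write PNG pairs plus a JSON manifest of all parameters; returns manifest path."""
    from .imgio import write_image

    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = {"n": n, "seed": seed, "height": height, "width": width, "items": []}
    for i, (clean, degraded, params, tag) in enumerate(make_fixture_set(n, seed, height, width)):
        clean_path = os.path.join(directory, f"clean_{i:03d}.png")
        deg_path = os.path.join(directory, f"degraded_{i:03d}.png")
        write_image(clean, clean_path)
        write_image(degraded, deg_path)
        manifest["items"].append({"index": i, "tag": tag, "clean": clean_path, "degraded": deg_path,
                                  **asdict(params)})
    path = os.path.join(directory, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
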