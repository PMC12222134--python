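"""End-to-end static-blur removal pipeline.

Stage order: adaptive colour compensation -> rolling-guidance MSR (with
display normalization) -> CLAHE + adaptive gamma on V -> multi-weight
pyramid fusion of the Retinex image with the contrast-enhanced image.

All parameters live in :class:`PipelineConfig`, loadable from a YAML file
with strict validation (unknown keys are rejected).  The pipeline is
fully deterministic: no randomness outside the synthetic module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import compensation, contrast, fusion, rgmsr
from .imgio import validate_image

logger = logging.getLogger("uwenhance")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the static-blur pipeline, with documented defaults.

    msr_scales/msr_weights : surround scales (px) and their mixture weights
    rgf_sigma_r / rgf_iterations / rgf_range_bins : rolling guidance filter
    epsilon : log-domain guard of the Retinex stage
    clahe_tiles / clahe_clip / clahe_bins : CLAHE grid and clip limit
    agc_alpha : adaptive gamma weighting exponent
    fusion_depth : pyramid depth (clamped to the image's feasible maximum)
    """

    msr_scales: tuple[float, ...] = (15.0, 80.0, 250.0)
    msr_weights: tuple[float, ...] | None = None
    rgf_sigma_r: float = 0.1
    rgf_iterations: int = 4
    rgf_range_bins: int = 16
    rgf_method: str = "auto"
    epsilon: float = 1.0 / 255.0
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 2.0
    clahe_bins: int = 256
    agc_alpha: float = 0.5
    fusion_depth: int = 5

    def msr_params(self) -> rgmsr.MsrParams:
        w = self.msr_weights
        if w is not None:
            s = sum(w)
            if abs(s - 1.0) >= 1e-6:
                raise ValueError(f"msr_weights sum to {s}, expected 1")
            if s != 1.0:
                logger.warning("renormalizing msr_weights (off by %.2e)", s - 1.0)
                w = tuple(x / s for x in w)
        return rgmsr.MsrParams(scales=tuple(self.msr_scales), weights=w, epsilon=self.epsilon)

    def rgf_params(self) -> rgmsr.RgfParams:
        return rgmsr.RgfParams(
            sigma_s=self.msr_scales[0],
            sigma_r=self.rgf_sigma_r,
            iterations=self.rgf_iterations,
            range_bins=self.rgf_range_bins,
            method=self.rgf_method,
        )

    def clahe_params(self) -> contrast.ClaheParams:
        return contrast.ClaheParams(tiles=tuple(self.clahe_tiles), clip_limit=self.clahe_clip, bins=self.clahe_bins)


_TUPLE_FIELDS = {"msr_scales", "msr_weights", "clahe_tiles"}


def load_config(path: str | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Build a config from an optional YAML file plus overrides.

    Unknown keys raise; ``msr_weights`` slightly off 1 (< 1e-6) are
    renormalized with a warning, larger deviations are an error.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    valid = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(data):
        if data[key] is not None:
            data[key] = tuple(data[key])
    cfg = PipelineConfig(**data)
    cfg.msr_params()  # validate eagerly
    cfg.clahe_params()
    return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def enhance_static(
    img: np.ndarray, cfg: PipelineConfig | None = None, return_intermediates: bool = False
):
    """Run the full static-blur removal chain on one image.

    Returns the fused image, or ``(fused, intermediates)`` with the
    per-stage images I_C, I_MSR*, I_ACG when requested.
    """
    cfg = cfg or PipelineConfig()
    arr = validate_image(img)
    depth = min(cfg.fusion_depth, fusion.max_pyramid_depth(arr.shape[:2]))
    logger.info("enhance_static: %dx%d image, config %s", arr.shape[0], arr.shape[1], cfg)

    stages: dict[str, np.ndarray] = {}
    try:
        i_c = compensation.compensate_colors(arr)
        stages["compensated"] = i_c
    except Exception as exc:
        raise StageError("compensation", exc) from exc
    try:
        refl = rgmsr.improved_msr(i_c, cfg.msr_params(), cfg.rgf_params())
        i_msr = rgmsr.normalize_reflectance(refl)
        stages["msr"] = i_msr
    except Exception as exc:
        raise StageError("rgmsr", exc) from exc
    try:
        i_acg = contrast.enhance_contrast(i_msr, cfg.clahe_params(), cfg.agc_alpha)
        stages["acg"] = i_acg
    except Exception as exc:
        raise StageError("contrast", exc) from exc
    try:
        fused = fusion.pyramid_fuse([i_msr, i_acg], depth=depth)
        stages["fused"] = fused
    except Exception as exc:
        raise StageError("fusion", exc) from exc

    if return_intermediates:
        return fused, stages
    return fused


def channel_mean_spread(img: np.ndarray) -> float:
    """Max minus min of the per-channel means — the colour-cast magnitude."""
    means = np.asarray(img, dtype=float).reshape(-1, 3).mean(axis=0)
    return float(means.max() - means.min())
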