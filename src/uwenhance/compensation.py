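"""Adaptive colour compensation.

Water attenuates red light much faster than green or blue, so raw
underwater frames carry a strong blue/green cast.  This stage boosts the
two attenuated channels toward the dominant one before any Retinex
processing.

The per-channel means are ranked, and two scalar coefficients are formed
from the ordered means (T_max >= T_mid >= T_min)::

    m = (T_max - T_min) / (T_max + T_min)      # for the weakest channel
    n = (T_max - T_mid) / (T_max + T_mid)      # for the middle channel

which are then applied per pixel::

    I_mid' = T_mid(i,j) + n * T_max(i,j)
    I_min' = T_min(i,j) + m * T_max(i,j)

The dominant channel is left untouched and the result is clipped to
[0, 1].  On an achromatic image m = n = 0 and the stage is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import validate_image

_CHANNEL_NAMES = ("R", "G", "B")


@dataclass(frozen=True)
class ChannelRanking:
    """Per-channel means, their ordering and the compensation coefficients.

    ``max_channel``/``mid_channel``/``min_channel`` are indices into
    (R, G, B).  ``degenerate`` flags an all-black image, where the
    coefficient ratios are 0/0 and compensation is skipped.
    """

    means: tuple[float, float, float]
    max_channel: int
    mid_channel: int
    min_channel: int
    m: float
    n: float
    degenerate: bool = False

    @property
    def channel_names(self) -> tuple[str, str, str]:
        return (
            _CHANNEL_NAMES[self.max_channel],
            _CHANNEL_NAMES[self.mid_channel],
            _CHANNEL_NAMES[self.min_channel],
        )


def rank_channels(img: np.ndarray) -> ChannelRanking:
    """Rank channel means and derive the compensation coefficients m, n.

    Ties are broken by fixed channel priority R < G < B: the lower index
    wins the higher rank slot, which keeps edge cases deterministic.
    """
    arr = validate_image(img)
    means = tuple(float(arr[:, :, c].mean()) for c in range(3))
    # sort by descending mean, ascending channel index on ties
    order = sorted(range(3), key=lambda c: (-means[c], c))
    i_max, i_mid, i_min = order
    t_max, t_mid, t_min = means[i_max], means[i_mid], means[i_min]

    if t_max + t_min == 0.0:  # all-black image
        return ChannelRanking(means, i_max, i_mid, i_min, 0.0, 0.0, degenerate=True)

    m = (t_max - t_min) / (t_max + t_min)
    n = (t_max - t_mid) / (t_max + t_mid) if (t_max + t_mid) > 0 else 0.0
    return ChannelRanking(means, i_max, i_mid, i_min, m, n)


def compensate_colors(img: np.ndarray) -> np.ndarray:
    """Apply adaptive colour compensation, returning the image I_C.

    The mid and min channels are raised per pixel by ``n`` resp. ``m``
    times the max channel's pixel value; the max channel is unchanged.
    Output is clipped to [0, 1].  Degenerate (all-black) input is
    returned unchanged.
    """
    arr = validate_image(img)
    rk = rank_channels(arr)
    if rk.degenerate:
        return arr.copy()

    out = arr.copy()
    t_max_pix = arr[:, :, rk.max_channel]
    out[:, :, rk.mid_channel] = arr[:, :, rk.mid_channel] + rk.n * t_max_pix
    out[:, :, rk.min_channel] = arr[:, :, rk.min_channel] + rk.m * t_max_pix
    return np.clip(out, 0.0, 1.0)
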