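"""Attention peak extraction and 2-D feature mapping.

After filtering, each colour channel is summarised by the gray level where
its retained energy concentrates (the attention peak ``h*``) together with
the channel count averaged over a small window ``[h* - n, h* + n]`` that
damps single-bin noise.  The pair is then mapped to a point in a fixed
2-D plane: ``x`` is the peak gray level, ``y = H - s/S * n_ave`` places
high energy low on an inverted axis.  One image therefore reduces to
three points — one per channel — and the whole downstream analysis
(training, monitoring) happens on those triples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .adaptive_filter import FilterThresholds, apply_filter, find_thresholds
from .config import MappingConfig, RunConfig
from .energy import EnergySpectrum, compute_energy
from .exceptions import EmptyBandError, IeamscError

__all__ = ["AttentionPoint", "Point", "MappedTriple", "attention_peak", "map_point", "process_image"]

CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class AttentionPoint:
    """Peak gray level and window-averaged count of one channel."""

    channel: str
    h_star: int
    n_ave: float


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass(frozen=True)
class MappedTriple:
    """The three per-channel feature points of one image.

    Carries the thresholds and attention points it was derived from, and
    the configuration used, so that batches can be audited and configs
    checked for consistency at training time.
    """

    R: Point
    G: Point
    B: Point
    thresholds: Optional[FilterThresholds] = None
    attention: Optional[tuple[AttentionPoint, AttentionPoint, AttentionPoint]] = None
    config: Optional[RunConfig] = None
    image_id: Optional[str] = None

    def point(self, channel: str) -> Point:
        return {"R": self.R, "G": self.G, "B": self.B}[channel]


def attention_peak(
    filtered: EnergySpectrum,
    t: FilterThresholds,
    channel: str,
    n: int = 2,
    window_mode: str = "clipped",
) -> AttentionPoint:
    """Find the channel's energy concentration point in the retained band.

    ``h_star`` is the argmax of the channel counts over the open band
    ``(T1, T2)`` (ties to the smallest gray level).  ``n_ave`` averages
    the counts over the window ``[h_star - n, h_star + n]`` intersected
    with the band; in ``clipped`` mode the divisor is the number of bins
    actually used, in ``strict`` mode it is always ``2n + 1``.

    Raises
    ------
    EmptyBandError
        If the channel has no energy anywhere in the band.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    if n < 0:
        raise ValueError("window half-width n must be >= 0")
    counts = filtered.channel(channel)
    lo, hi = t.T1 + 1, t.T2 - 1  # inclusive band limits
    band = counts[lo : hi + 1]
    if band.size == 0 or band.sum() == 0:
        raise EmptyBandError("no tea energy in band")
    h_star = lo + int(np.argmax(band))
    w_lo = max(h_star - n, lo)
    w_hi = min(h_star + n, hi)
    window = counts[w_lo : w_hi + 1]
    divisor = (2 * n + 1) if window_mode == "strict" else window.size
    return AttentionPoint(channel=channel, h_star=h_star, n_ave=float(window.sum()) / divisor)


def _integerise(v: float, mode: str) -> int:
    if mode == "floor":
        return math.floor(v)
    return math.floor(v + 0.5)  # round half-up


def map_point(
    a: AttentionPoint,
    cfg: MappingConfig,
    x_scale: float = 1.0,
    y_scale: float = 1.0,
) -> Point:
    """Map an attention point onto the 2-D feature plane.

    ``x = h_star`` and ``y = H - int(n_ave * s / S)``, clamped at zero:
    stronger energy maps lower on the inverted vertical axis, and a
    channel with no energy sits at the top (``y = H``).  Optional axis
    scales apply a common normalisation; distances downstream are
    consistent under any fixed rescaling.
    """
    y = cfg.H - _integerise(a.n_ave * cfg.s / cfg.S, cfg.int_mode)
    y = max(y, 0)
    return Point(x=a.h_star * x_scale, y=y * y_scale)


def process_image(
    image: np.ndarray,
    config: Optional[RunConfig] = None,
    image_id: Optional[str] = None,
) -> MappedTriple:
    """Run the full per-image pipeline: energy → filter → attention → map.

    Deterministic, and invariant under image rotations and flips (the
    histogram stage discards all spatial arrangement).
    """
    config = config or RunConfig()
    try:
        spectrum = compute_energy(image)
        t = find_thresholds(spectrum)
        filtered = apply_filter(spectrum, t)
        m = config.mapping
        points = tuple(
            attention_peak(filtered, t, ch, n=m.n, window_mode=m.window_mode)
            for ch in CHANNELS
        )
    except IeamscError as e:
        if image_id is not None:
            raise type(e)(f"{image_id}: {e}") from e
        raise
    r, g, b = (
        map_point(a, config.mapping, config.x_scale, config.y_scale) for a in points
    )
    return MappedTriple(
        R=r, G=g, B=b,
        thresholds=t, attention=points, config=config, image_id=image_id,
    )
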