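"""Synthetic tea-fixation image generator.

Produces RGB frames with the histogram structure the pipeline relies on:
a near-white background, elliptical leaf blobs whose per-channel gray
levels are green-dominant when fresh and darken/converge as a scalar
"fixation degree" rises from 0 to 1, and small near-black patches where
leaves overlap.  The luma histogram of such a frame has three separated
masses (shadow / leaf / background) and therefore the two interior
valleys the adaptive filter searches for.

Only the gray-level statistics matter downstream — the pipeline never
sees spatial structure — so blobs are plain ellipses, not leaf shapes.

The default channel-mean schedule interpolates linearly from
(70, 102, 72) at degree 0 to (56, 57, 56) at degree 1, with the channel
spread narrowing from 18 to 8 gray levels: the green channel starts
dominant and all three converge as fixation completes, which makes the
center triangle of a trained batch shrink monotonically with degree.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from skimage.draw import ellipse

__all__ = ["GeneratorParams", "generate_image", "generate_batch"]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one synthetic frame.

    ``degree`` is the fixation degree in [0, 1] (0 = under-fixed, bright
    green foliage; 1 = fully fixed, dark converged channels).  Fractions
    are of total pixels (``foreground_fraction``) and of foreground
    pixels (``overlap_fraction``).  Gray levels are 8-bit units.
    """

    degree: float = 0.0
    rows: int = 108
    cols: int = 192
    background_level: float = 245.0
    background_sd: float = 4.0
    foreground_fraction: float = 0.5
    overlap_fraction: float = 0.08
    overlap_level: float = 10.0
    overlap_sd: float = 4.0
    channel_means_fresh: tuple[float, float, float] = (70.0, 102.0, 72.0)
    channel_means_done: tuple[float, float, float] = (56.0, 57.0, 56.0)
    channel_sd_fresh: float = 18.0
    channel_sd_done: float = 8.0
    noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.degree <= 1.0:
            raise ValueError("degree must lie in [0, 1]")
        if self.rows < 8 or self.cols < 8:
            raise ValueError("image must be at least 8 x 8")
        if not 0.0 < self.foreground_fraction <= 1.0:
            raise ValueError("foreground_fraction must lie in (0, 1]")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError(
                "overlap_fraction is a fraction of the foreground and must lie in [0, 1]"
            )
        for m in (*self.channel_means_fresh, *self.channel_means_done):
            if not 0.0 < m < 125.0:
                raise ValueError("foreground channel means must lie in (0, 125)")

    def channel_means(self) -> tuple[float, float, float]:
        """Foreground per-channel means at this degree (linear schedule)."""
        d = self.degree
        return tuple(
            (1.0 - d) * f + d * e
            for f, e in zip(self.channel_means_fresh, self.channel_means_done)
        )

    def channel_sd(self) -> float:
        """Foreground channel spread at this degree (linear schedule)."""
        d = self.degree
        return (1.0 - d) * self.channel_sd_fresh + d * self.channel_sd_done


def _blob_mask(
    rng: np.random.Generator,
    rows: int,
    cols: int,
    target_pixels: float,
    axis_lo: int,
    axis_hi: int,
    within: Optional[np.ndarray] = None,
    max_blobs: int = 1000,
) -> np.ndarray:
    """Union of random ellipses until ``target_pixels`` is covered.

    With ``within`` given, ellipse centers are drawn from that mask and
    the result is intersected with it.
    """
    mask = np.zeros((rows, cols), dtype=bool)
    if within is not None:
        coords = np.argwhere(within)
        if coords.size == 0:
            return mask
    for _ in range(max_blobs):
        if mask.sum() >= target_pixels:
            break
        if within is not None:
            r0, c0 = coords[rng.integers(len(coords))]
        else:
            r0 = rng.integers(rows)
            c0 = rng.integers(cols)
        a = rng.integers(axis_lo, axis_hi + 1)
        b = rng.integers(axis_lo, axis_hi + 1)
        rr, cc = ellipse(r0, c0, a, b, shape=(rows, cols))
        mask[rr, cc] = True
    if within is not None:
        mask &= within
    return mask


def generate_image(params: GeneratorParams) -> np.ndarray:
    """Render one synthetic frame; bit-identical for identical params."""
    rng = np.random.default_rng(params.seed)
    rows, cols = params.rows, params.cols
    short = min(rows, cols)

    img = rng.normal(
        params.background_level, params.background_sd, size=(rows, cols, 3)
    )

    fg = _blob_mask(
        rng, rows, cols,
        target_pixels=params.foreground_fraction * rows * cols,
        axis_lo=max(3, short // 12), axis_hi=max(4, short // 5),
    )
    means = params.channel_means()
    sd = params.channel_sd()
    n_fg = int(fg.sum())
    for c in range(3):
        img[..., c][fg] = rng.normal(means[c], sd, size=n_fg)

    overlap = _blob_mask(
        rng, rows, cols,
        target_pixels=params.overlap_fraction * n_fg,
        axis_lo=2, axis_hi=max(3, short // 10),
        within=fg,
    )
    # overlap shadows are colourless: one gray draw shared by all channels,
    # so the low end of the luma histogram keeps the full overlap spread
    # (including the clipped mass at 0) and a clean valley forms above it
    n_ov = int(overlap.sum())
    shadow = rng.normal(params.overlap_level, params.overlap_sd, size=n_ov)
    for c in range(3):
        img[..., c][overlap] = shadow

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def generate_batch(params: GeneratorParams, n_images: int) -> list[np.ndarray]:
    """Generate ``n_images`` frames with sub-seeds derived from the master seed.

    The i-th frame of a batch depends only on ``params.seed`` and ``i``,
    so batches are reproducible and frames are mutually independent.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    sub_seeds = np.random.default_rng(params.seed).integers(
        0, 2**31, size=n_images
    )
    return [generate_image(replace(params, seed=int(s))) for s in sub_seeds]
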