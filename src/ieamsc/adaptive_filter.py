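"""Adaptive trough filtering of the energy spectrum.

A tea image on a white tray produces a luma histogram with (up to) three
masses: near-black leaf-overlap shadows at the very low end, the leaf
body in the mid grays, and the bright background at the high end.  The
two valleys separating them move from frame to frame, so the filter finds
them per image: ``T1`` is the gray level with the fewest luma pixels in
[0, 125], ``T2`` the one with the fewest in [126, 255].  Everything at or
below ``T1`` (shadow) and at or above ``T2`` (background) is discarded
from the channel histograms; the open band ``(T1, T2)`` is kept as
genuine leaf energy.

Filtering acts directly on histogram bins.  Zeroing the spatial pixels
and re-histogramming would give the same retained counts, so the
histogram-domain form is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergySpectrum
from .exceptions import DegenerateHistogramError

__all__ = ["FilterThresholds", "find_thresholds", "apply_filter", "LOWER_RANGE_END"]

#: Last gray level of the lower trough search range; the upper range
#: starts at the next level.
LOWER_RANGE_END = 125


@dataclass(frozen=True)
class FilterThresholds:
    """The two trough gray levels bounding the retained band (T1, T2)."""

    T1: int
    T2: int

    def __post_init__(self) -> None:
        if not (0 <= self.T1 <= LOWER_RANGE_END < self.T2 <= 255):
            raise ValueError(
                f"thresholds must satisfy 0 <= T1 <= {LOWER_RANGE_END} < T2 <= 255"
            )
        if self.T2 - self.T1 < 2:
            raise DegenerateHistogramError("degenerate histogram")

    @property
    def band(self) -> range:
        """Gray levels of the open retained band (T1, T2)."""
        return range(self.T1 + 1, self.T2)


def find_thresholds(spectrum: EnergySpectrum) -> FilterThresholds:
    """Locate the two luma-histogram troughs.

    T1 minimises the luma counts over [0, 125], T2 over [126, 255]; ties
    go to the smallest gray level, which keeps the retained band as wide
    as possible on the left and is deterministic.

    Raises
    ------
    DegenerateHistogramError
        If the luma histogram is empty, has all its mass in one bin, or
        the troughs leave no open band between them.
    """
    luma = spectrum.counts_luma
    if luma.sum() == 0:
        raise DegenerateHistogramError("degenerate histogram")
    if np.count_nonzero(luma) == 1:
        # single-colour image: no valley structure to find
        raise DegenerateHistogramError("degenerate histogram")
    split = LOWER_RANGE_END + 1
    t1 = int(np.argmin(luma[:split]))  # argmin takes the first minimum
    t2 = split + int(np.argmin(luma[split:]))
    return FilterThresholds(T1=t1, T2=t2)


def apply_filter(spectrum: EnergySpectrum, t: FilterThresholds) -> EnergySpectrum:
    """Zero the channel energy outside the retained band.

    For each of R, G, B the bins ``h <= T1`` and ``h >= T2`` are set to
    zero (the thresholds themselves are discarded); bins strictly inside
    ``(T1, T2)`` are untouched.  The luma histogram is kept as-is for
    diagnostics.  Idempotent by construction.
    """
    keep = np.zeros(256, dtype=bool)
    keep[t.T1 + 1 : t.T2] = True
    return spectrum.with_channels(
        R=np.where(keep, spectrum.counts_R, 0),
        G=np.where(keep, spectrum.counts_G, 0),
        B=np.where(keep, spectrum.counts_B, 0),
    )
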