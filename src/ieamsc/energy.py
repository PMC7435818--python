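"""Per-channel gray-level "energy" extraction.

The energy of a colour channel is its 256-bin gray-level histogram: the
number of pixels at each gray level.  A bright channel carries its mass in
high bins ("high energy"), a dark one in low bins.  Alongside the three
channel histograms we keep the histogram of the luma image (the standard
0.299/0.587/0.114 weighted gray conversion), which is what the adaptive
filter inspects for its troughs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from os import PathLike
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError

__all__ = [
    "EnergySpectrum",
    "as_rgb_image",
    "load_image",
    "to_luma",
    "compute_energy",
    "spectrum_to_frame",
]

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class EnergySpectrum:
    """Gray-level histograms of one RGB image.

    ``counts_R/G/B`` each hold 256 non-negative integers; before any
    filtering each sums to the pixel count of the image, as does
    ``counts_luma``.
    """

    counts_R: np.ndarray
    counts_G: np.ndarray
    counts_B: np.ndarray
    counts_luma: np.ndarray

    def __post_init__(self) -> None:
        for name in ("counts_R", "counts_G", "counts_B", "counts_luma"):
            v = np.asarray(getattr(self, name), dtype=np.int64)
            if v.shape != (256,):
                raise ValueError(f"{name} must have shape (256,)")
            if (v < 0).any():
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, v)

    def channel(self, name: str) -> np.ndarray:
        return {"R": self.counts_R, "G": self.counts_G, "B": self.counts_B}[name]

    def with_channels(
        self, R: np.ndarray, G: np.ndarray, B: np.ndarray
    ) -> "EnergySpectrum":
        return replace(self, counts_R=R, counts_G=G, counts_B=B)

    @property
    def n_pixels(self) -> int:
        return int(self.counts_luma.sum())


def as_rgb_image(pixels: np.ndarray) -> np.ndarray:
    """Validate / coerce an array into an 8-bit RGB raster.

    Accepts ``rows x cols x 3`` (or ``x 4``; the alpha plane is dropped
    with a warning).  Integer images wider than 8 bits and float images
    are rescaled onto [0, 255] with a warning; exact 8-bit data passes
    through untouched.
    """
    a = np.asarray(pixels)
    if a.ndim != 3 or a.shape[2] not in (3, 4):
        raise ValueError(f"expected rows x cols x 3 RGB array, got shape {a.shape}")
    if a.shape[0] < 1 or a.shape[1] < 1 or a.size == 0:
        raise EmptyInputError("empty input")
    if a.shape[2] == 4:
        warnings.warn("alpha channel dropped", stacklevel=2)
        a = a[:, :, :3]
    if a.dtype == np.uint8:
        return a
    if np.issubdtype(a.dtype, np.integer):
        if a.min() >= 0 and a.max() <= 255:
            return a.astype(np.uint8)
        warnings.warn("non-8-bit integer image rescaled to [0, 255]", stacklevel=2)
        a = a.astype(np.float64)
    elif np.issubdtype(a.dtype, np.floating):
        warnings.warn("float image rescaled to [0, 255]", stacklevel=2)
        a = a.astype(np.float64)
    else:
        raise ValueError(f"unsupported pixel dtype {a.dtype}")
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros(a.shape, dtype=np.uint8)
    scaled = (a - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def load_image(path: Union[str, PathLike]) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file into an 8-bit RGB array.

    Grayscale files are broadcast to three identical channels.
    """
    import imageio.v3 as iio

    try:
        a = iio.imread(path)
    except OSError:
        raise
    except Exception as e:  # plugin-specific errors vary; normalise them
        raise OSError(f"cannot read image {path}: {e}") from e
    if a.ndim == 2:
        a = np.stack([a, a, a], axis=-1)
    return as_rgb_image(a)


def to_luma(image: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to its integer luma image.

    Applies the BT.601 weighted sum 0.299 R + 0.587 G + 0.114 B per pixel
    and rounds half-up to the nearest integer.  The rounding rule matters:
    trough thresholds are gray levels of this image, so it is fixed here
    and used everywhere.
    """
    img = as_rgb_image(image).astype(np.float64)
    wr, wg, wb = LUMA_WEIGHTS
    y = wr * img[:, :, 0] + wg * img[:, :, 1] + wb * img[:, :, 2]
    return np.floor(y + 0.5).astype(np.uint8)


def compute_energy(image: np.ndarray) -> EnergySpectrum:
    """Tally the per-channel and luma gray-level histograms of an image.

    ``counts_c[h]`` is the number of pixels whose channel-``c`` value
    equals ``h``.  The tally only depends on the multiset of pixel values,
    which is what gives the whole pipeline its rotation invariance.
    """
    img = as_rgb_image(image)
    luma = to_luma(img)
    counts = [
        np.bincount(img[:, :, c].ravel(), minlength=256) for c in range(3)
    ]
    return EnergySpectrum(
        counts_R=counts[0],
        counts_G=counts[1],
        counts_B=counts[2],
        counts_luma=np.bincount(luma.ravel(), minlength=256),
    )


def spectrum_to_frame(spectrum: EnergySpectrum) -> pd.DataFrame:
    """Tabulate a spectrum as 256 rows with columns h, R, G, B, luma.

    ``DataFrame.to_csv(index=False)`` yields the documented 257-line CSV
    (header plus one row per gray level).
    """
    return pd.DataFrame(
        {
            "h": np.arange(256),
            "R": spectrum.counts_R,
            "G": spectrum.counts_G,
            "B": spectrum.counts_B,
            "luma": spectrum.counts_luma,
        }
    )
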