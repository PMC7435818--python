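"""Pipeline configuration.

Two layers:

* :class:`MappingConfig` — everything the per-image feature pipeline needs
  (attention window, mapping constants, rounding/window conventions).
* :class:`RunConfig` — a :class:`MappingConfig` plus the train/monitor
  level knobs (decision weight ``alpha``, optional per-axis normalisation
  scales, distance convention).

Both are frozen dataclasses so a configuration can be hashed into model
files and compared for equality when a model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

__all__ = ["MappingConfig", "RunConfig"]

_INT_MODES = ("round", "floor")
_WINDOW_MODES = ("clipped", "strict")
_DISTANCE_MODES = ("euclidean", "literal")


@dataclass(frozen=True)
class MappingConfig:
    """Constants of the attention / data-mapping stage.

    Parameters
    ----------
    H : int
        Vertical extent of the mapped feature plane; a channel with zero
        window-averaged energy maps to ``y = H`` (top of the inverted axis).
    s, S : int
        Scale pair for the count-to-plane mapping ``y = H - s/S * n_ave``.
        With the defaults a window average of 25 000 pixels spans 700
        vertical units.
    n : int
        Attention window half-width in gray levels: the count at the peak
        is averaged over ``[h* - n, h* + n]`` to damp single-bin noise.
    int_mode : {"round", "floor"}
        How the mapped ``y`` is integerised.  ``round`` is round-half-up;
        ``floor`` truncates (differs by at most one count unit).
    window_mode : {"clipped", "strict"}
        Divisor used when the attention window is clipped by the retained
        band: ``clipped`` divides by the number of bins actually used,
        ``strict`` always divides by ``2n + 1``.
    """

    H: int = 800
    s: int = 700
    S: int = 25000
    n: int = 2
    int_mode: str = "round"
    window_mode: str = "clipped"

    def __post_init__(self) -> None:
        if self.H <= 0 or self.s <= 0 or self.S <= 0:
            raise ValueError("H, s and S must be positive")
        if self.n < 0:
            raise ValueError("window half-width n must be >= 0")
        if self.int_mode not in _INT_MODES:
            raise ValueError(f"int_mode must be one of {_INT_MODES}")
        if self.window_mode not in _WINDOW_MODES:
            raise ValueError(f"window_mode must be one of {_WINDOW_MODES}")


@dataclass(frozen=True)
class RunConfig:
    """Full train/monitor configuration.

    ``alpha`` is the decision weight: a monitored distance sum is normal
    while ``|sum_S - sum_M| < alpha * sum_S``.  ``x_scale`` / ``y_scale``
    optionally normalise the feature axes (decisions are invariant to a
    common rescaling, so the defaults of 1 keep raw units: x in gray
    levels, y in mapped plane units).  ``distance_mode`` selects the plain
    Euclidean center distance (default) or the historical halved variant
    (``literal``).
    """

    mapping: MappingConfig = field(default_factory=MappingConfig)
    alpha: float = 0.2
    x_scale: float = 1.0
    y_scale: float = 1.0
    distance_mode: str = "euclidean"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not (self.x_scale > 0 and self.y_scale > 0):
            raise ValueError("axis scales must be positive")
        if self.distance_mode not in _DISTANCE_MODES:
            raise ValueError(f"distance_mode must be one of {_DISTANCE_MODES}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        d = dict(d)
        mapping = d.pop("mapping", {})
        return cls(mapping=MappingConfig(**mapping), **d)
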