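"""Center distances and the normal/abnormal decision.

The three channel cluster centers of a batch form a triangle in the
feature plane.  As fixation progresses the channels darken and converge,
so the triangle shrinks; its perimeter — the sum of the three pairwise
Euclidean center distances — is the single scalar the monitor compares.
A monitored image set is declared *normal* while its distance sum stays
within a relative tolerance of the trained standard:

    normal    iff  alpha * sum_S >  |sum_S - sum_M|
    abnormal  iff  alpha * sum_S <= |sum_S - sum_M|   (boundary inclusive)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .attention import CHANNELS, MappedTriple, Point, process_image
from .config import RunConfig
from .exceptions import EmptyInputError, IeamscError, UntrainedModelError

if TYPE_CHECKING:  # pragma: no cover
    from .trainer import TrainedModel

__all__ = [
    "DistanceSummary",
    "Decision",
    "MonitoringReport",
    "pairwise_center_distances",
    "decide",
    "mean_centers",
    "monitor_set",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceSummary:
    """The three pairwise center distances and their sum (the perimeter)."""

    d_RG: float
    d_RB: float
    d_GB: float

    @property
    def sum(self) -> float:
        return self.d_RG + self.d_RB + self.d_GB


@dataclass(frozen=True)
class Decision:
    """Outcome of one monitoring comparison, with its inputs attached."""

    verdict: str  # "normal" | "abnormal"
    sum_S: float
    sum_M: float
    alpha: float

    @property
    def threshold(self) -> float:
        return self.alpha * self.sum_S

    @property
    def deviation(self) -> float:
        return abs(self.sum_S - self.sum_M)


@dataclass(frozen=True)
class MonitoringReport:
    """Full diagnostic record of a monitoring run."""

    decision: Decision
    centers: dict[str, Point]
    distances: DistanceSummary
    triples: tuple[MappedTriple, ...]
    n_images: int
    n_skipped: int
    skipped: tuple[str, ...] = field(default_factory=tuple)


def _dist(p: Point, q: Point) -> float:
    return math.hypot(p.x - q.x, p.y - q.y)


def pairwise_center_distances(
    center_R: Point, center_G: Point, center_B: Point, mode: str = "euclidean"
) -> DistanceSummary:
    """Distances between the three channel centers.

    ``mode="euclidean"`` (default) is the plain L2 distance, which is the
    convention the published reference distance table follows.  The
    ``"literal"`` mode halves each distance (a 0.5-prefactor variant that
    appears in some write-ups of the method); it rescales the triangle
    uniformly and leaves every relative decision unchanged.
    """
    factor = 0.5 if mode == "literal" else 1.0
    return DistanceSummary(
        d_RG=factor * _dist(center_R, center_G),
        d_RB=factor * _dist(center_R, center_B),
        d_GB=factor * _dist(center_G, center_B),
    )


def decide(sum_S: float, sum_M: float, alpha: float = 0.2) -> Decision:
    """Apply the relative-deviation decision rule.

    Normal requires the strict inequality ``alpha * sum_S > |sum_S -
    sum_M|``; exact equality at the boundary is abnormal.
    """
    if not sum_S > 0:
        raise UntrainedModelError("untrained or degenerate model")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    verdict = "normal" if alpha * sum_S > abs(sum_S - sum_M) else "abnormal"
    return Decision(verdict=verdict, sum_S=sum_S, sum_M=sum_M, alpha=alpha)


def mean_centers(triples: Sequence[MappedTriple]) -> dict[str, Point]:
    """Per-channel arithmetic mean of the feature points of a batch."""
    if len(triples) == 0:
        raise EmptyInputError("empty input")
    centers = {}
    for ch in CHANNELS:
        xs = np.array([t.point(ch).x for t in triples], dtype=np.float64)
        ys = np.array([t.point(ch).y for t in triples], dtype=np.float64)
        centers[ch] = Point(x=float(xs.mean()), y=float(ys.mean()))
    return centers


def monitor_set(
    images: Sequence[np.ndarray],
    model: "TrainedModel",
    image_ids: Optional[Sequence[str]] = None,
) -> MonitoringReport:
    """Judge a monitoring image set against a trained standard.

    Each image is reduced to its feature triple; triples are averaged per
    channel into the monitoring centers, whose pairwise-distance sum is
    compared with the model's standard sum.  Images that fail the
    pipeline (e.g. a degenerate histogram) are skipped with a warning;
    only if *every* image fails is an error raised.
    """
    if len(images) == 0:
        raise EmptyInputError("empty input")
    ids = list(image_ids) if image_ids is not None else [None] * len(images)
    triples: list[MappedTriple] = []
    skipped: list[str] = []
    for img, img_id in zip(images, ids):
        try:
            triples.append(process_image(img, model.config, image_id=img_id))
        except IeamscError as e:
            label = img_id if img_id is not None else f"image#{len(triples) + len(skipped)}"
            log.warning("skipping %s: %s", label, e)
            skipped.append(str(label))
    if not triples:
        raise EmptyInputError("all images failed the pipeline")
    centers = mean_centers(triples)
    distances = pairwise_center_distances(
        centers["R"], centers["G"], centers["B"], mode=model.config.distance_mode
    )
    decision = decide(model.sum_S, distances.sum, alpha=model.config.alpha)
    return MonitoringReport(
        decision=decision,
        centers=centers,
        distances=distances,
        triples=tuple(triples),
        n_images=len(images),
        n_skipped=len(skipped),
        skipped=tuple(skipped),
    )
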