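"""Supervised cluster training: per-channel mean centers of a batch.

The "clustering" of this method is deliberately simple: within a channel
all feature points of the standard-time training batch form one cluster,
and the centroid minimising the within-cluster sum of squared Euclidean
distances (SSE) is the arithmetic mean.  A trained model is therefore
three mean points plus the pairwise-distance sum of the triangle they
form, together with the configuration that produced the points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np

from .attention import MappedTriple, Point
from .config import RunConfig
from .exceptions import ConfigMismatchError, EmptyInputError
from .monitor import mean_centers, pairwise_center_distances

__all__ = ["TrainedModel", "train_centers", "sse", "save_model", "load_model"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class TrainedModel:
    """Standard-time cluster centers and their distance sum."""

    center_R: Point
    center_G: Point
    center_B: Point
    sum_S: float
    n_train: int
    config: RunConfig
    label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict, compare=False)

    def center(self, channel: str) -> Point:
        return {"R": self.center_R, "G": self.center_G, "B": self.center_B}[channel]


def sse(points: Sequence[Point], center: Point) -> float:
    """Sum of squared Euclidean distances from ``points`` to ``center``."""
    if len(points) == 0:
        raise EmptyInputError("empty input")
    p = np.array([[pt.x, pt.y] for pt in points], dtype=np.float64)
    c = np.array([center.x, center.y], dtype=np.float64)
    return float(((p - c) ** 2).sum())


def train_centers(
    triples: Sequence[MappedTriple],
    label: str = "",
    config: Optional[RunConfig] = None,
) -> TrainedModel:
    """Aggregate a training batch into a model.

    Each channel center is the mean of that channel's points over all
    triples — the SSE-optimal centroid.  All triples must have been
    produced under one configuration; pass ``config`` explicitly for
    triples built by hand without one attached.
    """
    if len(triples) == 0:
        raise EmptyInputError("empty input")
    configs = {t.config for t in triples if t.config is not None}
    if len(configs) > 1:
        raise ConfigMismatchError("training triples mix different configurations")
    if configs:
        attached = configs.pop()
        if config is not None and config != attached:
            raise ConfigMismatchError("explicit config differs from triples' config")
        config = attached
    elif config is None:
        config = RunConfig()
    centers = mean_centers(triples)
    d = pairwise_center_distances(
        centers["R"], centers["G"], centers["B"], mode=config.distance_mode
    )
    return TrainedModel(
        center_R=centers["R"],
        center_G=centers["G"],
        center_B=centers["B"],
        sum_S=d.sum,
        n_train=len(triples),
        config=config,
        label=label,
    )


# -- persistence ---------------------------------------------------------


def save_model(model: TrainedModel, path: Union[str, PathLike]) -> None:
    """Write a model to JSON (sorted keys, lossless float repr).

    Timestamps or other run provenance belong in ``model.metadata``; the
    rest of the file is byte-reproducible for identical inputs.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "label": model.label,
        "centers": {
            ch: [model.center(ch).x, model.center(ch).y] for ch in ("R", "G", "B")
        },
        "sum_S": model.sum_S,
        "n_train": model.n_train,
        "config": model.config.to_dict(),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_model(path: Union[str, PathLike]) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {doc.get('schema_version')!r}")
    centers = {ch: Point(*doc["centers"][ch]) for ch in ("R", "G", "B")}
    return TrainedModel(
        center_R=centers["R"],
        center_G=centers["G"],
        center_B=centers["B"],
        sum_S=float(doc["sum_S"]),
        n_train=int(doc["n_train"]),
        config=RunConfig.from_dict(doc["config"]),
        label=doc.get("label", ""),
        metadata=doc.get("metadata", {}),
    )
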