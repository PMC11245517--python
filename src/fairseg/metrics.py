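"""Segmentation accuracy (IoU, Dice) and group-fairness metrics (SER, group-error SD).

Aggregation is macro-averaged and unweighted at each stage: per-class scores
are averaged over foreground classes into an image score, image scores are
averaged within each protected-group level, and fairness statistics are
computed on the per-level mean error rates ``1 - score``:

* ``SER = max_g(1 - s_g) / min_g(1 - s_g)`` — the skewed error ratio, >= 1,
  equal to 1 iff all group error rates coincide;
* ``SD`` — the population (divide-by-g) standard deviation of the group
  error rates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ATTRIBUTE_LEVELS, CohortRecord, group_levels

if TYPE_CHECKING:  # pragma: no cover
    from .training import TrainedArtifact

logger = logging.getLogger(__name__)

__all__ = [
    "MaskPair",
    "GroupScores",
    "FairnessReport",
    "compute_iou",
    "compute_dice",
    "image_score",
    "group_mean_scores",
    "compute_ser",
    "compute_group_sd",
    "audit",
]


@dataclass(frozen=True)
class MaskPair:
    """A predicted integer label mask and its gold-standard counterpart."""

    predicted: np.ndarray
    actual: np.ndarray

    def __post_init__(self) -> None:
        if self.predicted.shape != self.actual.shape:
            raise ValueError(
                f"mask shapes differ: predicted {self.predicted.shape} "
                f"vs actual {self.actual.shape}"
            )


def _binary_overlap(pair: MaskPair, class_id: int) -> tuple[int, int, int]:
    pred = pair.predicted == class_id
    act = pair.actual == class_id
    inter = int(np.count_nonzero(pred & act))
    return inter, int(np.count_nonzero(pred)), int(np.count_nonzero(act))


def compute_iou(pair: MaskPair, class_id: int) -> float:
    """Intersection over union for one class; both-empty masks score 1.0."""
    inter, n_pred, n_act = _binary_overlap(pair, class_id)
    union = n_pred + n_act - inter
    if union == 0:
        logger.debug("class %d empty in both masks; IoU defined as 1.0", class_id)
        return 1.0
    return inter / union


def compute_dice(pair: MaskPair, class_id: int) -> float:
    """Dice coefficient ``2|A∩B| / (|A| + |B|)``; both-empty masks score 1.0."""
    inter, n_pred, n_act = _binary_overlap(pair, class_id)
    if n_pred + n_act == 0:
        logger.debug("class %d empty in both masks; Dice defined as 1.0", class_id)
        return 1.0
    return 2.0 * inter / (n_pred + n_act)


_METRIC_FNS = {"iou": compute_iou, "dice": compute_dice}


def image_score(
    pair: MaskPair, metric: str, foreground_classes: Sequence[int] | None = None
) -> float:
    """Unweighted mean of per-foreground-class scores (background class 0 excluded)."""
    if metric not in _METRIC_FNS:
        raise ValueError(f"unknown metric {metric!r}")
    if foreground_classes is None:
        labels = np.union1d(np.unique(pair.predicted), np.unique(pair.actual))
        foreground_classes = [int(c) for c in labels if c != 0]
    if len(foreground_classes) == 0:
        raise ValueError("no foreground classes to score")
    fn = _METRIC_FNS[metric]
    return float(np.mean([fn(pair, c) for c in foreground_classes]))


@dataclass
class GroupScores:
    """Per-level mean score (IoU or Dice) for one protected attribute."""

    attribute: str
    metric: str
    per_level: dict[str, float]
    n_per_level: dict[str, int] = field(default_factory=dict)

    def errors(self) -> np.ndarray:
        return 1.0 - np.asarray(list(self.per_level.values()), dtype=float)


def group_mean_scores(
    pairs: Sequence[MaskPair],
    records: Sequence[CohortRecord],
    attribute: str,
    metric: str,
    foreground_classes: Sequence[int] | None = None,
) -> GroupScores:
    """Per-level unweighted mean of :func:`image_score` over each level's images."""
    if len(pairs) != len(records):
        raise ValueError("pairs and records must align one-to-one")
    levels = group_levels(records, attribute)
    per_level: dict[str, float] = {}
    n_per_level: dict[str, int] = {}
    for level in levels:
        scores = [
            image_score(p, metric, foreground_classes)
            for p, r in zip(pairs, records)
            if r.attributes.level(attribute) == level
        ]
        if not scores:
            logger.warning("level %s has no images; excluded", level.value)
            continue
        per_level[level.value] = float(np.mean(scores))
        n_per_level[level.value] = len(scores)
    return GroupScores(attribute=attribute, metric=metric,
                       per_level=per_level, n_per_level=n_per_level)


def compute_ser(scores: GroupScores | Mapping[str, float]) -> float:
    """Skewed error ratio: max over levels of ``1 - score`` divided by the min.

    All levels exactly at score 1 yield SER 1.0 (no error anywhere); exactly
    one level at 1 with others below raises (infinite ratio).
    """
    per_level = scores.per_level if isinstance(scores, GroupScores) else dict(scores)
    if len(per_level) < 2:
        raise ValueError("SER requires at least two group levels")
    errors = 1.0 - np.asarray(list(per_level.values()), dtype=float)
    if np.all(errors == 0):
        return 1.0
    if np.min(errors) == 0:
        raise ZeroDivisionError(
            "infinite SER: one group has zero error while another does not"
        )
    return float(np.max(errors) / np.min(errors))


def compute_group_sd(scores: GroupScores | Mapping[str, float]) -> float:
    """Population standard deviation (divide by g) of per-level error rates."""
    per_level = scores.per_level if isinstance(scores, GroupScores) else dict(scores)
    if len(per_level) < 2:
        raise ValueError("group SD requires at least two group levels")
    errors = 1.0 - np.asarray(list(per_level.values()), dtype=float)
    return float(np.std(errors))  # ddof=0: population normalization


@dataclass
class FairnessReport:
    """SER and group-error SD per (model, attribute, metric), with per-group scores."""

    model_id: str
    attribute: str
    entries: dict[str, dict] = field(default_factory=dict)  # metric -> summary

    def add(self, metric: str, scores: GroupScores) -> None:
        self.entries[metric] = {
            "per_level": dict(scores.per_level),
            "n_per_level": dict(scores.n_per_level),
            "ser": compute_ser(scores),
            "sd": compute_group_sd(scores),
        }

    def ser(self, metric: str) -> float:
        return self.entries[metric]["ser"]

    def sd(self, metric: str) -> float:
        return self.entries[metric]["sd"]

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "attribute": self.attribute,
            "metrics": self.entries,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Flat table mirroring the published result layout (one row per metric)."""
        rows = []
        for metric, e in self.entries.items():
            row: dict = {"model": self.model_id, "attribute": self.attribute,
                         "metric": metric}
            for level, score in e["per_level"].items():
                row[level] = score
            row["SER"] = e["ser"]
            row["SD"] = e["sd"]
            rows.append(row)
        return pd.DataFrame(rows)


def audit(
    trained: "TrainedArtifact",
    test_records: Sequence[CohortRecord],
    attribute: str,
    data: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None,
    threshold: float = 0.5,
    metrics: Sequence[str] = ("iou", "dice"),
) -> FairnessReport:
    """Audit a trained artifact on test records, grouped by a protected attribute.

    Predictions are made via ``predict_masks`` at the given threshold.  With a
    group-specific artifact each record is scored by its own level's model.
    ``data`` optionally maps patient_id -> (image, mask) arrays, bypassing disk.
    """
    from .io import load_sample
    from .model import predict_masks

    if attribute not in ATTRIBUTE_LEVELS:
        raise KeyError(f"unknown protected attribute {attribute!r}")
    if not test_records:
        raise ValueError("no test records to audit")

    pairs: list[MaskPair] = []
    n_classes = None
    for rec in test_records:
        model = trained.model_for(rec, attribute)
        image, mask = (
            data[rec.patient_id] if data is not None else load_sample(rec)
        )
        pred = predict_masks(model, image[None, None, :, :], threshold=threshold)[0]
        pairs.append(MaskPair(predicted=pred, actual=mask))
        n_classes = model.config.n_classes

    foreground = list(range(1, n_classes))
    report = FairnessReport(model_id=trained.config.strategy, attribute=attribute)
    for metric in metrics:
        report.add(metric, group_mean_scores(pairs, test_records, attribute, metric,
                                             foreground_classes=foreground))
    return report
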