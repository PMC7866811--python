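"""Deterministic stromal-cell classifier: immune cells vs fibroblasts.

The interactively trained classifier of the original workflow is formalized
as a nearest-centroid model in z-scored feature space over the three
morphometric features (nucleus area, circularity, stain intensity).  It is
fully deterministic — no randomness, no iterative fitting — which is what
the coarse two-class task needs, and the model serializes to a small JSON.

Classification is restricted to the ROI and to cells outside tumor glands:
tumor cells never enter the classifier because glands are annotation-defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd
import shapely

from .core import CellRecord, Polygon2D, positions_of
from .errors import EvaluationError, TrainingError

__all__ = [
    "FEATURE_NAMES",
    "TrainingSet",
    "ClassifierModel",
    "EvaluationResult",
    "train",
    "predict",
    "evaluate",
]

FEATURE_NAMES = ("nucleus_area_um2", "circularity", "stain_intensity")
CLASSES = ("immune", "fibroblast")


def _feature_matrix(cells: Sequence[CellRecord]) -> np.ndarray:
    return np.array(
        [[getattr(c, f) for f in FEATURE_NAMES] for c in cells], dtype=float
    ).reshape(-1, len(FEATURE_NAMES))


@dataclass
class TrainingSet:
    """Labelled feature examples with classes 'immune' / 'fibroblast'."""

    features: np.ndarray      # (n, n_features)
    labels: np.ndarray        # (n,) strings

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise TrainingError("features must be (n, p) with one label per row")
        if not np.isfinite(self.features).all():
            raise TrainingError("training features must be finite")

    @classmethod
    def from_cells(cls, cells: Sequence[CellRecord]) -> "TrainingSet":
        usable = [c for c in cells if c.true_class in CLASSES]
        return cls(_feature_matrix(usable), np.array([c.true_class for c in usable]))


@dataclass
class ClassifierModel:
    """Nearest-centroid model: per-class centroids and pooled feature scales."""

    feature_names: tuple[str, ...]
    centroids: dict[str, np.ndarray]
    scales: np.ndarray

    def to_json(self, path: str | PathLike) -> None:
        doc = {
            "feature_names": list(self.feature_names),
            "centroids": {k: list(map(float, v)) for k, v in self.centroids.items()},
            "scales": list(map(float, self.scales)),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path: str | PathLike) -> "ClassifierModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            feature_names=tuple(doc["feature_names"]),
            centroids={k: np.array(v, dtype=float) for k, v in doc["centroids"].items()},
            scales=np.array(doc["scales"], dtype=float),
        )


def train(training: TrainingSet, feature_names: Sequence[str] = FEATURE_NAMES) -> ClassifierModel:
    """Fit the nearest-centroid model.

    Scales are pooled within-class standard deviations.  Features whose
    pooled sd is zero (degenerate) are dropped with a warning when other
    features remain; if every feature is degenerate (e.g. a single example
    per class) unit scales are used instead so the model stays defined.
    """
    present = set(np.unique(training.labels))
    missing = [c for c in CLASSES if c not in present]
    if missing:
        raise TrainingError(f"training set lacks class(es): {missing}")

    X, y = training.features, training.labels
    centroids = {c: X[y == c].mean(axis=0) for c in CLASSES}
    n = len(X)
    ss = sum(((X[y == c] - centroids[c]) ** 2).sum(axis=0) for c in CLASSES)
    dof = n - len(CLASSES)
    scales = np.sqrt(ss / dof) if dof > 0 else np.zeros(X.shape[1])

    degenerate = ~(scales > 0)
    names = tuple(feature_names)
    if degenerate.all():
        warnings.warn(
            "all features have zero pooled spread; using unit scales", stacklevel=2
        )
        scales = np.ones_like(scales)
    elif degenerate.any():
        dropped = [names[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"dropping degenerate feature(s): {dropped}", stacklevel=2)
        keep = np.flatnonzero(~degenerate)
        names = tuple(names[i] for i in keep)
        centroids = {c: v[keep] for c, v in centroids.items()}
        scales = scales[keep]
    return ClassifierModel(feature_names=names, centroids=centroids, scales=scales)


def predict(
    model: ClassifierModel,
    cells: Sequence[CellRecord],
    roi: Polygon2D,
    glands: Sequence[Polygon2D] = (),
) -> pd.DataFrame:
    """Label cells inside the ROI and outside tumor glands.

    Returns a DataFrame with columns ``cell_id``, ``predicted_class``,
    ``x_um``, ``y_um`` covering exactly the classified cells (cells outside
    the ROI or inside a gland are excluded, not labelled).  A cell
    equidistant from both centroids is labelled immune.
    """
    cells = list(cells)
    if not cells:
        return pd.DataFrame(columns=["cell_id", "predicted_class", "x_um", "y_um"])
    xy = positions_of(cells)
    keep = shapely.contains_xy(roi.to_shapely(), xy[:, 0], xy[:, 1])
    for g in glands:
        keep &= ~shapely.contains_xy(g.to_shapely(), xy[:, 0], xy[:, 1])
    idx = np.flatnonzero(keep)
    feat_idx = [FEATURE_NAMES.index(f) for f in model.feature_names]
    X = _feature_matrix(cells)[np.ix_(idx, feat_idx)] / model.scales
    d = {c: np.linalg.norm(X - model.centroids[c] / model.scales, axis=1)
         for c in CLASSES}
    labels = np.where(d["immune"] <= d["fibroblast"], "immune", "fibroblast")
    return pd.DataFrame(
        {
            "cell_id": [cells[i].cell_id for i in idx],
            "predicted_class": labels,
            "x_um": xy[idx, 0],
            "y_um": xy[idx, 1],
        }
    )


@dataclass(frozen=True)
class EvaluationResult:
    confusion: pd.DataFrame   # rows = truth, columns = prediction
    accuracy: float


def evaluate(predicted: pd.DataFrame, truth: Sequence[CellRecord]) -> EvaluationResult:
    """2x2 confusion matrix and accuracy of predictions against true labels."""
    truth_map = {c.cell_id: c.true_class for c in truth}
    unknown = [cid for cid in predicted["cell_id"] if cid not in truth_map]
    if unknown:
        raise EvaluationError(
            f"{len(unknown)} predicted cell_id(s) missing from truth, e.g. {unknown[:3]}"
        )
    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for cid, pred in zip(predicted["cell_id"], predicted["predicted_class"]):
        true = truth_map[cid]
        if true in CLASSES:
            conf.loc[true, pred] += 1
    total = int(conf.to_numpy().sum())
    acc = float(np.trace(conf.to_numpy()) / total) if total else float("nan")
    return EvaluationResult(confusion=conf, accuracy=acc)
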