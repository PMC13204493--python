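"""Per-object features, 4-class random-forest classification, evaluation.

Detected candidates are sorted into four categories: ``CART`` (captured
CAR T-cells), ``PLATELET``, ``RBC`` (residual red cells that survived
depletion) and ``OTHER`` (debris / anomalous / broken cells). A
100-tree random forest over a fixed, ordered feature vector does the
sorting; sensitivity and specificity are reported one-vs-rest for the
CART class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from skimage.measure import label as cc_label, regionprops
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .prefilter import Candidate

__all__ = [
    "CLASSES",
    "FEATURE_NAMES",
    "ObjectClass",
    "TrainedModel",
    "EvalReport",
    "extract_features",
    "train_classifier",
    "classify",
    "evaluate",
    "save_model",
    "load_model",
]

#: The four object categories, in canonical order.
CLASSES = ("CART", "PLATELET", "RBC", "OTHER")

#: Frozen feature order — the contract that makes trained models portable.
FEATURE_NAMES = (
    "area_px",
    "equivalent_radius_px",
    "perimeter_px",
    "circularity",
    "eccentricity",
    "mean_intensity",
    "median_intensity",
    "sd_intensity",
    "min_intensity",
    "max_intensity",
    "intensity_q25",
    "intensity_q50",
    "intensity_q75",
    "ring_contrast",
    "local_sd_mean",
    "peak_score",
)


class ObjectClass(str):
    """One of the four categories; plain strings validated on use."""

    def __new__(cls, value: str):
        if value not in CLASSES:
            raise ValueError(f"unknown object class {value!r}; expected one of {CLASSES}")
        return super().__new__(cls, value)


def extract_features(candidate: Candidate, std_response: np.ndarray | None = None) -> np.ndarray:
    """Compute the ordered feature vector for one candidate.

    Intensity statistics are taken over the mask pixels of the raw crop.
    ``ring_contrast`` is the mean intensity of the outer annulus
    (0.6r < d <= r around the centroid, r the equivalent radius) minus
    that of the inner disc (d <= 0.6r). ``std_response`` is the stage-1
    local-SD grid over the crop; if omitted, the per-pixel SD is
    recomputed from the crop.
    """
    mask = candidate.mask
    crop = candidate.crop.astype(float)
    if not mask.any():
        raise ValueError("candidate mask is empty")

    labeled = cc_label(mask.astype(int))
    # largest connected component carries the shape statistics
    props = max(regionprops(labeled), key=lambda p: p.area)
    area = float(mask.sum())
    eq_radius = np.sqrt(area / np.pi)
    perimeter = float(props.perimeter) if props.perimeter > 0 else 1.0
    circularity = 4.0 * np.pi * float(props.area) / perimeter**2
    eccentricity = float(props.eccentricity)

    vals = crop[mask]
    q25, q50, q75 = np.percentile(vals, [25, 50, 75])

    cy, cx = props.centroid
    yy, xx = np.mgrid[0 : crop.shape[0], 0 : crop.shape[1]]
    dist = np.hypot(yy - cy, xx - cx)
    inner = mask & (dist <= 0.6 * eq_radius)
    outer = mask & (dist > 0.6 * eq_radius) & (dist <= eq_radius)
    inner_mean = float(crop[inner].mean()) if inner.any() else float(vals.mean())
    outer_mean = float(crop[outer].mean()) if outer.any() else float(vals.mean())
    ring_contrast = outer_mean - inner_mean

    if std_response is None:
        from .prefilter import local_std_filter

        win = min(9, (min(crop.shape) // 2) * 2 - 1)
        std_response = local_std_filter(crop, max(win, 3)) if min(crop.shape) >= 3 else np.zeros_like(crop)
    local_sd_mean = float(np.asarray(std_response)[mask].mean())

    return np.array(
        [
            area,
            eq_radius,
            perimeter,
            circularity,
            eccentricity,
            float(vals.mean()),
            float(np.median(vals)),
            float(vals.std()),  # population SD
            float(vals.min()),
            float(vals.max()),
            float(q25),
            float(q50),
            float(q75),
            ring_contrast,
            local_sd_mean,
            float(candidate.peak_score),
        ]
    )


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to reapply it safely."""

    forest: RandomForestClassifier
    n_trees: int
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    oob_score: float | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim == 1:
            features = features[None, :]
        if features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature length {features.shape[1]} != model's {len(self.feature_names)}"
            )
        return self.forest.predict(features)


def train_classifier(
    labeled: list[tuple[np.ndarray, str]],
    n_trees: int = 100,
    seed: int = 20240101,
) -> TrainedModel:
    """Fit the 100-tree random forest on labeled feature vectors.

    Depth is unlimited, sqrt features per split, bootstrap on; identical
    seed and data give identical predictions.
    """
    if not labeled:
        raise ValueError("no training data")
    X = np.asarray([f for f, _ in labeled], dtype=float)
    y = np.asarray([ObjectClass(c) for _, c in labeled])
    present, counts = np.unique(y, return_counts=True)
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if counts.min() < 5:
        raise ValueError("every class needs at least 5 examples")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TrainedModel(
        forest=forest,
        n_trees=n_trees,
        feature_names=FEATURE_NAMES,
        classes=CLASSES,
        seed=seed,
        oob_score=float(forest.oob_score_),
    )


def classify(
    model: TrainedModel, candidates: list[Candidate]
) -> tuple[list[Candidate], dict[str, int]]:
    """Label every candidate in place; return candidates and class counts."""
    counts = {c: 0 for c in model.classes}
    if not candidates:
        return candidates, counts
    feats = []
    for cand in candidates:
        if cand.features is None:
            cand.features = extract_features(cand)
        feats.append(cand.features)
    predictions = model.predict(np.asarray(feats))
    for cand, pred in zip(candidates, predictions):
        cand.label = str(pred)
        counts[cand.label] += 1
    return candidates, counts


@dataclass
class EvalReport:
    """Confusion matrix and one-vs-rest metrics for the positive class."""

    confusion: np.ndarray  # 4x4 counts, rows = true, cols = predicted
    class_order: tuple[str, ...]
    sensitivity: dict[str, float] = field(default_factory=dict)
    specificity: dict[str, float] = field(default_factory=dict)
    accuracy: float = 0.0
    n_train: int = 0
    n_test: int = 0
    positive: str = "CART"


def evaluate(
    model: TrainedModel,
    test: list[tuple[np.ndarray, str]],
    positive: str = "CART",
    n_train: int = 0,
) -> EvalReport:
    """One-vs-rest sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP)."""
    if not test:
        raise ValueError("test set is empty")
    X = np.asarray([f for f, _ in test], dtype=float)
    y_true = np.asarray([ObjectClass(c) for _, c in test])
    y_pred = model.predict(X)
    order = list(model.classes)
    cm = confusion_matrix(y_true, y_pred, labels=order)
    report = EvalReport(
        confusion=cm,
        class_order=tuple(order),
        accuracy=float((y_true == y_pred).mean()),
        n_train=n_train,
        n_test=len(test),
        positive=positive,
    )
    total = cm.sum()
    for i, cls in enumerate(order):
        tp = cm[i, i]
        fn = cm[i, :].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        report.sensitivity[cls] = tp / (tp + fn) if tp + fn else float("nan")
        report.specificity[cls] = tn / (tn + fp) if tn + fp else float("nan")
    return report


_MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Serialize with an embedded feature-order manifest."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "feature_names": list(model.feature_names),
            "classes": list(model.classes),
            "n_trees": model.n_trees,
            "seed": model.seed,
            "oob_score": model.oob_score,
            "forest": model.forest,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    return TrainedModel(
        forest=blob["forest"],
        n_trees=blob["n_trees"],
        feature_names=tuple(blob["feature_names"]),
        classes=tuple(blob["classes"]),
        seed=blob["seed"],
        oob_score=blob["oob_score"],
    )
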