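"""k-nearest-neighbour classification of ACC vectors.

The classifier stores the (optionally standardized) 45-dimensional training
vectors verbatim and predicts by majority vote over the k closest vectors
under a Euclidean (default) or Manhattan metric.  The score of a query is the
fraction of its k neighbours labelled allergen; the verdict is "probable
allergen" when that fraction reaches the decision threshold (default 0.5,
i.e. simple majority for odd k).  For queries called allergen, the most
probable route of exposure (food, inhalant or toxin) is read off the route
tags of the allergen-labelled neighbours.

k is restricted to odd values so a 0.5 threshold can never fall on a 50/50
vote.  Distance ties are broken by training-set insertion order (stable
sort), which together with the fixed feature layout makes predictions fully
deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .acc import LAYOUT_ID

ALLERGEN = "allergen"
NON_ALLERGEN = "non-allergen"
LABELS = (ALLERGEN, NON_ALLERGEN)
ROUTES = ("food", "inhalant", "toxin")

MODEL_FORMAT = "allerknn-knn-1"


class ModelError(ValueError):
    """Raised for invalid model construction or corrupt model files."""


@dataclass(frozen=True)
class LabeledInstance:
    """One training protein: identifier, ACC vector, class label, route tags.

    ``routes`` is non-empty exactly when the label is allergen; allergens may
    carry several routes (e.g. a food allergen that is also a toxin).
    """

    id: str
    vector: np.ndarray
    label: str
    routes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ModelError(f"unknown label {self.label!r}")
        if self.label == ALLERGEN and not self.routes:
            raise ModelError(f"allergen {self.id!r} must carry >= 1 route tag")
        if self.label == NON_ALLERGEN and self.routes:
            raise ModelError(f"non-allergen {self.id!r} must not carry routes")
        if not set(self.routes) <= set(ROUTES):
            raise ModelError(f"unknown route tag in {sorted(self.routes)}")


@dataclass(frozen=True)
class Neighbour:
    id: str
    distance: float
    label: str
    routes: frozenset[str]


@dataclass(frozen=True)
class Prediction:
    """Outcome of one query: verdict, allergen-neighbour fraction, evidence."""

    query_id: str
    verdict: str  # "probable_allergen" | "probable_non_allergen"
    score: float  # fraction of the k neighbours labelled allergen
    neighbours: tuple[Neighbour, ...]
    route: str | None  # set iff verdict is probable_allergen


@dataclass
class KNNModel:
    """Fitted k-nearest-neighbour model over 45-dimensional ACC vectors."""

    X: np.ndarray                 # m x d matrix actually used for distances
    ids: list[str]
    labels: list[str]
    routes: list[frozenset[str]]
    k: int = 3
    metric: str = "euclidean"
    layout: str = LAYOUT_ID
    # standardization fitted on training data; None when scaling is off
    scale_mean: np.ndarray | None = None
    scale_std: np.ndarray | None = None
    feature_mask: np.ndarray | None = None  # kept features (drops zero-variance)

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model to a versioned flat JSON file (deterministic bytes)."""
        doc = {
            "format": MODEL_FORMAT,
            "layout": self.layout,
            "k": self.k,
            "metric": self.metric,
            "scale_mean": None if self.scale_mean is None else self.scale_mean.tolist(),
            "scale_std": None if self.scale_std is None else self.scale_std.tolist(),
            "feature_mask": None if self.feature_mask is None else self.feature_mask.astype(int).tolist(),
            "ids": self.ids,
            "labels": self.labels,
            "routes": [sorted(r) for r in self.routes],
            "X": self.X.tolist(),
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "KNNModel":
        try:
            doc = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ModelError(f"cannot read model file {path}: {exc}") from exc
        if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
            raise ModelError(
                f"unsupported model file format {doc.get('format')!r} "
                f"(expected {MODEL_FORMAT!r})" if isinstance(doc, dict)
                else "model file is not a JSON object"
            )
        if doc.get("layout") != LAYOUT_ID:
            raise ModelError(
                f"feature layout mismatch: file has {doc.get('layout')!r}, "
                f"this build uses {LAYOUT_ID!r}"
            )
        return cls(
            X=np.asarray(doc["X"], dtype=float),
            ids=list(doc["ids"]),
            labels=list(doc["labels"]),
            routes=[frozenset(r) for r in doc["routes"]],
            k=int(doc["k"]),
            metric=str(doc["metric"]),
            layout=str(doc["layout"]),
            scale_mean=None if doc["scale_mean"] is None else np.asarray(doc["scale_mean"], dtype=float),
            scale_std=None if doc["scale_std"] is None else np.asarray(doc["scale_std"], dtype=float),
            feature_mask=None if doc["feature_mask"] is None else np.asarray(doc["feature_mask"], dtype=bool),
        )


def fit_knn(
    training: Sequence[LabeledInstance],
    k: int = 3,
    metric: str = "euclidean",
    scale: bool = False,
) -> KNNModel:
    """Fit a kNN model on labelled ACC vectors.

    With ``scale=True`` each feature is z-score standardized using means and
    standard deviations fitted on the training data only; zero-variance
    features are excluded with a warning (they carry no neighbour
    information and would divide by zero).

    Raises
    ------
    ModelError
        If the training set is empty or single-class, k is even or exceeds
        the training-set size, or the metric is unknown.
    """
    if not training:
        raise ModelError("training set is empty")
    if metric not in ("euclidean", "manhattan"):
        raise ModelError(f"unknown distance metric {metric!r}")
    if k < 1 or k % 2 == 0:
        raise ModelError(f"k must be odd and >= 1, got {k}")
    if k > len(training):
        raise ModelError(f"k={k} exceeds training-set size {len(training)}")
    present = {inst.label for inst in training}
    if len(present) < 2:
        raise ModelError(f"training set contains a single class: {present}")

    X = np.vstack([inst.vector for inst in training]).astype(float)
    dims = {inst.vector.shape for inst in training}
    if len(dims) != 1:
        raise ModelError(f"inconsistent vector lengths in training set: {dims}")

    scale_mean = scale_std = feature_mask = None
    if scale:
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        keep = std > 0
        if not keep.all():
            dropped = int((~keep).sum())
            warnings.warn(
                f"excluding {dropped} zero-variance feature(s) from the "
                f"standardized model", stacklevel=2,
            )
        feature_mask = keep
        scale_mean, scale_std = mean[keep], std[keep]
        X = (X[:, keep] - scale_mean) / scale_std

    return KNNModel(
        # C-contiguous so reduction order (hence distances) is identical
        # before and after a save/load round-trip
        X=np.ascontiguousarray(X),
        ids=[inst.id for inst in training],
        labels=[inst.label for inst in training],
        routes=[inst.routes for inst in training],
        k=k,
        metric=metric,
        scale_mean=scale_mean,
        scale_std=scale_std,
        feature_mask=feature_mask,
    )


def _distances(model: KNNModel, q: np.ndarray) -> np.ndarray:
    diff = model.X - q
    if model.metric == "euclidean":
        return np.sqrt((diff * diff).sum(axis=1))
    return np.abs(diff).sum(axis=1)


def predict(
    model: KNNModel,
    query: np.ndarray,
    threshold: float = 0.5,
    *,
    query_id: str = "",
) -> Prediction:
    """Classify one ACC vector against a fitted model.

    The query is standardized with the model's stored training-fold
    parameters when the model was fitted with scaling.  Neighbours are
    returned in non-decreasing distance order, ties resolved by training
    insertion order.
    """
    if model.n_instances == 0:
        raise ModelError("model has no training instances")
    q = np.asarray(query, dtype=float).ravel()
    if model.feature_mask is not None:
        if q.shape[0] != model.feature_mask.shape[0]:
            raise ModelError(
                f"query length {q.shape[0]} != expected {model.feature_mask.shape[0]}"
            )
        q = (q[model.feature_mask] - model.scale_mean) / model.scale_std
    elif q.shape[0] != model.X.shape[1]:
        raise ModelError(f"query length {q.shape[0]} != expected {model.X.shape[1]}")

    dist = _distances(model, q)
    order = np.argsort(dist, kind="stable")[: model.k]
    neighbours = tuple(
        Neighbour(
            id=model.ids[i],
            distance=float(dist[i]),
            label=model.labels[i],
            routes=model.routes[i],
        )
        for i in order
    )
    score = sum(nb.label == ALLERGEN for nb in neighbours) / model.k
    if score >= threshold:
        verdict = "probable_allergen"
        route = assign_route(neighbours)
    else:
        verdict = "probable_non_allergen"
        route = None
    return Prediction(
        query_id=query_id, verdict=verdict, score=score,
        neighbours=neighbours, route=route,
    )


def assign_route(neighbours: Sequence[Neighbour]) -> str | None:
    """Most probable route of exposure from the allergen-labelled neighbours.

    Each allergen neighbour contributes one count per route tag it carries
    (multi-route allergens vote for every one of their routes).  The route
    with the highest count wins; ties go to the route of the nearest
    allergen neighbour, then to the fixed order food < inhalant < toxin.
    Returns None (with a warning) when no neighbour is an allergen, which can
    only happen for allergen verdicts reached at a threshold below 0.5.
    """
    allergen_nbs = [nb for nb in neighbours if nb.label == ALLERGEN]
    if not allergen_nbs:
        warnings.warn("no allergen neighbour available for route assignment",
                      stacklevel=2)
        return None
    counts = {r: 0 for r in ROUTES}
    for nb in allergen_nbs:
        for r in nb.routes:
            counts[r] += 1
    best = max(counts.values())
    tied = [r for r in ROUTES if counts[r] == best]
    if len(tied) == 1:
        return tied[0]
    # nearest allergen neighbour whose routes intersect the tied set decides
    for nb in allergen_nbs:  # already sorted by distance
        hit = [r for r in ROUTES if r in nb.routes and r in tied]
        if hit:
            return hit[0]
    return tied[0]
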