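"""Performance metrics, cross-validation, the k-scan and route cross-comparison.

Metrics follow the usual two-class conventions with allergen as the positive
class: sensitivity TP/(TP+FN), specificity TN/(TN+FP), positive predictive
value TP/(TP+FP), F1 = 2*sens*ppv/(sens+ppv), all at a score threshold
(default 0.5).  AUC is computed by the Mann-Whitney rank formulation with
half credit for ties, which is the appropriate choice for kNN scores that
are coarse multiples of 1/k.

Cross-validation is stratified 5-fold (80/20); all fold-dependent fitting
(feature standardization, the model itself) uses the training fold only.
Fold metrics are aggregated by pooling confusion counts (micro-average);
per-fold reports are kept alongside.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .acc import DEFAULT_LAGS, acc_matrix
from .datasets import LabeledDataset, split_folds
from .knn import ALLERGEN, LabeledInstance, fit_knn, predict


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived metrics for one evaluation.

    Metrics undefined on the given data (e.g. sensitivity with no positive
    instances) are reported as NaN, never silently as zero.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    f1: float
    auc: float
    threshold: float
    n_evaluated: int

    def to_dict(self) -> dict:
        return asdict(self)

    def format_row(self, name: str = "") -> str:
        def fmt(x: float) -> str:
            return "   nan" if math.isnan(x) else f"{x:6.3f}"
        return (
            f"{name:<12} n={self.n_evaluated:<5d} "
            f"sens={fmt(self.sensitivity)} spec={fmt(self.specificity)} "
            f"ppv={fmt(self.ppv)} f1={fmt(self.f1)} auc={fmt(self.auc)}"
        )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return math.nan
    return num / den


def mann_whitney_auc(y_true: Sequence[bool], scores: Sequence[float]) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted half."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined for single-class input; reporting NaN",
                      stacklevel=3)
        return math.nan
    ranks = rankdata(s)  # average ranks handle ties -> half credit
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compute_metrics(
    predictions: Sequence[tuple[str, float]] | Sequence[tuple[bool, float]],
    threshold: float = 0.5,
) -> MetricsReport:
    """Score a list of ``(true label, allergen score)`` pairs.

    Labels may be the strings ``"allergen"`` / ``"non-allergen"`` or
    booleans (True = allergen).  A prediction is positive when its score is
    >= ``threshold``.
    """
    if not predictions:
        raise EvaluationError("no predictions to evaluate")
    y_true = []
    scores = []
    for label, score in predictions:
        truth = label if isinstance(label, (bool, np.bool_)) else label == ALLERGEN
        if not 0.0 <= score <= 1.0:
            raise EvaluationError(f"score {score} outside [0, 1]")
        y_true.append(bool(truth))
        scores.append(float(score))

    y = np.asarray(y_true)
    pred_pos = np.asarray(scores) >= threshold
    tp = int((y & pred_pos).sum())
    tn = int((~y & ~pred_pos).sum())
    fp = int((~y & pred_pos).sum())
    fn = int((y & ~pred_pos).sum())

    sens = _safe_div(tp, tp + fn, "sensitivity")
    spec = _safe_div(tn, tn + fp, "specificity")
    ppv = _safe_div(tp, tp + fp, "ppv")
    if math.isnan(sens) or math.isnan(ppv) or (sens + ppv) == 0:
        f1 = math.nan
        if not (math.isnan(sens) or math.isnan(ppv)):
            warnings.warn("F1 undefined (sensitivity + ppv = 0); reporting NaN",
                          stacklevel=2)
    else:
        f1 = 2 * sens * ppv / (sens + ppv)
    auc = mann_whitney_auc(y, scores)

    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sens, specificity=spec, ppv=ppv, f1=f1, auc=auc,
        threshold=threshold, n_evaluated=len(predictions),
    )


# ---------------------------------------------------------------------------
# pipeline configuration and featurization


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings; the defaults are the method's published operating
    point (maximum lag 5, k = 3, decision threshold 0.5)."""

    lags: int = DEFAULT_LAGS
    k: int = 3
    metric: str = "euclidean"
    scale: bool = False
    threshold: float = 0.5
    permissive: bool = False


def featurize(
    dataset: LabeledDataset, config: PipelineConfig = PipelineConfig()
) -> list[LabeledInstance]:
    """ACC-transform every clean record of a dataset into labelled instances."""
    records = dataset.clean_records
    ids, X = acc_matrix(
        ((r.id, r.sequence) for r in records),
        lags=config.lags, permissive=config.permissive,
    )
    return [
        LabeledInstance(id=r.id, vector=X[i], label=r.label, routes=r.routes)
        for i, r in enumerate(records)
    ]


def _evaluate_fold(
    train: LabeledDataset, test: LabeledDataset, config: PipelineConfig
) -> list[tuple[str, float]]:
    model = fit_knn(featurize(train, config), k=config.k,
                    metric=config.metric, scale=config.scale)
    pairs = []
    for inst in featurize(test, config):
        pred = predict(model, inst.vector, threshold=config.threshold,
                       query_id=inst.id)
        pairs.append((inst.label, pred.score))
    return pairs


@dataclass(frozen=True)
class CVResult:
    pooled: MetricsReport
    per_fold: tuple[MetricsReport, ...]
    macro: dict[str, float]  # per-fold mean of each metric

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled.to_dict(),
            "per_fold": [r.to_dict() for r in self.per_fold],
            "macro": self.macro,
        }


def _macro(per_fold: Sequence[MetricsReport]) -> dict[str, float]:
    keys = ("sensitivity", "specificity", "ppv", "f1", "auc")
    return {
        key: float(np.nanmean([getattr(r, key) for r in per_fold]))
        for key in keys
    }


def cross_validate(
    dataset: LabeledDataset,
    config: PipelineConfig = PipelineConfig(),
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified n-fold cross-validation of the kNN pipeline.

    Featurization parameters and the model are fitted per training fold
    only; the pooled report aggregates confusion counts over all test folds.
    """
    folds = split_folds(dataset, n_folds=n_folds, seed=seed)
    all_pairs: list[tuple[str, float]] = []
    per_fold: list[MetricsReport] = []
    for train, test in folds:
        pairs = _evaluate_fold(train, test, config)
        per_fold.append(compute_metrics(pairs, threshold=config.threshold))
        all_pairs.extend(pairs)
    pooled = compute_metrics(all_pairs, threshold=config.threshold)
    return CVResult(pooled=pooled, per_fold=tuple(per_fold), macro=_macro(per_fold))


def k_scan(
    dataset: LabeledDataset,
    k_values: Sequence[int] = (1, 3, 5, 7, 9),
    config: PipelineConfig = PipelineConfig(),
    n_folds: int = 5,
    seed: int = 0,
) -> dict[int, CVResult]:
    """Cross-validate the pipeline over several (odd) k on identical folds.

    Folds are computed once so the per-k comparison is paired.
    """
    for k in k_values:
        if k < 1 or k % 2 == 0:
            raise EvaluationError(f"k values must be odd and >= 1, got {k}")
    folds = split_folds(dataset, n_folds=n_folds, seed=seed)
    out: dict[int, CVResult] = {}
    for k in k_values:
        cfg = PipelineConfig(
            lags=config.lags, k=k, metric=config.metric, scale=config.scale,
            threshold=config.threshold, permissive=config.permissive,
        )
        all_pairs: list[tuple[str, float]] = []
        per_fold = []
        for train, test in folds:
            pairs = _evaluate_fold(train, test, cfg)
            per_fold.append(compute_metrics(pairs, threshold=cfg.threshold))
            all_pairs.extend(pairs)
        out[k] = CVResult(
            pooled=compute_metrics(all_pairs, threshold=cfg.threshold),
            per_fold=tuple(per_fold),
            macro=_macro(per_fold),
        )
    return out


# ---------------------------------------------------------------------------
# route cross-comparison


@dataclass(frozen=True)
class CrossCompareGrid:
    """Metrics for every (model route, test route) combination.

    Diagonal cells are honest held-out estimates: the model trained on each
    training fold is scored on the matching test fold of its own route.
    Off-diagonal cells score the same per-fold models on the test folds of a
    different route, so a model never sees its own test data.
    """

    cells: Mapping[tuple[str, str], MetricsReport]
    model_routes: tuple[str, ...]
    test_routes: tuple[str, ...]

    def to_tsv(self, metric: str = "sensitivity") -> str:
        lines = ["model\\test\t" + "\t".join(self.test_routes)]
        for mr in self.model_routes:
            vals = [getattr(self.cells[(mr, tr)], metric) for tr in self.test_routes]
            lines.append(mr + "\t" + "\t".join(f"{v:.3f}" for v in vals))
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            f"{mr}|{tr}": rep.to_dict() for (mr, tr), rep in self.cells.items()
        }


def cross_compare(
    route_datasets: Mapping[str, LabeledDataset],
    config: PipelineConfig = PipelineConfig(),
    n_folds: int = 5,
    seed: int = 0,
) -> CrossCompareGrid:
    """Train per-route models and score each on every route's test folds.

    ``route_datasets`` maps route names (typically food, inhalant, toxin and
    total) to labelled datasets.  Every dataset is split into the same
    number of stratified folds with the same seed; model route r evaluated
    on test route s pools, over folds f, the predictions of the model
    trained on fold f of r against the test fold f of s.
    """
    routes = tuple(route_datasets)
    folds = {r: split_folds(ds, n_folds=n_folds, seed=seed)
             for r, ds in route_datasets.items()}
    models: dict[str, list] = {}
    for r in routes:
        models[r] = [
            fit_knn(featurize(train, config), k=config.k,
                    metric=config.metric, scale=config.scale)
            for train, _test in folds[r]
        ]
    cells: dict[tuple[str, str], MetricsReport] = {}
    for mr in routes:
        for tr in routes:
            pairs: list[tuple[str, float]] = []
            for f in range(n_folds):
                model = models[mr][f]
                _train, test = folds[tr][f]
                for inst in featurize(test, config):
                    pred = predict(model, inst.vector,
                                   threshold=config.threshold, query_id=inst.id)
                    pairs.append((inst.label, pred.score))
            cells[(mr, tr)] = compute_metrics(pairs, threshold=config.threshold)
    return CrossCompareGrid(cells=cells, model_routes=routes, test_routes=routes)


def _json_safe(obj):
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


def write_report(obj, path: str | Path) -> None:
    """Serialize a report object (with ``to_dict``) to JSON; NaN -> null."""
    data = obj.to_dict() if hasattr(obj, "to_dict") else obj
    text = json.dumps(_json_safe(data), indent=2, sort_keys=True)
    Path(path).write_text(text + "\n")
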