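"""Comparison baselines for the classifier-selection experiment.

The kNN route uses this package's own implementation; naive Bayes, logistic
regression and decision-tree baselines delegate to scikit-learn — they are
reference points for the method comparison, not the contribution.  All
classifiers operate on the same 45-dimensional ACC vectors and are scored by
the evaluation module, so a single call reproduces the design of the
method-comparison experiment on any labelled dataset.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .evaluation import MetricsReport, compute_metrics
from .knn import ALLERGEN, LabeledInstance, fit_knn, predict

BASELINE_METHODS = ("knn", "nb", "lr", "dt")


class BaselineError(ValueError):
    pass


def _sklearn_estimator(method: str, seed: int):
    if method == "nb":
        return GaussianNB()
    if method == "lr":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=2000, random_state=seed)
        )
    if method == "dt":
        return DecisionTreeClassifier(random_state=seed)
    raise BaselineError(f"unknown method {method!r}")


def run_baselines(
    training: Sequence[LabeledInstance],
    test: Sequence[LabeledInstance],
    methods: Sequence[str] = BASELINE_METHODS,
    *,
    k: int = 3,
    threshold: float = 0.5,
    seed: int = 0,
) -> Mapping[str, MetricsReport]:
    """Train each requested classifier and score it on the held-out set.

    Train and test must be disjoint by instance id.  Scores fed to the
    metrics are the allergen-class probability (the allergen-neighbour
    fraction for kNN, ``predict_proba`` for the scikit-learn baselines).
    """
    overlap = {i.id for i in training} & {i.id for i in test}
    if overlap:
        raise BaselineError(f"train/test sets share ids: {sorted(overlap)[:5]}")
    for m in methods:
        if m not in BASELINE_METHODS:
            raise BaselineError(f"unknown method {m!r}; choose from {BASELINE_METHODS}")

    X_train = np.vstack([i.vector for i in training])
    y_train = np.array([i.label == ALLERGEN for i in training])
    X_test = np.vstack([i.vector for i in test])
    y_test = [i.label for i in test]

    reports: dict[str, MetricsReport] = {}
    for m in methods:
        if m == "knn":
            model = fit_knn(training, k=k)
            scores = [predict(model, x, threshold=threshold).score for x in X_test]
        else:
            est = _sklearn_estimator(m, seed)
            est.fit(X_train, y_train)
            pos = list(est.classes_).index(True)
            scores = est.predict_proba(X_test)[:, pos].tolist()
        reports[m] = compute_metrics(list(zip(y_test, scores)), threshold=threshold)
    return reports
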