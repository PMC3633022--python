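"""Independent brute-force oracles used to validate the production code.

These deliberately mirror the mathematical definitions with literal Python
loops and share no code with the package implementation.
"""

from __future__ import annotations

import math

# emission order must match the documented layout: pair-major, lag-minor
PAIR_ORDER = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def acc_oracle(zmatrix, lags: int) -> list[float]:
    """Quadruple-loop ACC transform straight from the covariance formulas.

    The lagged products are accumulated with ``math.fsum`` so the oracle
    itself introduces no rounding beyond the final division.
    """
    n = len(zmatrix)
    out = []
    for j, k in PAIR_ORDER:
        for lag in range(1, lags + 1):
            products = []
            for i in range(n - lag):
                products.append(zmatrix[i][j] * zmatrix[i + lag][k])
            out.append(math.fsum(products) / (n - lag))
    return out


def knn_oracle(train_vectors, train_labels, query, k: int, metric: str = "euclidean"):
    """Exhaustive-distance kNN: all pairwise distances, full stable sort.

    Returns (neighbour indices, allergen score) with ties broken by
    training insertion order.
    """
    dists = []
    for idx, vec in enumerate(train_vectors):
        if metric == "euclidean":
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(vec, query)))
        else:
            d = sum(abs(a - b) for a, b in zip(vec, query))
        dists.append((d, idx))
    dists.sort(key=lambda t: (t[0], t[1]))
    top = dists[:k]
    score = sum(train_labels[idx] == "allergen" for _, idx in top) / k
    return [idx for _, idx in top], score


def auc_oracle(y_true, scores) -> float:
    """O(n^2) pair-count AUC: ties between classes earn half credit."""
    pos = [s for y, s in zip(y_true, scores) if y]
    neg = [s for y, s in zip(y_true, scores) if not y]
    if not pos or not neg:
        return math.nan
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
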