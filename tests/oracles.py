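"""Independent brute-force oracles used to freeze expected values.

These deliberately share no code with the package: MI is a literal
summation over an explicit joint-count dictionary (math.fsum, so the
result is independent of term order), and the greedy ranking is the
naive O(n_features² · n_samples) loop.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def oracle_discretize(values, alpha=1.0):
    """Three states around mean ± alpha * population std, boundaries → 0."""
    values = np.asarray(values, dtype=float)
    mu = float(np.mean(values))
    sigma = float(np.std(values))
    out = []
    for v in values:
        if sigma == 0:
            out.append(0)
        elif v < mu - alpha * sigma:
            out.append(-1)
        elif v > mu + alpha * sigma:
            out.append(1)
        else:
            out.append(0)
    return out


def oracle_mi(x, y) -> float:
    """Plug-in MI in bits by direct summation over the joint counts."""
    x, y = list(x), list(y)
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    terms = []
    for (a, b), c in joint.items():
        pab = c / n
        terms.append(pab * math.log2(pab / ((px[a] / n) * (py[b] / n))))
    return math.fsum(terms)


def oracle_mrmr(X, y, alpha=1.0, n_select=None, score_decimals=10):
    """Naive greedy difference-criterion ranking; 1-based indices.

    Scores are compared after rounding to ``score_decimals`` places and
    ties go to the lowest feature index (strict > on the running best):
    distinct tables can have exactly equal MI sums as reals, so a
    tolerance grid is part of the tie-break contract."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    cols = [oracle_discretize(X[:, j], alpha) for j in range(m)]
    labels = list(y)
    relevance = [oracle_mi(cols[j], labels) for j in range(m)]
    if n_select is None:
        n_select = m
    order: list[int] = []
    chosen: list[int] = []
    for _ in range(n_select):
        best_j, best_score = None, None
        for j in range(m):
            if j in chosen:
                continue
            if chosen:
                red = math.fsum(oracle_mi(cols[j], cols[g]) for g in chosen) / len(chosen)
            else:
                red = 0.0
            score = round(relevance[j] - red, score_decimals)
            if best_score is None or score > best_score:
                best_j, best_score = j, score
        chosen.append(best_j)
        order.append(best_j + 1)
    return order


def oracle_valid_starts(window_len, k, center):
    """Filter every start 1..L-k+1 by explicit span membership."""
    keep = []
    for s in range(1, window_len - k + 2):
        span = set(range(s, s + k))
        if center not in span:
            keep.append(s)
    return keep
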