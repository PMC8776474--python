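"""Minimum-redundancy maximum-relevance (mRMR) feature ranking.

Continuous features are first discretized into three states around their
mean (below μ−α·σ, within μ±α·σ, above μ+α·σ).  Relevance of a feature
is its plug-in mutual information (in bits) with the class label;
redundancy is the mean mutual information with the features already
ranked.  The greedy "difference" (MID) rule repeatedly appends the
feature maximizing relevance − redundancy until every feature is ranked.

Ties at any greedy step break to the lowest feature index.  Ties are
decided on a tolerance grid: the greedy decision score is rounded to
``SCORE_DECIMALS`` (10) decimal places before comparison, because
distinct contingency tables can have exactly equal MI sums as real
numbers while their floating-point evaluations differ in the last few
ulps — without the grid, such true ties would be broken by rounding
noise.  MI terms are additionally summed in sorted order so
permutation-equivalent tables yield bitwise-identical MI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encode import FeatureMatrix
from .errors import ValidationError

#: decimal places at which greedy decision scores are compared; scores
#: closer than this are treated as tied (lowest feature index wins)
SCORE_DECIMALS = 10


def discretize(values: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Three-state discretization around the mean.

    States: −1 below ``μ − α·σ``, +1 above ``μ + α·σ``, 0 inside the
    closed interval (boundary values map to 0).  σ is the population
    standard deviation; a constant vector (σ = 0) maps entirely to 0.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a nonempty 1-D vector")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    mu = values.mean()
    sigma = values.std()  # population (ddof=0)
    states = np.zeros(values.size, dtype=np.int8)
    if sigma > 0:
        states[values < mu - alpha * sigma] = -1
        states[values > mu + alpha * sigma] = 1
    return states


def _mi_from_counts(counts: np.ndarray) -> float:
    """Plug-in MI in bits from a 2-D contingency table of counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    terms = np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0)
    # sorted summation: permutation-equivalent tables give identical floats
    return float(np.sort(terms, axis=None).sum())


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (bits) of two discrete vectors.

    Empirical joint distribution; cells with zero probability contribute
    nothing.  Nonnegative up to rounding (tiny negative results are
    clipped to 0).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("x and y must be 1-D")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("vectors must be nonempty")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    a, b = xi.max() + 1, yi.max() + 1
    counts = np.bincount(xi * b + yi, minlength=a * b).reshape(a, b)
    return max(_mi_from_counts(counts), 0.0)


def _batch_mi(x_codes: np.ndarray, nx: int, y_codes: np.ndarray, ny: int) -> np.ndarray:
    """MI (bits) of each column of ``x_codes`` against ``y_codes``.

    ``x_codes`` is (n_samples, m) with integer states in [0, nx);
    ``y_codes`` is (n_samples,) with states in [0, ny).  Uses the same
    sorted-term summation as :func:`_mi_from_counts` so values agree
    bitwise with the pairwise path.
    """
    n, m = x_codes.shape
    cell = nx * ny
    flat = (x_codes * ny + y_codes[:, None] + np.arange(m) * cell).ravel()
    counts = np.bincount(flat, minlength=m * cell).reshape(m, nx, ny).astype(float)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    terms = np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0)
    return np.sort(terms.reshape(m, cell), axis=1).sum(axis=1)


@dataclass
class RankedList:
    """An mRMR ordering with per-step scores.

    ``order`` is a permutation of the 1-based feature indices;
    ``step_scores`` holds, per rank, the triple (relevance MI(f, c),
    mean redundancy to the already-ranked features, difference).  The
    first-ranked feature has redundancy 0.
    """

    order: list[int]
    step_scores: list[tuple[float, float, float]]

    def __len__(self) -> int:
        return len(self.order)

    def top(self, n: int) -> list[int]:
        return self.order[:n]


def mrmr_rank(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    n_select: int | None = None,
    alpha: float = 1.0,
) -> RankedList:
    """Greedy mRMR ranking under the difference (MID) criterion.

    Accepts a :class:`FeatureMatrix` (labels taken from it) or a plain
    (n_samples, n_features) array plus a label vector.  Features are
    discretized once up front with :func:`discretize`; labels are used
    as-is as a discrete variable and are never discretized.  Pairwise
    feature–feature MI values are computed lazily, once per ranked
    feature, and reused across steps.
    """
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        y = matrix.y
    else:
        X = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValueError("labels are required when passing a raw matrix")
        y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("matrix must be 2-D with at least one feature")
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if y.shape != (n,):
        raise ValueError("label vector length must match sample count")
    if np.unique(y).size < 2:
        raise ValidationError("both classes must be present for mRMR ranking")
    if n_select is None:
        n_select = m
    if not 1 <= n_select <= m:
        raise ValueError(f"n_select={n_select} outside [1, {m}]")

    # discretize features once; map states {-1,0,1} -> codes {0,1,2}
    codes = np.empty((n, m), dtype=np.int64)
    for j in range(m):
        codes[:, j] = discretize(X[:, j], alpha=alpha) + 1
    y_codes = np.unique(y, return_inverse=True)[1]

    relevance = _batch_mi(codes, 3, y_codes, int(y_codes.max()) + 1)

    order: list[int] = []
    scores: list[tuple[float, float, float]] = []
    remaining = np.ones(m, dtype=bool)
    red_sum = np.zeros(m)

    for step in range(n_select):
        if step == 0:
            redundancy = np.zeros(m)
        else:
            redundancy = red_sum / step
        diff = relevance - redundancy
        diff[~remaining] = -np.inf
        # first max on the tolerance grid -> lowest index tie-break
        pick = int(np.argmax(np.round(diff, SCORE_DECIMALS)))
        order.append(pick + 1)
        scores.append((float(relevance[pick]), float(redundancy[pick]), float(diff[pick])))
        remaining[pick] = False
        if step < n_select - 1:
            red_sum += _batch_mi(codes, 3, codes[:, pick], 3)

    return RankedList(order=order, step_scores=scores)


def write_ranked(ranked: RankedList, path: str | Path, header: str | None = None) -> None:
    """Export TSV: rank, feature_id, relevance_bits, redundancy_bits, difference."""
    rows = [
        {
            "rank": r + 1,
            "feature_id": fid,
            "relevance_bits": rel,
            "redundancy_bits": red,
            "difference": diff,
        }
        for r, (fid, (rel, red, diff)) in enumerate(zip(ranked.order, ranked.step_scores))
    ]
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_ranked(path: str | Path) -> RankedList:
    df = pd.read_csv(path, sep="\t", comment="#")
    return RankedList(
        order=df["feature_id"].astype(int).tolist(),
        step_scores=list(
            zip(df["relevance_bits"], df["redundancy_bits"], df["difference"])
        ),
    )
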