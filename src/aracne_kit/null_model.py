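"""Permutation null model for MI thresholding.

Shuffling every gene row independently across samples destroys all
gene-gene dependence while preserving each marginal, so MI values computed
on the permuted matrix form the null distribution of the estimator under
independence. The empirical upper quantile of ``n0`` such values gives the
MI cutoff at a p-value; p-values below the empirical resolution 1/n0 use
an exponential right-tail extrapolation (a least-squares line fitted to
log survival against MI over the upper tail).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .apmi import DEFAULT_CHI2_CRIT, DEFAULT_MIN_POINTS, _apmi_y_of_x
from .data_io import ExpressionMatrix, TFIndexSet
from .ranking import rank_transform

#: Default number of null MI draws.
DEFAULT_N0 = 100_000
_MIN_TAIL_POINTS = 50


@dataclass
class NullDistribution:
    """Sorted null MI values plus the fitted right-tail survival model
    ln S(mi) = slope * mi + intercept."""

    mi_values: np.ndarray  # sorted ascending, length n0
    n0: int
    tail_slope: float
    tail_intercept: float

    def __post_init__(self) -> None:
        self.mi_values = np.asarray(self.mi_values, dtype=np.float64)
        if self.mi_values.shape != (self.n0,):
            raise ValueError("mi_values length must equal n0")
        if np.any(np.diff(self.mi_values) < 0):
            raise ValueError("mi_values must be sorted ascending")


def permute_matrix(matrix: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Independently shuffle each gene row across samples (seeded)."""
    rng = np.random.default_rng([int(seed), 0x9E3779B9])
    values = matrix.values.copy()
    for g in range(values.shape[0]):
        rng.shuffle(values[g])
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), values)


def _fit_tail(sorted_mis: np.ndarray, n0: int) -> tuple[float, float]:
    """Least-squares line of ln(empirical survival) vs MI over the largest
    ceil(n0/1000) (minimum 50) distinct upper-tail values."""
    distinct = np.unique(sorted_mis)  # ascending
    k = max(_MIN_TAIL_POINTS, math.ceil(n0 / 1000))
    tail = distinct[-k:] if distinct.size > k else distinct
    if tail.size < 2:
        # degenerate null (e.g. every MI clamped to zero at tiny M):
        # no tail model exists; thresholds below 1/n0 fall back to the
        # empirical maximum
        return float("nan"), float("nan")
    # survival S(v) = P(MI >= v), strictly positive at observed values
    surv = (n0 - np.searchsorted(sorted_mis, tail, side="left")) / n0
    slope, intercept = np.polyfit(tail, np.log(surv), 1)
    return float(slope), float(intercept)


def sample_null_mis(
    matrix: ExpressionMatrix,
    tfs: TFIndexSet,
    n0: int = DEFAULT_N0,
    seed: int = 0,
    chi2_crit: float = DEFAULT_CHI2_CRIT,
    min_points: int = DEFAULT_MIN_POINTS,
) -> NullDistribution:
    """Draw ``n0`` null MI values from a row-permuted copy of ``matrix``.

    Pairs are sampled uniformly with replacement from the hypothesis space
    (a TF row against a different gene row).
    """
    if n0 < 100:
        raise ValueError("n0 must be at least 100 for a defined tail fit")
    permuted = permute_matrix(matrix, seed)
    ranks = rank_transform(permuted, seed=int(seed) + 1)
    rng = np.random.default_rng([int(seed), 0x5D2E1F])
    tf_rows = tfs.sorted_rows()
    n_genes = ranks.n_genes
    t_idx = tf_rows[rng.integers(0, tf_rows.shape[0], size=n0)]
    g_idx = rng.integers(0, n_genes, size=n0)
    clash = g_idx == t_idx
    while np.any(clash):
        g_idx[clash] = rng.integers(0, n_genes, size=int(clash.sum()))
        clash = g_idx == t_idx
    rank_rows = ranks.ranks
    mis = np.empty(n0, dtype=np.float64)
    inv_cache: dict[int, np.ndarray] = {}
    for i in range(n0):
        t = int(t_idx[i])
        inv_x = inv_cache.get(t)
        if inv_x is None:
            x = rank_rows[t]
            inv_x = np.empty_like(x)
            inv_x[x] = np.arange(x.shape[0], dtype=np.intp)
            inv_cache[t] = inv_x
        mis[i], _ = _apmi_y_of_x(rank_rows[int(g_idx[i])][inv_x], chi2_crit, min_points)
    mis.sort()
    slope, intercept = _fit_tail(mis, n0)
    return NullDistribution(mis, n0, slope, intercept)


def mi_threshold(null: NullDistribution, p_value: float) -> float:
    """MI cutoff at ``p_value`` from the null distribution.

    For p >= 1/n0 the cutoff is the smallest observed null MI whose
    empirical survival is <= p; below the empirical resolution the fitted
    tail is extrapolated and floored just above the observed maximum.
    The cutoff is non-increasing in p.
    """
    if not (0.0 < p_value <= 1.0):
        raise ValueError("p_value must be in (0, 1]")
    a = null.mi_values
    n0 = null.n0
    if p_value >= 1.0 / n0:
        distinct = np.unique(a)
        surv = (n0 - np.searchsorted(a, distinct, side="left")) / n0
        ok = surv <= p_value  # survival is non-increasing along distinct
        if np.any(ok):
            return float(distinct[np.argmax(ok)])
        # ties at the maximum can leave no observed value at this p;
        # fall through to the tail extrapolation
    floor = float(np.nextafter(a[-1], np.inf))
    if not (null.tail_slope < 0):  # degenerate or missing fit: no usable decay
        return floor
    extrapolated = (math.log(p_value) - null.tail_intercept) / null.tail_slope
    return max(extrapolated, floor)
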