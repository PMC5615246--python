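"""Adaptive-partitioning mutual information (apMI) on the rank plane.

The estimator places the M points (x_rank_i, y_rank_i) of a gene pair in
the square [0, M) x [0, M) and refines a partition breadth-first: a FIFO
queue holds rectangles; a popped rectangle with enough points is quartered
at the integer midpoints of its rank intervals, and the four quadrant
counts are tested against local uniformity with the chi-square statistic

    T = sum_q (n_q - n/4)^2 / (n/4).

If T exceeds ``chi2_crit`` the quadrants are enqueued, otherwise the
rectangle is a leaf. Because ranks make both marginals exactly uniform,
the marginal mass of a width-w rank interval is w/M, and a leaf holding n
of the M points contributes its plug-in MI term

    (n/M) * ln( n*M / (w_x * w_y) )    [nats].

The root square is always quartered (when it holds at least ``min_points``
points): because ranking makes both marginals exactly uniform, the root's
quadrant counts are determined by a single hypergeometric draw, which
degrades the four-cell test there to one effective degree of freedom and
would otherwise collapse the independence null to an atom at zero MI.
From depth 1 on the chi-square gate applies as stated.

The total, clamped at zero, is the MI estimate. The breadth-first queue is
an iteration order, not a different estimator: it returns the same value
as a depth-first recursion, and its length stays within M - 3 entries in
practice (the queue never holds overlapping rectangles and empty quadrants
are dropped immediately).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from math import log

import numpy as np

from .ranking import RankMatrix

#: chi-square critical value, df=3, alpha=0.05 — the canonical choice for
#: a four-way split test.
DEFAULT_CHI2_CRIT = 7.815
#: Smallest rectangle population for which a split is attempted.
DEFAULT_MIN_POINTS = 8


@dataclass(frozen=True)
class PartitionState:
    """One queue entry: a half-open rank rectangle and its point count."""

    x_lo: int
    x_hi: int
    y_lo: int
    y_hi: int
    point_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_lo < self.x_hi and 0 <= self.y_lo < self.y_hi):
            raise ValueError("rectangle bounds must satisfy 0 <= lo < hi")
        if self.point_count < 0:
            raise ValueError("point count must be nonnegative")


@dataclass(frozen=True)
class MIResult:
    """MI estimate in nats plus the maximum queue length observed."""

    mi: float
    max_queue_length: int


def _validate_permutation(r: np.ndarray, name: str) -> np.ndarray:
    r = np.asarray(r)
    if r.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    m = r.shape[0]
    if not np.array_equal(np.sort(r), np.arange(m)):
        raise ValueError(f"{name} must be a permutation of 0..{m - 1}")
    return r.astype(np.intp)


def _apmi_y_of_x(
    y_of_x: np.ndarray, chi2_crit: float, min_points: int
) -> tuple[float, int]:
    """Core loop on the composed permutation y_of_x[x_rank] = y_rank."""
    m = y_of_x.shape[0]
    xs0 = np.arange(m, dtype=np.intp)
    queue: deque[tuple[int, int, int, int, np.ndarray, np.ndarray, bool]] = deque()
    queue.append((0, m, 0, m, xs0, y_of_x, True))
    max_queue = 1
    total = 0.0
    while queue:
        x_lo, x_hi, y_lo, y_hi, xs, ys, is_root = queue.popleft()
        n = xs.shape[0]
        w_x = x_hi - x_lo
        w_y = y_hi - y_lo
        split = n >= min_points and w_x >= 2 and w_y >= 2
        if split:
            x_mid = (x_lo + x_hi) // 2
            y_mid = (y_lo + y_hi) // 2
            left = xs < x_mid
            low = ys < y_mid
            quads = (left & low, left & ~low, ~left & low, ~left & ~low)
            counts = [int(q.sum()) for q in quads]
            e = n / 4.0
            t_stat = sum((c - e) ** 2 for c in counts) / e
            if is_root or t_stat > chi2_crit:
                bounds = (
                    (x_lo, x_mid, y_lo, y_mid),
                    (x_lo, x_mid, y_mid, y_hi),
                    (x_mid, x_hi, y_lo, y_mid),
                    (x_mid, x_hi, y_mid, y_hi),
                )
                for q, c, b in zip(quads, counts, bounds):
                    if c:  # empty quadrants contribute 0 and are dropped
                        queue.append((*b, xs[q], ys[q], False))
                if len(queue) > max_queue:
                    max_queue = len(queue)
                continue
        if n:
            total += (n / m) * log(n * m / (w_x * w_y))
    return max(total, 0.0), max_queue


def apmi_pair(
    x_ranks: np.ndarray,
    y_ranks: np.ndarray,
    chi2_crit: float = DEFAULT_CHI2_CRIT,
    min_points: int = DEFAULT_MIN_POINTS,
) -> MIResult:
    """Estimate I(x; y) in nats for two strict rank permutations.

    Both inputs must be permutations of 0..M-1 of the same length.
    The estimate is symmetric in its arguments and invariant under any
    strictly increasing transform applied upstream of ranking.
    """
    x = _validate_permutation(x_ranks, "x_ranks")
    y = _validate_permutation(y_ranks, "y_ranks")
    if x.shape[0] != y.shape[0]:
        raise ValueError("x_ranks and y_ranks must have equal length")
    inv_x = np.empty_like(x)
    inv_x[x] = np.arange(x.shape[0], dtype=np.intp)
    mi, max_queue = _apmi_y_of_x(y[inv_x], chi2_crit, min_points)
    return MIResult(mi=mi, max_queue_length=max_queue)


@dataclass
class CandidateNetwork:
    """TF x gene MI matrix with a Boolean edge mask.

    Row t corresponds to ``tf_rows[t]`` of the source matrix; columns are
    all genes. Self entries (a TF against itself) are NaN in ``mi`` and
    False in ``mask``; TF-TF entries are mirrored exactly.
    """

    tf_rows: np.ndarray  # sorted gene-row indices of the TFs
    gene_ids: list[str]
    mi: np.ndarray  # (n_tf, n_genes), nats; NaN at self entries
    mask: np.ndarray  # (n_tf, n_genes) bool; False at self entries
    max_queue_length: int = 0  # diagnostic over all pairs

    def __post_init__(self) -> None:
        self.tf_rows = np.asarray(self.tf_rows, dtype=np.intp)
        n_tf = self.tf_rows.shape[0]
        n_genes = len(self.gene_ids)
        if self.mi.shape != (n_tf, n_genes) or self.mask.shape != (n_tf, n_genes):
            raise ValueError("mi/mask shape must be (n_tf, n_genes)")

    @property
    def n_tf(self) -> int:
        return self.tf_rows.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def copy(self) -> "CandidateNetwork":
        return CandidateNetwork(
            self.tf_rows.copy(),
            list(self.gene_ids),
            self.mi.copy(),
            self.mask.copy(),
            self.max_queue_length,
        )


# -- worker state for process-level parallelism over TF rows ---------------
_WORKER: dict = {}


def _init_worker(ranks: np.ndarray, chi2_crit: float, min_points: int) -> None:
    _WORKER["ranks"] = ranks
    _WORKER["chi2_crit"] = chi2_crit
    _WORKER["min_points"] = min_points


def _tf_row_task(args: tuple[int, list[int]]) -> tuple[int, np.ndarray, np.ndarray, int]:
    """Compute MI of one TF row against a list of gene columns."""
    t_row, cols = args
    ranks = _WORKER["ranks"]
    chi2_crit = _WORKER["chi2_crit"]
    min_points = _WORKER["min_points"]
    x = ranks[t_row]
    inv_x = np.empty_like(x)
    inv_x[x] = np.arange(x.shape[0], dtype=np.intp)
    out = np.empty(len(cols), dtype=np.float64)
    max_queue = 0
    for k, g in enumerate(cols):
        out[k], q = _apmi_y_of_x(ranks[g][inv_x], chi2_crit, min_points)
        if q > max_queue:
            max_queue = q
    return t_row, np.asarray(cols, dtype=np.intp), out, max_queue


def compute_mi_matrix(
    ranks: RankMatrix,
    tfs,
    chi2_crit: float = DEFAULT_CHI2_CRIT,
    min_points: int = DEFAULT_MIN_POINTS,
    threads: int = 1,
) -> CandidateNetwork:
    """MI of every TF against every other gene.

    Each unordered pair is computed once; TF-TF entries are mirrored, so
    the result is identical whether run serially or with ``threads``
    worker processes (the estimator itself is exactly symmetric).
    """
    tf_rows = tfs.sorted_rows()
    if tf_rows.size and tf_rows[-1] >= ranks.n_genes:
        raise ValueError("TF index outside the rank matrix")
    n_tf = tf_rows.shape[0]
    n_genes = ranks.n_genes
    tf_pos = {int(r): i for i, r in enumerate(tf_rows)}
    mi = np.full((n_tf, n_genes), np.nan)
    mask = np.zeros((n_tf, n_genes), dtype=bool)

    # canonical work list: per TF row, the gene columns it owns
    tasks: list[tuple[int, list[int]]] = []
    for t_row in tf_rows:
        cols = [
            g
            for g in range(n_genes)
            if g != t_row and (g not in tf_pos or g > t_row)
        ]
        tasks.append((int(t_row), cols))

    if threads > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(
            max_workers=threads,
            initializer=_init_worker,
            initargs=(ranks.ranks, chi2_crit, min_points),
        ) as pool:
            results = list(pool.map(_tf_row_task, tasks))
    else:
        _init_worker(ranks.ranks, chi2_crit, min_points)
        results = [_tf_row_task(t) for t in tasks]

    max_queue = 0
    for t_row, cols, values, q in results:
        mi[tf_pos[t_row], cols] = values
        if q > max_queue:
            max_queue = q
    # mirror TF-TF entries from the canonical (smaller row, larger column)
    for i, t1 in enumerate(tf_rows):
        for j in range(i + 1, n_tf):
            t2 = int(tf_rows[j])
            mi[j, t1] = mi[i, t2]
    mask = ~np.isnan(mi)
    return CandidateNetwork(tf_rows, list(ranks.gene_ids), mi, mask, max_queue)
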