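"""Bootstrap aggregation and Poisson consolidation of inferred networks.

Each bootstrap resamples the M sample columns with replacement, reruns the
inference, and contributes its surviving edges to two accumulators: a
per-edge MI sum and a per-edge occurrence count. An edge seen k times out
of B bootstraps is tested against a Poisson null whose rate lambda is the
mean occurrence per possible edge slot; its tail probability
P(Poisson(lambda) >= k) is Bonferroni-corrected over the edges actually
observed, and edges with corrected p-value below alpha are claimed with
MI equal to the mean of their per-run MI values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .apmi import CandidateNetwork
from .data_io import ExpressionMatrix, NetworkTable


@dataclass
class BootstrapAggregate:
    """Summed MIs and occurrence counts over bootstrap runs."""

    tf_rows: np.ndarray
    gene_ids: list[str]
    mi_sum: np.ndarray  # (n_tf, n_genes)
    count: np.ndarray  # (n_tf, n_genes) int
    n_bootstraps: int = 0

    @classmethod
    def empty(cls, tf_rows: np.ndarray, gene_ids: list[str]) -> "BootstrapAggregate":
        shape = (len(tf_rows), len(gene_ids))
        return cls(
            np.asarray(tf_rows, dtype=np.intp),
            list(gene_ids),
            np.zeros(shape),
            np.zeros(shape, dtype=np.int64),
        )

    def __post_init__(self) -> None:
        if self.mi_sum.shape != self.count.shape:
            raise ValueError("mi_sum and count shapes must agree")


def bootstrap_sample(matrix: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Resample the M sample columns uniformly with replacement (seeded).

    Gene rows are unchanged; duplicated sample identifiers are suffixed to
    keep the resampled matrix's identifiers unique.
    """
    rng = np.random.default_rng([int(seed), 0xB0075])
    m = matrix.n_samples
    cols = rng.integers(0, m, size=m)
    sample_ids = []
    seen: dict[str, int] = {}
    for c in cols:
        base = matrix.sample_ids[int(c)]
        k = seen.get(base, 0)
        seen[base] = k + 1
        sample_ids.append(base if k == 0 else f"{base}.{k}")
    return ExpressionMatrix(
        list(matrix.gene_ids), sample_ids, matrix.values[:, cols].copy()
    )


def accumulate(
    agg: BootstrapAggregate, run_mask: np.ndarray, run_mi: np.ndarray
) -> BootstrapAggregate:
    """Add one run's surviving edges to the aggregate (in place).

    Order of accumulation across runs is immaterial: the result is a sum
    and a count.
    """
    if run_mask.shape != agg.count.shape or run_mi.shape != agg.mi_sum.shape:
        raise ValueError("run mask/MI shape does not match the aggregate")
    agg.count += run_mask.astype(np.int64)
    agg.mi_sum += np.where(run_mask, np.nan_to_num(run_mi), 0.0)
    agg.n_bootstraps += 1
    return agg


def accumulate_network(agg: BootstrapAggregate, net: CandidateNetwork) -> BootstrapAggregate:
    return accumulate(agg, net.mask, net.mi)


def canonical_edges(tf_rows: np.ndarray, n_genes: int) -> tuple[np.ndarray, np.ndarray]:
    """Directed TF->gene slots with self entries removed and each TF-TF
    pair kept once (smaller gene-row index as regulator).

    Returns (tf-row positions, gene columns) into an (n_tf, n_genes) grid.
    """
    tf_set = {int(r) for r in tf_rows}
    rows, cols = [], []
    for i, t in enumerate(tf_rows):
        t = int(t)
        for g in range(n_genes):
            if g == t or (g in tf_set and g < t):
                continue
            rows.append(i)
            cols.append(g)
    return np.asarray(rows, dtype=np.intp), np.asarray(cols, dtype=np.intp)


def poisson_tail(k: np.ndarray | int, lam: float) -> np.ndarray | float:
    """P(Poisson(lam) >= k)."""
    return stats.poisson.sf(np.asarray(k) - 1, lam)


def consolidate(agg: BootstrapAggregate, alpha: float = 0.05) -> NetworkTable:
    """Claim edges whose occurrence count is improbable under the Poisson
    null, after Bonferroni correction over the observed candidate edges."""
    if agg.n_bootstraps < 1:
        raise ValueError("consolidate requires at least one bootstrap run")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    rows, cols = canonical_edges(agg.tf_rows, len(agg.gene_ids))
    counts = agg.count[rows, cols]
    e_possible = rows.shape[0]
    lam = counts.sum() / e_possible
    observed = counts >= 1
    e_observed = int(observed.sum())
    if e_observed == 0:
        return NetworkTable()
    k = counts[observed]
    p = poisson_tail(k, lam)
    p_adj = np.minimum(1.0, p * e_observed)
    claimed = p_adj < alpha
    r_idx = rows[observed][claimed]
    c_idx = cols[observed][claimed]
    k_claimed = k[claimed]
    mi_mean = agg.mi_sum[r_idx, c_idx] / k_claimed
    table = pd.DataFrame(
        {
            "Regulator": [agg.gene_ids[int(agg.tf_rows[i])] for i in r_idx],
            "Target": [agg.gene_ids[int(g)] for g in c_idx],
            "MI": mi_mean,
            "Count": k_claimed,
            "AdjPvalue": p_adj[claimed],
        }
    )
    return NetworkTable(table)
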