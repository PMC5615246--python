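"""Rank transform: map each gene's expression profile to a strict
permutation of sample ranks (copula space).

Strict permutations are required by the quadrant-counting MI estimator,
so ties are broken uniformly at random with a generator derived
deterministically from (seed, gene index): the same matrix and seed always
give the same ranks, and ranking gene g is independent of every other row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix


@dataclass
class RankMatrix:
    """Per-gene 0-based ranks; every row is a permutation of 0..M-1."""

    gene_ids: list[str]
    sample_ids: list[str]
    ranks: np.ndarray  # shape (n_genes, n_samples), intp

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=np.intp)
        n_genes, m = self.ranks.shape
        if n_genes != len(self.gene_ids) or m != len(self.sample_ids):
            raise ValueError("rank matrix shape does not match identifiers")
        expected = np.arange(m, dtype=np.intp)
        if not np.all(np.sort(self.ranks, axis=1) == expected):
            raise ValueError("every row must be a permutation of 0..M-1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def _rank_row(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ranks that sort ascending with `values`; ties broken by `rng`."""
    m = values.shape[0]
    perm = rng.permutation(m)
    # stable sort of a pre-shuffled view = uniform random order within ties
    order = perm[np.argsort(values[perm], kind="stable")]
    ranks = np.empty(m, dtype=np.intp)
    ranks[order] = np.arange(m, dtype=np.intp)
    return ranks


def rank_transform(matrix: ExpressionMatrix, seed: int) -> RankMatrix:
    """Rank every gene row of `matrix` across samples.

    Row r of the result sorts ascending with row r of the input; ties are
    broken uniformly at random, reproducibly under (seed, row index).
    """
    ranks = np.empty(matrix.values.shape, dtype=np.intp)
    for g in range(matrix.n_genes):
        rng = np.random.default_rng([int(seed), g])
        ranks[g] = _rank_row(matrix.values[g], rng)
    return RankMatrix(list(matrix.gene_ids), list(matrix.sample_ids), ranks)
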