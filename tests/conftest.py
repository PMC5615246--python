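from __future__ import annotations

import numpy as np
import pytest

from aracne_kit import (
    CandidateNetwork,
    ExpressionMatrix,
    TrueNetwork,
    simulate_expression,
    write_expression,
    write_tf_list,
)


def rank_of(values: np.ndarray) -> np.ndarray:
    """0-based ranks for tie-free values (test-local helper)."""
    return np.argsort(np.argsort(values))


def gaussian_rank_pair(rho: float, m: int, rng: np.random.Generator):
    """Rank-transformed draw from a bivariate Gaussian with correlation rho."""
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=m)
    return rank_of(z[:, 0]), rank_of(z[:, 1])


def make_chain_network(
    w12: float = 0.9, w2g: float = 0.9, n_decoys: int = 0
) -> TrueNetwork:
    """X -> Y -> Z Markov chain (two TFs, one cascade target), optionally
    padded with unregulated decoy genes so the edge universe is large."""
    decoys = [f"G{k + 2:04d}" for k in range(n_decoys)]
    return TrueNetwork(
        tf_ids=["TF001", "TF002"],
        target_ids=["G0001"] + decoys,
        direct_edges={("TF001", "TF002"): w12, ("TF002", "G0001"): w2g},
        cascade_triples={("TF001", "TF002", "G0001")},
    )


def simulate_chain(
    seed: int, m: int = 500, noise_sd: float = 0.3, n_decoys: int = 0
) -> ExpressionMatrix:
    return simulate_expression(
        make_chain_network(n_decoys=n_decoys),
        n_samples=m,
        noise_sd=noise_sd,
        link="sigmoid",
        seed=seed,
    )


def random_candidate_network(
    rng: np.random.Generator, n_tf: int = 5, n_genes: int = 20, edge_prob: float = 0.6
) -> CandidateNetwork:
    """Random MI matrix + mask satisfying the candidate-network invariants
    (NaN/False at self entries, TF-TF entries mirrored)."""
    tf_rows = np.sort(rng.choice(n_genes, size=n_tf, replace=False))
    mi = rng.uniform(0.01, 1.0, size=(n_tf, n_genes))
    mask = rng.random((n_tf, n_genes)) < edge_prob
    for i, t1 in enumerate(tf_rows):
        mi[i, t1] = np.nan
        mask[i, t1] = False
        for j in range(i + 1, n_tf):
            t2 = int(tf_rows[j])
            mi[j, t1] = mi[i, t2]
            mask[j, t1] = mask[i, t2]
    gene_ids = [f"g{k}" for k in range(n_genes)]
    return CandidateNetwork(tf_rows, gene_ids, mi, mask)


def write_dataset_files(matrix: ExpressionMatrix, tf_ids, tmp_path):
    expr = tmp_path / "expr.tsv"
    tfs = tmp_path / "tfs.txt"
    write_expression(matrix, expr)
    write_tf_list(tf_ids, tfs)
    return expr, tfs


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(7)
    values = rng.normal(size=(6, 12))
    return ExpressionMatrix(
        [f"g{i}" for i in range(6)], [f"s{j}" for j in range(12)], values
    )
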