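"""One-step orchestration: read inputs, build the null model, compute the
candidate network, prune, optionally bootstrap, consolidate, write output.

The stage sequence is: rank transform -> pairwise apMI over TF x gene ->
MI thresholding at the permutation-null cutoff -> DPI pruning of
TF-TF-target triangles -> (optionally) bootstrap aggregation and Poisson
consolidation. With a fixed configuration and seed the written network
file is byte-identical across runs, serial or multi-process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import bootstrap as bs
from .apmi import (
    DEFAULT_CHI2_CRIT,
    DEFAULT_MIN_POINTS,
    CandidateNetwork,
    compute_mi_matrix,
)
from .data_io import (
    MIN_SAMPLES,
    ExpressionMatrix,
    NetworkTable,
    TFIndexSet,
    read_expression,
    read_tf_list,
    write_network,
)
from .null_model import DEFAULT_N0, mi_threshold, sample_null_mis
from .pruning import apply_threshold, dpi
from .ranking import rank_transform

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """User-facing parameters of a pipeline run."""

    expression_path: str
    tf_path: str
    output_path: str
    p_value: float = 1e-8
    n0: int = DEFAULT_N0
    bootstraps: int = 0
    dpi_tolerance: float = 0.0
    chi2_crit: float = DEFAULT_CHI2_CRIT
    min_points: int = DEFAULT_MIN_POINTS
    consolidation_alpha: float = 0.05
    seed: int = 0
    threads: int = 1
    #: recompute the null threshold inside every bootstrap instead of
    #: reusing the cutoff from the original matrix
    null_per_bootstrap: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")
        if self.bootstraps < 0:
            raise ValueError("bootstraps must be >= 0")
        if not (self.expression_path and self.tf_path and self.output_path):
            raise ValueError("all paths must be nonempty")


#: p = 1e-3 with 10 bootstraps, the bootstrap-mode benchmark setting.
PRESETS = {"paper-v2": {"p_value": 1e-3, "bootstraps": 10}}


def apply_preset(config: PipelineConfig, preset: str) -> PipelineConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return replace(config, **PRESETS[preset])


def network_from_candidate(net: CandidateNetwork) -> NetworkTable:
    """Edge table of a single (no-bootstrap) run: count 1, no p-value."""
    rows, cols = bs.canonical_edges(net.tf_rows, net.n_genes)
    keep = net.mask[rows, cols]
    r_idx, c_idx = rows[keep], cols[keep]
    table = pd.DataFrame(
        {
            "Regulator": [net.gene_ids[int(net.tf_rows[i])] for i in r_idx],
            "Target": [net.gene_ids[int(g)] for g in c_idx],
            "MI": net.mi[r_idx, c_idx],
            "Count": np.ones(r_idx.shape[0], dtype=np.int64),
            "AdjPvalue": np.full(r_idx.shape[0], np.nan),
        }
    )
    return NetworkTable(table)


def _infer_single(
    matrix: ExpressionMatrix,
    tfs: TFIndexSet,
    threshold: float,
    config: PipelineConfig,
    rank_seed: int,
    stage: str,
) -> CandidateNetwork:
    """rank -> apMI -> threshold -> DPI for one (possibly resampled) matrix."""
    ranks = rank_transform(matrix, seed=rank_seed)
    candidate = compute_mi_matrix(
        ranks, tfs, config.chi2_crit, config.min_points, threads=config.threads
    )
    thresholded = apply_threshold(candidate, threshold)
    pruned = dpi(thresholded, tfs, config.dpi_tolerance)
    logger.info(
        "%s: edges after threshold=%d, after DPI=%d (max queue length %d)",
        stage,
        int(thresholded.mask.sum()),
        int(pruned.mask.sum()),
        candidate.max_queue_length,
    )
    return pruned


def run_pipeline(config: PipelineConfig) -> NetworkTable:
    """Run the full inference and write the network to the output path."""
    matrix = read_expression(config.expression_path)
    if matrix.n_samples < MIN_SAMPLES:
        raise ValueError(f"pipeline requires at least {MIN_SAMPLES} samples")
    tfs = read_tf_list(config.tf_path, matrix)
    logger.info(
        "input: M=%d samples, N_genes=%d, N_tf=%d",
        matrix.n_samples,
        matrix.n_genes,
        len(tfs),
    )
    null = sample_null_mis(
        matrix, tfs, config.n0, config.seed, config.chi2_crit, config.min_points
    )
    threshold = mi_threshold(null, config.p_value)
    logger.info("MI threshold at p=%g: %.6g nats (n0=%d)", config.p_value, threshold, config.n0)

    if config.bootstraps == 0:
        pruned = _infer_single(matrix, tfs, threshold, config, config.seed, "single run")
        net = network_from_candidate(pruned)
    else:
        agg = bs.BootstrapAggregate.empty(tfs.sorted_rows(), matrix.gene_ids)
        for b in range(config.bootstraps):
            seed_b = config.seed + 1 + b
            resampled = bs.bootstrap_sample(matrix, seed_b)
            thr_b = threshold
            if config.null_per_bootstrap:
                null_b = sample_null_mis(
                    resampled, tfs, config.n0, seed_b, config.chi2_crit, config.min_points
                )
                thr_b = mi_threshold(null_b, config.p_value)
            pruned_b = _infer_single(
                resampled, tfs, thr_b, config, seed_b, f"bootstrap {b + 1}"
            )
            bs.accumulate_network(agg, pruned_b)
        net = bs.consolidate(agg, config.consolidation_alpha)
    if len(net) == 0:
        logger.warning("no edges survive; writing header-only network file")
    write_network(net, config.output_path)
    logger.info("wrote %d edges to %s", len(net), config.output_path)
    return net
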