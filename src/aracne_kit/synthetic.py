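"""Synthetic ground-truth regulatory networks and expression matrices.

The generator emulates the statistical structure the inference pipeline
assumes: transcription factors regulate targets through noisy, possibly
nonlinear links, and a fraction of TFs sit in the middle of regulatory
cascades (t1 -> t2 -> g). Cascade targets depend on the upstream TF only
through the middle TF — an exact Markov chain — so the data-processing
inequality I(t1; g) <= min(I(t1; t2), I(t2; g)) holds in the generating
law, which is precisely the premise the DPI pruning step exploits.

Realistic RNA-seq count noise (negative-binomial dispersion, library-size
effects) is deliberately not modelled: the pipeline ranks each gene before
estimating MI, so any monotone per-gene distortion of these Gaussian
profiles leaves every inferred quantity unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    ExpressionMatrix,
    NetworkTable,
    write_expression,
    write_tf_list,
)

#: link weights are drawn uniformly from this interval, keeping the signal
#: strength of every direct edge controllably strong
WEIGHT_RANGE = (0.6, 1.0)

Edge = tuple[str, str]


@dataclass
class TrueNetwork:
    """Ground-truth wiring: direct edges with strengths plus the cascade
    triples (t1, t2, g) whose shortcut edge (t1, g) is absent."""

    tf_ids: list[str]
    target_ids: list[str]
    direct_edges: dict[Edge, float] = field(default_factory=dict)
    cascade_triples: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for reg, tgt in self.direct_edges:
            if reg == tgt:
                raise ValueError("self edges are not allowed")
        for t1, t2, g in self.cascade_triples:
            if (t1, t2) not in self.direct_edges or (t2, g) not in self.direct_edges:
                raise ValueError("cascade triple not backed by direct edges")
            if (t1, g) in self.direct_edges:
                raise ValueError("cascade triple has a direct shortcut edge")

    @property
    def gene_ids(self) -> list[str]:
        return self.tf_ids + self.target_ids


def generate_grn(
    n_tf: int,
    n_targets: int,
    density: float,
    cascade_fraction: float = 0.0,
    seed: int = 0,
) -> TrueNetwork:
    """Random TF -> target network plus optional TF -> TF -> target cascades.

    Each (TF, target) direct edge is present independently with
    probability ``density``; ``cascade_fraction`` of the TFs are wired as
    middle nodes of chains fed by a root TF. Reproducible under ``seed``.
    """
    if n_tf < 2 or n_targets < 1:
        raise ValueError("need at least 2 TFs and 1 target")
    if not (0.0 <= density <= 1.0) or not (0.0 <= cascade_fraction < 1.0):
        raise ValueError("density in [0,1], cascade_fraction in [0,1)")
    rng = np.random.default_rng([int(seed), 0x6E7])
    tf_ids = [f"TF{i + 1:03d}" for i in range(n_tf)]
    target_ids = [f"G{i + 1:04d}" for i in range(n_targets)]
    lo, hi = WEIGHT_RANGE
    edges: dict[Edge, float] = {}
    present = rng.random((n_tf, n_targets)) < density
    weights = rng.uniform(lo, hi, (n_tf, n_targets))
    for i in range(n_tf):
        for j in range(n_targets):
            if present[i, j]:
                edges[(tf_ids[i], target_ids[j])] = float(weights[i, j])

    triples: set[tuple[str, str, str]] = set()
    n_mid = min(int(round(cascade_fraction * n_tf)), n_tf - 1)
    if n_mid:
        # the last n_mid TFs become middle nodes, each fed by a root TF
        mid = tf_ids[n_tf - n_mid:]
        roots = tf_ids[: n_tf - n_mid]
        for t2 in mid:
            t1 = roots[int(rng.integers(0, len(roots)))]
            edges[(t1, t2)] = float(rng.uniform(lo, hi))
            for g in target_ids:
                if (t2, g) in edges and (t1, g) not in edges:
                    triples.add((t1, t2, g))
    return TrueNetwork(tf_ids, target_ids, edges, triples)


def _link(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "sigmoid":
        return np.tanh(z)  # zero-centred sigmoid
    raise ValueError(f"unknown link {name!r}; choose 'linear' or 'sigmoid'")


def simulate_expression(
    net: TrueNetwork,
    n_samples: int,
    noise_sd: float,
    link: str = "sigmoid",
    seed: int = 0,
) -> ExpressionMatrix:
    """Draw an expression matrix from the network's generating law.

    Root TFs are i.i.d. standard normal per sample; every regulated node
    is link(weighted sum of its regulators) plus Gaussian noise of
    standard deviation ``noise_sd``. Raises on cyclic wiring.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    genes = net.gene_ids
    regulators: dict[str, list[tuple[str, float]]] = {g: [] for g in genes}
    for (reg, tgt), w in net.direct_edges.items():
        regulators[tgt].append((reg, w))

    # Kahn topological order; the generator never creates cycles, but
    # hand-built networks might
    in_deg = {g: len(regulators[g]) for g in genes}
    ready = [g for g in genes if in_deg[g] == 0]
    order: list[str] = []
    downstream: dict[str, list[str]] = {g: [] for g in genes}
    for (reg, tgt) in net.direct_edges:
        downstream[reg].append(tgt)
    while ready:
        g = ready.pop()
        order.append(g)
        for d in downstream[g]:
            in_deg[d] -= 1
            if in_deg[d] == 0:
                ready.append(d)
    if len(order) != len(genes):
        raise ValueError("cyclic wiring: expression model is acyclic by design")

    rng = np.random.default_rng([int(seed), 0x51E])
    values: dict[str, np.ndarray] = {}
    for g in order:
        regs = sorted(regulators[g])  # deterministic accumulation order
        if not regs:
            values[g] = rng.standard_normal(n_samples)
        else:
            z = np.zeros(n_samples)
            for reg, w in regs:
                z += w * values[reg]
            values[g] = _link(link, z) + noise_sd * rng.standard_normal(n_samples)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    data = np.vstack([values[g] for g in genes])
    return ExpressionMatrix(list(genes), sample_ids, data)


def write_true_network(net: TrueNetwork, path: str | Path) -> None:
    """Ground-truth edge list as TSV (Regulator, Target, Strength)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("Regulator\tTarget\tStrength\n")
        for (reg, tgt), w in sorted(net.direct_edges.items()):
            fh.write(f"{reg}\t{tgt}\t{w:.6g}\n")


def write_dataset(
    net: TrueNetwork, matrix: ExpressionMatrix, out_prefix: str | Path
) -> dict[str, Path]:
    """Write expression TSV, TF list and true-network TSV with one prefix."""
    prefix = Path(out_prefix)
    paths = {
        "expression": prefix.with_name(prefix.name + ".expression.tsv"),
        "tfs": prefix.with_name(prefix.name + ".tfs.txt"),
        "network": prefix.with_name(prefix.name + ".true_network.tsv"),
    }
    write_expression(matrix, paths["expression"])
    write_tf_list(net.tf_ids, paths["tfs"])
    write_true_network(net, paths["network"])
    return paths


def edge_metrics(inferred: NetworkTable, truth: TrueNetwork) -> dict[str, float]:
    """Precision and recall of an inferred edge list against the ground
    truth, matching TF-TF edges in either orientation."""
    true_pairs = {frozenset(e) for e in truth.direct_edges}
    found = {
        frozenset((r, t))
        for r, t in zip(inferred.rows["Regulator"], inferred.rows["Target"])
    }
    tp = len(found & true_pairs)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(true_pairs) if true_pairs else float("nan")
    return {"precision": precision, "recall": recall, "true_positives": tp,
            "inferred": len(found), "true_edges": len(true_pairs)}
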