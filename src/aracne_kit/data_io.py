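"""Input/output for the network-inference pipeline.

Three plain-text formats are supported:

* an expression matrix TSV — header row of sample identifiers, then one
  row per gene (gene identifier followed by numeric values);
* a transcription-factor list — one gene identifier per line, ``#``
  comments ignored;
* the inferred-network TSV written by :func:`write_network`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Minimum number of samples for which the adaptive-partitioning MI
#: estimator can form at least one partition (min_points default is 8).
MIN_SAMPLES = 8

NETWORK_COLUMNS = ("Regulator", "Target", "MI", "Count", "AdjPvalue")


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric expression matrix.

    Expression units are taken as provided; the pipeline ranks each gene
    across samples, so any per-gene monotone transform (log, TPM vs FPKM,
    ...) leaves every downstream quantity unchanged.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample identifiers must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "missing or non-finite value at gene "
                f"{self.gene_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class TFIndexSet:
    """Row indices of the genes treated as candidate regulators."""

    tf_indices: frozenset[int]

    def __post_init__(self) -> None:
        if not self.tf_indices:
            raise ValueError("transcription-factor set must be nonempty")
        if any(i < 0 for i in self.tf_indices):
            raise ValueError("TF indices must be nonnegative")

    def sorted_rows(self) -> np.ndarray:
        return np.array(sorted(self.tf_indices), dtype=np.intp)

    def __len__(self) -> int:
        return len(self.tf_indices)


@dataclass
class NetworkTable:
    """Final edge list: regulator, target, MI (nats), occurrence count and
    Bonferroni-adjusted Poisson p-value (NaN when run without bootstraps)."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(NETWORK_COLUMNS))
    )

    def __post_init__(self) -> None:
        missing = set(NETWORK_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"network table missing columns: {sorted(missing)}")
        self.rows = self.rows.loc[:, list(NETWORK_COLUMNS)].reset_index(drop=True)
        if len(self.rows):
            if (self.rows["Regulator"] == self.rows["Target"]).any():
                raise ValueError("self-edges are not allowed")
            if self.rows.duplicated(subset=["Regulator", "Target"]).any():
                raise ValueError("duplicate (regulator, target) rows")

    def __len__(self) -> int:
        return len(self.rows)


def read_expression(path: str | Path, min_samples: int = MIN_SAMPLES) -> ExpressionMatrix:
    """Read an expression TSV (header of sample ids, one gene per row).

    Raises ``ValueError`` on duplicate gene identifiers, on any missing or
    non-numeric cell (naming the offending gene and sample), and on fewer
    than ``min_samples`` samples.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] < min_samples:
        raise ValueError(
            f"{path}: {df.shape[1]} samples found, at least {min_samples} required"
        )
    gene_ids = [str(g) for g in df.index]
    dupes = df.index[df.index.duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate gene identifier {dupes[0]!r}")
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError
                values[i, j] = float(cell)
                if not np.isfinite(values[i, j]):
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: missing or non-numeric value at gene "
                    f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix in the TSV dialect read_expression accepts."""
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.to_csv(Path(path), sep="\t", float_format="%.10g", index_label="gene")


def read_tf_list(path: str | Path, matrix: ExpressionMatrix) -> TFIndexSet:
    """Read a TF list (one identifier per line) against an expression matrix.

    Listed genes absent from the matrix are skipped with a warning; if no
    listed gene is present a ``ValueError`` is raised.
    """
    path = Path(path)
    row_of = {g: i for i, g in enumerate(matrix.gene_ids)}
    indices: set[int] = set()
    listed = 0
    with open(path) as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if not name:
                continue
            listed += 1
            if name in row_of:
                indices.add(row_of[name])
            else:
                logger.warning("TF %r not present in expression matrix; skipped", name)
    if not indices:
        raise ValueError(
            f"{path}: none of the {listed} listed transcription factors "
            "are present in the expression matrix"
        )
    return TFIndexSet(frozenset(indices))


def write_tf_list(tf_ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{t}\n" for t in tf_ids))


def write_network(net: NetworkTable, path: str | Path) -> None:
    """Write a network table as TSV, sorted by (regulator, target).

    MI is printed with 6 significant digits; the adjusted p-value column
    holds ``NA`` for runs without bootstrapping. Output is byte-stable for
    a given table.
    """
    rows = net.rows.sort_values(["Regulator", "Target"], kind="mergesort")
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(NETWORK_COLUMNS) + "\n")
        for reg, tgt, mi, count, padj in rows.itertuples(index=False):
            p_str = "NA" if padj is None or (isinstance(padj, float) and np.isnan(padj)) else f"{padj:.6g}"
            fh.write(f"{reg}\t{tgt}\t{mi:.6g}\t{int(count)}\t{p_str}\n")


def read_network(path: str | Path) -> NetworkTable:
    df = pd.read_csv(path, sep="\t", dtype={"Regulator": str, "Target": str})
    df["AdjPvalue"] = pd.to_numeric(df["AdjPvalue"], errors="coerce")
    return NetworkTable(df)
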