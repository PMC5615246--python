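"""Network pruning: MI thresholding and the Data Processing Inequality.

For a Markov chain g1 -> g2 -> g3 the DPI guarantees
I(g1; g3) <= min(I(g1; g2), I(g2; g3)), so in every fully connected
TF-TF-target triangle the strictly weakest edge is presumed indirect and
removed. Removals are decided against a snapshot of the input mask and
applied at the end, which makes the result independent of the order in
which triangles are visited — the property that lets the pruning run
fully in parallel with no change of output.
"""

from __future__ import annotations

import numpy as np

from .apmi import CandidateNetwork
from .data_io import TFIndexSet


def apply_threshold(net: CandidateNetwork, threshold: float) -> CandidateNetwork:
    """Keep edges with MI >= threshold; MI values are untouched."""
    out = net.copy()
    with np.errstate(invalid="ignore"):
        out.mask = np.where(np.isnan(out.mi), False, out.mi >= threshold)
    return out


def dpi(
    net: CandidateNetwork, tfs: TFIndexSet, tolerance: float = 0.0
) -> CandidateNetwork:
    """Apply the DPI to every TF-TF-target triangle of a thresholded network.

    An edge of a triangle whose three edges all survive in the INPUT mask
    is removed iff its MI is strictly below (1 - tolerance) times the
    minimum of the other two. Degenerate triangles (repeated node) are
    skipped; ties are retained. tolerance=0 is strict DPI, tolerance=1
    leaves the mask unchanged.
    """
    if not (0.0 <= tolerance <= 1.0):
        raise ValueError("tolerance must be in [0, 1]")
    tf_rows = net.tf_rows
    pos_of = {int(r): i for i, r in enumerate(tf_rows)}
    if not all(int(r) in pos_of for r in tfs.sorted_rows()):
        raise ValueError("TF set does not match the candidate network")
    mi = net.mi
    mask = net.mask  # input snapshot; never modified during evaluation
    keep_factor = 1.0 - tolerance
    remove = np.zeros_like(mask)

    n_tf = tf_rows.shape[0]
    gene_is_tf = np.zeros(net.n_genes, dtype=bool)
    gene_is_tf[tf_rows] = True
    for i in range(n_tf):
        t1 = int(tf_rows[i])
        for j in range(i + 1, n_tf):
            t2 = int(tf_rows[j])
            if not mask[i, t2]:
                continue
            mi_tt = mi[i, t2]
            both = mask[i] & mask[j]
            both[t1] = both[t2] = False
            if not both.any():
                continue
            g = np.nonzero(both)[0]
            a = mi[i, g]  # t1 - g
            b = mi[j, g]  # t2 - g
            remove[i, g] |= a < np.minimum(b, mi_tt) * keep_factor
            remove[j, g] |= b < np.minimum(a, mi_tt) * keep_factor
            if np.any(mi_tt < np.minimum(a, b) * keep_factor):
                remove[i, t2] = remove[j, t1] = True
    out = net.copy()
    out.mask = mask & ~remove
    return out
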