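"""Independent reference implementations used as test oracles.

These are deliberately written in the most transparent style available —
plain recursion, triple loops, cumulative sums — and share no code with
the package, so agreement between the two routes is informative.
"""

from __future__ import annotations

import math

import numpy as np


def apmi_recursive(x_ranks, y_ranks, chi2_crit: float = 7.815, min_points: int = 8) -> float:
    """Depth-first recursive adaptive-partitioning MI (nats)."""
    m = len(x_ranks)
    points = list(zip([int(v) for v in x_ranks], [int(v) for v in y_ranks]))

    def rec(x_lo, x_hi, y_lo, y_hi, pts, is_root=False):
        n = len(pts)
        w_x, w_y = x_hi - x_lo, y_hi - y_lo
        if n >= min_points and w_x >= 2 and w_y >= 2:
            x_mid, y_mid = (x_lo + x_hi) // 2, (y_lo + y_hi) // 2
            quads = {(0, 0): [], (0, 1): [], (1, 0): [], (1, 1): []}
            for x, y in pts:
                quads[(x >= x_mid, y >= y_mid)].append((x, y))
            e = n / 4.0
            t = sum((len(q) - e) ** 2 for q in quads.values()) / e
            # the root square is always quartered; the chi-square gate
            # applies from depth 1 on
            if is_root or t > chi2_crit:
                return (
                    rec(x_lo, x_mid, y_lo, y_mid, quads[(0, 0)])
                    + rec(x_lo, x_mid, y_mid, y_hi, quads[(0, 1)])
                    + rec(x_mid, x_hi, y_lo, y_mid, quads[(1, 0)])
                    + rec(x_mid, x_hi, y_mid, y_hi, quads[(1, 1)])
                )
        if n == 0:
            return 0.0
        return (n / m) * math.log(n * m / (w_x * w_y))

    return max(rec(0, m, 0, m, points, is_root=True), 0.0)


def dpi_bruteforce(mi, mask, tf_rows, tolerance: float, triangle_order=None):
    """Triple-loop DPI over all TF-TF-target triangles of the input mask.

    ``triangle_order`` permutes the order in which triangles are examined;
    removals are collected first and applied at the end, so the result
    must not depend on it.
    """
    mi = np.asarray(mi)
    mask = np.asarray(mask)
    n_tf, n_genes = mask.shape
    tf_rows = [int(t) for t in tf_rows]
    pos_of = {t: i for i, t in enumerate(tf_rows)}
    factor = 1.0 - tolerance
    triangles = [
        (i, j, g)
        for i in range(n_tf)
        for j in range(i + 1, n_tf)
        for g in range(n_genes)
        if g not in (tf_rows[i], tf_rows[j])
    ]
    if triangle_order is not None:
        triangles = [triangles[k] for k in triangle_order]
    remove = np.zeros_like(mask)
    for i, j, g in triangles:
        t1, t2 = tf_rows[i], tf_rows[j]
        if not (mask[i, t2] and mask[i, g] and mask[j, g]):
            continue
        e1, e2, e3 = mi[i, g], mi[j, g], mi[i, t2]
        if e1 < min(e2, e3) * factor:
            remove[i, g] = True
        if e2 < min(e1, e3) * factor:
            remove[j, g] = True
        if e3 < min(e1, e2) * factor:
            remove[i, t2] = True
            remove[pos_of[t2], t1] = True
    return mask & ~remove


def poisson_tail_cumsum(k: int, lam: float) -> float:
    """P(Poisson(lam) >= k) by explicit summation of the pmf."""
    if k <= 0:
        return 1.0
    total = 0.0
    term = math.exp(-lam)
    for i in range(k):
        if i > 0:
            term *= lam / i
        total += term
    return max(0.0, 1.0 - total)
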