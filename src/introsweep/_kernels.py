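"""Numba inner loops for the composite-likelihood scan.

The transformed conditional probabilities depend on (alpha, distance) only
through the scaled distance s = alpha*d, so for each candidate divergence D
the scan precomputes a table of per-class log-probability differences
(sweep minus background) on a uniform s-grid over [0, cutoff] and the
kernel reduces each likelihood evaluation to a gather-and-sum with linear
interpolation. Sites with s >= cutoff contribute the null term to both
models and therefore a zero difference.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def delta_loglik_profile(positions, class_rows, test_pos, alphas, table, cutoff, ds):
    """ln CL1(alpha, D) - ln CL0 for each alpha, one divergence table.

    positions: sorted site coordinates (float64).
    class_rows: per-site row index into ``table`` (int64; -1 = skip site).
    table: (n_classes, n_grid) log-probability differences on the s-grid.
    ds: grid step, cutoff / (n_grid - 1).
    """
    out = np.empty(alphas.size)
    n_sites = positions.size
    for a in range(alphas.size):
        alpha = alphas[a]
        radius = cutoff / alpha
        lo = np.searchsorted(positions, test_pos - radius)
        hi = np.searchsorted(positions, test_pos + radius)
        if hi > n_sites:
            hi = n_sites
        acc = 0.0
        for m in range(lo, hi):
            row = class_rows[m]
            if row < 0:
                continue
            d = positions[m] - test_pos
            if d < 0.0:
                d = -d
            if d < 1.0:
                d = 1.0  # coincident test and data site: evaluate at 1 bp
            s = alpha * d
            if s >= cutoff:
                continue
            x = s / ds
            j = int(x)
            w = x - j
            acc += table[row, j] * (1.0 - w) + table[row, j + 1] * w
        out[a] = acc
    return out
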