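"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own code paths: the dip oracle
minimises the sup distance between the ECDF and piecewise-linear
unimodal CDFs directly with linear programming; the ODBA oracle is a
plain loop re-evaluation of the definition.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def running_mean_brute(x, k):
    """Windowed mean, offsets [-k//2, (k-1)//2], truncated at edges."""
    x = np.asarray(x, float)
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - k // 2)
        hi = min(n, i + (k - 1) // 2 + 1)
        out[i] = x[lo:hi].mean()
    return out


def odba_brute(raw, k=10):
    """Sum over samples and axes of |a - running mean of a|."""
    raw = np.asarray(raw, float)
    total = 0.0
    for ax in range(3):
        rm = running_mean_brute(raw[:, ax], k)
        total += np.abs(raw[:, ax] - rm).sum()
    return total


def _lp_dip_fixed_mode(x, j, atom):
    """Min sup deviation for a unimodal CDF with mode at data point j.

    The CDF is piecewise linear with knots at the data points (optimal
    fits need no others).  ``atom=False``: continuous, convex through
    knot j from the left, concave from knot j on.  ``atom=True``: the
    CDF may jump at x_j (an atom at the mode); knot j splits into a
    left-limit and a right-value variable with relaxed deviation
    bounds.  Returns np.inf when infeasible.
    """
    n = len(x)
    if atom:
        # positions: g_0..g_{j-1}, gminus_j, gplus_j, g_{j+1}..g_{n-1}
        m = n + 1
        xs = np.concatenate([x[: j + 1], x[j:]])
        lo_c = np.concatenate(
            [np.arange(1, j + 1) / n, [j / n], [(j + 1) / n],
             np.arange(j + 2, n + 1) / n]
        )
        hi_c = np.concatenate(
            [np.arange(0, j) / n, [j / n], [(j + 1) / n],
             np.arange(j + 1, n) / n]
        )
        conv_centres = range(1, j)        # within left block 0..j
        conc_centres = range(j + 2, m - 1)  # within right block j+1..m-1
    else:
        m = n
        xs = x
        lo_c = np.arange(1, n + 1) / n    # g_i >= (i+1)/n - eps
        hi_c = np.arange(0, n) / n        # g_i <= i/n + eps (left limit)
        conv_centres = range(1, j)        # triples with knots <= j
        conc_centres = range(j + 1, m - 1)  # triples with knots >= j
    nv = m + 1  # + eps
    A_ub, b_ub = [], []

    def row(pairs, rhs):
        r = np.zeros(nv)
        for idx, c in pairs:
            r[idx] = c
        A_ub.append(r)
        b_ub.append(rhs)

    for i in range(m):
        row([(i, -1.0), (nv - 1, -1.0)], -lo_c[i])
        row([(i, 1.0), (nv - 1, -1.0)], hi_c[i])
    for i in range(m - 1):  # monotone
        row([(i, 1.0), (i + 1, -1.0)], 0.0)
    for centres, sign in [(conv_centres, 1.0), (conc_centres, -1.0)]:
        for i in centres:
            d1 = xs[i] - xs[i - 1]
            d2 = xs[i + 1] - xs[i]
            if d1 <= 0 or d2 <= 0:
                continue
            # convex: slope(i-1,i) <= slope(i,i+1); concave reversed
            row([(i - 1, -sign * d2), (i, sign * (d1 + d2)),
                 (i + 1, -sign * d1)], 0.0)

    c = np.zeros(nv)
    c[-1] = 1.0
    res = linprog(
        c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
        bounds=[(0.0, 1.0)] * m + [(0.0, 1.0)], method="highs",
    )
    return res.fun if res.status == 0 else np.inf


def dip_brute(x):
    """Dip by direct minimisation over piecewise-linear unimodal CDFs."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    best = np.inf
    for j in range(n):
        best = min(best, _lp_dip_fixed_mode(x, j, atom=False))
        best = min(best, _lp_dip_fixed_mode(x, j, atom=True))
    return best
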