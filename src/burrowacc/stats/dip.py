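"""Hartigan's dip statistic and bootstrap test of unimodality.

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and the class of unimodal CDFs (convex below the mode,
concave above, with at most one atom at the mode).  It is computed with
the classical iterative algorithm: repeatedly fit the greatest convex
minorant (GCM) and least concave majorant (LCM) of the ECDF on a
shrinking candidate modal interval, tracking the largest deviation the
best unimodal fit cannot avoid.  Distances are kept in step-count units
internally and converted by 1/(2n) at the end, so the dip of a balanced
two-point sample is 0.25 and the universal lower bound is 1/(2n).

The test bootstraps the null from uniform(0, 1) samples of the same
size — the classical least-favourable unimodal reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["DipResult", "dip_statistic", "dip_test", "dip_null_sample"]


def _gcm_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull (touch points) of (x, y), x ascending."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # keep turn clockwise-or-straight for a lower hull
            if (x[b] - x[a]) * (y[i] - y[a]) <= (y[b] - y[a]) * (x[i] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def _lcm_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Upper concave hull (touch points) of (x, y), x ascending."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (x[b] - x[a]) * (y[i] - y[a]) >= (y[b] - y[a]) * (x[i] - x[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def _interp(xq, xk, yk):
    return np.interp(xq, xk, yk)


def dip_statistic(x) -> float:
    """Dip statistic of a 1-D sample (n >= 2, finite values)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("dip needs at least 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip needs finite values")
    if x[0] == x[-1]:
        return 0.0

    lo, hi = 0, n - 1
    dip = 1.0  # count units; universal floor 1/(2n) after scaling
    idx = np.arange(n, dtype=float)

    for _ in range(n):
        sl = slice(lo, hi + 1)
        xs = x[sl]
        g_rel = _gcm_indices(xs, idx[sl])          # fit through lower corners i
        l_rel = _lcm_indices(xs, idx[sl] + 1.0)    # fit through upper corners i+1
        g = g_rel + lo
        l = l_rel + lo

        # largest gap between the two curves, and where it occurs
        gap_g = _interp(x[g], x[l], idx[l] + 1.0) - idx[g]        # at gcm knots
        gap_l = (idx[l] + 1.0) - _interp(x[l], x[g], idx[g])      # at lcm knots
        d = 0.0
        new_lo, new_hi = lo, hi
        if gap_g.size:
            j = int(np.argmax(gap_g))
            if gap_g[j] > d:
                d = float(gap_g[j])
                new_lo = int(g[j])
                new_hi = int(l[min(np.searchsorted(l, g[j]), l.size - 1)])
        if gap_l.size:
            j = int(np.argmax(gap_l))
            if gap_l[j] > d:
                d = float(gap_l[j])
                new_hi = int(l[j])
                k = np.searchsorted(g, l[j], side="right") - 1
                new_lo = int(g[max(k, 0)])
        if d <= dip:
            break

        # deviations the unimodal fit cannot avoid outside the new modal
        # interval: ECDF above the GCM on the convex side, below the LCM
        # on the concave side
        dl = 0.0
        gk = g[g <= new_lo]
        if gk.size >= 2:
            dev = (idx[lo : new_lo + 1] + 1.0) - _interp(
                x[lo : new_lo + 1], x[gk], idx[gk]
            )
            dl = float(dev.max())
        du = 0.0
        lk = l[l >= new_hi]
        if lk.size >= 2:
            dev = _interp(x[new_hi : hi + 1], x[lk], idx[lk] + 1.0) - idx[
                new_hi : hi + 1
            ]
            du = float(dev.max())
        dip = max(dip, dl, du)
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi

    return dip / (2.0 * n)


@dataclass(frozen=True)
class DipResult:
    D: float
    p: float
    n: int
    n_boot: int


@lru_cache(maxsize=32)
def _cached_null(n: int, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array(
        [dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)]
    )


def dip_null_sample(n: int, n_boot: int = 2000, seed: int = 0) -> np.ndarray:
    """Bootstrap null distribution of the dip for uniform samples of size n.

    Cached, so repeated tests at one sample size share the table (the
    same idea as the classical published quantile tables).
    """
    return _cached_null(int(n), int(n_boot), int(seed))


def dip_test(
    x, n_boot: int = 2000, seed: int = 0, null_dips: np.ndarray | None = None
) -> DipResult:
    """Dip test of unimodality with a uniform bootstrap null.

    p is the fraction of uniform-sample dips at this n that reach the
    observed statistic; a precomputed ``null_dips`` table may be passed.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("dip test needs n >= 4")
    D = dip_statistic(x)
    if null_dips is None:
        null_dips = dip_null_sample(x.size, n_boot, seed)
    p = float((null_dips >= D).mean())
    return DipResult(D=D, p=p, n=int(x.size), n_boot=int(len(null_dips)))
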