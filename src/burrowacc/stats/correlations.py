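"""Task-specialization associations and simple correlation helpers.

Caste systems predict negative correlations between individual
contributions to different cooperative tasks.  Each task dyad is
examined with a beta-binomial GLMM of one task's window counts on the
other task's proportion, with the social-group random intercept; the
association is reported as the marginal R-squared and the predictor's
Wald P.  An optional Grubbs screen flags single extreme individuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import fit_glmm

__all__ = ["pearson_with_t", "grubbs_outliers", "task_correlations"]


def pearson_with_t(x, y):
    """Pearson r with its t statistic: t = r * sqrt(df / (1 - r^2)), df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(sps.pearsonr(x, y).statistic)
    df = len(x) - 2
    t = r * np.sqrt(df / (1.0 - r**2)) if abs(r) < 1 else np.inf * np.sign(r)
    return r, float(t), df


def grubbs_outliers(x, alpha: float = 0.05) -> np.ndarray:
    """Indices of outliers by iterated two-sided Grubbs tests."""
    x = np.asarray(x, dtype=float)
    idx = np.arange(len(x))
    out = []
    while len(idx) > 2:
        v = x[idx]
        n = len(v)
        g = np.abs(v - v.mean()) / v.std(ddof=1)
        i = int(np.argmax(g))
        t2 = sps.t.ppf(1 - alpha / (2 * n), n - 2) ** 2
        crit = (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))
        if g[i] > crit:
            out.append(int(idx[i]))
            idx = np.delete(idx, i)
        else:
            break
    return np.array(sorted(out), dtype=int)


def task_correlations(
    table: pd.DataFrame,
    tasks: list[tuple[str, str, str]],
    group: str = "group_id",
    screen_outliers: bool = False,
) -> pd.DataFrame:
    """Pairwise task associations with a group random intercept.

    ``tasks`` lists (count_column, total_column, label) triples; every
    ordered pair (A regressed on B's proportion) is fitted as a
    beta-binomial GLMM.  Returns one row per dyad with marginal R2,
    the slope and its P value, and optionally the outlier count from a
    Grubbs screen of the predictor.
    """
    if len(table) < 10:
        raise ValueError("need >= 10 individuals")
    rows = []
    for cnt_a, tot_a, lab_a in tasks:
        for cnt_b, tot_b, lab_b in tasks:
            if lab_a >= lab_b:
                continue
            df = table.copy()
            prop_b = df[cnt_b] / df[tot_b]
            if prop_b.std() == 0:
                raise ValueError(f"constant predictor {lab_b}")
            df["_pred"] = (prop_b - prop_b.mean()) / prop_b.std()
            kept = df
            n_out = 0
            if screen_outliers:
                out = grubbs_outliers(df["_pred"].to_numpy())
                n_out = len(out)
                kept = df.drop(df.index[out])
            fit = fit_glmm(
                kept, response=cnt_a, fixed=["_pred"], group=group,
                family="betabinom", trials=tot_a,
            )
            rows.append(
                {
                    "response": lab_a,
                    "predictor": lab_b,
                    "slope": fit.beta[1],
                    "p": fit.p[1],
                    "marginal_r2": fit.marginal_r2,
                    "n_outliers_removed": n_out,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)
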