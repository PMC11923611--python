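"""Repeatability (intra-class correlation) of daily behavioural metrics.

A Gaussian random-intercept model on daily values partitions variance
into among-individual and residual components; repeatability is
r = var_individual / (var_individual + var_residual).  Significance
comes from a likelihood-ratio test against the intercept-only model,
referred to the boundary-corrected mixture 0.5*chi2_0 + 0.5*chi2_1
(the null variance sits on the edge of the parameter space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats as sps

__all__ = ["RepeatabilityResult", "repeatability"]


@dataclass(frozen=True)
class RepeatabilityResult:
    r_rpt: float
    var_individual: float
    var_residual: float
    lrt: float
    p: float
    n_individuals: int
    n_obs: int


def repeatability(
    daily_values, individual_ids, scale: str = "observed"
) -> RepeatabilityResult:
    """Intra-class correlation of a daily metric across individuals.

    ``scale='logit'`` transforms proportions before fitting (values
    clipped away from 0/1); the default models the observed scale.
    Needs >= 2 individuals with >= 2 days each.
    """
    y = np.asarray(daily_values, dtype=float)
    ids = np.asarray(individual_ids)
    ok = np.isfinite(y)
    y, ids = y[ok], ids[ok]
    if scale == "logit":
        y = special.logit(np.clip(y, 1e-6, 1 - 1e-6))
    elif scale != "observed":
        raise ValueError("scale must be 'observed' or 'logit'")
    uniq, counts = np.unique(ids, return_counts=True)
    if len(uniq) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 individuals with >= 2 days each")
    df = pd.DataFrame({"y": y, "ind": ids})
    model = sm.MixedLM.from_formula("y ~ 1", groups="ind", data=df)
    fit = model.fit(reml=False)
    var_ind = float(fit.cov_re.iloc[0, 0])
    var_res = float(fit.scale)
    null = sm.OLS(df["y"].to_numpy(), np.ones((len(df), 1))).fit()
    lrt = max(0.0, 2.0 * (fit.llf - null.llf))
    p = 0.5 * sps.chi2.sf(lrt, 1) + (0.5 if lrt == 0.0 else 0.0)
    return RepeatabilityResult(
        r_rpt=var_ind / (var_ind + var_res),
        var_individual=var_ind,
        var_residual=var_res,
        lrt=float(lrt),
        p=float(p),
        n_individuals=int(len(uniq)),
        n_obs=int(len(df)),
    )
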