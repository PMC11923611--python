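"""Individual growth index from a smoothed population growth surface.

Juvenile growth is summarised per individual from its first two capture
masses: the response is the mass gain between captures, modelled as a
sex-specific penalized-spline smooth of the first mass (growth slows
with size) plus a linear effect of the day gap between captures.  The
residual from this population surface is the growth index — positive
means the animal grew faster than expected for its starting mass, sex
and recapture interval.

Eligibility mirrors field practice: the first mass must be below 90 g
(roughly under one year of age) and the recapture 3-8 months later
(91-244 days inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "FIRST_MASS_MAX_G",
    "GAP_DAYS_MIN",
    "GAP_DAYS_MAX",
    "select_growth_pairs",
    "GrowthSurface",
    "fit_growth_surface",
    "growth_index",
]

FIRST_MASS_MAX_G = 90.0
GAP_DAYS_MIN = 91.0   # 3 months
GAP_DAYS_MAX = 244.0  # 8 months

_ALPHA_GRID = np.logspace(-2, 7, 10)


def select_growth_pairs(captures: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-two-capture growth pairs with eligibility filters applied.

    ``captures`` needs columns ``individual_id``, ``date`` (datetime or
    numeric days), ``mass_g``, ``sex``.  Returns ``(pairs, excluded)``
    where ``excluded`` carries one reason code per ineligible
    individual: ``single_capture``, ``first_mass_too_high``,
    ``gap_too_short`` or ``gap_too_long``.
    """
    req = {"individual_id", "date", "mass_g", "sex"}
    if not req <= set(captures.columns):
        raise ValueError(f"captures missing columns {sorted(req - set(captures.columns))}")
    rows, excl = [], []
    for ind, g in captures.groupby("individual_id", sort=True):
        g = g.sort_values("date")
        if len(g) < 2:
            excl.append({"individual_id": ind, "reason": "single_capture"})
            continue
        first, second = g.iloc[0], g.iloc[1]
        gap = second["date"] - first["date"]
        gap_days = float(gap.days if hasattr(gap, "days") else gap)
        if first["mass_g"] >= FIRST_MASS_MAX_G:
            excl.append({"individual_id": ind, "reason": "first_mass_too_high"})
        elif gap_days < GAP_DAYS_MIN:
            excl.append({"individual_id": ind, "reason": "gap_too_short"})
        elif gap_days > GAP_DAYS_MAX:
            excl.append({"individual_id": ind, "reason": "gap_too_long"})
        else:
            rows.append(
                {
                    "individual_id": ind,
                    "first_mass": float(first["mass_g"]),
                    "second_mass": float(second["mass_g"]),
                    "gap_days": gap_days,
                    "sex": first["sex"],
                }
            )
    cols = ["individual_id", "first_mass", "second_mass", "gap_days", "sex"]
    return (
        pd.DataFrame(rows, columns=cols),
        pd.DataFrame(excl, columns=["individual_id", "reason"]),
    )


@dataclass
class GrowthSurface:
    """Fitted per-sex growth smoothers with their observed mass ranges."""

    models: dict
    smoothers: dict
    mass_range: dict

    def predict(self, first_mass, sex, gap_days):
        """Predicted mass gain; extrapolation clamps to the boundary.

        Returns ``(prediction, extrapolated_flag)`` as arrays.
        """
        fm = np.atleast_1d(np.asarray(first_mass, dtype=float))
        gp = np.atleast_1d(np.asarray(gap_days, dtype=float))
        sx = np.atleast_1d(np.asarray(sex))
        pred = np.empty(len(fm))
        flag = np.zeros(len(fm), dtype=bool)
        for s in np.unique(sx):
            m = sx == s
            if s not in self.models:
                raise ValueError(f"no growth surface fitted for sex {s!r}")
            lo, hi = self.mass_range[s]
            fm_s = fm[m]
            flag[m] = (fm_s < lo) | (fm_s > hi)
            fm_c = np.clip(fm_s, lo, hi)
            exog = sm.add_constant(gp[m][:, None], has_constant="add")
            exog_smooth = self.smoothers[s].transform(fm_c[:, None])
            pred[m] = self.models[s].predict(
                exog=exog, exog_smooth=exog_smooth, transform=False
            )
        return pred, flag


def _fit_one_sex(df: pd.DataFrame) -> tuple:
    y = (df["second_mass"] - df["first_mass"]).to_numpy()
    x = df["first_mass"].to_numpy()[:, None]
    n = len(y)
    df_spline = int(min(8, max(4, n // 5)))
    bs = BSplines(x, df=[df_spline], degree=[3])
    exog = sm.add_constant(df["gap_days"].to_numpy()[:, None], has_constant="add")
    best = None
    for a in _ALPHA_GRID:
        res = GLMGam(y, exog=exog, smoother=bs, alpha=[a]).fit()
        edf = float(res.edf.sum())
        rss = float((res.resid_response**2).sum())
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, res)
    return best[1], bs


def fit_growth_surface(pairs: pd.DataFrame, min_pairs: int = 20) -> GrowthSurface:
    """Fit the population growth surface (one penalized smooth per sex).

    Smoothing strength is chosen by generalized cross-validation over a
    log-spaced grid, independently per sex.
    """
    if len(pairs) < min_pairs:
        raise ValueError(f"need >= {min_pairs} growth pairs, got {len(pairs)}")
    models, smoothers, ranges = {}, {}, {}
    for s, g in pairs.groupby("sex"):
        if len(g) < 5:
            raise ValueError(f"too few pairs ({len(g)}) for sex {s!r}")
        models[s], smoothers[s] = _fit_one_sex(g)
        ranges[s] = (float(g["first_mass"].min()), float(g["first_mass"].max()))
    return GrowthSurface(models, smoothers, ranges)


def growth_index(pairs: pd.DataFrame, surface: GrowthSurface) -> pd.DataFrame:
    """Observed minus predicted mass gain, per individual.

    Positive index = faster-than-average growth.  Rows needing
    extrapolation beyond the fitted first-mass range are flagged.
    """
    pred, flag = surface.predict(
        pairs["first_mass"].to_numpy(),
        pairs["sex"].to_numpy(),
        pairs["gap_days"].to_numpy(),
    )
    obs = (pairs["second_mass"] - pairs["first_mass"]).to_numpy()
    return pd.DataFrame(
        {
            "individual_id": pairs["individual_id"].to_numpy(),
            "growth_index_g": obs - pred,
            "extrapolated": flag,
        }
    )
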