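"""Budget-tier simulation: daily time budgets drawn directly from the
planted statistical models, skipping raw-signal synthesis.

Raw 25 Hz signal for a full study (~86 animals x 17 days) would be
billions of samples; parameter-recovery exercises only need the daily
window counts and ODBA means that the classification pipeline would
produce.  This tier draws those directly from the planted logit/log
models with group, individual and day noise, so mixed-model recovery
can run at the study's full design size in seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special

from .params import DEFAULT_EFFECTS, PlantedEffects

__all__ = ["simulate_budgets", "WINDOWS_PER_DAY"]

WINDOWS_PER_DAY = 43200  # 86400 s / 2 s windows


def _linear_predictors(meta: pd.DataFrame, eff: PlantedEffects, rng):
    """Per-individual etas for excavate, rest, ODBA and vertical eating."""
    m = meta
    status = m["breeder"].to_numpy(float)
    male = (m["sex"] == "M").to_numpy(float)
    gs_c = m["group_size"].to_numpy(float) - m["group_size"].mean()
    nb = status == 0

    # age and growth effects: within non-breeders, centred on that stratum
    agesq = (m["age_months"].to_numpy(float) - eff.exc_age_peak_months) ** 2
    age_term = np.where(nb, agesq, 0.0)
    age_term[nb] -= agesq[nb].mean()
    growth = np.where(nb, m["gain_dev"].to_numpy(float), 0.0)
    growth[nb] -= growth[nb].mean()

    groups, gidx = np.unique(m["group_id"].to_numpy(), return_inverse=True)
    u_exc = rng.normal(0, eff.exc_sd_group, len(groups))[gidx]
    u_rest = rng.normal(0, eff.rest_sd_group, len(groups))[gidx]
    u_odba = rng.normal(0, eff.odba_sd_group, len(groups))[gidx]

    eta_exc = (
        eff.exc_intercept + eff.exc_status * status
        + eff.exc_group_size * gs_c + eff.exc_status_x_gs * status * gs_c
        + eff.exc_sex_male * male + eff.exc_age_quad * age_term
        + eff.exc_growth * growth
        + u_exc + rng.normal(0, eff.exc_sd_ind, len(m))
    )
    eta_rest = (
        eff.rest_intercept + eff.rest_status * status
        + eff.rest_group_size * gs_c + eff.rest_status_x_gs * status * gs_c
        + eff.rest_sex_male * male + eff.rest_growth * growth
        + u_rest + rng.normal(0, eff.rest_sd_ind, len(m))
    )
    eta_odba = (
        eff.odba_intercept + eff.odba_status * status
        + eff.odba_group_size * gs_c + eff.odba_status_x_gs * status * gs_c
        + eff.odba_sex_male * male + eff.odba_growth * growth
        + u_odba + rng.normal(0, eff.odba_sd_ind, len(m))
    )
    bf = (status == 1) & (male == 0)
    bm = (status == 1) & (male == 1)
    eta_vert = (
        eff.vert_intercept + eff.vert_breeding_female * bf
        + eff.vert_breeding_male * bm
        + rng.normal(0, eff.vert_sd_ind, len(m))
    )
    return eta_exc, eta_rest, eta_odba, eta_vert


def simulate_budgets(
    meta: pd.DataFrame,
    effects: PlantedEffects = DEFAULT_EFFECTS,
    seed: int = 0,
    windows_per_day: int = WINDOWS_PER_DAY,
) -> pd.DataFrame:
    """Daily time-budget rows for every individual in ``meta``.

    Each day draws a day-level logit/log perturbation, then window
    counts binomially: excavate first, rest from the remainder (with
    the conditional probability that preserves its marginal share),
    movement and other splitting what is left.  Output columns match
    :func:`burrowacc.ethogram.daily_time_budget`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    eff = effects
    eta_exc, eta_rest, eta_odba, eta_vert = _linear_predictors(meta, eff, rng)
    rows = []
    for i, ind in enumerate(meta.itertuples()):
        days = int(round(ind.deployment_days))
        p_vert = special.expit(eta_vert[i])
        # food carrying shares the excavation work propensity
        fc_share = special.expit(
            special.logit(eff.fc_share_of_move)
            + eff.fc_exc_coupling * (eta_exc[i] - eff.exc_intercept)
        )
        for d in range(days):
            p_exc = special.expit(eta_exc[i] + rng.normal(0, eff.exc_sd_day))
            p_rest = special.expit(eta_rest[i] + rng.normal(0, eff.rest_sd_day))
            p_rest = min(p_rest, 0.995 * (1.0 - p_exc))
            n_tot = windows_per_day
            n_exc = rng.binomial(n_tot, p_exc)
            n_rest = rng.binomial(n_tot - n_exc, p_rest / (1.0 - p_exc))
            n_rem = n_tot - n_exc - n_rest
            n_move = rng.binomial(n_rem, eff.move_share_of_rem)
            n_other = n_rem - n_move
            n_eat = rng.binomial(n_other, eff.eat_share_of_other)
            n_fc = rng.binomial(n_move, fc_share)
            n_walk = rng.binomial(n_move - n_fc, eff.walk_share_of_move)
            mu = np.exp(eta_odba[i])
            mean_odba = rng.gamma(eff.odba_day_shape, mu / eff.odba_day_shape)
            prop_vert = (
                rng.binomial(n_eat, p_vert) / n_eat if n_eat > 0 else np.nan
            )
            rows.append(
                dict(
                    individual_id=ind.individual_id, day=d,
                    prop_rest=n_rest / n_tot, prop_excavate=n_exc / n_tot,
                    prop_move=n_move / n_tot, prop_other=n_other / n_tot,
                    n_excavate=int(n_exc), n_rest=int(n_rest),
                    n_food_carry=int(n_fc), n_walk_around=int(n_walk),
                    n_total=int(n_tot), mean_odba=float(mean_odba),
                    prop_vertical_eat=prop_vert,
                )
            )
    return pd.DataFrame(rows)
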