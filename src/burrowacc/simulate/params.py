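"""Planted effect sizes and noise levels for the synthetic study.

The generator emulates a wild population of cooperatively breeding
mole-rats carrying collar accelerometers: 11 groups averaging nine
animals, one breeding pair per group, ~17 days of continuous 25 Hz
recording per individual.  Effects on the behavioural metrics are
planted on the model scale (logit for proportions, log for ODBA) so
that downstream model fitting is a parameter-recovery exercise:

* excavating time: breeders excavate less, increasingly so in larger
  groups (negative status x group-size interaction), males less than
  females, a hump-shaped age effect peaking at 14 months, and a
  positive effect of growth rate;
* resting time: the mirror image (breeders rest more in large groups);
* ODBA: breeders and males less active overall;
* vertical eating: breeding females eat upright less often.

Age and growth effects apply within non-breeders and are centred over
that stratum, so the planted status contrast is exactly the marginal
breeder/non-breeder difference that the contrast models estimate
(breeders' covariate term is pinned at the non-breeder mean).

Day-to-day and between-individual logit noise for excavation are set
so the planted intra-class correlation of daily excavating time is
0.37.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PlantedEffects", "DEFAULT_EFFECTS"]

# intra-class correlation of daily excavating proportions.  The
# between-individual variance budget includes every planted source of
# stable individual differences: the age hump (-0.002 per (age-14)^2
# over ages 5-36 months contributes var ~0.075 on the logit scale),
# the growth slope (~0.017), the group intercept (0.01), and a free
# individual term that absorbs the remainder.
ICC_EXCAVATE = 0.37
_VAR_DAY_EXC = 0.20
_VAR_BETWEEN_TOTAL = ICC_EXCAVATE / (1.0 - ICC_EXCAVATE) * _VAR_DAY_EXC
_VAR_AGE_EXC = 0.0747
_VAR_GROWTH_EXC = 0.017
_VAR_GROUP_EXC = 0.01
_VAR_IND_EXC = max(
    _VAR_BETWEEN_TOTAL - _VAR_AGE_EXC - _VAR_GROWTH_EXC - _VAR_GROUP_EXC,
    1e-4,
)


@dataclass(frozen=True)
class PlantedEffects:
    """All generator coefficients, on logit (proportions) / log (ODBA) scales."""

    # proportion of time in excavating activities
    exc_intercept: float = -2.442          # logit(0.08)
    exc_status: float = -0.542
    exc_group_size: float = -0.005
    exc_status_x_gs: float = -0.066
    exc_sex_male: float = -0.139
    exc_age_quad: float = -0.002           # per (months - 14)^2, non-breeders
    exc_age_peak_months: float = 14.0
    exc_growth: float = 0.01               # per g of growth deviation
    exc_sd_group: float = 0.10
    exc_sd_ind: float = _VAR_IND_EXC**0.5
    exc_sd_day: float = _VAR_DAY_EXC**0.5

    # proportion of time resting
    rest_intercept: float = 0.619          # logit(0.65)
    rest_status: float = 0.324
    rest_group_size: float = 0.011
    rest_status_x_gs: float = 0.018
    rest_sex_male: float = 0.181
    rest_growth: float = -0.006
    rest_sd_group: float = 0.05
    rest_sd_ind: float = 0.25
    rest_sd_day: float = 0.30

    # overall dynamic body acceleration (per-window sum, ms^-2)
    odba_intercept: float = 3.33           # log(~28)
    odba_status: float = -0.274
    odba_group_size: float = -0.007
    odba_status_x_gs: float = -0.020
    odba_sex_male: float = -0.100
    odba_growth: float = 0.008
    odba_sd_group: float = 0.03
    odba_sd_ind: float = 0.08
    odba_day_shape: float = 200.0          # gamma shape of daily means

    # vertical eating (upright posture share of eating windows)
    vert_intercept: float = 0.405          # logit(0.6)
    vert_breeding_female: float = -0.8
    vert_breeding_male: float = -0.1
    vert_sd_ind: float = 0.30

    # composition of the non-rest, non-excavate remainder
    move_share_of_rem: float = 8.0 / 27.0
    eat_share_of_other: float = 8.0 / 19.0

    # task-specialization structure: food carrying shares the excavation
    # work propensity (positive coupling on the logit scale), walk-around
    # locomotion does not
    fc_share_of_move: float = 0.15
    fc_exc_coupling: float = 0.5
    walk_share_of_move: float = 0.35


DEFAULT_EFFECTS = PlantedEffects()
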