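"""Semi-Markov behaviour schedules with planted category targets.

Behaviour sequences are generated as a renewal process over the
14-behaviour ethogram: each bout picks a behaviour with
frequency weights and holds it for a log-normal dwell time.  Category
weight multipliers are solved per individual-day so the expected time
share of excavating and resting equals the planted logit-model
targets (renewal-reward: the time share of behaviour b is
freq_b * E[dwell_b] / sum over all behaviours).  Explicit dwell times
give realistic bout structure for bout-based operators (walk-around),
unlike per-window independent draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from ..acc_io import LabeledInterval
from ..behavior_model import BEHAVIOURS, CATEGORY_MAP
from .params import DEFAULT_EFFECTS, PlantedEffects

__all__ = ["BehaviourScheduleModel", "simulate_schedule"]

# log-normal dwell medians (s) and sigmas; rest dominates and dwells long
_DWELL_MEDIAN = {
    "rest": 180.0, "dig": 20.0, "sweep": 12.0, "back-kick": 10.0,
    "run": 8.0, "walk": 10.0, "food-carry": 9.0, "eat": 40.0,
    "groom": 15.0, "scratch": 8.0, "sniff": 8.0, "gnaw": 12.0,
    "rear": 7.0, "shuffle": 8.0,
}
_DWELL_SIGMA = {b: 0.6 for b in BEHAVIOURS}

# relative bout frequencies within each category
_WITHIN_WEIGHTS = {
    "rest": 1.0,
    "dig": 1.0, "sweep": 0.8, "back-kick": 0.35,
    "run": 0.9, "walk": 1.0, "food-carry": 0.3,
    "eat": 0.55, "groom": 0.5, "scratch": 0.3, "sniff": 0.45,
    "gnaw": 0.3, "rear": 0.25, "shuffle": 0.4,
}


@dataclass
class BehaviourScheduleModel:
    """Dwell distributions, bout-frequency weights and planted targets."""

    effects: PlantedEffects = field(default_factory=lambda: DEFAULT_EFFECTS)
    dwell_median_s: dict = field(default_factory=lambda: dict(_DWELL_MEDIAN))
    dwell_sigma: dict = field(default_factory=lambda: dict(_DWELL_SIGMA))
    within_weights: dict = field(default_factory=lambda: dict(_WITHIN_WEIGHTS))

    def mean_dwell(self, b: str) -> float:
        s = self.dwell_sigma[b]
        return self.dwell_median_s[b] * float(np.exp(s * s / 2.0))

    def bout_weights(self, p_exc: float, p_rest: float) -> dict:
        """Bout-frequency weights whose long-run time shares hit the targets.

        Remaining probability mass splits between movement and other by
        the configured composition.
        """
        p_rem = max(1.0 - p_exc - p_rest, 1e-6)
        p_move = p_rem * self.effects.move_share_of_rem
        p_other = p_rem - p_move
        target = {"excavate": p_exc, "rest": p_rest,
                  "move": p_move, "other": p_other}
        time_mass = {
            c: sum(self.within_weights[b] * self.mean_dwell(b)
                   for b in BEHAVIOURS if CATEGORY_MAP[b] == c)
            for c in target
        }
        mult = {c: target[c] / time_mass[c] for c in target}
        w = {b: self.within_weights[b] * mult[CATEGORY_MAP[b]]
             for b in BEHAVIOURS}
        tot = sum(w.values())
        return {b: v / tot for b, v in w.items()}

    def transition_matrix(self, p_exc: float, p_rest: float) -> np.ndarray:
        """Next-bout behaviour probabilities (identical rows: renewals
        are drawn independently of the current state)."""
        w = self.bout_weights(p_exc, p_rest)
        row = np.array([w[b] for b in BEHAVIOURS])
        return np.tile(row, (len(BEHAVIOURS), 1))


def simulate_schedule(
    eta_exc_ind: float,
    eta_rest_ind: float,
    model: BehaviourScheduleModel,
    days: float,
    seed,
) -> list[LabeledInterval]:
    """One individual's behaviour intervals tiling ``days`` of recording.

    ``eta_*`` are the individual's logit-scale linear predictors; a
    fresh day-level perturbation is drawn per calendar day.  Intervals
    cover [0, days*86400] exactly with no gaps or overlaps.
    """
    rng = np.random.default_rng(seed)
    eff = model.effects
    names = list(BEHAVIOURS)
    med = np.array([model.dwell_median_s[b] for b in names])
    sig = np.array([model.dwell_sigma[b] for b in names])
    out: list[LabeledInterval] = []
    total_s = days * 86400.0
    t = 0.0
    day_end = 0.0
    probs = None
    while t < total_s - 1e-9:
        if t >= day_end - 1e-9:  # new day: refresh targets
            day_end = min(day_end + 86400.0, total_s) if day_end else min(86400.0, total_s)
            p_exc = special.expit(eta_exc_ind + rng.normal(0, eff.exc_sd_day))
            p_rest = special.expit(eta_rest_ind + rng.normal(0, eff.rest_sd_day))
            p_rest = min(p_rest, 0.995 * (1.0 - p_exc))
            w = model.bout_weights(p_exc, p_rest)
            probs = np.array([w[b] for b in names])
        b = int(rng.choice(len(names), p=probs))
        dwell = float(med[b] * np.exp(rng.normal(0.0, sig[b])))
        end = min(t + dwell, day_end)
        out.append(LabeledInterval(t, end, names[b]))
        t = end
    return out
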