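"""Full synthetic datasets on disk: ACC CSVs, label CSVs, metadata, truth.

Ties the generator tiers together: population -> per-individual
behaviour schedule -> raw 25 Hz signal, written in the CSV dialects the
I/O module reads, plus a ``truth.json`` recording every planted
parameter for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..acc_io import write_acc
from .budgets import _linear_predictors
from .params import DEFAULT_EFFECTS, PlantedEffects
from .population import PopulationConfig, make_population
from .schedule import BehaviourScheduleModel, simulate_schedule
from .signal import IndividualSignalOffsets, SignalModel, synthesize_acc

__all__ = ["generate_dataset"]


def generate_dataset(
    config: PopulationConfig,
    out_dir: str | Path,
    effects: PlantedEffects = DEFAULT_EFFECTS,
    deployment_days: float | None = None,
    write_csv: bool = True,
):
    """Generate a complete dataset; returns (meta, schedules, series).

    ``deployment_days`` overrides per-individual deployment lengths
    (fractional days make quick smoke runs possible).  With
    ``write_csv`` the acceleration (`<id>_acc.csv`), labels
    (`<id>_labels.csv`), `metadata.csv`, `captures.csv` and
    `truth.json` are written under ``out_dir``.
    """
    out = Path(out_dir)
    if write_csv:
        out.mkdir(parents=True, exist_ok=True)
    meta, captures, truth = make_population(config)
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(3 + 2 * len(meta))
    rng_eff = np.random.default_rng(child[2])
    eta_exc, eta_rest, eta_odba, eta_vert = _linear_predictors(
        meta, effects, rng_eff
    )
    sched_model = BehaviourScheduleModel(effects=effects)
    sig_model = SignalModel()
    from scipy.special import expit

    schedules, series_list = {}, {}
    for i, ind in enumerate(meta.itertuples()):
        days = deployment_days if deployment_days is not None else ind.deployment_days
        ivs = simulate_schedule(
            eta_exc[i], eta_rest[i], sched_model, days, child[3 + 2 * i]
        )
        rng_i = np.random.default_rng(child[3 + 2 * i + 1])
        offs = IndividualSignalOffsets.draw(rng_i)
        series = synthesize_acc(
            ivs, sig_model, config.rate_hz, seed=rng_i.integers(2**31),
            individual_id=ind.individual_id, offsets=offs,
            p_vertical_eat=float(expit(eta_vert[i])),
        )
        schedules[ind.individual_id] = ivs
        series_list[ind.individual_id] = series
        if write_csv:
            write_acc(series, out / f"{ind.individual_id}_acc.csv")
            pd.DataFrame(
                [
                    {"start_s": iv.start_s, "end_s": iv.end_s,
                     "behaviour": iv.behaviour}
                    for iv in ivs
                ]
            ).to_csv(out / f"{ind.individual_id}_labels.csv", index=False)

    truth = dict(
        truth,
        effects=dataclasses.asdict(effects),
        eta_excavate=dict(zip(meta.individual_id, map(float, eta_exc))),
        eta_rest=dict(zip(meta.individual_id, map(float, eta_rest))),
        eta_odba=dict(zip(meta.individual_id, map(float, eta_odba))),
        p_vertical_eat=dict(
            zip(meta.individual_id, map(float, expit(eta_vert)))
        ),
    )
    if write_csv:
        meta.to_csv(out / "metadata.csv", index=False)
        captures.to_csv(out / "captures.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return meta, schedules, series_list, truth
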