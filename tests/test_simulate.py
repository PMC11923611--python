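"""Generator invariants: population structure, schedule tiling, signal
posture geometry, planted-effect plumbing and dataset round trips."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from burrowacc.acc_io import attach_labels, read_acc, segment_windows
from burrowacc.behavior_model import BEHAVIOURS, CATEGORY_MAP
from burrowacc.signal_features import mean_z
from burrowacc.simulate import (
    DEFAULT_EFFECTS,
    BehaviourScheduleModel,
    PopulationConfig,
    SignalModel,
    generate_dataset,
    make_population,
    make_training_set,
    simulate_budgets,
    simulate_schedule,
    synthesize_acc,
)
from burrowacc.acc_io import LabeledInterval


class TestPopulation:
    def test_default_structure(self):
        meta, caps, truth = make_population(PopulationConfig(seed=3))
        assert meta.group_id.nunique() == 11
        assert len(meta) == sum(truth["group_sizes"])
        per_group = meta.groupby("group_id")["breeder"].sum()
        assert (per_group == 2).all()  # one breeding pair each
        sexes = meta[meta.breeder].groupby("group_id")["sex"].nunique()
        assert (sexes == 2).all()
        assert (caps.groupby("individual_id").size() == 2).all()

    def test_reproducible_from_seed(self):
        a, _, _ = make_population(PopulationConfig(seed=11))
        b, _, _ = make_population(PopulationConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_group_rejected(self):
        cfg = PopulationConfig(n_groups=2, group_sizes=[1, 5])
        with pytest.raises(ValueError, match="breeding pair"):
            make_population(cfg)

    def test_mini_profile_varies_group_size(self):
        cfg = PopulationConfig.mini()
        meta, _, _ = make_population(cfg)
        assert meta.group_id.nunique() == 4
        assert meta.group_size.nunique() > 1


class TestSchedule:
    def test_intervals_tile_deployment(self):
        model = BehaviourScheduleModel()
        ivs = simulate_schedule(-2.44, 0.62, model, days=0.5, seed=5)
        assert ivs[0].start_s == 0.0
        assert ivs[-1].end_s == pytest.approx(0.5 * 86400)
        for a, b in zip(ivs, ivs[1:]):
            assert b.start_s == pytest.approx(a.end_s)

    def test_long_run_share_hits_planted_target(self):
        # silence day-to-day noise to isolate the renewal-reward property
        eff = dataclasses.replace(
            DEFAULT_EFFECTS, exc_sd_day=1e-9, rest_sd_day=1e-9
        )
        model = BehaviourScheduleModel(effects=eff)
        target = expit(-2.44)
        ivs = simulate_schedule(-2.44, 0.62, model, days=17, seed=8)
        tot = ivs[-1].end_s
        exc = sum(
            iv.end_s - iv.start_s
            for iv in ivs
            if CATEGORY_MAP[iv.behaviour] == "excavate"
        )
        assert exc / tot == pytest.approx(target, abs=0.01)

    def test_transition_matrix_rows_sum_to_one(self):
        model = BehaviourScheduleModel()
        P = model.transition_matrix(0.08, 0.65)
        assert P.shape == (14, 14)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_breeder_target_below_matched_nonbreeder(self):
        eff = DEFAULT_EFFECTS
        gs_c = 3.0  # larger-than-average group
        nb = eff.exc_intercept + eff.exc_group_size * gs_c
        br = nb + eff.exc_status + eff.exc_status_x_gs * gs_c
        assert expit(br) < expit(nb)


class TestSignal:
    def test_noiseless_rest_is_constant_gravity_magnitude(self):
        model = SignalModel(params={"rest": (0.0, 0.0, 0.8, 0.0, (1, 1, 1))})
        ivs = [LabeledInterval(0.0, 10.0, "rest")]
        s = synthesize_acc(ivs, model, 25.0, seed=0)
        mags = np.linalg.norm(s.samples, axis=1)
        assert np.allclose(mags, 9.8, atol=1e-9)

    def test_vertical_eat_windows_below_cutoff(self):
        ivs = [LabeledInterval(0.0, 402.0, "eat")]
        s = synthesize_acc(ivs, SignalModel(), 25.0, seed=2, p_vertical_eat=1.0)
        wins = segment_windows(s)
        frac = np.mean([mean_z(w) < 4.9 for w in wins])
        assert frac >= 0.99

    def test_horizontal_postures_above_cutoff(self):
        for beh in ("rest", "dig", "run", "walk"):
            ivs = [LabeledInterval(0.0, 100.0, beh)]
            s = synthesize_acc(ivs, SignalModel(), 25.0, seed=3,
                               p_vertical_eat=0.0)
            wins = segment_windows(s)
            assert np.mean([mean_z(w) >= 4.9 for w in wins]) > 0.95, beh

    def test_schedule_labels_cover_most_windows(self):
        model = BehaviourScheduleModel()
        ivs = simulate_schedule(-2.44, 0.62, model, days=0.1, seed=4)
        s = synthesize_acc(ivs, SignalModel(), 25.0, seed=4)
        wins = segment_windows(s)
        wins, _ = attach_labels(wins, ivs)
        frac = np.mean([w.label is not None for w in wins])
        assert frac >= 0.90

    def test_zero_separability_collapses_classes(self):
        model = SignalModel(separability=0.0)
        a = model.behaviour_params("rest")
        b = model.behaviour_params("dig")
        assert a[:4] == pytest.approx(b[:4])

    def test_training_set_is_balanced_and_owned(self):
        raw, labels, owners = make_training_set(
            n_individuals=3, windows_per_class=9, seed=1
        )
        assert raw.shape[1:] == (50, 3)
        counts = pd.Series(labels).value_counts()
        assert set(counts.index) == set(BEHAVIOURS)
        assert counts.nunique() == 1
        assert len(np.unique(owners)) == 3


class TestBudgetTier:
    def test_counts_and_proportions_consistent(self):
        meta, _, _ = make_population(PopulationConfig.mini())
        bud = simulate_budgets(meta, seed=1, windows_per_day=4000)
        props = bud[["prop_rest", "prop_excavate", "prop_move", "prop_other"]]
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)
        assert (bud.n_excavate == (bud.prop_excavate * bud.n_total).round()).all()
        assert (bud.n_food_carry + bud.n_walk_around
                <= bud.prop_move * bud.n_total + 1).all()
        assert (bud.groupby("individual_id").day.count()
                == meta.set_index("individual_id").deployment_days.round()[
                    bud.groupby("individual_id").day.count().index]).all()

    def test_mean_excavation_near_eight_percent(self):
        meta, _, _ = make_population(PopulationConfig(seed=21))
        bud = simulate_budgets(meta, seed=21, windows_per_day=4000)
        nb = meta.loc[~meta.breeder, "individual_id"]
        assert bud[bud.individual_id.isin(nb)].prop_excavate.mean() == pytest.approx(
            0.08, abs=0.03
        )

    def test_breeding_females_eat_vertically_less(self):
        meta, _, _ = make_population(PopulationConfig(seed=2))
        bud = simulate_budgets(meta, seed=2, windows_per_day=40000)
        m = bud.groupby("individual_id").prop_vertical_eat.mean().reset_index()
        m = m.merge(meta, on="individual_id")
        bf = m[(m.breeder) & (m.sex == "F")].prop_vertical_eat.mean()
        nb = m[~m.breeder].prop_vertical_eat.mean()
        assert bf < nb


class TestGenerateDataset:
    def test_micro_dataset_round_trips(self, tmp_path):
        cfg = PopulationConfig(
            n_groups=2, group_sizes=[2, 3], deployment_days_mean=1,
            deployment_days_sd=0, seed=9,
        )
        meta, schedules, series, truth = generate_dataset(
            cfg, tmp_path, deployment_days=0.02  # ~29 min each
        )
        assert len(meta) == 5
        f = tmp_path / f"{meta.individual_id.iloc[0]}_acc.csv"
        (back,) = read_acc(f, rate_hz=25)
        assert back.n_samples == series[meta.individual_id.iloc[0]].n_samples
        on_disk = json.loads((tmp_path / "truth.json").read_text())
        assert on_disk["effects"]["exc_status"] == pytest.approx(-0.542)
        assert set(on_disk["eta_excavate"]) == set(meta.individual_id)
        labels = pd.read_csv(
            tmp_path / f"{meta.individual_id.iloc[0]}_labels.csv"
        )
        assert labels.start_s.iloc[0] == 0.0
        assert labels.end_s.iloc[-1] == pytest.approx(0.02 * 86400)
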