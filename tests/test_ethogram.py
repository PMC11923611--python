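"""Bout construction, walk-around rules, vertical eating, time budgets."""

import numpy as np
import pandas as pd
import pytest

from burrowacc.ethogram import (
    build_bouts,
    daily_time_budget,
    vertical_eating_proportion,
    walk_around_windows,
)


class TestBuildBouts:
    def test_simple_runs(self):
        bouts = build_bouts(["rest", "rest", "excavate"], window_s=2.0)
        assert [(b.category, b.duration_s) for b in bouts] == [
            ("rest", 4.0), ("excavate", 2.0)
        ]

    def test_alternating_is_one_bout_per_window(self):
        cats = ["rest", "move"] * 10
        assert len(build_bouts(cats)) == 20

    def test_conservation(self, rng):
        cats = rng.choice(["rest", "excavate", "move", "other"], 500)
        bouts = build_bouts(cats, window_s=2.0)
        assert sum(b.n_windows for b in bouts) == 500
        assert sum(b.duration_s for b in bouts) == pytest.approx(1000.0)
        # concatenation reconstructs the sequence
        rebuilt = np.concatenate([[b.category] * b.n_windows for b in bouts])
        assert (rebuilt == cats).all()

    def test_unordered_starts_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            build_bouts(["rest", "rest"], starts=[2.0, 0.0])
        with pytest.raises(ValueError, match="contiguous"):
            build_bouts(["rest", "rest"], starts=[0.0, 6.0])


def _cats(spec):
    """Expand [(category, n_windows), ...] into a window sequence."""
    out = []
    for c, n in spec:
        out += [c] * n
    return out


class TestWalkAround:
    def test_short_movement_bout_excluded(self):
        # 4 s movement bout: not strictly > 5 s
        bouts = build_bouts(_cats([("rest", 40), ("move", 2), ("rest", 10)]))
        assert walk_around_windows(bouts) == []

    def test_recent_excavation_excludes_bout(self):
        # excavate ends 30 s before an 8 s movement bout
        bouts = build_bouts(
            _cats([("excavate", 5), ("rest", 15), ("move", 4), ("rest", 5)])
        )
        assert walk_around_windows(bouts) == []

    def test_excavation_just_outside_minute_is_ignored(self):
        # last excavate window ends 61 s before the movement bout start
        seq = _cats([("excavate", 5), ("rest", 31), ("move", 4), ("rest", 5)])
        bouts = build_bouts(seq)
        move_start = 5 + 31
        assert walk_around_windows(bouts) == list(
            range(move_start, move_start + 4)
        )

    def test_subset_of_movement_and_no_excavate_means_all_qualify(self, rng):
        cats = rng.choice(["rest", "move", "other"], 400, p=[0.6, 0.25, 0.15])
        bouts = build_bouts(cats)
        wa = walk_around_windows(bouts)
        assert all(cats[i] == "move" for i in wa)
        long_move = [
            i
            for b in bouts
            if b.category == "move" and b.duration_s > 5.0
            for i in range(b.first_index, b.first_index + b.n_windows)
        ]
        assert wa == long_move

    def test_food_carry_windows_dropped_when_behaviours_known(self):
        seq = _cats([("rest", 31), ("move", 4)])
        behs = ["rest"] * 31 + ["walk", "food-carry", "walk", "walk"]
        bouts = build_bouts(seq)
        wa = walk_around_windows(bouts, behaviours=behs)
        assert wa == [31, 33, 34]


class TestVerticalEating:
    def test_all_vertical(self):
        assert vertical_eating_proportion([2.0, 3.0], ["eat", "eat"]) == 1.0

    def test_half_vertical(self):
        mz = [2.0, 9.8, 2.0, 9.8]
        assert vertical_eating_proportion(mz, ["eat"] * 4) == 0.5

    def test_no_eating_is_missing_not_zero(self):
        assert vertical_eating_proportion([9.8], ["rest"]) is None


class TestDailyTimeBudget:
    def _frame(self, cats, start=0.0):
        return pd.DataFrame(
            {
                "individual_id": "a",
                "start_s": start + 2.0 * np.arange(len(cats)),
                "category": cats,
                "odba": 1.0,
            }
        )

    def test_pure_rest_day(self):
        out = daily_time_budget(self._frame(["rest"] * 100))
        assert out.loc[0, "prop_rest"] == 1.0
        assert out.loc[0, "prop_excavate"] == 0.0
        assert out.loc[0, "incomplete"]  # far fewer than a day of windows

    def test_proportions_sum_to_one(self, rng):
        cats = rng.choice(["rest", "excavate", "move", "other"], 1000)
        out = daily_time_budget(self._frame(cats))
        total = out[
            ["prop_rest", "prop_excavate", "prop_move", "prop_other"]
        ].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)
        assert out.loc[0, "n_excavate"] == (cats == "excavate").sum()

    def test_planted_eight_percent_schedule(self, rng):
        n = 43200  # one full day of 2 s windows
        cats = np.where(rng.uniform(size=n) < 0.08, "excavate", "rest")
        out = daily_time_budget(self._frame(cats))
        se = np.sqrt(0.08 * 0.92 / n)
        assert out.loc[0, "prop_excavate"] == pytest.approx(0.08, abs=5 * se)
        assert not out.loc[0, "incomplete"]

    def test_permutation_invariance_within_day(self, rng):
        cats = rng.choice(["rest", "excavate", "move", "other"], 500)
        a = daily_time_budget(self._frame(cats))
        b = daily_time_budget(self._frame(rng.permutation(cats)))
        cols = ["prop_rest", "prop_excavate", "prop_move", "prop_other"]
        assert np.allclose(a[cols], b[cols])

    def test_days_split_at_midnight(self):
        df = pd.concat(
            [
                self._frame(["rest"] * 10, start=0.0),
                self._frame(["excavate"] * 10, start=86400.0),
            ]
        )
        out = daily_time_budget(df)
        assert list(out["day"]) == [0, 1]
        assert out.loc[1, "prop_excavate"] == 1.0
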