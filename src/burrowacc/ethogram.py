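"""Bouts, derived behaviours and per-individual-day time budgets.

Window-level predictions are condensed to maximal runs of one category
("bouts"), from which derived behaviours are computed:

* walk-around — movement bouts longer than 5 s with no excavating
  window in the preceding minute; locomotion unrelated to digging work
  sequences (dig, sweep backwards, run back to the digging point), a
  possible tunnel-patrolling proxy;
* vertical-eating proportion — share of eating windows in an upright
  posture (mean z below half gravity), indicating eating directly from
  an in-ground tuber rather than from detached pieces;
* daily time budgets — per individual-day category proportions, the
  window counts behind them (for beta-binomial models) and mean ODBA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior_model import CATEGORIES
from .signal_features import VERTICAL_CUTOFF_MS2

__all__ = [
    "Bout",
    "build_bouts",
    "walk_around_windows",
    "vertical_eating_proportion",
    "daily_time_budget",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive windows sharing one category."""

    individual_id: str
    category: str
    start_s: float
    end_s: float
    first_index: int
    n_windows: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def build_bouts(
    categories,
    window_s: float = 2.0,
    individual_id: str = "",
    start_s: float = 0.0,
    starts=None,
) -> list[Bout]:
    """Collapse per-window categories into maximal bouts.

    ``starts``, when given, are the window start times and must be
    contiguous and ascending; otherwise windows are assumed contiguous
    from ``start_s``.  Concatenating the bouts reconstructs the window
    sequence exactly.
    """
    cats = np.asarray(categories)
    n = len(cats)
    if n == 0:
        return []
    if starts is not None:
        starts = np.asarray(starts, dtype=float)
        d = np.diff(starts)
        if np.any(d <= 0):
            raise ValueError("window starts must be strictly ascending")
        if np.any(np.abs(d - window_s) > 1e-6):
            raise ValueError("window starts must be contiguous")
        start_s = float(starts[0])
    change = np.flatnonzero(cats[1:] != cats[:-1]) + 1
    edges = np.concatenate([[0], change, [n]])
    return [
        Bout(
            individual_id=individual_id,
            category=str(cats[a]),
            start_s=start_s + a * window_s,
            end_s=start_s + b * window_s,
            first_index=int(a),
            n_windows=int(b - a),
        )
        for a, b in zip(edges[:-1], edges[1:])
    ]


def walk_around_windows(
    bouts: list[Bout],
    window_s: float = 2.0,
    min_bout_s: float = 5.0,
    lookback_s: float = 60.0,
    behaviours=None,
    exclude_food_carry: bool = True,
) -> list[int]:
    """Window indices belonging to walk-around movement.

    A movement bout qualifies when its duration strictly exceeds
    ``min_bout_s`` and the half-open interval ``[start - lookback_s,
    start)`` contains no excavate-category window.  With 2-s windows the
    ">5 s" rule means bouts of at least 3 windows.  When window-level
    ``behaviours`` are supplied, food-carry windows are dropped from the
    result (food transport is a different task), controlled by
    ``exclude_food_carry``.
    """
    exc_spans = [
        (b.start_s, b.end_s) for b in bouts if b.category == "excavate"
    ]
    exc_starts = np.array([s for s, _ in exc_spans])
    exc_ends = np.array([e for _, e in exc_spans])
    out: list[int] = []
    for b in bouts:
        if b.category != "move" or not b.duration_s > min_bout_s:
            continue
        lo = b.start_s - lookback_s
        # any excavate window overlapping [lo, start)?
        if len(exc_starts) and np.any(
            (exc_starts < b.start_s - 1e-9) & (exc_ends > lo + 1e-9)
        ):
            continue
        idx = range(b.first_index, b.first_index + b.n_windows)
        if behaviours is not None and exclude_food_carry:
            idx = [i for i in idx if behaviours[i] != "food-carry"]
        out.extend(idx)
    return out


def vertical_eating_proportion(
    mean_z_values,
    predicted_behaviours,
    cutoff: float = VERTICAL_CUTOFF_MS2,
) -> float | None:
    """Proportion of eating windows with an upright posture.

    Returns ``None`` (missing, not zero) when no window is predicted as
    eating.
    """
    mz = np.asarray(mean_z_values, dtype=float)
    beh = np.asarray(predicted_behaviours)
    eating = beh == "eat"
    if not eating.any():
        return None
    return float((mz[eating] < cutoff).mean())


def daily_time_budget(
    predictions: pd.DataFrame,
    window_s: float = 2.0,
    vertical_cutoff: float = VERTICAL_CUTOFF_MS2,
) -> pd.DataFrame:
    """Per individual-day category proportions, counts and mean ODBA.

    ``predictions`` needs columns ``individual_id``, ``start_s``,
    ``category`` and ``odba``; optional ``behaviour`` and ``mean_z``
    enable the vertical-eating proportion.  Days are floor(start_s /
    86400) in logger-local time.  Days with fewer than half the expected
    windows are flagged ``incomplete`` but kept.
    """
    df = predictions.copy()
    required = {"individual_id", "start_s", "category", "odba"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"predictions missing columns {sorted(missing)}")
    df["day"] = np.floor(df["start_s"] / SECONDS_PER_DAY).astype(int)
    expected = SECONDS_PER_DAY / window_s
    rows = []
    for (ind, day), g in df.groupby(["individual_id", "day"], sort=True):
        n_total = len(g)
        if n_total == 0:
            continue
        props = {
            f"prop_{c}": float((g["category"] == c).mean()) for c in CATEGORIES
        }
        row = {
            "individual_id": ind,
            "day": int(day),
            **props,
            "n_excavate": int((g["category"] == "excavate").sum()),
            "n_total": int(n_total),
            "mean_odba": float(g["odba"].mean()),
            "incomplete": bool(n_total < 0.5 * expected),
        }
        if {"behaviour", "mean_z"} <= set(g.columns):
            row["prop_vertical_eat"] = vertical_eating_proportion(
                g["mean_z"].to_numpy(), g["behaviour"].to_numpy(), vertical_cutoff
            )
        else:
            row["prop_vertical_eat"] = None
        rows.append(row)
    return pd.DataFrame(rows)
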