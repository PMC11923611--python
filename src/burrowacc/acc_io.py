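"""Reading, writing and windowing of tri-axial acceleration streams.

Collar loggers record x/y/z acceleration (ms^-2) continuously at a fixed
rate (25 Hz for the axy4 collars this package targets).  Streams are cut
into contiguous, non-overlapping fixed-length windows (2 s by default),
which are the atomic unit for feature extraction and classification.
Ground-truth behaviour labels arrive as time intervals and are attached
to a window only when a single behaviour fully covers it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AccSeries",
    "LabeledInterval",
    "Window",
    "AccFormatError",
    "AccValidationError",
    "read_acc",
    "write_acc",
    "segment_windows",
    "attach_labels",
]

#: samples may jitter by up to this many nominal intervals before the
#: stream is treated as broken and split into separate series
GAP_TOLERANCE_INTERVALS = 2.0


class AccFormatError(ValueError):
    """Input file does not conform to the expected CSV dialect."""


class AccValidationError(ValueError):
    """Input parsed but violates a content invariant (NaN, overlap...)."""


@dataclass
class AccSeries:
    """Uniformly sampled tri-axial acceleration for one deployment segment.

    Attributes
    ----------
    individual_id : str
        Animal identifier.
    start_time : float
        Offset (s) of the first sample relative to the deployment origin.
    rate_hz : float
        Sampling rate; 25 Hz for the target loggers.
    samples : ndarray of shape (n, 3)
        Acceleration in ms^-2, columns x, y, z.
    """

    individual_id: str
    start_time: float
    rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise AccValidationError("samples must have shape (n, 3)")
        if self.rate_hz <= 0:
            raise AccValidationError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            bad = np.where(~np.isfinite(self.samples).all(axis=1))[0]
            raise AccValidationError(
                f"non-finite samples at rows {bad[:10].tolist()}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass(frozen=True)
class LabeledInterval:
    """A behaviour observed from ``start_s`` to ``end_s`` (series time)."""

    start_s: float
    end_s: float
    behaviour: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise AccValidationError("interval must have end_s > start_s")


@dataclass
class Window:
    """One fixed-length segment of a stream.

    ``label`` is a ground-truth behaviour (present only when one interval
    fully covers the window), ``predicted`` a classifier output; ``odba``
    and ``features`` are filled by :mod:`burrowacc.signal_features`.
    """

    individual_id: str
    index: int
    start_s: float
    raw: np.ndarray
    label: str | None = None
    predicted: str | None = None
    odba: float | None = None
    features: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.raw.shape[0]


def _split_on_gaps(
    t: np.ndarray, xyz: np.ndarray, individual_id: str, rate_hz: float
) -> list[AccSeries]:
    dt = np.diff(t)
    nominal = 1.0 / rate_hz
    breaks = np.where(dt > GAP_TOLERANCE_INTERVALS * nominal)[0]
    out = []
    start = 0
    for b in list(breaks) + [len(t) - 1]:
        stop = b + 1
        out.append(
            AccSeries(individual_id, float(t[start]), rate_hz, xyz[start:stop])
        )
        start = stop
    return out


def read_acc(
    path: str | Path, rate_hz: float = 25.0, individual_id: str | None = None
) -> list[AccSeries]:
    """Read an acceleration CSV (``timestamp,x,y,z``).

    Timestamps may be numeric seconds or ISO-8601; they are converted to
    seconds from the first sample.  Gaps larger than two nominal sample
    intervals split the stream, so the result is a list of gap-free
    series (usually of length one).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = ["timestamp", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AccFormatError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise AccFormatError(f"{path}: empty file")
    try:
        t = df["timestamp"].astype(float).to_numpy()
    except (ValueError, TypeError):
        ts = pd.to_datetime(df["timestamp"], utc=True)
        t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    if np.any(np.diff(t) < 0):
        raise AccValidationError(f"{path}: timestamps not monotone")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        rows = np.where(~np.isfinite(xyz).all(axis=1))[0]
        raise AccValidationError(
            f"{path}: non-finite values at rows {rows[:10].tolist()}"
        )
    ind = individual_id if individual_id is not None else path.stem
    return _split_on_gaps(t - t[0], xyz, ind, rate_hz)


def write_acc(series: AccSeries, path: str | Path) -> None:
    """Write a series in the CSV dialect `read_acc` expects."""
    t = series.start_time + np.arange(series.n_samples) / series.rate_hz
    df = pd.DataFrame(
        {
            "timestamp": t,
            "x": series.samples[:, 0],
            "y": series.samples[:, 1],
            "z": series.samples[:, 2],
        }
    )
    df.to_csv(path, index=False)


def segment_windows(series: AccSeries, window_s: float = 2.0) -> list[Window]:
    """Cut a series into contiguous non-overlapping windows.

    Windows are aligned to the series start; the trailing partial window
    is discarded.  A series shorter than one window yields an empty list.
    """
    n_per = int(round(series.rate_hz * window_s))
    if n_per <= 0:
        raise ValueError("window_s too small for the sampling rate")
    n_win = series.n_samples // n_per
    return [
        Window(
            individual_id=series.individual_id,
            index=i,
            start_s=series.start_time + i * window_s,
            raw=series.samples[i * n_per : (i + 1) * n_per],
        )
        for i in range(n_win)
    ]


def attach_labels(
    windows: Sequence[Window],
    intervals: Iterable[LabeledInterval],
    window_s: float = 2.0,
) -> tuple[list[Window], int]:
    """Attach ground-truth labels to fully covered windows.

    A window [a, a + window_s) is labelled iff one interval contains it
    entirely — the training convention of single-behaviour segments.
    Intervals shorter than the window can never label anything; they are
    counted and reported so the share of omitted short behaviours can be
    tracked.  Returns ``(windows, n_omitted_short_intervals)``.
    """
    ivs = sorted(intervals, key=lambda iv: iv.start_s)
    for a, b in zip(ivs, ivs[1:]):
        if b.start_s < a.end_s - 1e-9:
            raise AccValidationError(
                f"overlapping intervals at {b.start_s:.3f}s"
            )
    omitted = sum(1 for iv in ivs if iv.end_s - iv.start_s < window_s)
    starts = np.array([iv.start_s for iv in ivs])
    ends = np.array([iv.end_s for iv in ivs])
    eps = 1e-9
    for w in windows:
        a, b = w.start_s, w.start_s + window_s
        j = np.searchsorted(starts, a + eps) - 1
        if j >= 0 and starts[j] <= a + eps and ends[j] >= b - eps:
            w.label = ivs[j].behaviour
    return list(windows), omitted
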