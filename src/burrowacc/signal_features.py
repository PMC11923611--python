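"""ODBA, posture statistics and the per-window feature vector.

Overall dynamic body acceleration (ODBA) is the activity proxy used
throughout: each axis is smoothed with a 10-point running mean, the
absolute deviations from that running mean are summed over samples and
across the three axes.  It is zero for any static posture and invariant
to constant offsets (e.g. gravity re-orientation between deployments).

Every window is also summarised by a fixed vector of 50 features (per
axis distribution/dynamics statistics, cross-axis correlations and
whole-window magnitude/posture summaries), the input to the behaviour
classifier.  The feature list is frozen: names and order are in
``FEATURE_NAMES`` and documented in docs/methods.md.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from .acc_io import Window

__all__ = [
    "FEATURE_NAMES",
    "running_mean",
    "odba",
    "odba_stack",
    "mean_z",
    "is_vertical",
    "extract_features",
    "extract_features_stack",
]

#: default vertical-eating posture cutoff: half standard gravity, ms^-2
VERTICAL_CUTOFF_MS2 = 4.9

_PER_AXIS = [
    "mean", "sd", "min", "max", "range", "skew", "kurt",
    "q25", "q50", "q75", "mad1", "zerocross", "domfreq_frac",
]
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{ax}_{f}" for ax in "xyz" for f in _PER_AXIS]
    + ["corr_xy", "corr_xz", "corr_yz"]
    + ["odba", "odba_x", "odba_y", "odba_z",
       "vm_mean", "vm_sd", "tilt", "vm_iqr"]
)
assert len(FEATURE_NAMES) == 50


def running_mean(signal: Sequence[float] | np.ndarray, k: int = 10) -> np.ndarray:
    """Centred running mean of up to ``k`` points, truncated at edges.

    For even ``k`` the window around element ``i`` spans offsets
    ``[-k//2, k//2 - 1]``; edges use whatever part of the window exists.
    Output has the same length as the input.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D sequence")
    n = x.size
    lo_off, hi_off = -(k // 2), (k - 1) // 2 + 1  # half-open [i+lo, i+hi)
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(n)
    lo = np.clip(i + lo_off, 0, n)
    hi = np.clip(i + hi_off, 0, n)
    return (c[hi] - c[lo]) / (hi - lo)


def _running_mean_axis0(a: np.ndarray, k: int) -> np.ndarray:
    """Running mean along axis 0 of a (n, ...) array, same convention."""
    n = a.shape[0]
    lo_off, hi_off = -(k // 2), (k - 1) // 2 + 1
    c = np.concatenate([np.zeros((1,) + a.shape[1:]), np.cumsum(a, axis=0)])
    i = np.arange(n)
    lo = np.clip(i + lo_off, 0, n)
    hi = np.clip(i + hi_off, 0, n)
    shape = (n,) + (1,) * (a.ndim - 1)
    return (c[hi] - c[lo]) / (hi - lo).reshape(shape)


def _dynamic(raw: np.ndarray, k: int) -> np.ndarray:
    """Deviation of each axis from its running mean; raw is (..., n, 3).

    Axes are centred by their window mean first (a no-op analytically,
    since the running mean is linear), so constant signals give exactly
    zero and large static offsets cost no precision.
    """
    ax = raw.ndim - 2
    c = raw - raw.mean(axis=ax, keepdims=True)
    if raw.ndim == 2:
        return c - _running_mean_axis0(c, k)
    sm = np.stack([_running_mean_axis0(c[j], k) for j in range(c.shape[0])])
    return c - sm


def odba(window: Window | np.ndarray, k: int = 10, scale: str = "sum") -> float:
    """ODBA of one window: sum over samples and axes of |a - runmean(a)|.

    ``scale='per_sample_mean'`` divides by the sample count, giving a
    rate-independent value; only relative comparisons are used
    downstream so either convention is self-consistent.
    """
    raw = window.raw if isinstance(window, Window) else np.asarray(window, float)
    if raw.ndim != 2 or raw.shape[1] != 3:
        raise ValueError("window must contain (n, 3) samples")
    if raw.shape[0] < 2:
        raise ValueError("ODBA needs at least 2 samples")
    total = float(np.abs(_dynamic(raw, k)).sum())
    if scale == "per_sample_mean":
        return total / raw.shape[0]
    if scale != "sum":
        raise ValueError("scale must be 'sum' or 'per_sample_mean'")
    return total


def odba_stack(raw: np.ndarray, k: int = 10, scale: str = "sum") -> np.ndarray:
    """ODBA for a stack of windows, shape (m, n, 3) -> (m,)."""
    dev = np.abs(_dynamic(np.asarray(raw, float), k))
    out = dev.sum(axis=(1, 2))
    if scale == "per_sample_mean":
        out = out / raw.shape[1]
    return out


def mean_z(window: Window | np.ndarray) -> float:
    raw = window.raw if isinstance(window, Window) else np.asarray(window, float)
    if raw.size == 0:
        raise ValueError("empty window")
    return float(raw[:, 2].mean())


def is_vertical(window: Window | np.ndarray, cutoff: float = VERTICAL_CUTOFF_MS2) -> bool:
    """True iff the window's mean z is strictly below the posture cutoff.

    Mean z reflects how much of gravity loads the dorso-ventral axis: an
    upright animal (pitched > 60 deg) takes mean z below half gravity.
    """
    return mean_z(window) < cutoff


def extract_features(window: Window, k: int = 10) -> np.ndarray:
    """The 50-feature vector for one window (order = ``FEATURE_NAMES``)."""
    out = extract_features_stack(window.raw[None, :, :], k=k)[0]
    window.features = out
    return out


def extract_features_stack(raw: np.ndarray, k: int = 10) -> np.ndarray:
    """Feature matrix for a stack of windows: (m, n, 3) -> (m, 50).

    Degenerate (constant) signals get zeros for the dispersion, shape,
    spectral and correlation features so the vector is always finite.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError("expected stack of shape (m, n_samples, 3)")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite values in window samples")
    m, n, _ = raw.shape
    cols: list[np.ndarray] = []

    mean = raw.mean(axis=1)                      # (m, 3)
    centred = raw - mean[:, None, :]
    # effectively-constant axes get 0 for shape/dynamic features; the
    # relative tolerance absorbs cancellation noise around large offsets
    m2 = (centred**2).mean(axis=1)
    live = np.sqrt(m2) > 1e-9 * (1.0 + np.abs(mean))
    sd = np.where(live, np.sqrt(m2), 0.0)
    q25, q50, q75 = np.percentile(raw, [25, 50, 75], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m3 = (centred**3).mean(axis=1)
        m4 = (centred**4).mean(axis=1)
        skew = np.where(live, m3 / np.where(live, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(live, m4 / np.where(live, m2, 1.0) ** 2 - 3.0, 0.0)
    mad1 = np.abs(np.diff(raw, axis=1)).mean(axis=1)
    zc = np.where(
        live,
        (centred[:, :-1, :] * centred[:, 1:, :] < 0).sum(axis=1),
        0,
    ).astype(float)
    # dominant-frequency power fraction of the mean-subtracted signal
    spec = np.abs(np.fft.rfft(centred, axis=1)) ** 2
    power = spec[:, 1:, :]
    tot = power.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        domfrac = np.where(
            live, power.max(axis=1) / np.where(tot > 0, tot, 1.0), 0.0
        )

    for ax in range(3):
        cols += [
            mean[:, ax], sd[:, ax], raw[:, :, ax].min(axis=1),
            raw[:, :, ax].max(axis=1),
            raw[:, :, ax].max(axis=1) - raw[:, :, ax].min(axis=1),
            skew[:, ax], kurt[:, ax],
            q25[:, ax], q50[:, ax], q75[:, ax],
            mad1[:, ax], zc[:, ax], domfrac[:, ax],
        ]

    # pairwise correlations, 0 when either axis is constant
    for a, b in [(0, 1), (0, 2), (1, 2)]:
        cov = (centred[:, :, a] * centred[:, :, b]).mean(axis=1)
        denom = sd[:, a] * sd[:, b]
        cols.append(np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0))

    dev = np.abs(_dynamic(raw, k))
    odba_axes = dev.sum(axis=1)                  # (m, 3)
    cols.append(odba_axes.sum(axis=1))
    cols += [odba_axes[:, ax] for ax in range(3)]

    vm = np.linalg.norm(raw, axis=2)             # (m, n)
    cols += [vm.mean(axis=1), vm.std(axis=1, ddof=0)]
    norm = np.linalg.norm(mean, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tilt = np.where(
            norm > 0, np.arccos(np.clip(mean[:, 2] / np.where(norm > 0, norm, 1.0), -1, 1)), 0.0
        )
    cols.append(tilt)
    vq25, vq75 = np.percentile(vm, [25, 75], axis=1)
    cols.append(vq75 - vq25)

    out = np.column_stack(cols)
    assert out.shape == (m, 50)
    return out
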