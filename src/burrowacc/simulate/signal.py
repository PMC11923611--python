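"""Raw tri-axial signal synthesis with behaviour-dependent structure.

Each behaviour has a characteristic static posture (a pitch angle that
distributes gravity between the surge (x) and dorso-ventral (z) axes),
a band-limited oscillatory dynamic component (amplitude, dominant
frequency, axis mix) and Gaussian sensor noise.  Digging-type
behaviours are high-amplitude and mid-frequency, running is fast and
surge-dominated, resting is nearly static.  Eating bouts adopt an
upright posture (pitch 70 deg, mean z < 4.9 ms^-2) with a per-
individual probability, emulating eating directly from an in-ground
tuber versus from detached pieces.

Individuals get small random offsets in posture, amplitude and
frequency so that leave-individuals-out evaluation is meaningful.  A
``separability`` dial interpolates all behaviour parameter sets toward
their common mean: at 0 every behaviour shares one signal model and a
classifier can only reach chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..acc_io import AccSeries, LabeledInterval
from ..behavior_model import BEHAVIOURS

__all__ = ["SignalModel", "IndividualSignalOffsets", "synthesize_acc",
           "make_training_set"]

G = 9.8  # standard gravity, ms^-2

# behaviour -> (pitch_deg, amplitude ms^-2, dominant freq Hz, noise sd, axis mix)
_BEHAVIOUR_SIGNALS: dict[str, tuple] = {
    "rest":       (5.0, 0.06, 0.8, 0.06, (0.3, 0.3, 0.4)),
    "dig":        (25.0, 3.2, 3.6, 0.35, (0.5, 0.2, 0.3)),
    "sweep":      (10.0, 2.4, 2.8, 0.30, (0.2, 0.55, 0.25)),
    "back-kick":  (5.0, 2.9, 1.8, 0.30, (0.25, 0.2, 0.55)),
    "run":        (8.0, 2.0, 5.0, 0.25, (0.6, 0.2, 0.2)),
    "walk":       (8.0, 0.9, 2.0, 0.15, (0.5, 0.25, 0.25)),
    "food-carry": (14.0, 1.1, 2.3, 0.20, (0.35, 0.45, 0.2)),
    "eat":        (15.0, 0.45, 1.2, 0.12, (0.4, 0.3, 0.3)),
    "groom":      (20.0, 0.7, 3.0, 0.15, (0.3, 0.5, 0.2)),
    "scratch":    (12.0, 1.6, 4.5, 0.20, (0.25, 0.3, 0.45)),
    "sniff":      (35.0, 0.3, 1.5, 0.10, (0.4, 0.3, 0.3)),
    "gnaw":       (22.0, 0.8, 3.8, 0.15, (0.45, 0.35, 0.2)),
    "rear":       (55.0, 0.35, 0.9, 0.12, (0.3, 0.3, 0.4)),
    "shuffle":    (6.0, 0.7, 1.1, 0.20, (0.4, 0.4, 0.2)),
}

VERTICAL_EAT_PITCH_DEG = 70.0  # 9.8*cos(70deg) ~ 3.35 < 4.9


@dataclass
class SignalModel:
    """Per-behaviour signal parameters with a separability dial."""

    params: dict = field(default_factory=lambda: dict(_BEHAVIOUR_SIGNALS))
    separability: float = 1.0
    vertical_eat_pitch_deg: float = VERTICAL_EAT_PITCH_DEG

    def behaviour_params(self, behaviour: str) -> tuple:
        pitch, amp, freq, noise, mix = self.params[behaviour]
        if self.separability >= 1.0:
            return pitch, amp, freq, noise, np.asarray(mix)
        allp = np.array([p[:4] for p in self.params.values()])
        allmix = np.array([p[4] for p in self.params.values()])
        mp, mmix = allp.mean(axis=0), allmix.mean(axis=0)
        s = self.separability
        pitch, amp, freq, noise = mp + s * (np.array([pitch, amp, freq, noise]) - mp)
        return pitch, amp, freq, noise, mmix + s * (np.asarray(mix) - mmix)


@dataclass(frozen=True)
class IndividualSignalOffsets:
    """Collar fit and gait idiosyncrasies of one animal."""

    pitch_offset_deg: float = 0.0
    amp_mult: float = 1.0
    freq_mult: float = 1.0

    @staticmethod
    def draw(rng) -> "IndividualSignalOffsets":
        return IndividualSignalOffsets(
            pitch_offset_deg=float(rng.normal(0.0, 4.0)),
            amp_mult=float(np.exp(rng.normal(0.0, 0.12))),
            freq_mult=float(np.exp(rng.normal(0.0, 0.06))),
        )


def _bout_signal(n, t0, pitch_deg, amp, freq, noise, mix, rng, rate_hz):
    t = t0 + np.arange(n) / rate_hz
    pitch = np.deg2rad(pitch_deg + rng.normal(0.0, 2.0))
    gravity = np.array([G * np.sin(pitch), 0.0, G * np.cos(pitch)])
    f = freq * np.exp(rng.normal(0.0, 0.05))
    out = np.empty((n, 3))
    root = np.sqrt(np.asarray(mix) / np.sum(mix))
    for ax in range(3):
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        dyn = amp * root[ax] * (
            np.sin(2 * np.pi * f * t + ph1)
            + 0.35 * np.sin(4 * np.pi * f * t + ph2)
        )
        out[:, ax] = gravity[ax] + dyn + rng.normal(0.0, noise, n)
    return out


def synthesize_acc(
    intervals: list[LabeledInterval],
    model: SignalModel | None = None,
    rate_hz: float = 25.0,
    seed=0,
    individual_id: str = "sim",
    offsets: IndividualSignalOffsets | None = None,
    p_vertical_eat: float = 0.6,
) -> AccSeries:
    """Synthesize a continuous tri-axial stream from behaviour intervals.

    Behaviour boundaries are aligned to whole samples; each eat bout is
    upright with probability ``p_vertical_eat``.
    """
    model = model or SignalModel()
    offsets = offsets or IndividualSignalOffsets()
    rng = np.random.default_rng(seed)
    total_s = intervals[-1].end_s
    n_total = int(round(total_s * rate_hz))
    out = np.empty((n_total, 3))
    pos = 0
    for iv in intervals:
        n = int(round(iv.end_s * rate_hz)) - pos
        if n <= 0:
            continue
        pitch, amp, freq, noise, mix = model.behaviour_params(iv.behaviour)
        if iv.behaviour == "eat" and rng.uniform() < p_vertical_eat:
            pitch = model.vertical_eat_pitch_deg
        out[pos : pos + n] = _bout_signal(
            n, pos / rate_hz,
            pitch + offsets.pitch_offset_deg,
            amp * offsets.amp_mult,
            freq * offsets.freq_mult,
            noise, mix, rng, rate_hz,
        )
        pos += n
    return AccSeries(individual_id, 0.0, rate_hz, out[:pos])


def make_training_set(
    n_individuals: int = 16,
    windows_per_class: int = 300,
    window_s: float = 2.0,
    rate_hz: float = 25.0,
    seed: int = 0,
    separability: float = 1.0,
):
    """Ground-truth labelled windows emulating videotaped lab sessions.

    For each animal and behaviour one long single-behaviour bout is
    synthesized and windowed, giving ``windows_per_class`` labelled
    windows per behaviour spread over ``n_individuals`` individuals.
    Returns ``(raw_stack, labels, individual_ids)``; features are left
    to the caller so tests can exercise the real extraction path.
    """
    model = SignalModel(separability=separability)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(n_individuals)]
    per_ind = int(np.ceil(windows_per_class / n_individuals))
    n_per = int(round(rate_hz * window_s))
    stacks, labels, owners = [], [], []
    for i, rng in enumerate(rngs):
        off = IndividualSignalOffsets.draw(rng)
        for b in BEHAVIOURS:
            iv = [LabeledInterval(0.0, (per_ind + 1) * window_s, b)]
            series = synthesize_acc(
                iv, model, rate_hz, seed=rng.integers(2**31),
                offsets=off, p_vertical_eat=0.5,
            )
            n_win = per_ind
            raw = series.samples[: n_win * n_per].reshape(n_win, n_per, 3)
            stacks.append(raw)
            labels += [b] * n_win
            owners += [f"I{i:02d}"] * n_win
    return np.concatenate(stacks), np.array(labels), np.array(owners)
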