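"""ODBA, running mean, posture statistics and the 50-feature vector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burrowacc.acc_io import Window
from burrowacc.signal_features import (
    FEATURE_NAMES,
    extract_features,
    extract_features_stack,
    is_vertical,
    mean_z,
    odba,
    odba_stack,
    running_mean,
)
from oracles import odba_brute, running_mean_brute


def _window(raw):
    return Window("w", 0, 0.0, np.asarray(raw, float))


def _random_window(seed, n=50):
    rng = np.random.default_rng(seed)
    return rng.normal(0, 1, (n, 3)) + [0.5, -0.3, 9.8]


class TestRunningMean:
    def test_constant_unchanged(self):
        assert np.allclose(running_mean(np.full(30, 3.3), 10), 3.3)

    def test_full_truncation_two_points(self):
        assert np.allclose(running_mean([0.0, 10.0], 10), [5.0, 5.0])

    @given(st.integers(1, 12), st.integers(1, 60))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, k, n):
        rng = np.random.default_rng(k * 100 + n)
        x = rng.normal(size=n)
        assert np.allclose(running_mean(x, k), running_mean_brute(x, k))

    def test_rejects_bad_k(self):
        with pytest.raises(ValueError):
            running_mean([1.0, 2.0], 0)


class TestOdba:
    def test_zero_for_constant_window(self):
        assert odba(_window(np.tile([0, 0, 9.8], (50, 1)))) == 0.0

    def test_offset_invariance(self):
        raw = _random_window(1)
        shifted = raw + [2.5, -7.0, 123.0]
        assert abs(odba(_window(raw)) - odba(_window(shifted))) < 1e-9

    def test_homogeneous_in_dynamic_component(self):
        rng = np.random.default_rng(5)
        dyn = rng.normal(0, 1, (50, 3))
        base = np.tile([0, 0, 9.8], (50, 1))
        assert odba(_window(base + 2 * dyn)) == pytest.approx(
            2 * odba(_window(base + dyn)), rel=1e-12
        )

    def test_sine_matches_brute_force(self):
        t = np.arange(50) / 25
        raw = np.zeros((50, 3))
        raw[:, 0] = 3.0 * np.sin(2 * np.pi * 2.0 * t)
        assert odba(_window(raw)) == pytest.approx(odba_brute(raw), abs=1e-10)

    def test_stack_agrees_with_scalar_path(self):
        stack = np.stack([_random_window(s) for s in range(8)])
        vals = odba_stack(stack)
        assert np.allclose(vals, [odba(_window(w)) for w in stack])

    def test_per_sample_mean_scale(self):
        raw = _random_window(2)
        assert odba(_window(raw), scale="per_sample_mean") == pytest.approx(
            odba(_window(raw)) / 50
        )

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            odba(_window(np.zeros((1, 3))))


class TestPosture:
    def test_mean_z_constant(self):
        assert mean_z(_window(np.tile([0, 0, 9.8], (50, 1)))) == pytest.approx(9.8)

    def test_pitch_sixty_degrees_gives_half_gravity(self):
        z = 9.8 * np.cos(np.deg2rad(60))
        raw = np.tile([9.8 * np.sin(np.deg2rad(60)), 0, z], (50, 1))
        assert mean_z(_window(raw)) == pytest.approx(4.9)

    @pytest.mark.parametrize(
        "mz,expected", [(2.0, True), (4.9, False), (9.8, False)]
    )
    def test_vertical_cutoff_is_strict(self, mz, expected):
        raw = np.tile([0.0, 0.0, mz], (50, 1))
        assert is_vertical(_window(raw)) is expected


class TestFeatures:
    def test_fifty_named_features(self):
        assert len(FEATURE_NAMES) == 50
        assert len(set(FEATURE_NAMES)) == 50

    def test_constant_window_degenerate_values(self):
        f = dict(zip(FEATURE_NAMES, extract_features(_window(np.tile([1.0, -2.0, 9.8], (50, 1))))))
        assert f["x_mean"] == pytest.approx(1.0)
        assert f["z_mean"] == pytest.approx(9.8)
        for name in ["x_sd", "y_range", "z_skew", "x_kurt", "y_mad1",
                     "z_zerocross", "x_domfreq_frac", "corr_xy", "odba",
                     "vm_sd", "vm_iqr"]:
            assert f[name] == pytest.approx(0.0, abs=1e-12), name
        assert np.all(np.isfinite(list(f.values())))

    def test_deterministic(self):
        raw = _random_window(9)
        assert np.array_equal(
            extract_features(_window(raw)), extract_features(_window(raw))
        )

    def test_offset_only_change_keeps_dynamic_features(self):
        raw = _random_window(11)
        shifted = raw + [3.0, -1.0, 0.5]
        a = dict(zip(FEATURE_NAMES, extract_features(_window(raw))))
        b = dict(zip(FEATURE_NAMES, extract_features(_window(shifted))))
        dynamic = [
            n for n in FEATURE_NAMES
            if (n.startswith(("x_", "y_", "z_"))
                and any(n.endswith(s) for s in
                        ("_sd", "_skew", "_kurt", "_mad1", "_domfreq_frac")))
            or n.startswith(("corr_", "odba"))
        ]
        for name in dynamic:
            assert a[name] == pytest.approx(b[name], abs=1e-9), name

    def test_nan_input_rejected(self):
        raw = _random_window(3)
        raw[10, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            extract_features_stack(raw[None])

    def test_rest_odba_stochastically_below_dig(self):
        from scipy.stats import mannwhitneyu

        from burrowacc.acc_io import LabeledInterval
        from burrowacc.simulate import SignalModel, synthesize_acc

        model = SignalModel()
        vals = {}
        for beh in ("rest", "dig"):
            iv = [LabeledInterval(0.0, 2 * 1001.0, beh)]
            s = synthesize_acc(iv, model, 25.0, seed=17)
            raw = s.samples[: 1000 * 50].reshape(1000, 50, 3)
            vals[beh] = odba_stack(raw)
        stat = mannwhitneyu(vals["rest"], vals["dig"], alternative="less")
        assert stat.pvalue < 0.01
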