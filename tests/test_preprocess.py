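import numpy as np
import pytest
from scipy.special import erfc

from infantdot.datagen import ActivationSpec, ChannelRecording, generate_recording
from infantdot.errors import ConfigError
from infantdot.hemodynamics import make_schedule
from infantdot.preprocess import (
    PreprocessConfig,
    bandpass,
    detect_artifacts,
    exclude_triggers,
    preprocess_recording,
    resample_to_common_base,
    superficial_signal_regression,
)


def _rec(values, times=None, sds=None, triggers=(), annotations=()):
    """Recording from log-amplitude values (channels x times)."""
    values = np.atleast_2d(np.asarray(values, float))
    n_ch, n_t = values.shape
    times = np.arange(n_t, dtype=float) if times is None else np.asarray(times, float)
    sds = [30.0] * n_ch if sds is None else sds
    channels = [(i, i, float(s)) for i, s in enumerate(sds)]
    return ChannelRecording(
        amplitudes=np.exp(values),
        times_s=times,
        triggers=list(triggers),
        channels=channels,
        annotations=list(annotations),
    )


class TestResample:
    def test_uniform_input_identity(self):
        rec = _rec(np.random.default_rng(0).normal(size=(3, 50)))
        out = resample_to_common_base(rec, 1.0)
        assert np.allclose(out.amplitudes, rec.amplitudes)
        assert np.allclose(out.times_s, rec.times_s)

    def test_linear_ramp_exact(self):
        # linear interpolation is exact on affine amplitude signals
        t = np.arange(0, 120, 1.2)
        ramp = 0.01 * t + 0.5
        rec = ChannelRecording(ramp[None, :], t, [], [(0, 0, 30.0)])
        out = resample_to_common_base(rec, 1.0)
        expected = 0.01 * out.times_s + 0.5
        assert np.allclose(out.amplitudes[0], expected, atol=1e-12)

    def test_sinusoid_error_bound(self):
        # linear interpolation error <= h^2 max|f''| / 8
        f = 0.05
        t = np.arange(0, 400, 1.2)
        x = 2.0 + np.sin(2 * np.pi * f * t)
        rec = ChannelRecording(x[None, :], t, [], [(0, 0, 30.0)])
        out = resample_to_common_base(rec, 1.0)
        truth = 2.0 + np.sin(2 * np.pi * f * out.times_s)
        bound = 1.2**2 * (2 * np.pi * f) ** 2 / 8
        assert np.abs(out.amplitudes[0] - truth).max() <= bound

    def test_upsampling_guard(self):
        rec = _rec(np.zeros((1, 30)), times=np.arange(30) * 1.2)
        with pytest.raises(ConfigError):
            resample_to_common_base(rec, 20.0)

    def test_triggers_preserved(self):
        rec = _rec(np.zeros((1, 100)), times=np.arange(100) * 1.2, triggers=[(30.0, "happy")])
        out = resample_to_common_base(rec, 1.0)
        assert out.triggers == [(30.0, "happy")]


class TestBandpass:
    def _gain(self, freq, n=6000, fs=1.0):
        t = np.arange(n) / fs
        x = 0.01 * np.sin(2 * np.pi * freq * t)
        rec = _rec(x[None, :], times=t)
        out = bandpass(rec, 0.007, 0.2)
        y = np.log(out.amplitudes[0])
        # amplitude by quadrature fit on the central section
        mid = slice(n // 4, 3 * n // 4)
        c = np.cos(2 * np.pi * freq * t[mid])
        s = np.sin(2 * np.pi * freq * t[mid])
        a = 2 * np.mean(y[mid] * s)
        b = 2 * np.mean(y[mid] * c)
        return np.hypot(a, b) / 0.01

    def test_dc_removed(self):
        rec = _rec(np.full((2, 400), 0.3))
        out = bandpass(rec, 0.007, 0.2)
        assert np.abs(np.log(out.amplitudes)).max() < 1e-8

    def test_passband_gain(self):
        assert self._gain(0.05) == pytest.approx(1.0, abs=0.05)

    def test_low_edge_minus_3db(self):
        g = 20 * np.log10(self._gain(0.007, n=20000))
        assert g == pytest.approx(-3.0, abs=0.5)

    def test_high_edge_minus_3db(self):
        g = 20 * np.log10(self._gain(0.2))
        assert g == pytest.approx(-3.0, abs=0.5)

    def test_short_recording_warns(self):
        rec = _rec(np.random.default_rng(1).normal(size=(1, 100)))
        with pytest.warns(UserWarning):
            bandpass(rec, 0.007, 0.2)

    def test_channel_permutation_commutes(self, rng):
        x = rng.normal(size=(5, 300)) * 0.01
        rec = _rec(x)
        perm = rng.permutation(5)
        out1 = bandpass(rec, 0.007, 0.2).amplitudes[perm]
        out2 = bandpass(_rec(x[perm], sds=[30.0] * 5), 0.007, 0.2).amplitudes
        assert np.allclose(out1, out2)


class TestSSR:
    def test_identical_channels_zero_residual(self, rng):
        g = rng.normal(size=400) * 0.01
        x = np.tile(g, (6, 1))
        rec = _rec(x, sds=[8, 8, 30, 30, 40, 40])
        out = superficial_signal_regression(rec, 12.0)
        assert np.abs(np.log(out.amplitudes)).max() < 1e-12

    def test_brain_signal_recovery(self, rng):
        n = 2000
        g = rng.normal(size=n)
        brain = rng.normal(size=n)
        brain -= brain @ g / (g @ g) * g  # orthogonal by construction
        long = 0.01 * (brain + 0.8 * g)
        x = np.vstack([0.01 * g, 0.01 * g, long])
        rec = _rec(x, sds=[8, 9, 30])
        out = superficial_signal_regression(rec, 12.0)
        resid = np.log(out.amplitudes[2])
        r_reg = np.corrcoef(resid, g)[0, 1]
        r_brain = np.corrcoef(resid, brain)[0, 1]
        assert abs(r_reg) < 1e-10
        assert r_brain > 0.99

    def test_zero_regressor_mean_centers(self, rng):
        x = rng.normal(size=(3, 200)) * 0.01
        x[0] = 0.0
        rec = _rec(x, sds=[8, 30, 40])
        out = superficial_signal_regression(rec, 12.0)
        expected = x - x.mean(axis=1, keepdims=True)
        assert np.allclose(np.log(out.amplitudes), expected, atol=1e-12)

    def test_no_short_channels(self, rng):
        rec = _rec(rng.normal(size=(2, 100)) * 0.01, sds=[20, 30])
        with pytest.raises(ConfigError):
            superficial_signal_regression(rec, 12.0)
        with pytest.warns(UserWarning):
            superficial_signal_regression(rec, 12.0, on_missing="warn")

    def test_idempotent(self, rng):
        x = rng.normal(size=(5, 500)) * 0.01
        rec = _rec(x, sds=[8, 8, 25, 30, 40])
        once = superficial_signal_regression(rec, 12.0)
        twice = superficial_signal_regression(once, 12.0)
        assert np.allclose(once.amplitudes, twice.amplitudes, atol=1e-12)


class TestArtifactDetection:
    def test_clean_noise_rarely_flagged_at_k7(self, rng):
        x = rng.normal(size=(10, 2000)) * 0.01
        rec = _rec(x)
        mask, k = detect_artifacts(rec, k=7.0)
        n_ch, n_t = x.shape
        bound = n_ch * n_t * erfc(7 / np.sqrt(2)) + 3
        assert mask.sum() <= bound

    @pytest.mark.parametrize("k", [3.5, 7.0])
    def test_large_transient_flagged(self, rng, k):
        x = rng.normal(size=(4, 1000)) * 0.01
        x[:, 500:503] += 10 * x.std()
        rec = _rec(x)
        mask, _ = detect_artifacts(rec, k=k)
        assert mask[500:503].all()

    def test_annotation_only_mask(self):
        x = np.zeros((2, 200))
        rec = _rec(x, annotations=[(50.0, 5.0, "crying")])
        mask, _ = detect_artifacts(rec, k=7.0)
        t = rec.times_s
        assert np.array_equal(mask, (t >= 50.0) & (t <= 55.0))

    def test_k_outside_range_rejected(self, rng):
        rec = _rec(rng.normal(size=(2, 100)) * 0.01)
        with pytest.raises(ConfigError):
            detect_artifacts(rec, k=10.0)

    def test_auto_k_sensitivity_on_synthetic_truth(self, ctx):
        """Auto-threshold recovers >= 90% of generator-planted artifacts of
        >= 5x SD amplitude."""
        schedule = make_schedule(3, seed=2)
        spec = ActivationSpec(
            shot_noise_sd=0.003, global_amp=0.01, drift_sd=0.005,
            artifact_rate_per_min=1.5, artifact_amp_k=5.0, seed=21,
        )
        rec = generate_recording(ctx.head, ctx.S, schedule, spec)
        assert rec.annotations, "generator must plant artifacts"
        truth = np.zeros(rec.times_s.size, bool)
        for o, d, _ in rec.annotations:
            truth |= (rec.times_s >= o) & (rec.times_s <= o + d)
        stripped = rec.copy_with(annotations=[])  # detection must not peek
        mask, chosen = detect_artifacts(stripped, k="auto")
        sensitivity = (mask & truth).sum() / truth.sum()
        assert 3.5 <= chosen <= 7.0
        assert sensitivity >= 0.9


class TestTriggerExclusion:
    times = np.arange(0.0, 200.0)

    def test_empty_mask_retains_all(self):
        triggers = [(20.0, "happy"), (60.0, "sad")]
        mask = np.zeros(self.times.size, bool)
        kept, verdict = exclude_triggers(
            triggers, mask, self.times, min_reps=1, conditions=("happy", "sad")
        )
        assert kept == triggers
        assert verdict.passed

    def test_min_reps_rule(self):
        triggers = [(float(20 + 40 * i), "happy") for i in range(4)]
        mask = np.zeros(self.times.size, bool)
        _, verdict = exclude_triggers(
            triggers, mask, self.times, min_reps=5, conditions=("happy",)
        )
        assert not verdict.passed
        assert verdict.reps_per_condition["happy"] == 4

    def test_boundary_overlap_excluded(self):
        triggers = [(50.0, "happy")]
        mask = np.zeros(self.times.size, bool)
        mask[68] = True  # epoch [-1, 18] around 50 touches t=68
        kept, _ = exclude_triggers(triggers, mask, self.times, epoch_span_s=(-1, 18))
        assert kept == []
        mask2 = np.zeros(self.times.size, bool)
        mask2[69] = True  # just outside
        kept2, _ = exclude_triggers(triggers, mask2, self.times, epoch_span_s=(-1, 18))
        assert kept2 == triggers


class TestFullChain:
    def test_ssr_rerun_is_noop(self, ctx):
        schedule = make_schedule(3, seed=5)
        spec = ActivationSpec(shot_noise_sd=0.003, global_amp=0.01, seed=6)
        rec = generate_recording(ctx.head, ctx.S, schedule, spec)
        out, mask, log = preprocess_recording(rec, PreprocessConfig())
        again = superficial_signal_regression(out, 12.0)
        assert np.allclose(np.log(again.amplitudes), np.log(out.amplitudes), atol=1e-10)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            PreprocessConfig(band_lo_hz=0.3, band_hi_hz=0.2)
        with pytest.raises(ConfigError):
            PreprocessConfig(artifact_k=10.0)
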