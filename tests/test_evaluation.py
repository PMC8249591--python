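import numpy as np
import pytest

from periphnn.containers import MetricCurve, ResponseField
from periphnn.datasets import greenwood_cf_axis
from periphnn.evaluation import (ac_dc_ratio, evaluate_surrogate, excitation_pattern,
                                 firing_rate_response, half_wave_rectified_rms,
                                 metric4_stimuli, potential_level_growth,
                                 rate_level_curve, rmse, synchrony_level_curve,
                                 vector_strength)
from periphnn.reference import ANFTeacher, IHCTeacher
from periphnn.stimuli import Stimulus, pure_tone


class _DummyModel:
    """Deterministic waveform generator standing in for a periphery model."""

    def __init__(self, make_channel, kind="potential", cf_axis=(1e3,)):
        self.make_channel = make_channel
        self.output_kind = kind
        self.cf_axis = np.asarray(cf_axis, dtype=float)

    def respond(self, stim: Stimulus) -> ResponseField:
        n = len(stim.samples)
        t = np.arange(n) / stim.fs
        on = stim.onset_s
        v = self.make_channel(t, on)
        values = np.tile(v[:, None], (1, len(self.cf_axis)))
        units = "V" if self.output_kind == "potential" else "spikes_per_s"
        return ResponseField(values, stim.fs, self.cf_axis, units)


class TestVectorStrength:
    def test_raised_cosine_rate_gives_half(self):
        fs, fm = 20e3, 100.0
        t = np.arange(int(0.4 * fs)) / fs  # integer number of periods
        r = 80.0 * (1 + np.cos(2 * np.pi * fm * t))
        assert vector_strength(r, fs, fm) == pytest.approx(0.5, abs=1e-9)

    def test_half_wave_rectified_cosine_gives_pi_over_four(self):
        fs, fm = 20e3, 100.0
        t = np.arange(int(0.4 * fs)) / fs
        r = np.clip(np.cos(2 * np.pi * fm * t), 0.0, None)
        assert vector_strength(r, fs, fm) == pytest.approx(np.pi / 4, abs=1e-3)

    def test_constant_rate_gives_zero(self):
        assert vector_strength(np.full(8000, 50.0), 20e3, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_for_nonnegative_rates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = np.abs(rng.standard_normal(4000)) * rng.uniform(0.1, 100)
            vs = vector_strength(r, 20e3, 100.0)
            assert 0.0 <= vs <= 1.0

    def test_zero_rate_undefined(self):
        with pytest.raises(ZeroDivisionError):
            vector_strength(np.zeros(100), 20e3, 100.0)


class TestHalfWaveRectifiedRMS:
    def test_sinusoid_gives_half_amplitude(self):
        fs, a = 20e3, 3.0
        t = np.arange(int(0.1 * fs)) / fs
        v = a * np.sin(2 * np.pi * 1e3 * t)
        assert half_wave_rectified_rms(v) == pytest.approx(a / 2, abs=1e-3 * a)

    def test_zero_input_gives_zero(self):
        assert half_wave_rectified_rms(np.zeros(100)) == 0.0


class TestACDCRatio:
    def test_constructed_sinusoid_convention(self):
        """V = rest + 5 mV DC + 2.5 mV sinusoid -> AC/DC = (2.5/sqrt2)/5."""

        def channel(t, on):
            v = np.full_like(t, -57e-3)
            stim_on = t >= on
            v[stim_on] = -57e-3 + 5e-3 + 2.5e-3 * np.sin(2 * np.pi * 500 * (t[stim_on] - on))
            return v

        model = _DummyModel(channel, cf_axis=[500.0])
        curve = ac_dc_ratio(model, [500.0])
        assert curve.y[0] == pytest.approx((2.5e-3 / np.sqrt(2)) / 5e-3, abs=1e-3)

    def test_dc_only_response_gives_zero(self):
        def channel(t, on):
            v = np.full_like(t, -57e-3)
            v[t >= on] = -50e-3
            return v

        model = _DummyModel(channel, cf_axis=[500.0])
        assert ac_dc_ratio(model, [500.0]).y[0] == pytest.approx(0.0, abs=1e-9)

    def test_teacher_ratio_declines_with_frequency(self):
        teacher = IHCTeacher(np.array([250.0, 2000.0]))
        curve = ac_dc_ratio(teacher, [250.0, 2000.0])
        assert curve.y[1] < curve.y[0]


@pytest.fixture(scope="module")
def multi_cf_teacher():
    return IHCTeacher(greenwood_cf_axis(41, 200.0, 8e3))


class TestExcitationPattern:
    def test_silence_gives_flat_pattern_at_rest(self):
        teacher = IHCTeacher(np.array([500.0, 1e3, 2e3]))
        stim = Stimulus(np.zeros(2560), 20e3, None, "tone", onset_s=0.0128)
        resp = teacher.respond(stim)
        assert np.allclose(resp.values, teacher.v_rest, atol=1e-9)

    def test_low_level_peak_near_tone_frequency(self, multi_cf_teacher):
        pattern = excitation_pattern(multi_cf_teacher, freqs=[1e3],
                                     levels=[10])[(1e3, 10)]
        peak_cf = multi_cf_teacher.cf_axis[np.argmax(pattern.y)]
        assert abs(np.log2(peak_cf / 1e3)) <= 0.5

    def test_peak_shifts_basalward_with_level(self, multi_cf_teacher):
        patterns = excitation_pattern(multi_cf_teacher, freqs=[1e3], levels=[10, 90])
        low_cf = multi_cf_teacher.cf_axis[np.argmax(patterns[(1e3, 10)].y)]
        high_cf = multi_cf_teacher.cf_axis[np.argmax(patterns[(1e3, 90)].y)]
        assert high_cf > low_cf


class TestPotentialLevelGrowth:
    def test_teacher_growth_monotone_to_90dB(self):
        teacher = IHCTeacher(np.array([4e3]))
        curve = potential_level_growth(teacher, levels=range(0, 91, 10))
        assert np.all(np.diff(curve.y) > 0)


class TestFiringRate:
    def test_silence_returns_spontaneous_rate(self):
        teacher = ANFTeacher(np.array([1e3]), "hsr")
        stim = Stimulus(np.zeros(8000), 20e3, None, "tone")
        curve = firing_rate_response(teacher, stim, cf=1e3)
        assert np.mean(curve.y) == pytest.approx(68.5, abs=1.0)

    def test_phase_locking_at_1kHz_but_not_4kHz(self):
        stims = metric4_stimuli(lead_s=0.02)
        rel = {}
        for f in (1e3, 4e3):
            teacher = ANFTeacher(np.array([f]), "hsr")
            curve = firing_rate_response(teacher, stims[f"tone_{int(f)}"])
            r = curve.y[2400:6400]  # steady-state segment
            spec = np.abs(np.fft.rfft(r - r.mean()))
            k = int(round(f * len(r) / 20e3))
            rel[f] = spec[k] / (r.mean() * len(r))
        assert rel[1e3] > 2 * rel[4e3]


class TestRateLevel:
    def test_constant_rate_model_gives_flat_curve(self):
        model = _DummyModel(lambda t, on: np.full_like(t, 42.0), kind="rate",
                            cf_axis=[1007.0])
        curve = rate_level_curve(model, 1007.0, levels=[0, 50, 100])
        assert np.allclose(curve.y, 42.0)

    def test_hsr_saturates_and_lsr_keeps_growing(self):
        hsr = rate_level_curve(ANFTeacher(np.array([1007.0]), "hsr"), 1007.0)
        lsr = rate_level_curve(ANFTeacher(np.array([1007.0]), "lsr"), 1007.0)
        slope40 = hsr.y[5] - hsr.y[3]
        slope90 = hsr.y[10] - hsr.y[8]
        assert slope90 < slope40           # sharp saturation
        assert lsr.y[10] > lsr.y[6]        # sloping, non-saturating


class TestSynchronyLevel:
    def test_vector_strength_within_bounds_across_levels(self):
        teacher = ANFTeacher(np.array([1007.0]), "msr")
        curve = synchrony_level_curve(teacher, 1007.0, levels=[30, 50, 70, 90])
        assert np.all((curve.y >= 0) & (curve.y <= 1))


class TestRMSE:
    def test_identical_zero(self):
        assert rmse(np.arange(5.0), np.arange(5.0)) == 0.0

    def test_constant_offset(self):
        assert rmse(np.zeros(10), np.full(10, 0.3)) == pytest.approx(0.3)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        brute = (sum((x - y) ** 2 for x, y in zip(a, b)) / 50) ** 0.5
        assert rmse(a, b) == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))


class TestEvaluateSurrogate:
    def test_teacher_against_itself_gives_zero_rmse_and_full_schema(self):
        ihc = IHCTeacher(np.array([250.0, 2000.0]))
        anf = ANFTeacher(np.array([1007.0, 3972.7]), "hsr")
        report = evaluate_surrogate([(ihc, ihc), (anf, anf)])
        metrics = [k for k in report if k.startswith("m")]
        assert sorted(metrics) == ["m1", "m2", "m3", "m4", "m5", "m6"]
        assert set(report["rmse_table"]) == set(metrics)
        for v in report["rmse_table"].values():
            assert v == pytest.approx(0.0, abs=1e-12)
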