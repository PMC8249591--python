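import numpy as np
import pytest
from scipy.integrate import solve_ivp

from periphnn.reference import (ANFStandin, ANFTeacher, FIBER_PRESETS, HH_PARAMS,
                                IHCStandin, IHCTeacher, estimate_adaptation_time,
                                hh_spike_times, onset_recovery_curve, simulate_hh,
                                steady_state_fraction)
from periphnn.stimuli import pure_tone, step_current


class TestHodgkinHuxley:
    def test_zero_current_holds_resting_potential(self):
        V = simulate_hh(step_current(0.0, 0.0, 0.3, 100e3))
        assert np.all(np.abs(V[5000:] - HH_PARAMS["V0"]) < 1.0)

    def test_sustained_10uA_fires_repetitively(self):
        V = simulate_hh(step_current(10.0, 0.0, 0.5, 100e3))
        spikes = hh_spike_times(V, 100e3)
        assert len(spikes) > 10

    def test_threshold_current_gives_nondecaying_train(self):
        # currents >= 7.5 uA/cm^2 sustain firing: bounded ISIs to the end
        V = simulate_hh(step_current(7.5, 0.0, 0.5, 100e3))
        spikes = hh_spike_times(V, 100e3)
        assert len(spikes) > 10
        assert np.max(np.diff(spikes)) < 0.03
        assert spikes[-1] > 0.45

    def test_subthreshold_current_does_not_sustain_firing(self):
        V = simulate_hh(step_current(5.0, 0.0, 0.5, 100e3))
        spikes = hh_spike_times(V, 100e3)
        assert len(spikes) <= 2  # transient onset spike only

    def test_spike_amplitude_bounded(self):
        V = simulate_hh(step_current(50.0, 0.0, 0.3, 100e3))
        assert V.max() - V.min() < 120.0

    def test_deterministic(self):
        s = step_current(10.0, 0.0, 0.2, 100e3)
        assert np.array_equal(simulate_hh(s), simulate_hh(s))

    def test_spike_count_matches_independent_ode_oracle(self):
        """Adaptive Runge-Kutta integration of the same equations (scipy)
        reproduces the fixed-step exponential-Euler spike count."""
        p = HH_PARAMS
        amp, dur = 10.0, 0.2

        def alpha_beta(v):
            am = 1.0 if abs(v + 40) < 1e-7 else 0.1 * (v + 40) / (1 - np.exp(-(v + 40) / 10))
            bm = 4.0 * np.exp(-(v + 65) / 18)
            ah = 0.07 * np.exp(-(v + 65) / 20)
            bh = 1.0 / (1 + np.exp(-(v + 35) / 10))
            an = 0.1 if abs(v + 55) < 1e-7 else 0.01 * (v + 55) / (1 - np.exp(-(v + 55) / 10))
            bn = 0.125 * np.exp(-(v + 65) / 80)
            return am, bm, ah, bh, an, bn

        def rhs(t, y):
            v, m, h, n = y
            am, bm, ah, bh, an, bn = alpha_beta(v)
            ina = p["g_Na"] * m ** 3 * h * (v - p["E_Na"])
            ik = p["g_K"] * n ** 4 * (v - p["E_K"])
            il = p["g_L"] * (v - p["E_L"])
            return [(amp - ina - ik - il) / p["C_m"],
                    am * (1 - m) - bm * m, ah * (1 - h) - bh * h,
                    an * (1 - n) - bn * n]

        v0 = p["V0"]
        am, bm, ah, bh, an, bn = alpha_beta(v0)
        y0 = [v0, am / (am + bm), ah / (ah + bh), an / (an + bn)]
        t_eval = np.arange(0, dur, 1e-5) * 1e3  # ms
        sol = solve_ivp(rhs, (0, dur * 1e3), y0, t_eval=t_eval, max_step=0.02,
                        rtol=1e-6, atol=1e-8)
        oracle_spikes = hh_spike_times(sol.y[0], 100e3)
        ours = hh_spike_times(simulate_hh(step_current(amp, 0.0, dur, 100e3)), 100e3)
        assert abs(len(ours) - len(oracle_spikes)) <= 1


class TestIHCStandin:
    def test_silence_rests_at_resting_potential(self):
        ihc = IHCStandin()
        v = ihc.transduce(np.zeros((1000, 2)))
        assert np.allclose(v, ihc.v_rest)

    def test_depolarisation_grows_with_drive(self):
        ihc = IHCStandin()
        small = ihc.transduce(np.full((2000, 1), 2e-8))[-1, 0]
        large = ihc.transduce(np.full((2000, 1), 2e-7))[-1, 0]
        assert ihc.v_rest < small < large


class TestANFStandin:
    @pytest.mark.parametrize("name,sr", [("hsr", 68.5), ("msr", 10.0), ("lsr", 1.0)])
    def test_spontaneous_rate_calibration(self, name, sr):
        anf = ANFStandin(name)
        rate = anf.rate(np.full(100000, -0.057))
        assert np.mean(rate[50000:]) == pytest.approx(sr, abs=0.5)

    def test_onset_peak_exceeds_late_rate(self):
        teacher = ANFTeacher(np.array([1e3]), "hsr")
        stim = pure_tone(1e3, 70.0, 0.5, 20e3).with_lead_silence(0.02)
        r = teacher.respond(stim).channel(1e3)
        on = int(0.02 * 20e3)
        assert np.max(r[on : on + 400]) > np.mean(r[-2000:])

    def test_store_budget_closed(self):
        """Change in total store content equals integrated fluxes each step."""
        anf = ANFStandin("hsr")
        v = np.full(20000, -0.057)
        v[5000:] = -0.040  # strong drive
        q, w, release = anf.stores(v)
        f = anf.fiber
        dt = 1.0 / anf.fs
        transfer = np.maximum(f.x_transfer * w[:-1] * (1 - q[:-1] / f.q_max), 0.0)
        dq = np.diff(q) - dt * (transfer - release)
        dw = np.diff(w) - dt * (f.y_replenish * (f.w_max - w[:-1]) - transfer
                                + f.rho_recycle * release)
        content = q[:-1] + w[:-1]
        assert np.max(np.abs(dq) + np.abs(dw)) < 1e-8 * content.max()

    def test_rate_nonnegative_and_deterministic(self):
        anf = ANFStandin("lsr")
        v = -0.057 + 0.02 * np.clip(np.sin(np.linspace(0, 20, 30000)), 0, None)
        r1, r2 = anf.rate(v), anf.rate(v)
        assert np.all(r1 >= 0)
        assert np.array_equal(r1, r2)


class TestAdaptationTime:
    def test_exponential_decay_matches_closed_form(self):
        fs, tau = 100e3, 10e-3
        r_ss, r_pk = 100.0, 300.0
        t = np.arange(int(0.2 * fs)) / fs
        r = r_ss + (r_pk - r_ss) * np.exp(-t / tau)
        expected = tau * np.log((r_pk - r_ss) / (0.05 * r_ss))
        assert estimate_adaptation_time(r, fs) == pytest.approx(expected, rel=0.02)

    def test_constant_response_returns_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert estimate_adaptation_time(np.full(1000, 5.0), 1e3) == 0.0

    def test_slow_synapse_adapts_slower_than_transduction(self):
        import warnings

        stim = pure_tone(1e3, 70.0, 1.0, 20e3).with_lead_silence(0.02)
        on = int(0.02 * 20e3)
        ihc = IHCTeacher(np.array([1e3]))
        with warnings.catch_warnings():
            # the memoryless transduction stage may settle instantly (time 0)
            warnings.simplefilter("ignore", UserWarning)
            t_ihc = estimate_adaptation_time(
                ihc.respond(stim).channel(1e3)[on:], 20e3, oscillatory=True)
        lsr = ANFTeacher(np.array([1e3]), "lsr")
        t_lsr = estimate_adaptation_time(
            lsr.respond(stim).channel(1e3)[on:], 20e3, smooth_s=5e-3)
        assert t_lsr > t_ihc


class TestSteadyStateFraction:
    def test_constant_rate_is_one(self):
        assert steady_state_fraction(np.full(25000, 50.0), 20e3, 0.4, 1.0) == 1.0

    def test_exponential_analytic_value(self):
        fs, tau = 20e3, 0.05
        t = np.arange(int(1.05 * fs)) / fs
        r = 100.0 + 200.0 * np.exp(-t / tau)
        frac = steady_state_fraction(r, fs, 0.4, 1.0)
        expected = (1 - np.exp(-0.4 / tau)) / (1 - np.exp(-1.0 / tau))
        assert frac == pytest.approx(expected, abs=0.02)

    def test_fast_fiber_completes_more_adaptation_than_slow(self):
        stim = pure_tone(1e3, 70.0, 1.0, 20e3).with_lead_silence(0.02)
        on = int(0.02 * 20e3)
        fracs = {}
        for name in ("hsr", "lsr"):
            t = ANFTeacher(np.array([1e3]), name)
            r = t.respond(stim).channel(1e3)[on:]
            fracs[name] = steady_state_fraction(r, 20e3, 0.4, 0.95)
        assert fracs["hsr"] > fracs["lsr"]


@pytest.fixture(scope="module")
def lsr_curve():
    teacher = ANFTeacher(np.array([2e3]), "lsr")
    return onset_recovery_curve(teacher, FIBER_PRESETS["lsr"], [0.1, 0.7, 1.3, 1.9])


class TestOnsetRecovery:
    def test_reference_isi_normalises_to_exactly_one(self, lsr_curve):
        assert lsr_curve.y[-1] == pytest.approx(1.0, abs=1e-12)

    def test_curve_nondecreasing_in_isi(self, lsr_curve):
        assert np.all(np.diff(lsr_curve.y) >= -1e-9)

    def test_short_interval_recovers_less_than_long(self, lsr_curve):
        assert lsr_curve.y[0] < lsr_curve.y[2]
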