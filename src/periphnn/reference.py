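"""Analytical "teacher" models: cochlear drive, IHC transduction, ANF synapse, HH axon.

These are the mechanistic models the surrogates are trained to imitate.  The
cochlear, IHC and ANF stages are documented desk-scale stand-ins, built to
reproduce the qualitative response repertoire of the auditory periphery —
tonotopic tuning with compressive growth and a basal-ward excitation shift,
saturating mechano-electrical transduction with a membrane low-pass that
limits AC receptor potentials above ~700 Hz, and a three-store synapse whose
release dynamics produce onset adaptation, slow recovery, and the classic
spontaneous-rate classes (68.5 / 10 / 1 spikes/s).  All constants live here
and in docs/methods.md; they are this package's own choices.

The Hodgkin-Huxley axon is the standard squid-axon description (four states
V, m, h, n with the classic rate functions and conductances), integrated with
a fixed-step exponential-Euler scheme.

Every model is deterministic: same input and parameters give identical
output, and output length equals input length at the 100-kHz solver rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .containers import MetricCurve, ResponseField
from .stimuli import Stimulus

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    def njit(f):
        return _njit(cache=False)(f)
except Exception:  # pragma: no cover - numba is normally present
    def njit(f):
        return f

#: Internal integration rate for all analytical modules [Hz].
SOLVE_FS = 100e3
#: Output rate of the teacher chain (training/evaluation rate) [Hz].
MODEL_FS = 20e3

__all__ = [
    "SOLVE_FS", "MODEL_FS", "FiberParams", "FIBER_PRESETS",
    "simulate_hh", "hh_spike_times", "CochlearStandin", "IHCStandin",
    "ANFStandin", "IHCTeacher", "ANFTeacher",
    "estimate_adaptation_time", "steady_state_fraction", "onset_recovery_curve",
]


# ---------------------------------------------------------------------------
# Hodgkin-Huxley squid axon
# ---------------------------------------------------------------------------

HH_PARAMS = {
    "C_m": 1.0,        # uF/cm^2
    "g_Na": 120.0,     # mS/cm^2
    "g_K": 36.0,
    "g_L": 0.3,
    "E_Na": 50.0,      # mV
    "E_K": -77.0,
    "E_L": -54.387,
    "V0": -65.0,
}


@njit
def _hh_loop(I, dt, C_m, g_Na, g_K, g_L, E_Na, E_K, E_L, V0):
    n_t = I.shape[0]
    V = np.empty(n_t)
    v = V0
    # gates start at their steady state for V0
    u = v + 40.0
    am = 1.0 if abs(u) < 1e-7 else 0.1 * u / (1.0 - np.exp(-u / 10.0))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    un = v + 55.0
    an = 0.1 if abs(un) < 1e-7 else 0.01 * un / (1.0 - np.exp(-un / 10.0))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    m = am / (am + bm)
    h = ah / (ah + bh)
    n = an / (an + bn)
    for i in range(n_t):
        u = v + 40.0
        am = 1.0 if abs(u) < 1e-7 else 0.1 * u / (1.0 - np.exp(-u / 10.0))
        bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        un = v + 55.0
        an = 0.1 if abs(un) < 1e-7 else 0.01 * un / (1.0 - np.exp(-un / 10.0))
        bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
        # exponential-Euler gate updates
        tm = am + bm
        m = am / tm + (m - am / tm) * np.exp(-dt * tm)
        th = ah + bh
        h = ah / th + (h - ah / th) * np.exp(-dt * th)
        tn = an + bn
        n = an / tn + (n - an / tn) * np.exp(-dt * tn)
        gna = g_Na * m ** 3 * h
        gk = g_K * n ** 4
        g_tot = gna + gk + g_L
        V_inf = (gna * E_Na + gk * E_K + g_L * E_L + I[i]) / g_tot
        v = V_inf + (v - V_inf) * np.exp(-dt * g_tot / C_m)
        V[i] = v
    return V


def simulate_hh(current: Stimulus, params: dict | None = None,
                dt_ms: float | None = None) -> np.ndarray:
    """Membrane potential [mV] of the squid giant axon driven by ``current``.

    ``current.samples`` is in uA/cm^2 at ``current.fs`` (nominally the
    100-kHz solver rate, giving a 0.01-ms step); ``dt_ms`` overrides the step
    for oracle-grade fine integration.  Output has one sample per input
    sample.  Non-finite states abort with a diagnostic.
    """
    p = dict(HH_PARAMS)
    if params:
        p.update(params)
    dt = 1e3 / current.fs if dt_ms is None else dt_ms
    V = _hh_loop(np.ascontiguousarray(current.samples, dtype=np.float64), dt,
                 p["C_m"], p["g_Na"], p["g_K"], p["g_L"],
                 p["E_Na"], p["E_K"], p["E_L"], p["V0"])
    if not np.all(np.isfinite(V)):
        raise RuntimeError(
            "Hodgkin-Huxley integration diverged (non-finite membrane potential); "
            "reduce the time step or the input amplitude")
    return V


def hh_spike_times(V: np.ndarray, fs: float, threshold_mV: float = 0.0) -> np.ndarray:
    """Times of upward threshold crossings of the membrane potential [s]."""
    above = V >= threshold_mV
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    return idx / fs


# ---------------------------------------------------------------------------
# Cochlear drive stand-in (tonotopic filterbank with compressive tip)
# ---------------------------------------------------------------------------


class CochlearStandin:
    """Level-dependent tonotopic drive: compressive tip + linear low-side tail.

    Each CF channel sums two pathways applied to the sound pressure [Pa]:

    * a sharp band-pass at CF whose output passes through a broken-stick
      compressor (exponent ``compress_exp`` above the knee) — dominant at low
      levels, so excitation peaks at CF = tone frequency;
    * a broader, linear band-pass centred half an octave below CF — at high
      levels it overtakes the compressed tip, moving the excitation maximum
      basal-ward (to higher CF), as in mammalian cochleae.

    Output is a displacement-like drive in metres.
    """

    name = "cochlea_standin"
    solve_fs = SOLVE_FS

    def __init__(self, cf_axis, fs: float = SOLVE_FS,
                 g_tip: float = 3.5e-6, knee_m: float = 1e-8,
                 compress_exp: float = 0.3, g_tail: float = 2e-7,
                 tail_knee_m: float = 1e-7, tail_exp: float = 0.5):
        self.cf_axis = np.atleast_1d(np.asarray(cf_axis, dtype=float))
        self.fs = fs
        self.params = dict(g_tip=g_tip, knee_m=knee_m, compress_exp=compress_exp,
                           g_tail=g_tail, tail_knee_m=tail_knee_m, tail_exp=tail_exp)
        self._tip_sos = []
        self._tail_sos = []
        nyq = fs / 2
        for cf in self.cf_axis:
            lo, hi = cf * 2 ** (-1 / 6), min(cf * 2 ** (1 / 6), 0.95 * nyq)
            self._tip_sos.append(signal.butter(2, [lo, hi], "bandpass", fs=fs,
                                               output="sos"))
            c = cf * 2 ** -0.5
            lo, hi = c * 2 ** -0.45, min(c * 2 ** 0.45, 0.95 * nyq)
            self._tail_sos.append(signal.butter(2, [lo, hi], "bandpass", fs=fs,
                                                output="sos"))

    @staticmethod
    def _broken_stick(u: np.ndarray, knee: float, c: float) -> np.ndarray:
        a = np.abs(u)
        out = np.where(a > knee, knee * (a / knee + 1e-300) ** c, a)
        return np.sign(u) * out

    def drive(self, pressure: np.ndarray) -> np.ndarray:
        """Pressure waveform [Pa] at ``self.fs`` -> (n_t, n_cf) displacement [m]."""
        pressure = np.asarray(pressure, dtype=float)
        out = np.empty((len(pressure), len(self.cf_axis)))
        p = self.params
        for i in range(len(self.cf_axis)):
            tip = signal.sosfilt(self._tip_sos[i], p["g_tip"] * pressure)
            tail = signal.sosfilt(self._tail_sos[i], p["g_tail"] * pressure)
            out[:, i] = (self._broken_stick(tip, p["knee_m"], p["compress_exp"])
                         + self._broken_stick(tail, p["tail_knee_m"], p["tail_exp"]))
        return out


# ---------------------------------------------------------------------------
# IHC transduction stand-in
# ---------------------------------------------------------------------------


class IHCStandin:
    """Saturating mechano-electrical transduction plus membrane low-pass.

    The stereocilia displacement-to-conductance stage is an asymmetric
    Boltzmann (offset ``u0`` makes depolarisation dominate, producing the DC
    component of the receptor potential); the membrane is a first-order
    low-pass whose cutoff (650 Hz) makes the AC/DC ratio decline for stimulus
    frequencies above ~600-700 Hz.  Resting potential -57 mV.
    """

    name = "ihc_standin"
    solve_fs = SOLVE_FS

    def __init__(self, fs: float = SOLVE_FS, v_rest: float = -0.057,
                 g_max: float = 0.06, u0: float = 5e-8, s_u: float = 4e-8,
                 cutoff_hz: float = 650.0):
        self.fs = fs
        self.params = dict(v_rest=v_rest, g_max=g_max, u0=u0, s_u=s_u,
                           cutoff_hz=cutoff_hz)

    @property
    def v_rest(self) -> float:
        return self.params["v_rest"]

    def transduce(self, drive: np.ndarray) -> np.ndarray:
        """Drive [m], shape (n_t, n_cf) -> receptor potential [V], same shape."""
        from scipy.special import expit

        p = self.params
        s = expit((drive - p["u0"]) / p["s_u"])
        s0 = expit(-p["u0"] / p["s_u"])
        g = p["g_max"] * (s - s0)
        rc = 1.0 / (2 * np.pi * p["cutoff_hz"])
        alpha = (1.0 / self.fs) / (rc + 1.0 / self.fs)
        v_ac = signal.lfilter([alpha], [1.0, alpha - 1.0], g, axis=0)
        return p["v_rest"] + v_ac


# ---------------------------------------------------------------------------
# ANF synapse stand-in (three-store diffusion)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FiberParams:
    """Parameters of one auditory-nerve-fiber preset.

    ``sr_target`` is the spontaneous rate the preset is calibrated to;
    ``recovery_level_dB`` is the tone level used in the onset-recovery
    characterisation (the fiber's threshold plus 40 dB: 60/65/75 dB SPL for
    the high/medium/low-SR presets).  The remaining fields parameterise the
    three stores: an immediate store (capacity ``q_max``) whose refill from
    the reservoir is gated by free capacity, a reservoir refilled from the
    factory at rate ``y`` toward ``w_max``, and a recycling fraction ``rho``
    of released transmitter returned to the reservoir.  Release rate is
    ``k(V) * q`` with ``k`` a Boltzmann function of the receptor potential.
    """

    name: str
    sr_target: float          # spikes/s
    recovery_level_dB: float  # dB SPL (threshold + 40 dB)
    k_max: float              # 1/s
    v_half: float             # V
    s_v: float                # V
    x_transfer: float         # 1/s reservoir -> immediate
    y_replenish: float        # 1/s factory -> reservoir
    rho_recycle: float
    w_max: float = 1.0
    q_max: float = 1.0

    @property
    def threshold_dB(self) -> float:
        """Level used in the recovery metric (presentation level, dB SPL)."""
        return self.recovery_level_dB

    def release_rate(self, v: np.ndarray) -> np.ndarray:
        """Boltzmann release-driving function k(V) [1/s]."""
        return self.k_max / (1.0 + np.exp(-(np.asarray(v) - self.v_half) / self.s_v))


FIBER_PRESETS: dict[str, FiberParams] = {
    "hsr": FiberParams("hsr", 68.5, 60.0, k_max=1500.0, v_half=-0.045, s_v=0.0020,
                       x_transfer=60.0, y_replenish=10.0, rho_recycle=0.4),
    "msr": FiberParams("msr", 10.0, 65.0, k_max=2000.0, v_half=-0.040, s_v=0.0022,
                       x_transfer=15.0, y_replenish=5.0, rho_recycle=0.4),
    "lsr": FiberParams("lsr", 1.0, 75.0, k_max=3000.0, v_half=-0.034, s_v=0.0025,
                       x_transfer=4.0, y_replenish=2.0, rho_recycle=0.4),
}


@njit
def _store_loop(k, dt, x, y, rho, w_max, q_max, q0, w0):
    n_t = k.shape[0]
    q = np.empty(n_t + 1)
    w = np.empty(n_t + 1)
    q[0] = q0
    w[0] = w0
    for i in range(n_t):
        transfer = x * w[i] * (1.0 - q[i] / q_max)
        if transfer < 0.0:
            transfer = 0.0
        release = k[i] * q[i]
        q[i + 1] = q[i] + dt * (transfer - release)
        w[i + 1] = w[i] + dt * (y * (w_max - w[i]) - transfer + rho * release)
    return q, w


class ANFStandin:
    """Three-store synapse: instantaneous firing rate from receptor potential.

    Integrated with explicit Euler at the 100-kHz solver rate.  The silent
    steady state is solved in closed form at construction and the rate scale
    ``A`` calibrated so the spontaneous rate equals the preset's target
    exactly; simulations start from that steady state.
    """

    name = "anf_standin"
    solve_fs = SOLVE_FS

    def __init__(self, fiber: FiberParams | str, fs: float = SOLVE_FS,
                 v_rest: float = -0.057):
        if isinstance(fiber, str):
            fiber = FIBER_PRESETS[fiber]
        self.fiber = fiber
        self.fs = fs
        k_rest = float(fiber.release_rate(v_rest))

        def _w_residual(w):
            q = fiber.x_transfer * w / (k_rest + fiber.x_transfer * w / fiber.q_max)
            return (fiber.y_replenish * (fiber.w_max - w)
                    - (1.0 - fiber.rho_recycle) * k_rest * q)

        w_rest = brentq(_w_residual, 0.0, fiber.w_max, xtol=1e-15)
        q_rest = fiber.x_transfer * w_rest / (
            k_rest + fiber.x_transfer * w_rest / fiber.q_max)
        self.q_rest, self.w_rest, self.k_rest = q_rest, w_rest, k_rest
        self.rate_scale = fiber.sr_target / (k_rest * q_rest)

    def rate(self, vihc: np.ndarray) -> np.ndarray:
        """Receptor potential [V] (n_t,) or (n_t, n_cf) -> rate [spikes/s]."""
        v = np.asarray(vihc, dtype=float)
        squeeze = v.ndim == 1
        v2 = v[:, None] if squeeze else v
        out = np.empty_like(v2)
        dt = 1.0 / self.fs
        f = self.fiber
        for c in range(v2.shape[1]):
            k = np.ascontiguousarray(f.release_rate(v2[:, c]))
            q, w = _store_loop(k, dt, f.x_transfer, f.y_replenish, f.rho_recycle,
                               f.w_max, f.q_max, self.q_rest, self.w_rest)
            if np.any(q < 0) or np.any(w < 0):
                raise RuntimeError(
                    "store quantity went negative: integration-step failure "
                    "(reduce the time step)")
            out[:, c] = self.rate_scale * k * q[:-1]
        return out[:, 0] if squeeze else out

    def stores(self, vihc_1d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Immediate/reservoir trajectories and release flux, for diagnostics."""
        k = np.ascontiguousarray(self.fiber.release_rate(np.asarray(vihc_1d)))
        f = self.fiber
        q, w = _store_loop(k, 1.0 / self.fs, f.x_transfer, f.y_replenish,
                           f.rho_recycle, f.w_max, f.q_max, self.q_rest, self.w_rest)
        return q, w, k * q[:-1]


# ---------------------------------------------------------------------------
# Teacher chains (stimulus -> response field at the 20-kHz model rate)
# ---------------------------------------------------------------------------


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    from .datasets import resample_to_model_rate

    return resample_to_model_rate(x, fs_in, fs_out)


@dataclass
class IHCTeacher:
    """Full analytical chain to receptor potential: cochlea -> IHC.

    ``respond`` resamples the stimulus to the 100-kHz solver rate, runs the
    stand-ins, and returns the receptor potential at the 20-kHz model rate in
    volts.  ``output_kind`` tags the stage for the metric procedures.
    """

    cf_axis: np.ndarray
    output_kind: str = field(default="potential", init=False)

    def __post_init__(self):
        self.cf_axis = np.atleast_1d(np.asarray(self.cf_axis, dtype=float))
        self.cochlea = CochlearStandin(self.cf_axis)
        self.ihc = IHCStandin()

    @property
    def v_rest(self) -> float:
        return self.ihc.v_rest

    def drive_field(self, stim: Stimulus) -> ResponseField:
        """BM-like drive at the model rate (surrogate input), in metres."""
        p100 = _resample(stim.samples, stim.fs, SOLVE_FS)
        d = self.cochlea.drive(p100)
        return ResponseField(_resample(d, SOLVE_FS, MODEL_FS), MODEL_FS,
                             self.cf_axis, "m")

    def respond(self, stim: Stimulus) -> ResponseField:
        p100 = _resample(stim.samples, stim.fs, SOLVE_FS)
        v = self.ihc.transduce(self.cochlea.drive(p100))
        return ResponseField(_resample(v, SOLVE_FS, MODEL_FS), MODEL_FS,
                             self.cf_axis, "V")


@dataclass
class ANFTeacher:
    """Full analytical chain to firing rate: cochlea -> IHC -> ANF synapse."""

    cf_axis: np.ndarray
    fiber: FiberParams | str = "hsr"
    output_kind: str = field(default="rate", init=False)

    def __post_init__(self):
        self.cf_axis = np.atleast_1d(np.asarray(self.cf_axis, dtype=float))
        self.cochlea = CochlearStandin(self.cf_axis)
        self.ihc = IHCStandin()
        self.anf = ANFStandin(self.fiber)
        self.fiber = self.anf.fiber

    def ihc_field(self, stim: Stimulus) -> ResponseField:
        """Receptor potential at the model rate (ANF-surrogate input), volts."""
        p100 = _resample(stim.samples, stim.fs, SOLVE_FS)
        v = self.ihc.transduce(self.cochlea.drive(p100))
        return ResponseField(_resample(v, SOLVE_FS, MODEL_FS), MODEL_FS,
                             self.cf_axis, "V")

    def respond(self, stim: Stimulus) -> ResponseField:
        p100 = _resample(stim.samples, stim.fs, SOLVE_FS)
        v = self.ihc.transduce(self.cochlea.drive(p100))
        r = self.anf.rate(v)
        r20 = np.clip(_resample(r, SOLVE_FS, MODEL_FS), 0.0, None)
        return ResponseField(r20, MODEL_FS, self.cf_axis, "spikes_per_s")


# ---------------------------------------------------------------------------
# Adaptation / recovery characterisation
# ---------------------------------------------------------------------------


def estimate_adaptation_time(response: np.ndarray, fs: float,
                             oscillatory: bool = False,
                             smooth_s: float = 0.0) -> float:
    """Time from onset peak until the envelope settles within +-5% of steady state.

    Steady state is the mean of the final 10% of the (stimulated) segment;
    the returned duration is measured from the envelope peak to the first
    sample after which the envelope stays inside ``steady_state +- 5%``.
    ``oscillatory=True`` uses the magnitude of the analytic signal as the
    envelope (for receptor potentials); rates are used raw.  ``smooth_s``
    optionally applies a moving average to the envelope first (useful for
    strongly phase-locked rate traces whose envelope ripples).  A response
    with no peak above the steady-state band returns 0 with a warning.
    """
    r = np.asarray(response, dtype=float)
    env = np.abs(signal.hilbert(r - r.mean())) + r.mean() if oscillatory else r
    if smooth_s > 0:
        w = max(1, int(round(smooth_s * fs)))
        env = np.convolve(env, np.ones(w) / w, mode="same")
    n = len(env)
    ss = float(np.mean(env[int(np.floor(0.9 * n)):]))
    band = 0.05 * abs(ss)
    i_peak = int(np.argmax(env))
    if env[i_peak] <= ss + band:
        warnings.warn("no onset peak above the steady-state band; adaptation time 0")
        return 0.0
    outside = np.abs(env - ss) > band
    last_outside = int(np.max(np.flatnonzero(outside), initial=-1))
    i_enter = last_outside + 1
    if i_enter <= i_peak:
        return 0.0
    return (i_enter - i_peak) / fs


def steady_state_fraction(response: np.ndarray, fs: float,
                          t_probe: float = 0.4, t_ref: float = 1.0,
                          smooth_s: float = 10e-3) -> float:
    """Fraction of the onset adaptation completed by ``t_probe``.

    Rates are smoothed with a 10-ms moving average; the fraction is
    ``(r_peak - r(t_probe)) / (r_peak - r(t_ref))`` with the peak taken
    before ``t_probe``, i.e. how much of the decay from the onset peak to the
    final (reference-time) rate has been reached at the probe time.  A
    constant response (no decay) returns 1.  A fast-adapting fiber scores
    close to 1; a slowly adapting fiber scores lower.
    """
    r = np.asarray(response, dtype=float)
    if not t_probe < t_ref <= len(r) / fs:
        raise ValueError("need t_probe < t_ref <= response duration")
    w = max(1, int(round(smooth_s * fs)))
    smooth = np.convolve(r, np.ones(w) / w, mode="same")
    i_probe = int(round(t_probe * fs))
    i_ref = min(int(round(t_ref * fs)), len(r) - 1)
    ref = smooth[i_ref]
    if ref == 0:
        raise ZeroDivisionError("reference rate is zero; fraction undefined")
    peak = float(np.max(smooth[: i_probe + 1]))
    denom = peak - ref
    if denom <= 0:
        return 1.0
    return float((peak - smooth[i_probe]) / denom)


def onset_recovery_curve(model, fiber: FiberParams, isi_grid,
                         freq: float = 2e3, tone_dur: float = 0.1,
                         ref_isi: float = 1.9, peak_window_s: float = 0.05,
                         fs: float = MODEL_FS) -> MetricCurve:
    """Recovery of the second-tone onset peak versus interstimulus interval.

    For each ISI a pair of ``tone_dur`` tones at the fiber's recovery level
    (threshold + 40 dB) is presented; the maximum rate within
    ``peak_window_s`` of the second-tone onset is normalised by the same
    quantity at the reference ISI (1.9 s), so the curve ends at exactly 1.
    """
    from .stimuli import tone_pair

    isi_grid = np.asarray(isi_grid, dtype=float)

    def second_peak(isi: float) -> float:
        stim = tone_pair(freq, fiber.recovery_level_dB, isi, tone_dur, fs=fs)
        resp = model.respond(stim)
        r = resp.channel(freq)
        i0 = int(round(stim.meta["second_onset_s"] * resp.fs))
        i1 = min(len(r), i0 + int(round(peak_window_s * resp.fs)))
        return float(np.max(r[i0:i1]))

    ref = second_peak(ref_isi)
    y = np.array([second_peak(isi) for isi in isi_grid]) / ref
    return MetricCurve(isi_grid, y, "s", "normalised onset peak",
                       name="onset_recovery",
                       meta={"freq": freq, "level_dB": fiber.recovery_level_dB,
                             "ref_isi": ref_isi})
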