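"""Model-agnostic evaluation metrics for IHC and ANF stages.

Six classical experimental-neuroscience characterisations, applicable to any
model exposing ``respond(stimulus) -> ResponseField`` with a ``cf_axis`` and
an ``output_kind`` of ``"potential"`` (IHC stage) or ``"rate"`` (ANF stage):

1. excitation patterns (mean receptor potential across CF vs tone level),
2. AC/DC ratio of the receptor potential vs stimulus frequency,
3. half-wave-rectified receptor-potential growth with level,
4. firing-rate traces for tones and amplitude-modulated tones,
5. rate-level curves,
6. synchrony-level curves (vector strength at the modulation frequency).

All stimulus conventions (durations, ramps, measurement windows) live in
``METRIC_CONFIG``.  Responses are measured relative to stimulus onset; every
evaluation stimulus carries leading silence covering at least the analysis
pre-onset window and, for surrogates, their left context.
"""

from __future__ import annotations

import numpy as np

from .containers import MetricCurve, ResponseField
from .stimuli import Stimulus, pure_tone, sam_tone

__all__ = [
    "METRIC_CONFIG", "excitation_pattern", "ac_dc_ratio", "potential_level_growth",
    "firing_rate_response", "rate_level_curve", "synchrony_level_curve",
    "vector_strength", "half_wave_rectified_rms", "rmse", "evaluate_surrogate",
    "SurrogateIHCModel", "SurrogateANFModel",
]

#: Stimulus and measurement conventions per metric.
METRIC_CONFIG = {
    "m1": dict(freqs=(500.0, 1000.0, 2000.0), levels=tuple(range(10, 91, 10)),
               ramp_dur=5e-3, total_s=0.128),
    "m2": dict(level_dB=80.0, tone_dur=80e-3, ramp_dur=5e-3,
               ac_window=(50e-3, 70e-3), rest_window=(-15e-3, -5e-3)),
    "m3": dict(freq=4e3, levels=tuple(range(0, 101, 10)), tone_dur=80e-3,
               ramp_dur=5e-3, steady_window=(50e-3, 70e-3)),
    "m4": dict(freqs=(1e3, 4e3), level_dB=70.0, tone_dur=0.4, tone_ramp=5e-3,
               sam_ramp=7.8e-3, fm=100.0, m=1.0),
    "m5": dict(freqs=(1007.0, 3972.7), levels=tuple(range(0, 101, 10)),
               tone_dur=50e-3, ramp_dur=2.5e-3, rate_window=(10e-3, 40e-3)),
    "m6": dict(carriers=(1007.0, 3972.7), fm=100.0, m=1.0, dur=0.4,
               ramp_dur=7.8e-3, levels=tuple(range(0, 101, 10)),
               steady_from=0.1),
}


def _lead(model, minimum: float = 0.02) -> float:
    """Leading-silence duration: at least the analysis pre-window, plus any
    left context the model needs."""
    return max(minimum, getattr(model, "context_s", 0.0))


def _segment(resp: ResponseField, onset_s: float, window: tuple[float, float]) -> slice:
    i0 = int(round((onset_s + window[0]) * resp.fs))
    i1 = int(round((onset_s + window[1]) * resp.fs))
    return slice(max(i0, 0), i1)


# ---------------------------------------------------------------------------
# Metric 1
# ---------------------------------------------------------------------------


def excitation_pattern(model, freqs=None, levels=None,
                       lead_s: float | None = None) -> dict[tuple, MetricCurve]:
    """Mean depolarisation across CF for tones of several frequencies/levels.

    The tone duration is unspecified by convention; it fills the evaluation
    window after the leading context silence.  Returns one curve (x = CF,
    y = mean receptor potential re rest, volts) per (freq, level).
    """
    cfg = METRIC_CONFIG["m1"]
    freqs = cfg["freqs"] if freqs is None else freqs
    levels = cfg["levels"] if levels is None else levels
    lead = _lead(model) if lead_s is None else lead_s
    out = {}
    for f in freqs:
        for lv in levels:
            tone_dur = cfg["total_s"]
            stim = pure_tone(f, lv, tone_dur, ramp_dur=cfg["ramp_dur"])
            stim = stim.with_lead_silence(lead)
            resp = model.respond(stim)
            rest = resp.values[: int(lead * resp.fs * 0.8), :].mean(axis=0)
            seg = _segment(resp, stim.onset_s, (cfg["ramp_dur"], tone_dur))
            y = resp.values[seg, :].mean(axis=0) - rest
            out[(f, lv)] = MetricCurve(model.cf_axis, y, "Hz", "V",
                                       name="excitation_pattern",
                                       meta={"freq": f, "level_dB": lv})
    return out


# ---------------------------------------------------------------------------
# Metric 2
# ---------------------------------------------------------------------------


def ac_dc_ratio(model, freqs, level_dB: float | None = None,
                lead_s: float | None = None) -> MetricCurve:
    """AC/DC ratio of the receptor potential versus stimulus frequency.

    AC is the RMS of the mean-subtracted steady-state segment (50-70 ms after
    onset); DC is the steady-state mean minus the resting potential measured
    15-5 ms before onset.  Tones are presented at the probed CF at 80 dB SPL.
    A zero DC component yields NaN (undefined) for that frequency.
    """
    cfg = METRIC_CONFIG["m2"]
    level = cfg["level_dB"] if level_dB is None else level_dB
    lead = _lead(model) if lead_s is None else lead_s
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    y = np.empty(len(freqs))
    for i, f in enumerate(freqs):
        stim = pure_tone(f, level, cfg["tone_dur"], ramp_dur=cfg["ramp_dur"])
        stim = stim.with_lead_silence(lead)
        resp = model.respond(stim)
        v = resp.channel(f)
        steady = v[_segment(resp, stim.onset_s, cfg["ac_window"])]
        rest = v[_segment(resp, stim.onset_s, cfg["rest_window"])]
        ac = float(np.sqrt(np.mean((steady - steady.mean()) ** 2)))
        dc = float(steady.mean() - rest.mean())
        y[i] = ac / dc if dc != 0 else np.nan
    return MetricCurve(freqs, y, "Hz", "AC/DC", name="ac_dc_ratio",
                       meta={"level_dB": level})


# ---------------------------------------------------------------------------
# Metric 3
# ---------------------------------------------------------------------------


def half_wave_rectified_rms(v: np.ndarray) -> float:
    """RMS of the positive part of a mean-subtracted segment."""
    v = np.asarray(v, dtype=float)
    rect = np.clip(v - v.mean(), 0.0, None)
    return float(np.sqrt(np.mean(rect ** 2)))


def potential_level_growth(model, freq: float | None = None, levels=None,
                           lead_s: float | None = None) -> MetricCurve:
    """Half-wave-rectified receptor-potential RMS versus tone level (4 kHz)."""
    cfg = METRIC_CONFIG["m3"]
    freq = cfg["freq"] if freq is None else freq
    levels = np.asarray(cfg["levels"] if levels is None else levels, dtype=float)
    lead = _lead(model) if lead_s is None else lead_s
    y = np.empty(len(levels))
    for i, lv in enumerate(levels):
        stim = pure_tone(freq, lv, cfg["tone_dur"], ramp_dur=cfg["ramp_dur"])
        stim = stim.with_lead_silence(lead)
        resp = model.respond(stim)
        v = resp.channel(freq)
        y[i] = half_wave_rectified_rms(v[_segment(resp, stim.onset_s,
                                                  cfg["steady_window"])])
    return MetricCurve(levels, y, "dB SPL", "V", name="potential_level_growth",
                       meta={"freq": freq})


# ---------------------------------------------------------------------------
# Metric 4
# ---------------------------------------------------------------------------


def firing_rate_response(model, stimulus: Stimulus, cf: float | None = None) -> MetricCurve:
    """Firing-rate trace at the probed CF for a tone or SAM tone."""
    resp = model.respond(stimulus)
    probe = cf if cf is not None else stimulus.meta.get(
        "freq", stimulus.meta.get("carrier", model.cf_axis[0]))
    r = resp.channel(probe)
    return MetricCurve(resp.t, r, "s", "spikes/s", name="firing_rate",
                       meta={"cf": probe, "kind": stimulus.kind,
                             "onset_s": stimulus.onset_s})


def metric4_stimuli(lead_s: float = 0.02) -> dict[str, Stimulus]:
    """The standard Metric-4 stimulus set (70 dB tones and SAM tones, 1/4 kHz)."""
    cfg = METRIC_CONFIG["m4"]
    out = {}
    for f in cfg["freqs"]:
        tone = pure_tone(f, cfg["level_dB"], cfg["tone_dur"], ramp_dur=cfg["tone_ramp"])
        sam = sam_tone(f, cfg["fm"], cfg["m"], cfg["level_dB"], cfg["tone_dur"],
                       ramp_dur=cfg["sam_ramp"])
        out[f"tone_{int(f)}"] = tone.with_lead_silence(lead_s)
        out[f"sam_{int(f)}"] = sam.with_lead_silence(lead_s)
    return out


# ---------------------------------------------------------------------------
# Metric 5
# ---------------------------------------------------------------------------


def rate_level_curve(model, freq: float, levels=None,
                     lead_s: float | None = None) -> MetricCurve:
    """Mean rate 10-40 ms after onset versus level, probe CF = tone frequency."""
    cfg = METRIC_CONFIG["m5"]
    levels = np.asarray(cfg["levels"] if levels is None else levels, dtype=float)
    lead = _lead(model) if lead_s is None else lead_s
    y = np.empty(len(levels))
    for i, lv in enumerate(levels):
        stim = pure_tone(freq, lv, cfg["tone_dur"], ramp_dur=cfg["ramp_dur"])
        stim = stim.with_lead_silence(lead)
        resp = model.respond(stim)
        r = resp.channel(freq)
        y[i] = float(np.mean(r[_segment(resp, stim.onset_s, cfg["rate_window"])]))
    return MetricCurve(levels, y, "dB SPL", "spikes/s", name="rate_level",
                       meta={"freq": freq})


# ---------------------------------------------------------------------------
# Metric 6
# ---------------------------------------------------------------------------


def vector_strength(rate: np.ndarray, fs: float, fm: float) -> float:
    """|F(fm)| / |F(0)| of a firing-rate trace (0 = none, 1 = perfect synchrony)."""
    rate = np.asarray(rate, dtype=float)
    X = np.fft.rfft(rate)
    if abs(X[0]) == 0:
        raise ZeroDivisionError("zero mean rate: vector strength undefined")
    k = int(round(fm * len(rate) / fs))
    return float(np.abs(X[k]) / np.abs(X[0]))


def synchrony_level_curve(model, carrier: float, levels=None,
                          lead_s: float | None = None) -> MetricCurve:
    """Vector strength at the modulation frequency versus SAM-tone level.

    Fully modulated 400-ms tones; the Fourier components are computed on the
    steady-state portion only (from 100 ms after onset to offset, an integer
    number of modulation periods), excluding the onset transient.
    """
    cfg = METRIC_CONFIG["m6"]
    levels = np.asarray(cfg["levels"] if levels is None else levels, dtype=float)
    lead = _lead(model) if lead_s is None else lead_s
    y = np.empty(len(levels))
    for i, lv in enumerate(levels):
        stim = sam_tone(carrier, cfg["fm"], cfg["m"], lv, cfg["dur"],
                        ramp_dur=cfg["ramp_dur"])
        stim = stim.with_lead_silence(lead)
        resp = model.respond(stim)
        r = resp.channel(carrier)
        n_per = int((cfg["dur"] - cfg["steady_from"] - cfg["ramp_dur"]) * cfg["fm"])
        i0 = int(round((stim.onset_s + cfg["steady_from"]) * resp.fs))
        n = int(round(n_per * resp.fs / cfg["fm"]))
        y[i] = vector_strength(r[i0 : i0 + n], resp.fs, cfg["fm"])
    return MetricCurve(levels, y, "dB SPL", "vector strength",
                       name="synchrony_level", meta={"carrier": carrier,
                                                     "fm": cfg["fm"]})


# ---------------------------------------------------------------------------
# RMSE and the combined report
# ---------------------------------------------------------------------------


def rmse(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Root-mean-square error, in the units of the compared quantity."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.sqrt(np.mean((x - x_hat) ** 2)))


def _stage_metrics(surrogate, teacher) -> dict:
    """Run the metrics appropriate to one stage on both models."""
    kind = teacher.output_kind
    report = {}
    if kind == "potential":
        freqs = np.asarray(teacher.cf_axis, dtype=float)
        pairs = {
            "m1": (excitation_pattern(surrogate), excitation_pattern(teacher)),
            "m2": (ac_dc_ratio(surrogate, freqs), ac_dc_ratio(teacher, freqs)),
            "m3": (potential_level_growth(surrogate), potential_level_growth(teacher)),
        }
        for name, (s, t) in pairs.items():
            if isinstance(s, dict):
                ys = np.concatenate([c.y for c in s.values()])
                yt = np.concatenate([c.y for c in t.values()])
            else:
                ys, yt = s.y, t.y
            report[name] = {"surrogate": s, "teacher": t, "rmse": rmse(yt, ys)}
    else:
        cfg5 = METRIC_CONFIG["m5"]
        stims = metric4_stimuli(lead_s=_lead(surrogate))
        m4_s = {k: firing_rate_response(surrogate, st) for k, st in stims.items()}
        m4_t = {k: firing_rate_response(teacher, st) for k, st in stims.items()}
        report["m4"] = {"surrogate": m4_s, "teacher": m4_t,
                        "rmse": rmse(np.concatenate([c.y for c in m4_t.values()]),
                                     np.concatenate([c.y for c in m4_s.values()]))}
        for name, fn, xs in (("m5", rate_level_curve, cfg5["freqs"]),
                             ("m6", synchrony_level_curve,
                              METRIC_CONFIG["m6"]["carriers"])):
            s = {f: fn(surrogate, f) for f in xs}
            t = {f: fn(teacher, f) for f in xs}
            report[name] = {"surrogate": s, "teacher": t,
                            "rmse": rmse(np.concatenate([c.y for c in t.values()]),
                                         np.concatenate([c.y for c in s.values()]))}
    return report


def evaluate_surrogate(surrogate, teacher=None, metric_suite=None) -> dict:
    """Run the evaluation suite and an RMSE table for surrogate/teacher pairs.

    Either a single ``(surrogate, teacher)`` pair (metrics of that stage
    only) or a list of pairs covering both stages (all six metrics).  The
    returned dict maps metric name -> {surrogate, teacher, rmse}, plus an
    ``"rmse_table"`` summary.
    """
    pairs = surrogate if isinstance(surrogate, (list, tuple)) and teacher is None \
        else [(surrogate, teacher)]
    report: dict = {}
    for s, t in pairs:
        report.update(_stage_metrics(s, t))
    if metric_suite is not None:
        report = {k: v for k, v in report.items() if k in metric_suite or k == "rmse_table"}
    report["rmse_table"] = {k: v["rmse"] for k, v in report.items()
                            if isinstance(v, dict) and "rmse" in v}
    return report


# ---------------------------------------------------------------------------
# Surrogate wrappers implementing the model protocol
# ---------------------------------------------------------------------------


class _SurrogateBase:
    def __init__(self, net, teacher, stage_in: str, stage_out: str, kind: str):
        from .reference import MODEL_FS

        self.net = net
        self.teacher = teacher
        self.stage_in, self.stage_out = stage_in, stage_out
        self.output_kind = kind
        self.cf_axis = teacher.cf_axis
        self.fs = MODEL_FS
        self.context_s = net.spec.L_l / MODEL_FS

    def _input_field(self, stim):
        raise NotImplementedError

    def respond(self, stim: Stimulus) -> ResponseField:
        from .architecture import extrapolate_channels
        from .datasets import scale_signal, unscale_signal

        fin = self._input_field(stim)
        x = scale_signal(fin.values, self.stage_in)
        block = self.net.spec.stride ** self.net.spec.n_enc
        pad = (-len(x)) % block
        x = np.pad(x, ((0, pad), (0, 0)))
        y = extrapolate_channels(self.net, x)
        y = y[: len(fin.values)]
        out = unscale_signal(y, self.stage_out)
        units = "V" if self.output_kind == "potential" else "spikes_per_s"
        if self.output_kind == "rate":
            out = np.clip(out, 0.0, None)
        return ResponseField(out, fin.fs, self.cf_axis, units)


class SurrogateIHCModel(_SurrogateBase):
    """Trained IHC surrogate behind the analytical cochlear front-end."""

    def __init__(self, net, teacher):
        super().__init__(net, teacher, "bm", "ihc", "potential")

    def _input_field(self, stim):
        return self.teacher.drive_field(stim)


class SurrogateANFModel(_SurrogateBase):
    """Trained ANF surrogate behind the analytical cochlea+IHC front-end."""

    def __init__(self, net, teacher):
        super().__init__(net, teacher, "ihc", "anf", "rate")

    def _input_field(self, stim):
        return self.teacher.ihc_field(stim)
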