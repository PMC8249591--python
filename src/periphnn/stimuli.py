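"""Acoustic and current stimulus generation with dB-SPL calibration.

All acoustic stimuli are pressure waveforms in pascal, calibrated against the
reference pressure ``P0 = 2e-5 Pa`` so that a level of ``L`` dB SPL means
``20*log10(rms/P0) == L``.  Pure tones are calibrated analytically (the
amplitude ``P0*sqrt(2)*10**(L/20)`` fixes the RMS in closed form) and ramped
afterwards; amplitude-modulated tones are constructed first and then globally
rescaled to the target RMS, matching the two distinct calibration conventions
used for tonal versus modulated stimuli.  Current stimuli (for the
Hodgkin-Huxley axon) carry ``level_dB=None`` and are expressed in uA/cm^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile

#: Reference pressure for dB SPL, in Pa.
P0 = 2e-5

__all__ = [
    "P0",
    "Stimulus",
    "pure_tone",
    "sam_tone",
    "tone_pair",
    "step_current",
    "speech_like_corpus",
    "rms",
    "spl",
    "hanning_ramp",
    "write_wav",
    "read_wav",
]


def rms(x: np.ndarray) -> float:
    """Root-mean-square of a waveform."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(np.square(x))))


def spl(x: np.ndarray) -> float:
    """Sound pressure level of a pressure waveform in dB re P0."""
    return 20.0 * np.log10(rms(x) / P0)


@dataclass(frozen=True)
class Stimulus:
    """A single-channel calibrated waveform.

    Parameters
    ----------
    samples:
        Instantaneous amplitudes; Pa for acoustic stimuli, uA/cm^2 for
        current stimuli.
    fs:
        Sampling rate in Hz.
    level_dB:
        Nominal level in dB SPL, or ``None`` for current stimuli.
    kind:
        One of ``tone``, ``sam``, ``tone_pair``, ``step``, ``corpus_item``.
    onset_s:
        Time of stimulus onset within ``samples`` (leading silence before
        this point), in seconds.  Metric procedures measure windows relative
        to this onset.
    """

    samples: np.ndarray
    fs: float
    level_dB: float | None
    kind: str
    onset_s: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("stimulus samples must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def with_lead_silence(self, dur_s: float) -> "Stimulus":
        """Prepend exact zeros and shift the recorded onset accordingly."""
        n = int(round(dur_s * self.fs))
        samples = np.concatenate([np.zeros(n), self.samples])
        return replace(self, samples=samples, onset_s=self.onset_s + n / self.fs)


def hanning_ramp(n_samples: int, ramp_samples: int) -> np.ndarray:
    """Multiplicative envelope with raised-cosine on/off ramps.

    The on (off) ramp is the first (last) half of a raised-cosine window of
    length ``2*ramp_samples``; the envelope is 1 in between.
    """
    env = np.ones(n_samples)
    if ramp_samples <= 0:
        return env
    if 2 * ramp_samples > n_samples:
        raise ValueError("ramps longer than the stimulus")
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_samples) / ramp_samples))
    env[:ramp_samples] = ramp
    env[-ramp_samples:] = ramp[::-1]
    return env


def _check_tone_args(freq: float, duration: float, fs: float, ramp_dur: float) -> None:
    if freq >= fs / 2:
        raise ValueError(f"tone frequency {freq} Hz at or above Nyquist ({fs / 2} Hz)")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if ramp_dur < 0 or duration <= 2 * ramp_dur:
        raise ValueError("need duration > 2*ramp_dur >= 0")


def pure_tone(
    freq: float,
    level_dB: float,
    duration: float,
    fs: float = 20e3,
    ramp_dur: float = 5e-3,
    ramp_shape: str = "hanning",
) -> Stimulus:
    """Calibrated pure tone ``P0*sqrt(2)*10**(L/20)*sin(2*pi*f*t)``.

    The amplitude fixes the RMS of the unramped tone analytically; the ramps
    are applied multiplicatively afterwards and no re-normalisation takes
    place (a ramped tone therefore has slightly lower RMS than nominal).
    """
    _check_tone_args(freq, duration, fs, ramp_dur)
    if ramp_shape != "hanning":
        raise ValueError(f"unknown ramp shape: {ramp_shape!r}")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = P0 * np.sqrt(2.0) * 10.0 ** (level_dB / 20.0) * np.sin(2 * np.pi * freq * t)
    x *= hanning_ramp(n, int(round(ramp_dur * fs)))
    return Stimulus(x, fs, level_dB, "tone", meta={"freq": freq, "ramp_dur": ramp_dur})


def sam_tone(
    carrier: float,
    fm: float = 100.0,
    m: float = 1.0,
    level_dB: float = 70.0,
    duration: float = 0.4,
    fs: float = 20e3,
    ramp_dur: float = 7.8e-3,
) -> Stimulus:
    """Sinusoidally amplitude-modulated tone.

    The waveform ``[1 + m*cos(2*pi*fm*t + pi)] * sin(2*pi*fc*t)`` (the +pi
    modulator phase makes a fully modulated tone start in a dip) is globally
    rescaled so its full-duration RMS meets ``level_dB``, then ramped.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("modulation depth m must lie in [0, 1]")
    _check_tone_args(carrier, duration, fs, ramp_dur)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = (1.0 + m * np.cos(2 * np.pi * fm * t + np.pi)) * np.sin(2 * np.pi * carrier * t)
    target = P0 * 10.0 ** (level_dB / 20.0)
    x *= target / rms(x)
    x *= hanning_ramp(n, int(round(ramp_dur * fs)))
    return Stimulus(
        x, fs, level_dB, "sam",
        meta={"carrier": carrier, "fm": fm, "m": m, "ramp_dur": ramp_dur},
    )


def tone_pair(
    freq: float,
    level_dB: float,
    isi: float,
    tone_dur: float = 0.1,
    fs: float = 20e3,
    ramp_dur: float = 5e-3,
) -> Stimulus:
    """Two identical ramped tones separated by ``isi`` seconds of exact zeros."""
    if isi < 0:
        raise ValueError("interstimulus interval must be non-negative")
    tone = pure_tone(freq, level_dB, tone_dur, fs, ramp_dur)
    gap = np.zeros(int(round(isi * fs)))
    x = np.concatenate([tone.samples, gap, tone.samples])
    return Stimulus(
        x, fs, level_dB, "tone_pair",
        meta={"freq": freq, "isi": isi, "tone_dur": tone_dur,
              "second_onset_s": (len(tone.samples) + len(gap)) / fs},
    )


def step_current(
    amplitude: float,
    onset: float,
    dur: float,
    fs: float = 100e3,
    tail: float = 0.0,
) -> Stimulus:
    """Step current pulse in uA/cm^2: zero, then ``amplitude`` for ``dur``, then zero."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    i0 = int(round(onset * fs))
    i1 = i0 + int(round(dur * fs))
    x = np.zeros(i1 + int(round(tail * fs)))
    x[i0:i1] = amplitude
    return Stimulus(x, fs, None, "step", onset_s=i0 / fs,
                    meta={"amplitude": amplitude, "dur": dur})


def random_step_currents(
    n_items: int,
    amp_range: tuple[float, float] = (0.0, 1000.0),
    onset: float = 0.01,
    dur: float = 0.05,
    fs: float = 100e3,
    seed: int = 0,
) -> list[Stimulus]:
    """Batch of step pulses with amplitudes drawn uniformly from ``amp_range``."""
    rng = np.random.default_rng(seed)
    amps = rng.uniform(*amp_range, size=n_items)
    return [step_current(a, onset, dur, fs) for a in amps]


def speech_like_corpus(
    n_items: int,
    dur: float = 0.5,
    fs: float = 20e3,
    seed: int = 0,
    levels_dB: tuple[float, float] = (70.0, 130.0),
    n_bands: int = 8,
    f_lo: float = 100.0,
    f_hi: float = 8e3,
) -> list[Stimulus]:
    """Seeded synthetic broadband corpus with speech-like envelope statistics.

    Each item is pink-weighted noise in ``n_bands`` log-spaced bands, each band
    multiplied by an independent slow (2-10 Hz) raised envelope, summed and
    RMS-calibrated.  The first ``ceil(n/2)`` items are calibrated to the lower
    level and the rest to the higher level, so the corpus spans the two-level
    intensity range needed for a surrogate to learn saturation behaviour.
    """
    if n_items < 2:
        raise ValueError("need at least 2 corpus items (one per level)")
    rng = np.random.default_rng(seed)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    edges = np.geomspace(f_lo, min(f_hi, 0.45 * fs), n_bands + 1)
    n_low = (n_items + 1) // 2
    items = []
    for i in range(n_items):
        level = levels_dB[0] if i < n_low else levels_dB[1]
        spec = (rng.standard_normal(n // 2 + 1)
                + 1j * rng.standard_normal(n // 2 + 1))
        freqs = np.fft.rfftfreq(n, 1.0 / fs)
        x = np.zeros(n)
        for b in range(n_bands):
            mask = (freqs >= edges[b]) & (freqs < edges[b + 1])
            band = np.fft.irfft(np.where(mask, spec, 0.0), n)
            # pink weighting: ~1/sqrt(f) amplitude per band centre
            w = 1.0 / np.sqrt(np.sqrt(edges[b] * edges[b + 1]) / f_lo)
            fm_env = rng.uniform(2.0, 10.0)
            phase = rng.uniform(0, 2 * np.pi)
            env = 0.5 * (1.0 + np.sin(2 * np.pi * fm_env * t + phase))
            x += w * env * band
        x *= P0 * 10.0 ** (level / 20.0) / rms(x)
        items.append(Stimulus(x, fs, level, "corpus_item", meta={"index": i}))
    return items


# -- WAV persistence ---------------------------------------------------------
#
# WAV files are dimensionless; the sidecar JSON records the calibration
# constant (Pa per full scale) so levels survive a round trip.

def write_wav(stim: Stimulus, path: str | Path, pa_per_fullscale: float | None = None) -> None:
    path = Path(path)
    if pa_per_fullscale is None:
        peak = float(np.max(np.abs(stim.samples)))
        pa_per_fullscale = peak if peak > 0 else 1.0
    data = (stim.samples / pa_per_fullscale).astype(np.float32)
    wavfile.write(path, int(stim.fs), data)
    sidecar = {
        "pa_per_fullscale": pa_per_fullscale,
        "level_dB": stim.level_dB,
        "kind": stim.kind,
        "onset_s": stim.onset_s,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_wav(path: str | Path) -> Stimulus:
    path = Path(path)
    fs, data = wavfile.read(path)
    data = np.asarray(data, dtype=float)
    if data.dtype.kind == "i":  # pragma: no cover - dtype normalised above
        data = data / np.iinfo(data.dtype).max
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    else:
        sidecar = {"pa_per_fullscale": 1.0, "level_dB": None, "kind": "corpus_item",
                   "onset_s": 0.0}
    samples = data * sidecar["pa_per_fullscale"]
    return Stimulus(samples, float(fs), sidecar["level_dB"], sidecar["kind"],
                    onset_s=sidecar.get("onset_s", 0.0))
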