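"""Training-data conventions: resampling, scaling, padding, windowing, CF flattening.

The teacher chain is solved at 100 kHz and its outputs downsampled to the
20-kHz model rate; waveforms are rescaled into training units (displacement
x1e6, receptor potential x10, firing rate x1e-2) so the data have magnitudes
near unity; responses are sliced into 50%-overlap windows flanked by left and
right context (zero-filled beyond the signal edges); and the per-CF channels
of every item are flattened into independent single-channel training
sequences, because the IHC/ANF stages are assumed CF-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

from .containers import ResponseField

__all__ = [
    "resample_to_model_rate", "scale_signal", "unscale_signal", "add_silence",
    "slice_windows", "flatten_cf", "greenwood_cf_axis", "build_training_set",
    "TrainingWindowSet", "STAGE_SCALING",
]

#: Multiplicative factors taking raw units into training units.
STAGE_SCALING = {"bm": 1e6, "ihc": 10.0, "anf": 1e-2}


def resample_to_model_rate(x: np.ndarray, fs_in: float = 100e3,
                           fs_out: float = 20e3) -> np.ndarray:
    """Anti-aliased polyphase resampling (rational ratio), along axis 0.

    The anti-alias filter is an explicit zero-phase FIR (Kaiser beta 10,
    ~100 dB stopband, cutoff at 95% of the narrower Nyquist) rather than the
    short default, so aliased components stay below -60 dB; edges are
    extended linearly so constant offsets (resting potentials) survive
    without boundary ringing.
    """
    x = np.asarray(x, dtype=float)
    ratio = Fraction(fs_out / fs_in).limit_denominator(10000)
    if ratio == 1:
        return x.copy()
    up, down = ratio.numerator, ratio.denominator
    fs_hi = fs_in * up
    cutoff = 0.95 * min(fs_in, fs_out) / 2
    n_taps = 128 * max(up, down) + 1
    h = signal.firwin(n_taps, cutoff, fs=fs_hi, window=("kaiser", 10.0))
    return signal.resample_poly(x, up, down, axis=0, window=h, padtype="line")


def scale_signal(x: np.ndarray, stage: str) -> np.ndarray:
    """Raw units -> training units for stage in {bm, ihc, anf}."""
    if stage not in STAGE_SCALING:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGE_SCALING)}")
    return np.asarray(x, dtype=float) * STAGE_SCALING[stage]


def unscale_signal(x: np.ndarray, stage: str) -> np.ndarray:
    """Exact inverse of :func:`scale_signal`."""
    if stage not in STAGE_SCALING:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGE_SCALING)}")
    return np.asarray(x, dtype=float) / STAGE_SCALING[stage]


def add_silence(x: np.ndarray, fs: float, pre: float = 0.5, post: float = 1.0) -> np.ndarray:
    """Prepend/append exact zeros (axis 0), default 0.5 s before and 1 s after."""
    x = np.asarray(x, dtype=float)
    pad = [(int(round(pre * fs)), int(round(post * fs)))] + [(0, 0)] * (x.ndim - 1)
    return np.pad(x, pad)


def slice_windows(x: np.ndarray, L: int, L_l: int, L_r: int,
                  overlap: float = 0.5) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Slice a 1-D sequence into context-padded input windows.

    Hop is ``L * (1 - overlap)``; window count ``floor((len - L)/hop) + 1``.
    Each input window spans ``[start - L_l, start + L + L_r)`` with zeros
    beyond the signal edges; the returned index ranges ``(start, start + L)``
    locate each window's output (target) segment.  A sequence shorter than
    ``L`` yields a single zero-padded window with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("slice_windows expects a 1-D sequence")
    hop = int(round(L * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large: hop would be < 1 sample")
    n = len(x)
    if n < L:
        warnings.warn(f"sequence length {n} < window {L}; emitting one padded window")
        x = np.pad(x, (0, L - n))
        n = L
    n_win = (n - L) // hop + 1
    L_c = L_l + L + L_r
    xp = np.pad(x, (L_l, L_r))
    inputs = np.empty((n_win, L_c))
    ranges = []
    for i in range(n_win):
        start = i * hop
        inputs[i] = xp[start : start + L_c]
        ranges.append((start, start + L))
    return inputs, ranges


@dataclass
class TrainingWindowSet:
    """Paired, scaled, context-padded training windows with provenance."""

    inputs: np.ndarray    # (count, L_c)
    targets: np.ndarray   # (count, L)
    input_scaling: str
    target_scaling: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must pair up one-to-one")
        if not (np.all(np.isfinite(self.inputs)) and np.all(np.isfinite(self.targets))):
            raise ValueError("non-finite entries in training windows")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("inputs", data=self.inputs)
            f.create_dataset("targets", data=self.targets)
            f.attrs["input_scaling"] = self.input_scaling
            f.attrs["target_scaling"] = self.target_scaling
            for k, v in self.provenance.items():
                f.attrs[f"prov_{k}"] = v

    @classmethod
    def load(cls, path: str | Path) -> "TrainingWindowSet":
        with h5py.File(path, "r") as f:
            prov = {k[5:]: (v.item() if hasattr(v, "item") else v)
                    for k, v in f.attrs.items() if k.startswith("prov_")}
            return cls(f["inputs"][...], f["targets"][...],
                       str(f.attrs["input_scaling"]), str(f.attrs["target_scaling"]),
                       prov)


def flatten_cf(field_pairs: list[tuple[ResponseField, ResponseField]]
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Each CF channel of each paired field becomes one single-channel sequence.

    ``n_items`` paired fields with ``n_cf`` channels yield
    ``n_items * n_cf`` sequence pairs.
    """
    out = []
    for fin, ftgt in field_pairs:
        if fin.values.shape != ftgt.values.shape:
            raise ValueError(
                f"paired fields must share shape; got {fin.values.shape} vs "
                f"{ftgt.values.shape}")
        if not np.array_equal(fin.cf_axis, ftgt.cf_axis):
            raise ValueError("paired fields must share the CF axis")
        for c in range(fin.n_cf):
            out.append((fin.values[:, c], ftgt.values[:, c]))
    return out


def greenwood_cf_axis(n_cf: int = 201, f_min: float = 112.0,
                      f_max: float = 12e3) -> np.ndarray:
    """CFs uniform in the Greenwood place coordinate of the human cochlea.

    ``f(x) = A (10**(a x) - k)`` with the human constants A=165.4 Hz, a=2.1
    (x as fractional distance from apex), k=0.88; the place coordinates of
    ``f_min``/``f_max`` are inverted and sampled uniformly, so the endpoints
    match exactly.
    """
    if n_cf < 2:
        raise ValueError("need at least 2 CFs")
    if f_min >= f_max:
        raise ValueError("need f_min < f_max")
    A, a, k = 165.4, 2.1, 0.88

    def place(f):
        return np.log10(f / A + k) / a

    x = np.linspace(place(f_min), place(f_max), n_cf)
    cfs = A * (10.0 ** (a * x) - k)
    cfs[0], cfs[-1] = f_min, f_max
    return cfs


def build_training_set(corpus, teacher, spec, stage: str,
                       seed: int | None = None,
                       anf_silence: tuple[float, float] = (0.5, 1.0)
                       ) -> TrainingWindowSet:
    """Run the full data pipeline for one surrogate stage.

    ``corpus`` is a list of :class:`~periphnn.stimuli.Stimulus`; ``teacher``
    an :class:`~periphnn.reference.IHCTeacher` (stage ``"ihc"``: drive ->
    receptor potential) or :class:`~periphnn.reference.ANFTeacher` (stage
    ``"anf"``: receptor potential -> rate).  Stimuli are solved at 100 kHz,
    outputs downsampled to 20 kHz, scaled into training units, sliced into
    50%-overlap context windows per the ``spec`` geometry and flattened
    across CF.  For the ANF stage, silence (default 0.5 s before / 1 s
    after) is added to each stimulus before simulation so the windows carry
    adaptation and recovery behaviour.
    """
    if stage not in ("ihc", "anf"):
        raise ValueError("stage must be 'ihc' or 'anf'")
    in_stage = "bm" if stage == "ihc" else "ihc"
    pairs = []
    for stim in corpus:
        if stage == "anf":
            from dataclasses import replace

            padded = add_silence(stim.samples, stim.fs, *anf_silence)
            stim = replace(stim, samples=padded,
                           onset_s=stim.onset_s + anf_silence[0])
            fin = teacher.ihc_field(stim)
        else:
            fin = teacher.drive_field(stim)
        ftgt = teacher.respond(stim)
        fin = fin.with_values(scale_signal(fin.values, in_stage))
        ftgt = ftgt.with_values(scale_signal(ftgt.values, stage))
        pairs.append((fin, ftgt))
    sequences = flatten_cf(pairs)
    all_inputs, all_targets = [], []
    for x_in, x_tgt in sequences:
        wins_in, ranges = slice_windows(x_in, spec.L, spec.L_l, spec.L_r)
        tgt_padded = np.pad(x_tgt, (0, max(0, spec.L - len(x_tgt))))
        wins_tgt = np.stack([tgt_padded[a:b] for a, b in ranges])
        all_inputs.append(wins_in)
        all_targets.append(wins_tgt)
    return TrainingWindowSet(
        np.concatenate(all_inputs), np.concatenate(all_targets),
        input_scaling=in_stage, target_scaling=stage,
        provenance={"seed": -1 if seed is None else seed, "stage": stage,
                    "n_items": len(corpus), "n_cf": len(teacher.cf_axis),
                    "L": spec.L, "L_l": spec.L_l, "L_r": spec.L_r},
    )
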