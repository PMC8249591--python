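"""Shared in-memory containers: multichannel response fields and metric curves."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

#: Recognised unit/scaling tags for response fields.
UNIT_TAGS = {
    "m",            # basilar-membrane-like displacement, metres
    "um_scaled",    # displacement * 1e6
    "V",            # IHC receptor potential, volts
    "dV_scaled",    # potential * 10
    "spikes_per_s",     # ANF instantaneous rate
    "100spikes_scaled",  # rate * 1e-2
    "mV",           # membrane potential (HH axon)
    "raw",
}


@dataclass
class ResponseField:
    """A time x N_CF matrix of model outputs with an explicit CF axis and units.

    ``values`` has shape ``(n_samples, n_cf)``; single-channel responses use
    ``n_cf == 1``.  The CF axis must be strictly monotonic.
    """

    values: np.ndarray
    fs: float
    cf_axis: np.ndarray
    units: str = "raw"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.values.shape[1] > 1 and \
                len(np.atleast_1d(self.cf_axis)) == 1:
            self.values = self.values.T
        self.cf_axis = np.atleast_1d(np.asarray(self.cf_axis, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (time x n_cf)")
        if self.values.shape[1] != len(self.cf_axis):
            raise ValueError(
                f"n_cf mismatch: values have {self.values.shape[1]} channels, "
                f"cf_axis has {len(self.cf_axis)}")
        d = np.diff(self.cf_axis)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("cf_axis must be strictly monotonic")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("response values must be finite")
        if self.units not in UNIT_TAGS:
            raise ValueError(f"unknown units tag {self.units!r}")

    @property
    def n_cf(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, cf: float) -> np.ndarray:
        """Waveform of the channel whose CF is closest to ``cf``."""
        idx = int(np.argmin(np.abs(self.cf_axis - cf)))
        return self.values[:, idx]

    def with_values(self, values: np.ndarray, units: str | None = None) -> "ResponseField":
        return replace(self, values=values, units=units or self.units)

    def save(self, path: str | Path, name: str = "response") -> None:
        with h5py.File(path, "a") as f:
            if name in f:
                del f[name]
            g = f.create_group(name)
            g.create_dataset("values", data=self.values)
            g.create_dataset("cf_axis", data=self.cf_axis)
            g.attrs["fs"] = self.fs
            g.attrs["units"] = self.units

    @classmethod
    def load(cls, path: str | Path, name: str = "response") -> "ResponseField":
        with h5py.File(path, "r") as f:
            g = f[name]
            return cls(g["values"][...], float(g.attrs["fs"]), g["cf_axis"][...],
                       str(g.attrs["units"]))


@dataclass
class MetricCurve:
    """x/y arrays with units for one of the six evaluation metrics."""

    x: np.ndarray
    y: np.ndarray
    x_units: str
    y_units: str
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have equal length")
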