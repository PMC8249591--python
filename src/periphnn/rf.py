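"""Receptive-field arithmetic for strided convolutional encoders.

For an encoder of ``N`` conv layers with filter length ``k`` and stride ``s``
per layer, the receptive field of one bottleneck unit is

    r_N = sum_{n=1..N} (k - 1) * s**(n - 1)  +  1

which for ``s = 2`` collapses to ``(k - 1) * (2**N - 1) + 1``.  A surrogate of
a dynamical model can only represent adaptation over time spans shorter than
its receptive field, so the adaptation time of the model to be approximated
(times the sampling rate) sets a lower bound on ``r_N``; these helpers turn
that bound into (depth, kernel) suggestions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RFQuery", "receptive_field", "min_encoder_layers", "advise_architecture"]


@dataclass(frozen=True)
class RFQuery:
    n_layers: int
    kernel: int
    stride: int = 2
    target_rf: int | None = None

    def __post_init__(self):
        if self.n_layers < 1 or self.kernel < 1 or self.stride < 1:
            raise ValueError("need n_layers >= 1, kernel >= 1, stride >= 1")


def receptive_field(n_layers: int, kernel: int, stride: int = 2) -> int:
    """Receptive-field size (in input samples) of one bottleneck unit."""
    RFQuery(n_layers, kernel, stride)
    return sum((kernel - 1) * stride ** (n - 1) for n in range(1, n_layers + 1)) + 1


def min_encoder_layers(target_rf: int, kernel: int, stride: int = 2) -> int:
    """Smallest encoder depth whose receptive field strictly exceeds ``target_rf``."""
    if target_rf < 1:
        raise ValueError("target_rf must be >= 1")
    if kernel < 2 or stride < 1:
        raise ValueError("need kernel >= 2 for the receptive field to grow")
    n = 1
    while receptive_field(n, kernel, stride) <= target_rf:
        n += 1
    return n


def advise_architecture(
    adaptation_time: float,
    fs: float,
    kernel_options: list[int] = (8, 16, 32, 64, 128),
) -> list[dict]:
    """Suggest (depth, kernel) pairs whose receptive field covers an adaptation time.

    ``target_rf = ceil(adaptation_time * fs)`` samples; for each kernel option
    the minimal stride-2 encoder depth is returned together with the resulting
    receptive field and a recommended input window ``L`` (smallest multiple of
    ``2**N`` that is at least ``target_rf``, so the window is both long enough
    and divisible by the total downsampling factor).
    """
    if adaptation_time < 0:
        raise ValueError("adaptation_time must be non-negative")
    import math

    target_rf = max(1, math.ceil(adaptation_time * fs))
    out = []
    for k in kernel_options:
        n = min_encoder_layers(target_rf, k)
        rf = receptive_field(n, k)
        block = 2 ** n
        window = block * max(1, math.ceil(target_rf / block))
        out.append({
            "kernel": int(k),
            "n_layers": int(n),
            "rf_samples": int(rf),
            "rf_ms": 1e3 * rf / fs,
            "window_L": int(window),
            "target_rf": int(target_rf),
        })
    return out
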