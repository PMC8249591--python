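"""Encoder-decoder surrogate architectures with exact parameter accounting.

A surrogate maps an input window of ``L_c = L_l + L + L_r`` samples (output
window ``L`` plus left/right context) through ``n_total/2`` stride-2 encoder
convolutions and ``n_total/2`` stride-2 transposed decoder convolutions back
to ``L_c`` samples, after which the context is cropped away.  Skip
connections concatenate each encoder layer's (post-activation) output onto
the decoder layer of matching temporal resolution:

* decoder layer 1 receives the bottleneck alone (``F -> F`` channels),
* decoder layers ``2 .. N-1`` receive ``concat(previous decoder output,
  encoder layer N-j+1 output)`` (``2F -> F``),
* the final decoder layer receives a skip as well and maps ``2F -> 1`` with
  no activation.

This wiring, with biases in every conv layer and one PReLU slope per filter
channel, is what makes the closed-form trainable-parameter count in
:func:`count_trainable_params` exact, and is validated against built-network
introspection in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .containers import ResponseField

__all__ = [
    "SurrogateSpec", "preset_specs", "build_surrogate", "count_trainable_params",
    "crop_context", "extrapolate_channels", "merge_modules",
    "ConvEncoderDecoder", "MergedModel", "GeometryError",
]


class GeometryError(ValueError):
    """Incompatible window/context geometry between connected modules."""


@dataclass(frozen=True)
class SurrogateSpec:
    """Complete description of one encoder-decoder surrogate.

    ``L``: output window; ``L_l``/``L_r``: left/right context; ``n_total``:
    total conv layers (encoder + decoder, even); ``filters``: channels per
    hidden layer; ``kernel``: filter length; ``enc_act``/``dec_act``:
    activation tags.  The final decoder layer always has no activation and
    ``out_channels`` output channels.
    """

    L: int
    L_l: int
    L_r: int
    n_total: int
    filters: int
    kernel: int
    enc_act: str = "tanh"
    dec_act: str = "sigmoid"
    stride: int = 2
    out_channels: int = 1
    name: str = ""

    def __post_init__(self):
        if self.n_total % 2 or self.n_total < 4:
            raise ValueError("n_total must be even and >= 4")
        if self.enc_act not in nn.ACTIVATIONS or self.dec_act not in nn.ACTIVATIONS:
            raise ValueError("unknown activation tag")
        if self.L_c % self.stride ** self.n_enc:
            raise ValueError(
                f"L_c={self.L_c} must be divisible by {self.stride ** self.n_enc} "
                f"(stride**n_enc) so every encoder layer halves the window exactly")

    @property
    def L_c(self) -> int:
        return self.L_l + self.L + self.L_r

    @property
    def n_enc(self) -> int:
        return self.n_total // 2

    @property
    def bottleneck_len(self) -> int:
        return self.L_c // self.stride ** self.n_enc

    def to_dict(self) -> dict:
        return asdict(self)


def preset_specs() -> dict[str, SurrogateSpec]:
    """The published full-scale architectures for IHC and the three ANF types."""
    ihc = SurrogateSpec(L=2048, L_l=256, L_r=256, n_total=6, filters=128, kernel=16,
                        enc_act="tanh", dec_act="sigmoid", name="ihc")
    anf_geo = dict(L=8192, L_l=7936, L_r=256, n_total=28, filters=64, kernel=8)
    return {
        "ihc": ihc,
        "anf_h": SurrogateSpec(**anf_geo, enc_act="prelu", dec_act="prelu", name="anf_h"),
        "anf_m": SurrogateSpec(**anf_geo, enc_act="prelu", dec_act="prelu", name="anf_m"),
        "anf_l": SurrogateSpec(**anf_geo, enc_act="tanh", dec_act="sigmoid", name="anf_l"),
    }


def desk_scale_specs() -> dict[str, SurrogateSpec]:
    """Reduced geometries with the same layer structure, for desk-scale training."""
    return {
        "ihc_small": SurrogateSpec(L=512, L_l=64, L_r=64, n_total=6, filters=32,
                                   kernel=16, enc_act="tanh", dec_act="sigmoid",
                                   name="ihc_small"),
        "anf_small": SurrogateSpec(L=1024, L_l=960, L_r=64, n_total=12, filters=16,
                                   kernel=8, enc_act="tanh", dec_act="sigmoid",
                                   name="anf_small"),
    }


def count_trainable_params(spec: SurrogateSpec) -> int:
    """Closed-form trainable-parameter count, independent of any framework.

    encoder: ``(k*1*F + F) + (N-1)*(k*F^2 + F)``;
    decoder: ``(k*F^2 + F) + (N-2)*(k*2F*F + F) + (k*2F*out + out)``;
    plus one PReLU slope per channel for every activated layer whose
    activation is PReLU (encoder layers and the first ``N-1`` decoder layers).
    """
    N, F, k, out = spec.n_enc, spec.filters, spec.kernel, spec.out_channels
    if N < 2:
        raise ValueError("need at least 2 encoder layers")
    enc = (k * 1 * F + F) + (N - 1) * (k * F * F + F)
    dec = (k * F * F + F) + (N - 2) * (k * 2 * F * F + F) + (k * 2 * F * out + out)
    extra = 0
    if spec.enc_act == "prelu":
        extra += N * F
    if spec.dec_act == "prelu":
        extra += (N - 1) * F
    return enc + dec + extra


class ConvEncoderDecoder:
    """A built surrogate network: forward, analytic backward, (de)serialisation."""

    def __init__(self, spec: SurrogateSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        N, F, k, s = spec.n_enc, spec.filters, spec.kernel, spec.stride
        self.enc_convs, self.enc_acts = [], []
        in_ch = 1
        for _ in range(N):
            self.enc_convs.append(nn.Conv1d(in_ch, F, k, s, rng))
            self.enc_acts.append(nn.make_activation(spec.enc_act, F))
            in_ch = F
        self.dec_convs, self.dec_acts = [], []
        for j in range(1, N + 1):
            cin = F if j == 1 else 2 * F
            cout = spec.out_channels if j == N else F
            self.dec_convs.append(nn.ConvTranspose1d(cin, cout, k, s, rng))
            self.dec_acts.append(nn.Identity() if j == N
                                 else nn.make_activation(spec.dec_act, F))
        self._skip_cache = None

    # -- execution ----------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, T) -> (B, out_channels, T), T any multiple of 2**n_enc."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, None, :]
        if x.shape[2] % self.spec.stride ** self.spec.n_enc:
            raise GeometryError(
                f"input length {x.shape[2]} is not a multiple of "
                f"{self.spec.stride ** self.spec.n_enc}")
        enc_outs = []
        h = x
        for conv, act in zip(self.enc_convs, self.enc_acts):
            h = act.forward(conv.forward(h))
            enc_outs.append(h)
        N = self.spec.n_enc
        d = enc_outs[-1]
        for j in range(1, N + 1):
            if j >= 2:
                d = np.concatenate([d, enc_outs[N - j]], axis=1)
            d = self.dec_acts[j - 1].forward(self.dec_convs[j - 1].forward(d))
        self._skip_cache = True
        return d

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backpropagate an output gradient; returns the input gradient."""
        if self._skip_cache is None:
            raise RuntimeError("backward called before forward")
        N, F = self.spec.n_enc, self.spec.filters
        skip_grads = [None] * N  # gradient flowing into enc_outs[i] via skips
        g = gy
        for j in range(N, 0, -1):
            g = self.dec_convs[j - 1].backward(self.dec_acts[j - 1].backward(g))
            if j >= 2:
                g, g_skip = g[:, :F, :], g[:, F:, :]
                i = N - j
                skip_grads[i] = g_skip if skip_grads[i] is None else skip_grads[i] + g_skip
        # g now flows into enc_outs[-1] (the bottleneck input of decoder 1)
        skip_grads[N - 1] = g if skip_grads[N - 1] is None else skip_grads[N - 1] + g
        g = 0.0
        for i in range(N - 1, -1, -1):
            g = g + skip_grads[i] if skip_grads[i] is not None else g
            g = self.enc_convs[i].backward(self.enc_acts[i].backward(g))
        return g

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- parameters ---------------------------------------------------------

    def _layers(self):
        return [*self.enc_convs, *self.enc_acts, *self.dec_convs, *self.dec_acts]

    def param_pairs(self):
        return [(p, g) for layer in self._layers() for _, p, g in layer.params()]

    def zero_grad(self):
        for _, g in self.param_pairs():
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self.param_pairs())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.param_pairs()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.param_pairs(), weights, strict=True):
            p[...] = w

    def save(self, path) -> None:
        """Checkpoint: weights (npz) plus a framework-neutral JSON manifest."""
        import hashlib
        import json
        from pathlib import Path

        path = Path(path)
        weights = self.get_weights()
        np.savez(path, **{f"w{i}": w for i, w in enumerate(weights)})
        digest = hashlib.sha256(b"".join(w.tobytes() for w in weights)).hexdigest()
        manifest = {"spec": self.spec.to_dict(),
                    "shapes": [list(w.shape) for w in weights],
                    "sha256": digest}
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path) -> "ConvEncoderDecoder":
        import json
        from pathlib import Path

        path = Path(path)
        manifest = json.loads(path.with_suffix(".manifest.json").read_text())
        model = cls(SurrogateSpec(**manifest["spec"]))
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as z:
            model.set_weights([z[f"w{i}"] for i in range(len(z.files))])
        return model


def build_surrogate(spec: SurrogateSpec, seed: int = 0) -> ConvEncoderDecoder:
    """Construct a trainable network from a spec (seeded weight init)."""
    return ConvEncoderDecoder(spec, seed=seed)


def crop_context(output, L_l: int, L_r: int):
    """Remove left/right context samples: keeps ``[L_l, T - L_r)``.

    Accepts a 1-D array, a (batch, ch, time) array, or a ResponseField.
    """
    if isinstance(output, ResponseField):
        if L_r == 0:
            values = output.values[L_l:, :]
        else:
            values = output.values[L_l:-L_r, :]
        return output.with_values(values)
    x = np.asarray(output)
    T = x.shape[-1]
    if L_l == 0 and L_r == 0:
        return x
    if L_l + L_r >= T:
        raise GeometryError(f"contexts {L_l}+{L_r} do not fit in length {T}")
    return x[..., L_l : T - L_r]


def extrapolate_channels(model: ConvEncoderDecoder, field_values: np.ndarray) -> np.ndarray:
    """Apply a single-channel model independently to each CF channel.

    ``field_values`` has shape ``(time, n_cf)``; the trained weights are
    shared across channels, so the operation is exactly
    permutation-equivariant in the channel axis.  Returns ``(time, n_cf)``.
    """
    v = np.asarray(field_values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    batch = v.T[:, None, :]  # (n_cf, 1, time)
    out = model.forward(batch)
    return out[:, 0, :].T


def merge_modules(chain: list) -> "MergedModel":
    """Couple surrogates by feeding each model's un-cropped output to the next.

    Elements may be single models or lists of models (a parallel bank, e.g.
    the three fiber types fed by one IHC stage); a bank's outputs are stacked
    as separate output channels.  Cropping happens once, at the end, using
    the accumulated left/right context of all stages.
    """
    return MergedModel(chain)


class MergedModel:
    def __init__(self, chain: list):
        if not chain:
            raise GeometryError("empty chain")
        self.chain = list(chain)
        # accumulated context: one spec per stage (banks share a geometry)
        stage_specs = []
        for el in self.chain:
            if isinstance(el, (list, tuple)):
                geos = {(m.spec.L, m.spec.L_l, m.spec.L_r, m.spec.n_enc) for m in el}
                if len(geos) != 1:
                    raise GeometryError("parallel bank members must share geometry")
                stage_specs.append(el[0].spec)
            else:
                stage_specs.append(el.spec)
        self.stage_specs = stage_specs
        self.L_l_total = sum(s.L_l for s in stage_specs)
        self.L_r_total = sum(s.L_r for s in stage_specs)
        self.block = max(s.stride ** s.n_enc for s in stage_specs)
        self.spec = stage_specs[-1]

    def _flat(self):
        out = []
        for el in self.chain:
            out.extend(el if isinstance(el, (list, tuple)) else [el])
        return out

    @property
    def n_params(self) -> int:
        return sum(m.n_params for m in self._flat())

    def required_input(self) -> int:
        """Minimum input length (and divisibility) for a non-empty output."""
        need = self.L_l_total + self.L_r_total + self.block
        return -(-need // self.block) * self.block

    def forward(self, x: np.ndarray, crop: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, None, :]
        T = x.shape[2]
        if T % self.block:
            raise GeometryError(
                f"merged-model input length {T} must be a multiple of {self.block}")
        if crop and T <= self.L_l_total + self.L_r_total:
            raise GeometryError(
                f"input length {T} too short: stages consume {self.L_l_total} left + "
                f"{self.L_r_total} right context samples; need >= {self.required_input()}")
        h = x
        for el in self.chain:
            if isinstance(el, (list, tuple)):
                h = np.concatenate([m.forward(h) for m in el], axis=1)
            else:
                h = el.forward(h)
        if crop:
            h = crop_context(h, self.L_l_total, self.L_r_total)
        return h

    def __call__(self, x):
        return self.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backward through the whole chain (uncropped geometry only)."""
        g = gy
        for el in reversed(self.chain):
            if isinstance(el, (list, tuple)):
                parts = np.split(g, len(el), axis=1)
                g = sum(m.backward(p) for m, p in zip(el, parts))
            else:
                g = el.backward(g)
        return g
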