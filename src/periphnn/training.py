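"""Surrogate training (L1 loss, Adam) and backprop stimulus restoration.

Training minimises the mean absolute error between surrogate outputs (after
context cropping) and teacher targets, with a seeded 90/10 train/validation
split, early stopping on validation L1 and best-checkpoint restoration.

The restoration application trains a small preprocessor network so that a
"pathological" periphery model (reduced fiber population) driven by the
processed stimulus reproduces the output of the "normal" model driven by the
raw stimulus; the loss combines time-domain L1 with the L1 between magnitude
spectra, both backpropagated analytically through the frozen models.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .architecture import ConvEncoderDecoder, SurrogateSpec, build_surrogate, crop_context
from .datasets import TrainingWindowSet
from .nn import Adam

__all__ = [
    "TrainConfig", "l1_loss", "l1_loss_grad", "train_surrogate",
    "spectral_l1", "optimize_stimulus_preprocessor", "scale_population",
    "PopulationModel",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    loss: str = "L1"                  # or "L1_time_plus_spectrum"
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    patience: int = 20                # early stopping on validation L1
    val_fraction: float = 0.1
    checkpoint_every: int = 0         # epochs; 0 = never write to disk
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def l1_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute error."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.abs(pred - target)))


def l1_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """d(mean|pred - target|)/d pred (subgradient 0 at ties)."""
    return np.sign(pred - target) / pred.size


def spectral_l1(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """L1 between magnitude spectra of the last axis, and its gradient w.r.t. ``a``.

    Uses the full DFT; the gradient follows from ``d|X_k|/dx = Re(conj(X_k) /
    |X_k| * F_k)``, evaluated via an FFT of the weighted phase factors (and
    checked against finite differences in the tests).
    """
    A = np.fft.fft(a, axis=-1)
    B = np.fft.fft(b, axis=-1)
    magA, magB = np.abs(A), np.abs(B)
    loss = float(np.mean(np.abs(magA - magB)))
    w = np.sign(magA - magB) / magA.size
    safe = np.where(magA == 0, 1.0, magA)
    c = w * np.conj(A) / safe
    grad = np.real(np.fft.fft(c, axis=-1))
    return loss, grad


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train_surrogate(spec: SurrogateSpec, window_set: TrainingWindowSet,
                    config: TrainConfig | None = None,
                    log_path: str | Path | None = None
                    ) -> tuple[ConvEncoderDecoder, list[dict]]:
    """Train a surrogate on context-padded windows; returns (model, history).

    The loss is evaluated on the cropped output window (the context samples
    are free).  History rows carry epoch, train and validation L1; the model
    returned carries the best-validation weights.  Divergence (non-finite
    loss) aborts and restores the last finite checkpoint.
    """
    config = config or TrainConfig()
    if window_set.inputs.shape[1] != spec.L_c or window_set.targets.shape[1] != spec.L:
        raise ValueError(
            f"window geometry {window_set.inputs.shape[1]}/{window_set.targets.shape[1]}"
            f" does not match spec L_c={spec.L_c}, L={spec.L}")
    rng = np.random.default_rng(config.seed)
    model = build_surrogate(spec, seed=config.seed)
    opt = Adam(model.param_pairs(), lr=config.learning_rate)

    n = len(window_set)
    n_val = max(1, int(round(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X = window_set.inputs[:, None, :]
    Y = window_set.targets[:, None, :]

    def val_loss() -> float:
        out = model.forward(X[val_idx])
        return l1_loss(crop_context(out, spec.L_l, spec.L_r), Y[val_idx])

    history: list[dict] = []
    best = (np.inf, model.get_weights())
    bad_epochs = 0
    for epoch in range(config.epochs):
        train_losses = []
        for idx in _batches(len(train_idx), config.batch_size, rng):
            b = train_idx[idx]
            model.zero_grad()
            out = model.forward(X[b])
            pred = crop_context(out, spec.L_l, spec.L_r)
            loss = l1_loss(pred, Y[b])
            if not np.isfinite(loss):
                model.set_weights(best[1])
                raise RuntimeError(
                    f"training diverged at epoch {epoch}; restored best checkpoint")
            g = np.zeros_like(out)
            g[:, :, spec.L_l : spec.L_l + spec.L] = l1_loss_grad(pred, Y[b])
            model.backward(g)
            opt.step()
            train_losses.append(loss)
        vl = val_loss()
        history.append({"epoch": epoch, "train_l1": float(np.mean(train_losses)),
                        "val_l1": vl})
        if vl < best[0]:
            best = (vl, model.get_weights())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
        if config.checkpoint_every and config.checkpoint_dir and \
                (epoch + 1) % config.checkpoint_every == 0:
            Path(config.checkpoint_dir).mkdir(parents=True, exist_ok=True)
            model.save(Path(config.checkpoint_dir) / f"epoch{epoch:04d}.npz")
    model.set_weights(best[1])
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "train_l1", "val_l1"])
            writer.writeheader()
            writer.writerows(history)
    return model, history


def scale_population(rate_field: np.ndarray, n_fibers: int) -> np.ndarray:
    """Summed firing rate of ``n_fibers`` identical fibers (pointwise scaling)."""
    if n_fibers < 0:
        raise ValueError("fiber count must be non-negative")
    return np.asarray(rate_field, dtype=float) * n_fibers


@dataclass
class PopulationModel:
    """A frozen surrogate (or chain) whose output is scaled by a fiber count."""

    net: object          # ConvEncoderDecoder or MergedModel (uncropped forward)
    n_fibers: int

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x) * self.n_fibers

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy * self.n_fibers)


def optimize_stimulus_preprocessor(
    normal_model, pathological_model, corpus: np.ndarray,
    config: TrainConfig | None = None,
    preprocessor_spec: SurrogateSpec | None = None,
    spectral_weight: float = 1.0,
) -> tuple[ConvEncoderDecoder, dict]:
    """Train a preprocessor so the pathological chain mimics the normal one.

    ``corpus`` is an array of input windows (n, T), already in the input
    units/scaling of the models (e.g. amplitude-normalised 4-kHz tones of
    varied levels and modulation depths).  Both models must support
    ``forward``/``backward`` (differentiable); the preprocessor ``x -> x_hat``
    is trained so that ``pathological(x_hat)`` matches ``normal(x)`` under
    time-domain L1 plus magnitude-spectrum L1.

    Returns the trained preprocessor and a report with the unprocessed
    baseline loss and the final loss.
    """
    config = config or TrainConfig(learning_rate=1e-3, epochs=60, batch_size=8)
    corpus = np.asarray(corpus, dtype=float)
    if corpus.ndim == 2:
        corpus = corpus[:, None, :]
    T = corpus.shape[2]
    if preprocessor_spec is None:
        preprocessor_spec = SurrogateSpec(L=T, L_l=0, L_r=0, n_total=4, filters=8,
                                          kernel=8, enc_act="tanh", dec_act="tanh",
                                          name="preprocessor")
    for m in (normal_model, pathological_model):
        if not (hasattr(m, "forward") and hasattr(m, "backward")):
            raise TypeError("models must be differentiable (forward/backward)")
    pre = build_surrogate(preprocessor_spec, seed=config.seed)
    opt = Adam(pre.param_pairs(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    targets = normal_model.forward(corpus)  # frozen reference responses

    def chain_loss(x_hat: np.ndarray, target: np.ndarray, backprop: bool) -> float:
        r_hat = pathological_model.forward(x_hat)
        lt = l1_loss(r_hat, target)
        ls, gs = spectral_l1(r_hat, target)
        if backprop:
            g = l1_loss_grad(r_hat, target) + spectral_weight * gs
            gx = pathological_model.backward(g)
            pre.backward(gx)
        return lt + spectral_weight * ls

    baseline = float(np.mean([chain_loss(corpus[[i]], targets[[i]], False)
                              for i in range(len(corpus))]))
    history = []
    for epoch in range(config.epochs):
        losses = []
        for idx in _batches(len(corpus), config.batch_size, rng):
            pre.zero_grad()
            x = corpus[idx]
            x_hat = pre.forward(x)
            losses.append(chain_loss(x_hat, targets[idx], True))
            opt.step()
        history.append(float(np.mean(losses)))
    final = float(np.mean([chain_loss(pre.forward(corpus[[i]]), targets[[i]], False)
                           for i in range(len(corpus))]))
    report = {"baseline_loss": baseline, "final_loss": final, "history": history,
              "improved": final < baseline}
    return pre, report
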