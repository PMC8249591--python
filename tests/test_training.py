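import numpy as np
import pytest

from periphnn.architecture import (SurrogateSpec, build_surrogate, crop_context,
                                   merge_modules)
from periphnn.datasets import TrainingWindowSet, slice_windows
from periphnn.training import (TrainConfig, l1_loss, l1_loss_grad,
                               optimize_stimulus_preprocessor, scale_population,
                               spectral_l1, train_surrogate, PopulationModel)

TOY_SPEC = SurrogateSpec(L=64, L_l=16, L_r=16, n_total=4, filters=8, kernel=8,
                         enc_act="tanh", dec_act="tanh")


def _toy_window_set(n_samples=4000, seed=0):
    """Teacher = 3-tap linear filter; target for the convergence smoke test."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_samples) * 0.3
    y = np.convolve(x, [0.5, -0.3, 0.2], mode="same")
    wins, ranges = slice_windows(x, TOY_SPEC.L, TOY_SPEC.L_l, TOY_SPEC.L_r)
    tgts = np.stack([y[a:b] for a, b in ranges])
    return TrainingWindowSet(wins, tgts, "bm", "ihc")


class TestL1Loss:
    def test_identical_arrays_zero(self):
        x = np.arange(10.0)
        assert l1_loss(x, x) == 0.0

    def test_constant_offset(self):
        x = np.arange(10.0)
        assert l1_loss(x + 0.7, x) == pytest.approx(0.7)

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(100), rng.standard_normal(100)
        brute = sum(abs(ai - bi) for ai, bi in zip(a, b)) / 100
        assert l1_loss(a, b) == pytest.approx(brute, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros(3), np.zeros(4))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        g = l1_loss_grad(a, b)
        eps = 1e-7
        for i in range(0, 20, 5):
            ap, am = a.copy(), a.copy()
            ap[i] += eps
            am[i] -= eps
            assert g[i] == pytest.approx(
                (l1_loss(ap, b) - l1_loss(am, b)) / (2 * eps), rel=1e-4)


def test_spectral_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(5)
    a, b = rng.standard_normal(32), rng.standard_normal(32)
    _, g = spectral_l1(a, b)
    eps = 1e-6
    for i in range(0, 32, 7):
        ap, am = a.copy(), a.copy()
        ap[i] += eps
        am[i] -= eps
        fd = (spectral_l1(ap, b)[0] - spectral_l1(am, b)[0]) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)


class TestTrainSurrogate:
    def test_toy_linear_teacher_convergence(self):
        ws = _toy_window_set()
        cfg = TrainConfig(learning_rate=3e-3, epochs=200, batch_size=16, seed=2,
                          patience=200)
        _, history = train_surrogate(TOY_SPEC, ws, cfg)
        best = min(h["val_l1"] for h in history)
        target_rms = float(np.sqrt((ws.targets ** 2).mean()))
        assert best < 0.05 * target_rms

    def test_same_seed_identical_history(self):
        ws = _toy_window_set()
        cfg = TrainConfig(learning_rate=3e-3, epochs=5, batch_size=16, seed=2)
        _, h1 = train_surrogate(TOY_SPEC, ws, cfg)
        _, h2 = train_surrogate(TOY_SPEC, ws, cfg)
        assert h1 == h2

    def test_loss_history_improves(self):
        ws = _toy_window_set()
        cfg = TrainConfig(learning_rate=3e-3, epochs=30, batch_size=16, seed=2,
                          patience=30)
        _, history = train_surrogate(TOY_SPEC, ws, cfg)
        assert history[-1]["val_l1"] <= history[0]["val_l1"]

    def test_geometry_mismatch_rejected(self):
        ws = _toy_window_set()
        other = SurrogateSpec(L=128, L_l=0, L_r=0, n_total=4, filters=8, kernel=8)
        with pytest.raises(ValueError):
            train_surrogate(other, ws, TrainConfig(epochs=1))

    def test_training_log_written(self, tmp_path):
        ws = _toy_window_set()
        cfg = TrainConfig(learning_rate=3e-3, epochs=2, batch_size=16, seed=2)
        train_surrogate(TOY_SPEC, ws, cfg, log_path=tmp_path / "log.csv")
        lines = (tmp_path / "log.csv").read_text().strip().splitlines()
        assert lines[0] == "epoch,train_l1,val_l1" and len(lines) == 3


def test_windowed_outputs_agree_on_overlap_for_trained_model(
        trained_ihc, desk_ihc_spec, desk_window_set):
    """Context sufficiency: hop-shifted windows of a trained surrogate agree on
    their overlap (documented tolerance: 10% of the output standard deviation)."""
    model, _ = trained_ihc
    spec = desk_ihc_spec
    seq = desk_window_set.inputs[0]  # one L_c window; build a longer signal
    rng = np.random.default_rng(0)
    x = np.concatenate([seq, desk_window_set.inputs[5], desk_window_set.inputs[9]])
    hop = spec.L // 2
    xp = np.pad(x, (spec.L_l, spec.L_r))

    def window_out(start):
        win = xp[start : start + spec.L_c]
        out = model.forward(win[None, None, :])[0, 0]
        return crop_context(out, spec.L_l, spec.L_r)

    a = window_out(0)
    b = window_out(hop)
    overlap_a, overlap_b = a[hop:], b[: spec.L - hop]
    scale = np.std(np.concatenate([a, b]))
    assert np.sqrt(np.mean((overlap_a - overlap_b) ** 2)) < 0.10 * scale


class TestScalePopulation:
    def test_fiber_count_linear(self):
        r = np.array([1.0, 2.0])
        assert np.array_equal(scale_population(r, 10), 2 * scale_population(r, 5))
        assert np.all(scale_population(r, 0) == 0.0)

    def test_additive_in_rate(self):
        a, b = np.array([1.0, 2.0]), np.array([3.0, 4.0])
        assert np.array_equal(scale_population(a, 7) + scale_population(b, 7),
                              scale_population(a + b, 7))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            scale_population(np.zeros(2), -1)


@pytest.fixture(scope="module")
def frozen_net():
    return build_surrogate(TOY_SPEC, seed=8)


class TestStimulusRestoration:
    def test_identical_models_trained_toward_identity(self, frozen_net):
        """With identical normal/pathological models the unprocessed baseline is
        zero and training drives the preprocessor toward the identity."""
        rng = np.random.default_rng(0)
        corpus = rng.standard_normal((6, TOY_SPEC.L_c)) * 0.3
        cfg = TrainConfig(learning_rate=2e-3, epochs=25, batch_size=4, seed=1)
        _, report = optimize_stimulus_preprocessor(frozen_net, frozen_net, corpus, cfg)
        assert report["baseline_loss"] == pytest.approx(0.0, abs=1e-12)
        assert report["final_loss"] < report["history"][0]

    def test_population_mismatch_reduced_below_baseline(self, frozen_net):
        rng = np.random.default_rng(1)
        corpus = rng.standard_normal((6, TOY_SPEC.L_c)) * 0.3
        normal = PopulationModel(frozen_net, 10)
        patho = PopulationModel(frozen_net, 8)
        cfg = TrainConfig(learning_rate=2e-3, epochs=40, batch_size=4, seed=1)
        _, report = optimize_stimulus_preprocessor(normal, patho, corpus, cfg)
        assert report["final_loss"] < report["baseline_loss"]

    def test_non_differentiable_model_rejected(self):
        with pytest.raises(TypeError):
            optimize_stimulus_preprocessor(object(), object(), np.zeros((2, 32)))


def test_gradient_flows_through_merged_chain():
    spec = SurrogateSpec(L=32, L_l=8, L_r=8, n_total=4, filters=4, kernel=8)
    chain = merge_modules([build_surrogate(spec, seed=1),
                           build_surrogate(spec, seed=2)])
    x = np.random.default_rng(0).standard_normal((1, 1, 96)) * 0.2
    y = chain.forward(x, crop=False)
    gx = chain.backward(np.ones_like(y))
    assert gx.shape == x.shape and np.all(np.isfinite(gx)) and np.any(gx != 0)
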