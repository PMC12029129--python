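"""Training-protocol tests: AdamW, accumulation, early stopping, checkpoints."""

import numpy as np
import pytest

from nmrquant.models import MlpConfig, build_model
from nmrquant.nn import Tensor
from nmrquant.objectives import make_loss
from nmrquant.reference import MultipletSpec, MetaboliteLibrary, make_ppm_grid, synth_reference, tsp_reference
from nmrquant.simulator import AugmentationConfig, build_dataset
from nmrquant.distributions import ConcentrationSampler
from nmrquant.training import (
    AdamW,
    TrainConfig,
    baseline_presets,
    load_checkpoint,
    save_checkpoint,
    train,
)
from nmrquant.workflows import nnls_concentrations


@pytest.fixture(scope="module")
def toy_linear_problem():
    """Three metabolites with non-overlapping singlets: linearly solvable."""
    grid = make_ppm_grid(0.0, 10.0, 1500)
    refs = [
        synth_reference(f"m{i}", [MultipletSpec(center=c, n_protons=2, linewidth=8.0)],
                        grid, 400.0)
        for i, c in enumerate((2.0, 5.0, 8.0))
    ]
    lib = MetaboliteLibrary(grid=grid, references=refs, field_strength=400.0,
                            tsp=tsp_reference(grid, 400.0))
    ds = build_dataset(lib, 300, ConcentrationSampler("uniform"),
                       augmentation=AugmentationConfig.disabled(), seed=4,
                       dtype=np.float32)
    return lib, ds


def small_train_config(**kw):
    base = dict(loss="rae", learning_rate=1e-3, effective_batch_size=32,
                accumulation_steps=4, patience=50, max_epochs=10, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestAccumulation:
    def test_accumulated_gradient_equals_full_batch(self, rng):
        """4 x 16 accumulated sub-batches give the 64-batch gradient (MSE)."""
        cfg = MlpConfig(n_input=50, hidden_sizes=(10,), n_output=3)
        X = rng.normal(size=(64, 50))
        Y = rng.normal(size=(64, 3))
        loss_fn = make_loss("mse")

        model = build_model(cfg, seed=9, dtype=np.float64)
        loss_fn(model(X), Y).backward()
        full = [p.grad.copy() for p in model.parameters()]

        model2 = build_model(cfg, seed=9, dtype=np.float64)
        for k in range(4):
            sub = slice(16 * k, 16 * (k + 1))
            (loss_fn(model2(X[sub]), Y[sub]) * (16 / 64)).backward()
        acc = [p.grad for p in model2.parameters()]
        for g1, g2 in zip(full, acc):
            np.testing.assert_allclose(g1, g2, rtol=1e-6)

    def test_batch_size_must_divide_by_accumulation(self):
        with pytest.raises(ValueError, match="divisible"):
            TrainConfig(effective_batch_size=30, accumulation_steps=4)


class TestEarlyStopping:
    def test_patience_arithmetic_with_frozen_model(self, toy_linear_problem):
        """lr = 0 never improves after epoch 0, so training stops after
        exactly `patience` further epochs with the epoch-0 checkpoint."""
        _, ds = toy_linear_problem
        cfg = small_train_config(learning_rate=0.0, patience=5, max_epochs=100)
        trained = train(MlpConfig(n_input=1500, hidden_sizes=(8,), n_output=3), ds, cfg)
        assert trained.best_epoch == 0
        assert len(trained.history) == 6  # epoch 0 + 5 patience epochs

    def test_checkpoint_is_best_validation(self, toy_linear_problem):
        _, ds = toy_linear_problem
        cfg = small_train_config(max_epochs=15)
        trained = train(MlpConfig(n_input=1500, hidden_sizes=(16,), n_output=3), ds, cfg)
        vals = [h["val_loss"] for h in trained.history]
        assert trained.best_val_loss == pytest.approx(min(vals))
        assert trained.history[trained.best_epoch]["val_loss"] == pytest.approx(min(vals))

    def test_stop_callback_interrupts(self, toy_linear_problem):
        _, ds = toy_linear_problem
        cfg = small_train_config(max_epochs=50)
        trained = train(
            MlpConfig(n_input=1500, hidden_sizes=(8,), n_output=3), ds, cfg,
            stop_callback=lambda epoch, val: epoch >= 3,
        )
        assert len(trained.history) == 4


class TestConvergence:
    def test_mlp_solves_linear_toy_problem(self, toy_linear_problem):
        """Validation RAE falls below 0.05 on a linearly solvable mixture,
        approaching the exact NNLS solution."""
        lib, ds = toy_linear_problem
        cfg = small_train_config(learning_rate=1e-3, max_epochs=200,
                                 effective_batch_size=64)
        trained = train(MlpConfig(n_input=1500, hidden_sizes=(200,), n_output=3), ds, cfg)
        assert trained.best_val_loss < 0.05
        # NNLS is the exact solution of this clean linear problem
        X_val, Y_val = ds.val_arrays()
        from nmrquant.evaluation import mape_per_spectrum

        oracle = nnls_concentrations(lib, X_val, norm_constant=ds.norm_constant)
        assert mape_per_spectrum(oracle, Y_val).mean() < 0.1

    def test_training_is_reproducible(self, toy_linear_problem):
        _, ds = toy_linear_problem
        cfg = small_train_config(max_epochs=5)
        mc = MlpConfig(n_input=1500, hidden_sizes=(8,), n_output=3)
        a = train(mc, ds, cfg)
        b = train(mc, ds, cfg)
        assert [h["val_loss"] for h in a.history] == [h["val_loss"] for h in b.history]
        for p1, p2 in zip(a.model.state_arrays(), b.model.state_arrays()):
            np.testing.assert_array_equal(p1, p2)


class TestGuards:
    def test_non_finite_loss_aborts_with_diagnostic(self, toy_linear_problem):
        _, ds = toy_linear_problem
        X, Y = ds.train_arrays()
        X = X.copy()
        X[0, 0] = np.nan
        cfg = small_train_config(max_epochs=3)
        with pytest.raises(RuntimeError, match="epoch 0"):
            train(MlpConfig(n_input=1500, hidden_sizes=(8,), n_output=3),
                  (X, Y, *ds.val_arrays()), cfg)


class TestPresets:
    def test_baseline_values(self):
        p = baseline_presets()
        assert p["mlp-base"].learning_rate == 1e-3
        assert p["mlp-base"].effective_batch_size == 169
        assert p["cnn-base"].learning_rate == 5.3e-5
        assert p["cnn-base"].effective_batch_size == 64
        assert p["tx-base"].learning_rate == 1.5e-4
        assert p["tx-base"].effective_batch_size == 76

    def test_optimized_values(self):
        p = baseline_presets()
        assert p["mlp-opt"].learning_rate == 2.1e-3
        assert p["mlp-opt"].effective_batch_size == 124
        assert p["cnn-opt"].learning_rate == 2.1e-5
        assert p["cnn-opt"].loss.name == "quantile" and p["cnn-opt"].loss.q == 0.5
        assert p["tx-opt"].learning_rate == 5.0e-4
        assert p["tx-opt"].effective_batch_size == 244
        assert p["tx-opt"].weight_decay == 9.6e-3

    def test_all_presets_satisfy_invariants(self):
        for name, cfg in baseline_presets().items():
            assert cfg.patience >= 1
            assert cfg.effective_batch_size % cfg.accumulation_steps == 0, name
            assert cfg.weight_decay >= 0

    def test_epoch_caps_per_architecture(self):
        p = baseline_presets()
        assert p["mlp-base"].max_epochs == 5000
        assert p["cnn-base"].max_epochs == 500
        assert p["tx-base"].max_epochs == 1000


class TestCheckpoint:
    def test_save_load_round_trip(self, toy_linear_problem, tmp_path):
        _, ds = toy_linear_problem
        cfg = small_train_config(max_epochs=3)
        trained = train(MlpConfig(n_input=1500, hidden_sizes=(8,), n_output=3), ds, cfg)
        save_checkpoint(trained, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        X_val, _ = ds.val_arrays()
        np.testing.assert_allclose(back.predict(X_val), trained.predict(X_val),
                                   rtol=1e-6)
        assert back.best_epoch == trained.best_epoch
        assert len(back.history) == len(trained.history)


class TestAdamW:
    def test_decoupled_weight_decay_shrinks_unused_weights(self):
        """A parameter with zero gradient still decays toward zero."""
        p = Tensor(np.ones(3), requires_grad=True)
        opt = AdamW([p], lr=0.1, wd=0.5)
        p.grad = np.zeros(3)
        for _ in range(10):
            opt.step()
        assert np.all(p.data < 1.0) and np.all(p.data > 0.0)
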