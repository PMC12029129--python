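"""Optimization protocol: AdamW, gradient accumulation, early stopping.

Models train with decoupled weight decay (AdamW), an effective batch size
realized as several accumulated sub-batches per optimizer step, and early
stopping once a configurable number of epochs pass without a new best
validation loss.  The checkpoint returned is always the best-validation one.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .models import build_model, config_from_dict, config_to_dict
from .nn import Module, Tensor, no_grad
from .objectives import LossSpec, make_loss

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "AdamW",
    "train",
    "baseline_presets",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: Epoch caps per architecture kind.
DEFAULT_MAX_EPOCHS = {"mlp": 5000, "cnn": 500, "transformer": 1000}


@dataclass
class TrainConfig:
    loss: LossSpec = field(default_factory=lambda: LossSpec("rae"))
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    effective_batch_size: int = 64
    accumulation_steps: int = 4
    patience: int = 50
    max_epochs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.loss, str):
            self.loss = LossSpec(self.loss)
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.effective_batch_size % self.accumulation_steps != 0:
            raise ValueError(
                f"effective batch size {self.effective_batch_size} must be divisible "
                f"by accumulation_steps {self.accumulation_steps}"
            )


@dataclass
class TrainedModel:
    """A fitted model: config, weights, per-epoch history, best epoch."""

    model: Module
    model_config: object
    train_config: TrainConfig
    history: list[dict]
    best_epoch: int
    best_val_loss: float

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return predict(self.model, X, batch_size)


class AdamW:
    """Adam with decoupled weight decay (regularization constant ``wd``)."""

    def __init__(self, params: list[Tensor], lr: float, wd: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, wd
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def predict(model: Module, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Batched inference without graph construction."""
    outs = []
    with no_grad():
        for start in range(0, len(X), batch_size):
            outs.append(model(X[start : start + batch_size]).data)
    return np.concatenate(outs, axis=0)


def _accumulated_step(model, loss_fn, optimizer, Xb, Yb, n_sub: int):
    """One optimizer step over an effective batch split into sub-batches.

    Each sub-batch loss is weighted by its share of the effective batch so
    that, for mean-type losses, the accumulated gradient equals the gradient
    of the loss over the whole effective batch.
    """
    optimizer.zero_grad()
    n = len(Xb)
    bounds = np.linspace(0, n, n_sub + 1).astype(int)
    total = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        if a == b:
            continue
        weight = (b - a) / n
        out = model(Xb[a:b])
        l = loss_fn(out, Yb[a:b]) * weight
        l.backward()
        total += float(l.data)
    optimizer.step()
    return total


def train(
    model_config,
    dataset,
    train_config: TrainConfig,
    log_path: str | Path | None = None,
    verbose: bool = False,
    stop_callback=None,
) -> TrainedModel:
    """Fit a model on a :class:`~nmrquant.simulator.SpectralDataset`.

    ``dataset`` may also be a tuple ``(X_train, Y_train, X_val, Y_val)``.
    ``stop_callback(epoch, val_loss)`` (if given) is consulted after every
    epoch; returning True terminates training early (used for trial pruning).
    Raises ``RuntimeError`` with the epoch and batch index if the training
    loss goes non-finite.
    """
    if isinstance(dataset, tuple):
        X_train, Y_train, X_val, Y_val = dataset
    else:
        X_train, Y_train = dataset.train_arrays()
        X_val, Y_val = dataset.val_arrays()
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    model = build_model(model_config, seed=cfg.seed)
    loss_fn = make_loss(cfg.loss)
    optimizer = AdamW(model.parameters(), cfg.learning_rate, cfg.weight_decay)
    best_val = np.inf
    best_epoch = -1
    best_state: list[np.ndarray] | None = None
    history: list[dict] = []
    log_fh = open(log_path, "w") if log_path else None
    t0 = time.time()
    try:
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(X_train))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(X_train), cfg.effective_batch_size):
                idx = order[start : start + cfg.effective_batch_size]
                batch_loss = _accumulated_step(
                    model, loss_fn, optimizer, X_train[idx], Y_train[idx],
                    cfg.accumulation_steps,
                )
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {n_batches}"
                    )
                epoch_loss += batch_loss
                n_batches += 1
            train_loss = epoch_loss / max(n_batches, 1)
            with no_grad():
                val_loss = float(loss_fn(model(X_val), Y_val).data)
            record = {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "elapsed_s": time.time() - t0,
            }
            history.append(record)
            if log_fh:
                log_fh.write(json.dumps(record) + "\n")
                log_fh.flush()
            if verbose:
                print(f"epoch {epoch:4d}  train {train_loss:.5f}  val {val_loss:.5f}")
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_state = [p.copy() for p in model.state_arrays()]
            elif epoch - best_epoch >= cfg.patience:
                break
            if stop_callback is not None and stop_callback(epoch, val_loss):
                break
    finally:
        if log_fh:
            log_fh.close()
    if best_state is not None:
        model.load_state_arrays(best_state)
    return TrainedModel(
        model=model,
        model_config=model_config,
        train_config=cfg,
        history=history,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
    )


def baseline_presets() -> dict[str, TrainConfig]:
    """The hand-chosen and optimized training configurations by preset name.

    Batch sizes are effective batch sizes (accumulated over 4 sub-batches);
    epoch caps follow the per-architecture limits.  Optimized presets carry
    their tuned regularization constants.
    """
    return {
        "mlp-base": TrainConfig(LossSpec("rae"), 1e-3, 0.01, 169, 1,
                                50, DEFAULT_MAX_EPOCHS["mlp"]),
        "cnn-base": TrainConfig(LossSpec("rae"), 5.3e-5, 0.01, 64, 4,
                                50, DEFAULT_MAX_EPOCHS["cnn"]),
        "tx-base": TrainConfig(LossSpec("rae"), 1.5e-4, 0.01, 76, 4,
                               50, DEFAULT_MAX_EPOCHS["transformer"]),
        "mlp-opt": TrainConfig(LossSpec("rae"), 2.1e-3, 9.4e-3, 124, 4,
                               50, DEFAULT_MAX_EPOCHS["mlp"]),
        "cnn-opt": TrainConfig(LossSpec("quantile", q=0.5), 2.1e-5, 5.0e-3, 64, 4,
                               50, DEFAULT_MAX_EPOCHS["cnn"]),
        "tx-opt": TrainConfig(LossSpec("rae"), 5.0e-4, 9.6e-3, 244, 4,
                              50, DEFAULT_MAX_EPOCHS["transformer"]),
    }


def save_checkpoint(trained: TrainedModel, path: str | Path) -> None:
    """Single-file archive: config + weights + history."""
    meta = {
        "model_config": config_to_dict(trained.model_config),
        "train_config": {**asdict(trained.train_config),
                         "loss": asdict(trained.train_config.loss)},
        "history": trained.history,
        "best_epoch": trained.best_epoch,
        "best_val_loss": trained.best_val_loss,
    }
    arrays = {f"param_{i}": a for i, a in enumerate(trained.model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        arrays = [archive[f"param_{i}"] for i in range(len(archive.files) - 1)]
    model_config = config_from_dict(meta["model_config"])
    tc = dict(meta["train_config"])
    lw = tc["loss"]
    tc["loss"] = LossSpec(lw["name"], lw["q"], tuple(lw["mix_weights"]))
    train_config = TrainConfig(**tc)
    model = build_model(model_config, seed=train_config.seed)
    model.load_state_arrays(arrays)
    return TrainedModel(
        model=model,
        model_config=model_config,
        train_config=train_config,
        history=meta["history"],
        best_epoch=meta["best_epoch"],
        best_val_loss=meta["best_val_loss"],
    )
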