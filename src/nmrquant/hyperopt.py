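"""Hyperparameter search: search spaces, trial pruning and the tuning loop.

Search ranges mirror the full study: layer counts, kernel geometry, embedding
and binning sizes, with learning rate and regularization sampled
log-uniformly.  The sampler is pluggable behind a one-method interface;
the package ships a seeded random-search sampler, and any sequential
model-based sampler with the same ``suggest`` signature can be dropped in.

Pruning supports two rules: a median rule (stop a trial whose validation loss
at an epoch is worse than the median of previous trials at that epoch) and a
threshold rule (stop once the loss is still above a bound after a given
epoch).  The bound/epoch constants are loss-scale-dependent configuration,
not transferable truths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import CnnConfig, MlpConfig, TransformerConfig
from .objectives import LossSpec, make_loss
from .training import TrainConfig, train
from .evaluation import mape_per_spectrum

__all__ = [
    "SearchSpace",
    "PruneRule",
    "RandomSampler",
    "sample_config",
    "should_prune",
    "tune",
    "default_search_space",
    "default_prune_rule",
]


@dataclass
class SearchSpace:
    """Named parameter ranges for one architecture.

    ``int_ranges``: name -> (lo, hi) inclusive integer bounds.
    ``log_ranges``: name -> (lo, hi) sampled log-uniformly.
    ``choices``: name -> explicit option list.
    """

    architecture: str
    int_ranges: dict = field(default_factory=dict)
    log_ranges: dict = field(default_factory=dict)
    choices: dict = field(default_factory=dict)


def default_search_space(architecture: str) -> SearchSpace:
    """The study's search ranges for ``mlp``, ``cnn`` or ``transformer``."""
    if architecture == "mlp":
        return SearchSpace(
            "mlp",
            int_ranges={"n_hidden_layers": (1, 4), "hidden_nodes": (10, 1000),
                        "batch_size": (64, 1024)},
            log_ranges={"learning_rate": (1e-5, 1e-1), "weight_decay": (1e-6, 1e-2)},
            choices={"activation": ["relu", "leakyrelu", "elu"]},
        )
    if architecture == "cnn":
        return SearchSpace(
            "cnn",
            int_ranges={"n_conv_blocks": (1, 4), "kernel_size": (3, 12),
                        "kernel_stride": (1, 8), "channels": (5, 50),
                        "pooling_stride": (1, 2), "feedforward_size": (100, 250),
                        "batch_size": (64, 512)},
            log_ranges={"learning_rate": (1e-6, 1e-2), "weight_decay": (1e-6, 1e-2)},
            choices={"pooling": ["none", "max", "average"]},
        )
    if architecture == "transformer":
        return SearchSpace(
            "transformer",
            int_ranges={"n_encoder_layers": (1, 9), "batch_size": (32, 512)},
            log_ranges={"learning_rate": (1e-6, 1e-2), "weight_decay": (1e-6, 1e-2)},
            choices={"bin_size": [100, 200, 500, 1000, 2000],
                     "embed_dim": [256, 512, 1024],
                     "n_heads": [1, 2, 4, 8, 16],
                     "n_head_layers": [1, 2],
                     "feedforward_dim": [512, 1024, 2048]},
        )
    raise ValueError(f"unknown architecture {architecture!r}")


class RandomSampler:
    """Seeded uniform random search over a :class:`SearchSpace`.

    Implements the pluggable sampler interface: ``suggest(space, rng, trials)``
    returns a flat parameter dict.  ``trials`` (the table of completed trials)
    is accepted so sequential model-based samplers are drop-in replacements,
    but random search ignores it.
    """

    def suggest(self, space: SearchSpace, rng: np.random.Generator,
                trials: pd.DataFrame | None = None) -> dict:
        params: dict = {}
        for name, (lo, hi) in space.int_ranges.items():
            if name == "hidden_nodes":
                continue  # handled per-layer below
            params[name] = int(rng.integers(lo, hi + 1))
        for name, (lo, hi) in space.log_ranges.items():
            params[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for name, options in space.choices.items():
            params[name] = options[int(rng.integers(0, len(options)))]
        if "hidden_nodes" in space.int_ranges:
            lo, hi = space.int_ranges["hidden_nodes"]
            n = params["n_hidden_layers"]
            params["hidden_sizes"] = [int(rng.integers(lo, hi + 1)) for _ in range(n)]
        return params


def _to_configs(architecture: str, params: dict, n_input: int, n_output: int,
                loss: LossSpec, max_epochs: int, seed: int,
                accumulation_steps: int = 4):
    """Translate a sampled parameter dict into (model config, train config)."""
    batch = max(accumulation_steps,
                (params["batch_size"] // accumulation_steps) * accumulation_steps)
    tc = TrainConfig(
        loss=loss,
        learning_rate=params["learning_rate"],
        weight_decay=params["weight_decay"],
        effective_batch_size=batch,
        accumulation_steps=accumulation_steps,
        max_epochs=max_epochs,
        seed=seed,
    )
    if architecture == "mlp":
        mc = MlpConfig(n_input, tuple(params["hidden_sizes"]), params["activation"], n_output)
    elif architecture == "cnn":
        mc = CnnConfig(
            n_input, params["n_conv_blocks"], params["channels"], params["kernel_size"],
            params["kernel_stride"], params["pooling"], 2, params["pooling_stride"],
            params["feedforward_size"], n_output,
        )
    else:
        mc = TransformerConfig(
            n_input, params["bin_size"], params["embed_dim"], params["n_heads"],
            params["n_encoder_layers"], params["feedforward_dim"],
            params["n_head_layers"], n_output,
        )
    return mc, tc


def sample_config(
    space: SearchSpace,
    rng: np.random.Generator,
    n_input: int,
    n_output: int,
    loss: LossSpec | str = "rae",
    max_epochs: int = 100,
    seed: int = 0,
    sampler=None,
    trials: pd.DataFrame | None = None,
    max_attempts: int = 10,
):
    """Draw one valid (model config, train config, params) triple.

    Invalid draws (e.g. CNN geometries that collapse the spatial axis, or
    attention heads that do not divide the embedding dimension) are rejected
    and resampled; ``max_attempts`` consecutive failures abort with
    diagnostics.
    """
    if isinstance(loss, str):
        loss = LossSpec(loss)
    sampler = sampler or RandomSampler()
    errors = []
    for _ in range(max_attempts):
        params = sampler.suggest(space, rng, trials)
        try:
            if space.architecture == "transformer" and params["embed_dim"] % params["n_heads"]:
                raise ValueError("heads do not divide embedding dimension")
            mc, tc = _to_configs(space.architecture, params, n_input, n_output,
                                 loss, max_epochs, seed)
            return mc, tc, params
        except ValueError as exc:
            errors.append(str(exc))
    raise RuntimeError(
        f"{max_attempts} consecutive invalid {space.architecture} draws; last errors: "
        + "; ".join(errors[-3:])
    )


@dataclass
class PruneRule:
    """``median``: compare against peers at the same epoch.
    ``threshold``: (loss bound, epoch) pairs; a trial whose loss is still
    strictly above a bound at or after its epoch is stopped."""

    kind: str = "median"
    thresholds: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("median", "threshold"):
            raise ValueError(f"unknown prune rule {self.kind!r}")
        epochs = [e for _, e in self.thresholds]
        if epochs != sorted(epochs):
            raise ValueError("threshold epochs must be ascending")


def default_prune_rule(architecture: str) -> PruneRule:
    """Median rule for the MLP; loss/epoch thresholds for CNN and transformer."""
    if architecture == "mlp":
        return PruneRule("median")
    if architecture == "cnn":
        return PruneRule("threshold", ((5000.0, 15), (1000.0, 100)))
    if architecture == "transformer":
        return PruneRule("threshold", ((1000.0, 100),))
    raise ValueError(f"unknown architecture {architecture!r}")


def should_prune(
    rule: PruneRule,
    trial_history: list[float],
    peer_histories: list[list[float]],
    epoch: int,
) -> bool:
    """Decide whether to stop the current trial after ``epoch``.

    Histories are per-epoch validation losses aligned by 0-based epoch index;
    a threshold pair (bound, e) applies once e epochs have completed, i.e.
    from epoch index e - 1 on.  With no peers the median rule never prunes;
    threshold comparisons are strict (a loss exactly at the bound survives).
    """
    current = trial_history[epoch]
    if rule.kind == "threshold":
        return any(epoch + 1 >= e and current > bound for bound, e in rule.thresholds)
    peers = [h[epoch] for h in peer_histories if len(h) > epoch]
    if not peers:
        return False
    return current > float(np.median(peers))


def tune(
    architecture: str,
    dataset,
    objective_set: tuple[np.ndarray, np.ndarray],
    n_trials: int,
    objective: str = "mape",
    seed: int = 0,
    space: SearchSpace | None = None,
    prune_rule: PruneRule | None = None,
    loss: LossSpec | str = "rae",
    max_epochs: int = 100,
    sampler=None,
    table_path: str | Path | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Run seeded train+evaluate trials and return the best configuration.

    ``objective_set`` is (spectra, truth) with every analyte present; the
    objective is mean MAPE on it, or the pinball loss at q=0.5 (``objective=
    "quantile"``).  Pruning uses per-epoch validation losses.  The trial table
    (params, objective, pruned flag) is append-only; if ``table_path`` exists
    the search resumes after the trials already recorded there.
    """
    if objective not in ("mape", "quantile"):
        raise ValueError(f"objective must be 'mape' or 'quantile', got {objective!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = space or default_search_space(architecture)
    rule = prune_rule or default_prune_rule(architecture)
    X_obj, Y_obj = objective_set
    rows: list[dict] = []
    if table_path is not None and Path(table_path).exists():
        rows = pd.read_csv(table_path).to_dict("records")
    rng = np.random.default_rng(seed)
    # replay the RNG for completed trials so a resumed search is identical
    for _ in rows:
        sample_config(space, rng, dataset_n_input(dataset), dataset_n_output(dataset),
                      loss, max_epochs, seed, sampler)
    peer_histories: list[list[float]] = [
        json.loads(r["val_history"]) for r in rows if r.get("val_history")
    ]
    quantile_fn = make_loss(LossSpec("quantile", q=0.5))
    n_in, n_out = dataset_n_input(dataset), dataset_n_output(dataset)
    while len(rows) < n_trials:
        trial_id = len(rows)
        mc, tc, params = sample_config(space, rng, n_in, n_out, loss, max_epochs,
                                       seed + trial_id, sampler)
        history: list[float] = []
        pruned = {"flag": False}

        def callback(epoch: int, val_loss: float) -> bool:
            history.append(val_loss)
            if should_prune(rule, history, peer_histories, epoch):
                pruned["flag"] = True
                return True
            return False

        trained = train(mc, dataset, tc, stop_callback=callback)
        pred = trained.predict(X_obj)
        if objective == "mape":
            score = float(mape_per_spectrum(pred, Y_obj).mean())
        else:
            score = float(quantile_fn(pred, Y_obj).data)
        rows.append(
            {
                "trial": trial_id,
                "params": json.dumps(params),
                "objective": score,
                "pruned": pruned["flag"],
                "n_epochs": len(trained.history),
                "best_val_loss": trained.best_val_loss,
                "val_history": json.dumps([h["val_loss"] for h in trained.history]),
            }
        )
        peer_histories.append([h["val_loss"] for h in trained.history])
        if table_path is not None:
            pd.DataFrame(rows).to_csv(table_path, index=False)
    table = pd.DataFrame(rows)
    finished = table[~table["pruned"]]
    pool = finished if len(finished) else table
    best_row = pool.loc[pool["objective"].idxmin()]
    best = {
        "trial": int(best_row["trial"]),
        "params": json.loads(best_row["params"]),
        "objective": float(best_row["objective"]),
        "architecture": architecture,
        "all_pruned": bool(len(finished) == 0),
    }
    if best["all_pruned"]:
        import warnings

        warnings.warn("all trials were pruned; returning the best pruned-at value")
    return best, table


def dataset_n_input(dataset) -> int:
    if isinstance(dataset, tuple):
        return dataset[0].shape[1]
    return dataset.grid.n_points


def dataset_n_output(dataset) -> int:
    if isinstance(dataset, tuple):
        return dataset[1].shape[1]
    return dataset.n_analytes
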