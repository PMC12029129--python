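"""Regression losses for training concentration quantifiers.

All losses are pure functions of a (prediction, target) batch, evaluated on
autodiff tensors so the same code serves training and evaluation.  Targets
span four orders of magnitude (0.005-20 mM), so the battery deliberately mixes
scale-dependent losses (MSE, LogCosh), relative ones (RAE, RSE, MAPE), a
robust asymmetric one (quantile/pinball), a log-domain one (MSLE) and a
standardized 50:50 MSE+MAPE combination.

Definitions, for prediction p and target t over a batch:

* ``rae``      = sum|p - t| / sum|t - mean(t)|
* ``rse``      = sum(p - t)^2 / sum(t - mean(t))^2
* ``mse``      = mean (p - t)^2
* ``quantile`` = mean[ max(q*(t - p), (q - 1)*(t - p)) ]
* ``logcosh``  = mean log cosh(p - t)
* ``msle``     = mean (log(1 + p) - log(1 + t))^2
* ``mape``     = 100 * mean |p - t| / |t|   (percent)
* ``mse+mape`` = 0.5*MSE/<MSE> + 0.5*MAPE/<MAPE>, each term divided by its
  detached running mean so the two incommensurate scales contribute equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

__all__ = ["LossSpec", "make_loss", "loss", "loss_gradient_check", "LOSS_NAMES"]

LOSS_NAMES = ("rae", "rse", "mse", "quantile", "logcosh", "msle", "mape", "mse+mape")


@dataclass
class LossSpec:
    """Loss selection: a name plus its parameters.

    ``q`` only applies to the quantile loss; ``mix_weights`` to the
    MSE+MAPE combination (must sum to 1).
    """

    name: str = "rae"
    q: float = 0.5
    mix_weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        key = self.name.lower().replace("&", "+").replace(" ", "")
        if key.startswith("quantile"):  # accept e.g. "quantile(0.1)"
            if "(" in key:
                self.q = float(key[key.index("(") + 1 : key.index(")")])
            key = "quantile"
        if key not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; use one of {LOSS_NAMES}")
        self.name = key
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"quantile q must be in (0, 1), got {self.q}")
        if abs(sum(self.mix_weights) - 1.0) > 1e-9:
            raise ValueError(f"mix weights must sum to 1, got {self.mix_weights}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _check_shapes(pred: Tensor, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")


def _check_positive_targets(target: np.ndarray, name: str) -> None:
    bad = np.flatnonzero(target.reshape(-1) <= 0)
    if bad.size:
        raise ValueError(
            f"{name} requires strictly positive targets; "
            f"target flat index {bad[0]} is {target.reshape(-1)[bad[0]]}"
        )


def _rae(pred: Tensor, target: np.ndarray) -> Tensor:
    denom = float(np.abs(target - target.mean()).sum())
    if denom == 0.0:
        raise ValueError("RAE undefined for constant targets (zero denominator)")
    return (pred - target).abs().sum() * (1.0 / denom)


def _rse(pred: Tensor, target: np.ndarray) -> Tensor:
    denom = float(((target - target.mean()) ** 2).sum())
    if denom == 0.0:
        raise ValueError("RSE undefined for constant targets (zero denominator)")
    return ((pred - target) ** 2).sum() * (1.0 / denom)


def _mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - target
    return (diff * diff).sum() * (1.0 / diff.size)


def _quantile(pred: Tensor, target: np.ndarray, q: float) -> Tensor:
    err = _as_tensor(target) - pred  # t - p
    pin = err.relu() * q + (-err).relu() * (1.0 - q)
    return pin.sum() * (1.0 / err.size)


def _logcosh(pred: Tensor, target: np.ndarray) -> Tensor:
    # log cosh(x) = |x| + log1p(exp(-2|x|)) - log 2, stable for large |x|
    a = (pred - target).abs()
    stable = a + ((a * -2.0).exp() + 1.0).log() - float(np.log(2.0))
    return stable.sum() * (1.0 / a.size)


def _msle(pred: Tensor, target: np.ndarray) -> Tensor:
    _check_positive_targets(target, "MSLE")
    if np.any(pred.data <= -1.0):
        idx = int(np.flatnonzero(pred.data.reshape(-1) <= -1.0)[0])
        raise ValueError(f"MSLE undefined: prediction flat index {idx} is <= -1 mM")
    diff = (pred + 1.0).log() - np.log1p(target)
    return (diff * diff).sum() * (1.0 / diff.size)


def _mape(pred: Tensor, target: np.ndarray) -> Tensor:
    _check_positive_targets(target, "MAPE")
    rel = (pred - target).abs() * (1.0 / np.abs(target))
    return rel.sum() * (100.0 / rel.size)


@dataclass
class _CombinedLoss:
    """50:50 MSE + MAPE, each standardized by its detached running mean."""

    weights: tuple[float, float] = (0.5, 0.5)
    momentum: float = 0.99
    _running: list = field(default_factory=lambda: [None, None])

    def __call__(self, pred: Tensor, target: np.ndarray) -> Tensor:
        terms = [_mse(pred, target), _mape(pred, target)]
        out = None
        for i, (w, term) in enumerate(zip(self.weights, terms)):
            value = float(term.data)
            if self._running[i] is None:
                self._running[i] = value
            else:
                self._running[i] = self.momentum * self._running[i] + (1 - self.momentum) * value
            scale = self._running[i] if self._running[i] > 0 else 1.0
            piece = term * (w / scale)
            out = piece if out is None else out + piece
        return out


def make_loss(spec: LossSpec | str):
    """Build a callable ``(pred, target) -> scalar Tensor`` from a spec."""
    if isinstance(spec, str):
        spec = LossSpec(name=spec)
    simple = {
        "rae": _rae,
        "rse": _rse,
        "mse": _mse,
        "logcosh": _logcosh,
        "msle": _msle,
        "mape": _mape,
    }

    if spec.name == "quantile":
        q = spec.q

        def fn(pred, target):
            pred = _as_tensor(pred)
            target = np.asarray(target, dtype=float)
            _check_shapes(pred, target)
            return _quantile(pred, target, q)

        return fn
    if spec.name == "mse+mape":
        combined = _CombinedLoss(weights=spec.mix_weights)

        def fn(pred, target):
            pred = _as_tensor(pred)
            target = np.asarray(target, dtype=float)
            _check_shapes(pred, target)
            return combined(pred, target)

        return fn
    base = simple[spec.name]

    def fn(pred, target):
        pred = _as_tensor(pred)
        target = np.asarray(target, dtype=float)
        _check_shapes(pred, target)
        return base(pred, target)

    return fn


def loss(spec: LossSpec | str, pred, target) -> float:
    """One-shot loss evaluation returning a plain float."""
    return float(make_loss(spec)(pred, target).data)


def loss_gradient_check(
    spec: LossSpec | str,
    pred: np.ndarray,
    target: np.ndarray,
    eps: float = 1e-6,
) -> float:
    """Max relative deviation between autodiff and central finite differences.

    Points where the loss is non-differentiable (|p - t| < 10*eps for the
    absolute-value family) are skipped.  Uses float64 throughout.
    """
    fn = make_loss(spec)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    t = Tensor(pred.copy(), requires_grad=True)
    out = fn(t, target)
    out.backward()
    auto = t.grad.reshape(-1)
    flat = pred.reshape(-1)
    num = np.zeros_like(flat)
    kink = np.abs(pred - target).reshape(-1) < 10 * eps
    for i in range(flat.size):
        if kink[i]:
            continue
        for sign in (+1.0, -1.0):
            bumped = flat.copy()
            bumped[i] += sign * eps
            num[i] += sign * float(fn(Tensor(bumped.reshape(pred.shape)), target).data)
        num[i] /= 2.0 * eps
    scale = np.maximum(np.abs(auto), np.abs(num))
    scale[scale == 0] = 1.0
    devs = np.abs(auto - num) / scale
    devs[kink] = 0.0
    return float(devs.max())
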