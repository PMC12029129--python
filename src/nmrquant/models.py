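"""Quantification architectures: MLP, 1-D CNN and encoder-only transformer.

All three map a normalized spectrum vector (length ``n_input``) to a vector of
analyte concentration estimates in mM.  Forward passes are deterministic given
fixed weights (no dropout anywhere) and vectorized over the batch dimension.

The two configuration sets used throughout are available as named presets:
``mlp-base``/``cnn-base``/``tx-base`` are the initial hand-chosen designs and
``mlp-opt``/``cnn-opt``/``tx-opt`` the Bayesian-optimization winners.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    ACTIVATIONS,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    avgpool1d,
    conv1d,
    maxpool1d,
    sinusoidal_positional_encoding,
)

__all__ = [
    "MlpConfig",
    "CnnConfig",
    "TransformerConfig",
    "MlpModel",
    "CnnModel",
    "TransformerModel",
    "bin_spectrum",
    "build_model",
    "model_preset",
    "conv_output_length",
    "cnn_flat_size",
    "MODEL_PRESETS",
]


def bin_spectrum(spectrum: np.ndarray, bin_size: int) -> tuple[np.ndarray, int]:
    """Split a spectrum (or batch) into contiguous non-overlapping ppm bins.

    Returns ``(binned, n_pad)`` where ``binned`` has shape
    ``(..., n_bins, bin_size)`` and ``n_pad`` zeros were appended at the
    high-ppm end to make the length divisible by ``bin_size``.
    """
    spectrum = np.asarray(spectrum)
    n = spectrum.shape[-1]
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    if bin_size > n:
        raise ValueError(f"bin_size {bin_size} exceeds spectrum length {n}")
    n_pad = (-n) % bin_size
    if n_pad:
        pad_width = [(0, 0)] * (spectrum.ndim - 1) + [(0, n_pad)]
        spectrum = np.pad(spectrum, pad_width)
    n_bins = (n + n_pad) // bin_size
    return spectrum.reshape(*spectrum.shape[:-1], n_bins, bin_size), n_pad


@dataclass
class MlpConfig:
    n_input: int = 46000
    hidden_sizes: tuple[int, ...] = (200,)
    activation: str = "relu"
    n_output: int = 44
    kind: str = "mlp"

    def __post_init__(self) -> None:
        if not 1 <= len(self.hidden_sizes) <= 4:
            raise ValueError(f"MLP supports 1-4 hidden layers, got {len(self.hidden_sizes)}")
        ACTIVATIONS(self.activation)  # validate


@dataclass
class CnnConfig:
    n_input: int = 46000
    n_conv_blocks: int = 4
    channels: int = 42
    kernel_size: int = 6
    kernel_stride: int = 2
    pooling: str = "max"  # none | max | average
    pooling_size: int = 2
    pooling_stride: int = 2
    feedforward_size: int = 200
    n_output: int = 44
    kind: str = "cnn"

    def __post_init__(self) -> None:
        if self.pooling not in ("none", "max", "average"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if cnn_flat_size(self) < 1:
            raise ValueError("configuration collapses the spatial axis to < 1 point")


@dataclass
class TransformerConfig:
    n_input: int = 46000
    bin_size: int = 1000
    embed_dim: int = 512
    n_heads: int = 1
    n_encoder_layers: int = 1
    feedforward_dim: int = 2048
    n_head_layers: int = 1
    n_output: int = 44
    kind: str = "transformer"

    def __post_init__(self) -> None:
        if self.n_head_layers not in (1, 2):
            raise ValueError("final feedforward head supports 1 or 2 layers")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if self.bin_size > self.n_input:
            raise ValueError("bin_size exceeds input length")

    @property
    def seq_len(self) -> int:
        return -(-self.n_input // self.bin_size)  # ceil: zero-padded if needed


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid-mode output length: floor((L - K) / stride) + 1."""
    return (length - kernel) // stride + 1


def cnn_flat_size(cfg: CnnConfig) -> int:
    """Flattened feature size after all conv (+pool) blocks, by closed form."""
    length = cfg.n_input
    for _ in range(cfg.n_conv_blocks):
        length = conv_output_length(length, cfg.kernel_size, cfg.kernel_stride)
        if length < 1:
            return length
        if cfg.pooling != "none":
            length = conv_output_length(length, cfg.pooling_size, cfg.pooling_stride)
            if length < 1:
                return length
    return length * cfg.channels


class MlpModel(Module):
    def __init__(self, config: MlpConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        self._act = ACTIVATIONS(config.activation)
        sizes = [config.n_input, *config.hidden_sizes, config.n_output]
        self.layers = [Linear(a, b, rng, dtype) for a, b in zip(sizes[:-1], sizes[1:])]

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        for layer in self.layers[:-1]:
            t = self._act(layer(t))
        return self.layers[-1](t)


class CnnModel(Module):
    def __init__(self, config: CnnConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        self.convs = []
        in_ch = 1
        for _ in range(config.n_conv_blocks):
            bound = 1.0 / np.sqrt(in_ch * config.kernel_size)
            w = Tensor(
                rng.uniform(-bound, bound,
                            (config.channels, in_ch, config.kernel_size)).astype(dtype),
                requires_grad=True,
            )
            b = Tensor(np.zeros(config.channels, dtype=dtype), requires_grad=True)
            self.convs.append((w, b))
            in_ch = config.channels
        flat = cnn_flat_size(config)
        self.head1 = Linear(flat, config.feedforward_size, rng, dtype)
        self.head2 = Linear(config.feedforward_size, config.n_output, rng, dtype)

    def parameters(self):
        params = [t for pair in self.convs for t in pair]
        return params + self.head1.parameters() + self.head2.parameters()

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        B = t.shape[0]
        t = t.reshape(B, 1, t.shape[-1])
        cfg = self.config
        for w, b in self.convs:
            t = conv1d(t, w, b, stride=cfg.kernel_stride).relu()
            if cfg.pooling == "max":
                t = maxpool1d(t, cfg.pooling_size, cfg.pooling_stride)
            elif cfg.pooling == "average":
                t = avgpool1d(t, cfg.pooling_size, cfg.pooling_stride)
        t = t.reshape(B, t.shape[1] * t.shape[2])
        return self.head2(self.head1(t).relu())


class TransformerModel(Module):
    """Encoder-only transformer over a sequence of spectral bins.

    Each bin of raw intensities is embedded by one shared linear layer,
    sinusoidal positional encodings are added, the sequence runs through the
    encoder stack, and all positions are flattened into the final linear head.
    """

    def __init__(self, config: TransformerConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(seed)
        self.embed = Linear(config.bin_size, config.embed_dim, rng, dtype)
        self.pos = Tensor(
            sinusoidal_positional_encoding(config.seq_len, config.embed_dim, dtype)
        )
        self.encoder = [
            TransformerEncoderLayer(
                config.embed_dim, config.n_heads, config.feedforward_dim, rng, dtype
            )
            for _ in range(config.n_encoder_layers)
        ]
        flat = config.seq_len * config.embed_dim
        if config.n_head_layers == 2:
            self.head_hidden = Linear(flat, config.feedforward_dim, rng, dtype)
            self.head = Linear(config.feedforward_dim, config.n_output, rng, dtype)
        else:
            self.head_hidden = None
            self.head = Linear(flat, config.n_output, rng, dtype)

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        data = x.data if isinstance(x, Tensor) else np.asarray(x)
        binned, _ = bin_spectrum(data, self.config.bin_size)  # (B, S, bin)
        t = Tensor(binned)
        t = self.embed(t) + self.pos
        for layer in self.encoder:
            t = layer(t)
        B, S, E = t.shape
        t = t.reshape(B, S * E)
        if self.head_hidden is not None:
            t = self.head_hidden(t).relu()
        return self.head(t)


def build_model(config, seed: int = 0, dtype=np.float32) -> Module:
    """Instantiate the model class matching a config dataclass."""
    if isinstance(config, MlpConfig):
        return MlpModel(config, seed, dtype)
    if isinstance(config, CnnConfig):
        return CnnModel(config, seed, dtype)
    if isinstance(config, TransformerConfig):
        return TransformerModel(config, seed, dtype)
    raise TypeError(f"unknown model config type {type(config).__name__}")


_PRESET_FACTORIES = {
    "mlp-base": lambda i, o: MlpConfig(i, (200,), "relu", o),
    "cnn-base": lambda i, o: CnnConfig(i, 4, 42, 6, 2, "max", 2, 2, 200, o),
    "tx-base": lambda i, o: TransformerConfig(i, 1000, 512, 1, 1, 2048, n_output=o),
    "mlp-opt": lambda i, o: MlpConfig(i, (222, 463), "leakyrelu", o),
    "cnn-opt": lambda i, o: CnnConfig(i, 3, 35, 10, 4, "none", 2, 2, 233, o),
    "tx-opt": lambda i, o: TransformerConfig(i, 500, 512, 16, 1, 512, n_output=o),
}

MODEL_PRESETS = tuple(_PRESET_FACTORIES)


def model_preset(name: str, n_input: int = 46000, n_output: int = 44):
    """Named architecture preset, re-dimensioned to the given input/output."""
    if name not in _PRESET_FACTORIES:
        raise ValueError(f"unknown preset {name!r}; use one of {sorted(_PRESET_FACTORIES)}")
    return _PRESET_FACTORIES[name](n_input, n_output)


def config_to_dict(config) -> dict:
    return asdict(config)


def config_from_dict(d: dict):
    kind = d.get("kind")
    cls = {"mlp": MlpConfig, "cnn": CnnConfig, "transformer": TransformerConfig}[kind]
    d = dict(d)
    if kind == "mlp":
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
    return cls(**d)
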