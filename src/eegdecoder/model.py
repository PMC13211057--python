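"""The EEGDecoder architecture, the EEGNet-8,2 baseline, and exact footprint
accounting (trainable parameters and per-inference FLOPs).

EEGDecoder is a hybrid classifier for 19-channel, 5-s (1280-sample) EEG
trials: a two-stage 1-D CNN front end (conv -> batch-norm -> ELU -> max-pool,
twice, valid padding) reduces the time axis 1280 -> 1256 -> 314 -> 300 -> 75
while lifting to 64 feature channels; the (64, 75) map is permuted to a
75-step sequence of 64-dimensional embeddings, processed by a two-layer,
two-head Transformer encoder (post-norm, feed-forward width 2048, no
positional encoding), mean-pooled over time, and classified by a linear
64 -> 3 head producing raw class scores. With the default configuration the
model has exactly 654,723 trainable parameters and needs about 2.1e8 FLOPs
per inference.

FLOP convention: one multiply-accumulate counts as two floating-point
operations; elementwise work (bias adds, normalizations, activations,
pooling comparisons, softmax terms) is counted once per element.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import (
    AvgPool1d,
    BatchNorm,
    ChannelwiseTemporalConv,
    Conv1d,
    DepthwiseSpatialConv,
    DepthwiseTemporalConv,
    Dropout,
    ELU,
    ExpandFeatureDim,
    Flatten,
    Linear,
    MaxPool1d,
    Network,
    PermuteToSequence,
    TemporalMeanPool,
    TransformerEncoderLayer,
    softmax_lastaxis,
)


@dataclass(frozen=True)
class ModelConfig:
    """EEGDecoder hyperparameters (defaults reproduce the published model)."""

    in_channels: int = 19
    input_samples: int = 1280
    conv1_out: int = 64
    conv1_kernel: int = 25
    conv2_out: int = 64
    conv2_kernel: int = 15
    pool: int = 4
    encoder_layers: int = 2
    attention_heads: int = 2
    d_model: int = 64
    ffn_dim: int = 2048
    dropout: float = 0.1
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.d_model % self.attention_heads:
            raise ValueError("d_model must be divisible by attention_heads")
        if self.conv2_out != self.d_model:
            raise ValueError("CNN output channels must equal the embedding dimension")

    @property
    def d_k(self) -> int:
        return self.d_model // self.attention_heads

    @property
    def sequence_length(self) -> int:
        """Time steps after the CNN: valid convs shrink by kernel-1, pools divide."""
        t = self.input_samples
        t = (t - self.conv1_kernel + 1) // self.pool
        t = (t - self.conv2_kernel + 1) // self.pool
        return t


@dataclass(frozen=True)
class EEGNetConfig:
    """EEGNet-8,2 baseline hyperparameters."""

    in_channels: int = 19
    input_samples: int = 1280
    f1: int = 8
    depth_multiplier: int = 2
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.25
    depthwise_max_norm: float = 1.0
    dense_max_norm: float = 0.25
    n_classes: int = 3

    @property
    def f2(self) -> int:
        return self.f1 * self.depth_multiplier


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def scaled_dot_product_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V with row-stochastic attention weights."""
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
        raise ValueError("mismatched attention dimensions")
    d_k = q.shape[-1]
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(d_k)
    return softmax_lastaxis(scores) @ v


def temporal_mean_pool(z: np.ndarray) -> np.ndarray:
    """Mean over the time axis of a (T, d) or (N, T, d) sequence."""
    z = np.asarray(z)
    if z.shape[-2] < 1:
        raise ValueError("cannot pool an empty sequence")
    return z.mean(axis=-2)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_eegdecoder(cfg: ModelConfig | None = None, seed: int = 2025) -> Network:
    """Instantiate the CNN-Transformer classifier with seeded initialization."""
    cfg = cfg or ModelConfig()
    t_prime = cfg.sequence_length
    if t_prime < 1:
        raise ValueError("configuration collapses the time axis to nothing")
    rng = np.random.default_rng(seed)
    layers = [
        Conv1d(cfg.in_channels, cfg.conv1_out, cfg.conv1_kernel, rng, name="conv1"),
        BatchNorm(cfg.conv1_out, name="bn1"),
        ELU(name="elu1"),
        MaxPool1d(cfg.pool, name="pool1"),
        Conv1d(cfg.conv1_out, cfg.conv2_out, cfg.conv2_kernel, rng, name="conv2"),
        BatchNorm(cfg.conv2_out, name="bn2"),
        ELU(name="elu2"),
        MaxPool1d(cfg.pool, name="pool2"),
        PermuteToSequence(name="to_sequence"),
    ]
    for i in range(cfg.encoder_layers):
        layers.append(
            TransformerEncoderLayer(
                cfg.d_model, cfg.attention_heads, cfg.ffn_dim, rng,
                dropout=cfg.dropout, name=f"encoder{i}",
            )
        )
    layers += [
        TemporalMeanPool(name="mean_pool"),
        Linear(cfg.d_model, cfg.n_classes, rng, name="classifier"),
    ]
    return Network(layers, architecture="eegdecoder", config=asdict(cfg),
                   rng=np.random.default_rng(seed))


def build_eegnet(cfg: EEGNetConfig | None = None, seed: int = 2025) -> Network:
    """Instantiate the EEGNet-8,2 baseline with seeded initialization."""
    cfg = cfg or EEGNetConfig()
    rng = np.random.default_rng(seed)
    layers = [
        ExpandFeatureDim(name="expand"),
        ChannelwiseTemporalConv(1, cfg.f1, cfg.temporal_kernel, rng, name="temporal_conv"),
        BatchNorm(cfg.f1, name="bn1"),
        DepthwiseSpatialConv(cfg.f1, cfg.depth_multiplier, cfg.in_channels, rng,
                             max_norm=cfg.depthwise_max_norm, name="depthwise"),
        BatchNorm(cfg.f2, name="bn2"),
        ELU(name="elu1"),
        AvgPool1d(cfg.pool1, name="pool1"),
        Dropout(cfg.dropout, name="drop1"),
        DepthwiseTemporalConv(cfg.f2, cfg.separable_kernel, rng, name="separable_depth"),
        Conv1d(cfg.f2, cfg.f2, 1, rng, name="separable_point", bias=False),
        BatchNorm(cfg.f2, name="bn3"),
        ELU(name="elu2"),
        AvgPool1d(cfg.pool2, name="pool2"),
        Dropout(cfg.dropout, name="drop2"),
        Flatten(name="flatten"),
    ]
    flat = cfg.f2 * (cfg.input_samples // cfg.pool1 // cfg.pool2)
    layers.append(Linear(flat, cfg.n_classes, rng, name="classifier",
                         max_norm=cfg.dense_max_norm))
    return Network(layers, architecture="eegnet", config=asdict(cfg),
                   rng=np.random.default_rng(seed))


def build_model(architecture: str, seed: int = 2025,
                model_config: ModelConfig | EEGNetConfig | None = None) -> Network:
    if architecture == "eegdecoder":
        return build_eegdecoder(model_config, seed=seed)
    if architecture == "eegnet":
        return build_eegnet(model_config, seed=seed)
    raise ValueError(f"unknown architecture {architecture!r}")


# ---------------------------------------------------------------------------
# forward helpers
# ---------------------------------------------------------------------------

def _expected_input(net: Network) -> tuple[int, int]:
    return net.config["in_channels"], net.config["input_samples"]


def decoder_forward(net: Network, batch: np.ndarray, training: bool = False) -> np.ndarray:
    """Forward a (N, C, T) batch to (N, n_classes) raw scores, with shape checks."""
    batch = np.asarray(batch, dtype=np.float32)
    c, t = _expected_input(net)
    if batch.ndim != 3 or batch.shape[1] != c or batch.shape[2] != t:
        raise ValueError(
            f"expected batch of shape (N, {c}, {t}), got {batch.shape}"
        )
    scores = net.forward(batch, training=training)
    if not np.all(np.isfinite(scores)):
        raise FloatingPointError("non-finite class scores")
    return scores


def forward_with_intermediates(net: Network, batch: np.ndarray) -> tuple[np.ndarray, dict]:
    """Eval-mode forward that also returns every layer's output by name."""
    x = np.asarray(batch, dtype=np.float32)
    outputs: dict[str, np.ndarray] = {}
    for lyr in net.layers:
        x = lyr.forward(x, training=False)
        outputs[lyr.name] = x
    return x, outputs


# ---------------------------------------------------------------------------
# footprint accounting
# ---------------------------------------------------------------------------

def count_parameters(net: Network) -> int:
    """Exact count of trainable scalars by exhaustive enumeration."""
    return sum(p.size for p in net.parameters())


def count_parameters_closed_form(net: Network) -> int:
    """Independent count from each layer's configuration (no array access)."""
    return sum(lyr.param_count() for lyr in net.layers)


def expected_eegdecoder_parameters(cfg: ModelConfig | None = None) -> int:
    """Closed-form parameter total for the EEGDecoder from its hyperparameters."""
    cfg = cfg or ModelConfig()
    conv1 = cfg.conv1_out * (cfg.in_channels * cfg.conv1_kernel + 1) + 2 * cfg.conv1_out
    conv2 = cfg.conv2_out * (cfg.conv1_out * cfg.conv2_kernel + 1) + 2 * cfg.conv2_out
    d, f = cfg.d_model, cfg.ffn_dim
    attn = 3 * d * d + 3 * d + d * d + d
    ffn = f * (d + 1) + d * (f + 1)
    norms = 2 * (2 * d)
    encoder = cfg.encoder_layers * (attn + ffn + norms)
    head = cfg.n_classes * (d + 1)
    return conv1 + conv2 + encoder + head


def count_flops(net: Network, input_shape: tuple[int, int] | None = None) -> int:
    """Analytic per-inference FLOPs for a single trial.

    Walks the layer list, threading the shape through each layer's own
    accounting; unknown layer kinds raise rather than being skipped.
    """
    shape: tuple = tuple(input_shape) if input_shape else _expected_input(net)
    total = 0
    for lyr in net.layers:
        f, shape = lyr.flops(shape)
        total += int(f)
    return total


@dataclass
class FootprintReport:
    """Model footprint: exact counts plus measured per-trial latency."""

    parameter_count: int
    flops_per_inference: int
    latency_ms_mean: float
    latency_ms_median: float
    latency_ms_sd: float
    n_timed_trials: int
    backend: str
    batch_size: int = 1
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("extras")
        d.update(self.extras)
        return d
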