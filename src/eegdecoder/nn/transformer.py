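"""Transformer encoder pieces: scaled dot-product multi-head self-attention
and the post-norm encoder layer (residual, then layer normalization)."""

from __future__ import annotations

import numpy as np

from .core import Layer, Parameter, xavier_init, uniform_init
from .layers import Dropout, LayerNorm, Linear, ReLU


def softmax_lastaxis(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadSelfAttention(Layer):
    """Self-attention with ``h`` heads over batch-first (N, T, d) sequences.

    Queries, keys and values come from one combined input projection
    (3d x d); attention weights are row-stochastic after scaling the dot
    products by 1/sqrt(d_k). Attention-weight dropout is applied in training.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0, name: str = "attn"):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by the number of heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.name = name
        self.in_proj_weight = Parameter(f"{name}.in_proj.weight",
                                        xavier_init(rng, (3 * d_model, d_model), d_model, d_model))
        self.in_proj_bias = Parameter(f"{name}.in_proj.bias",
                                      np.zeros(3 * d_model, dtype=np.float32))
        self.out_proj_weight = Parameter(f"{name}.out_proj.weight",
                                         uniform_init(rng, (d_model, d_model), d_model))
        self.out_proj_bias = Parameter(f"{name}.out_proj.bias",
                                       np.zeros(d_model, dtype=np.float32))
        self.dropout = Dropout(dropout, name=f"{name}.drop")
        self._cache = None
        self.last_attention: np.ndarray | None = None

    def set_rng(self, rng):
        self.dropout.set_rng(rng)

    def _split_heads(self, x):
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        n, h, t, dk = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n, t, h * dk)

    def forward(self, x, training=False):
        n, t, d = x.shape
        qkv = x.reshape(-1, d) @ self.in_proj_weight.data.T + self.in_proj_bias.data
        qkv = qkv.reshape(n, t, 3, d)
        q = self._split_heads(qkv[:, :, 0])
        k = self._split_heads(qkv[:, :, 1])
        v = self._split_heads(qkv[:, :, 2])
        scale = 1.0 / np.sqrt(self.d_k)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        attn = softmax_lastaxis(scores)
        self.last_attention = attn
        attn_d = self.dropout.forward(attn, training=training)
        ctx = attn_d @ v
        merged = self._merge_heads(ctx)
        out = merged.reshape(-1, d) @ self.out_proj_weight.data.T + self.out_proj_bias.data
        if training:
            self._cache = (x, q, k, v, attn, attn_d, merged, scale)
        return out.reshape(n, t, d)

    def backward(self, grad):
        x, q, k, v, attn, attn_d, merged, scale = self._cache
        self._cache = None
        n, t, d = grad.shape
        g2 = grad.reshape(-1, d)
        self.out_proj_weight.grad += g2.T @ merged.reshape(-1, d)
        self.out_proj_bias.grad += g2.sum(axis=0)
        gmerged = (g2 @ self.out_proj_weight.data).reshape(n, t, d)
        gctx = self._split_heads(gmerged)
        gattn_d = gctx @ v.transpose(0, 1, 3, 2)
        gv = attn_d.transpose(0, 1, 3, 2) @ gctx
        gattn = self.dropout.backward(gattn_d)
        gscores = attn * (gattn - (gattn * attn).sum(axis=-1, keepdims=True))
        gscores *= scale
        gq = gscores @ k
        gk = gscores.transpose(0, 1, 3, 2) @ q
        gqkv = np.stack([
            self._merge_heads(gq), self._merge_heads(gk), self._merge_heads(gv)
        ], axis=2)                                                # n, t, 3, d
        g3 = gqkv.reshape(-1, 3 * d)
        self.in_proj_weight.grad += g3.T @ x.reshape(-1, d)
        self.in_proj_bias.grad += g3.sum(axis=0)
        return (g3 @ self.in_proj_weight.data).reshape(n, t, d)

    def parameters(self):
        return [self.in_proj_weight, self.in_proj_bias,
                self.out_proj_weight, self.out_proj_bias]

    def param_count(self):
        return 3 * self.d_model * self.d_model + 3 * self.d_model \
            + self.d_model * self.d_model + self.d_model

    def flops(self, in_shape):
        t, d = in_shape
        macs = 3 * t * d * d          # q, k, v projections
        macs += 2 * self.n_heads * t * t * self.d_k   # QK^T and AV
        macs += t * d * d             # output projection
        elementwise = 4 * t * d       # biases
        elementwise += self.n_heads * t * t * (1 + 5)  # scaling + softmax
        return 2 * macs + elementwise, (t, d)

    def describe(self):
        return {
            "op": "multihead_self_attention", "name": self.name,
            "d_model": self.d_model, "n_heads": self.n_heads,
            "weights": {"in_proj.weight": self.in_proj_weight.name,
                        "in_proj.bias": self.in_proj_bias.name,
                        "out_proj.weight": self.out_proj_weight.name,
                        "out_proj.bias": self.out_proj_bias.name},
        }


class TransformerEncoderLayer(Layer):
    """Post-norm encoder layer: y = LN(x + MHA(x)); z = LN(y + FFN(y)).

    The position-wise feed-forward net is Linear(d -> d_ff), rectifier,
    Linear(d_ff -> d), with dropout after the attention block, inside the
    feed-forward net and after it.
    """

    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator, dropout: float = 0.1,
                 name: str = "encoder"):
        self.d_model = d_model
        self.name = name
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng,
                                           dropout=dropout, name=f"{name}.self_attn")
        self.drop1 = Dropout(dropout, name=f"{name}.dropout1")
        self.norm1 = LayerNorm(d_model, name=f"{name}.norm1")
        self.linear1 = Linear(d_model, d_ff, rng, name=f"{name}.linear1")
        self.act = ReLU(name=f"{name}.relu")
        self.drop_ff = Dropout(dropout, name=f"{name}.dropout_ff")
        self.linear2 = Linear(d_ff, d_model, rng, name=f"{name}.linear2")
        self.drop2 = Dropout(dropout, name=f"{name}.dropout2")
        self.norm2 = LayerNorm(d_model, name=f"{name}.norm2")

    def set_rng(self, rng):
        for d in (self.attn, self.drop1, self.drop_ff, self.drop2):
            d.set_rng(rng)

    def forward(self, x, training=False):
        a = self.drop1.forward(self.attn.forward(x, training), training)
        y = self.norm1.forward(x + a, training)
        f = self.linear1.forward(y, training)
        f = self.act.forward(f, training)
        f = self.drop_ff.forward(f, training)
        f = self.linear2.forward(f, training)
        f = self.drop2.forward(f, training)
        return self.norm2.forward(y + f, training)

    def backward(self, grad):
        g = self.norm2.backward(grad)
        gf = self.drop2.backward(g)
        gf = self.linear2.backward(gf)
        gf = self.drop_ff.backward(gf)
        gf = self.act.backward(gf)
        gf = self.linear1.backward(gf)
        gy = g + gf
        gxa = self.norm1.backward(gy)
        ga = self.drop1.backward(gxa)
        gx = self.attn.backward(ga)
        return gxa + gx

    def parameters(self):
        return (self.attn.parameters() + self.norm1.parameters()
                + self.linear1.parameters() + self.linear2.parameters()
                + self.norm2.parameters())

    def param_count(self):
        return (self.attn.param_count() + self.norm1.param_count()
                + self.linear1.param_count() + self.linear2.param_count()
                + self.norm2.param_count())

    def flops(self, in_shape):
        total = 0
        f, shape = self.attn.flops(in_shape)
        total += f
        total += int(np.prod(shape))            # residual add
        f, shape = self.norm1.flops(shape)
        total += f
        f, mid = self.linear1.flops(shape)
        total += f
        total += int(np.prod(mid))              # rectifier
        f, back = self.linear2.flops(mid)
        total += f
        total += int(np.prod(back))             # residual add
        f, out = self.norm2.flops(back)
        total += f
        return total, out

    def describe(self):
        return {
            "op": "transformer_encoder_layer", "name": self.name,
            "d_model": self.d_model,
            "sublayers": [self.attn.describe(), self.norm1.describe(),
                          self.linear1.describe(), self.linear2.describe(),
                          self.norm2.describe()],
            "weights": {},
        }
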