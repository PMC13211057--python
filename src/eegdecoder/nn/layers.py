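"""Generic layers: 1-D convolution, normalization, activations, pooling,
linear maps and dropout, each with explicit backward passes."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft

from .core import Layer, Parameter, uniform_init


class Conv1d(Layer):
    """Temporal convolution over (N, C_in, L) with optional zero padding.

    ``padding=(left, right)``; the default (0, 0) is a valid (no-padding)
    convolution, which shrinks the time axis by ``kernel - 1``.

    Two mathematically equivalent realizations are provided: a direct
    im2col/GEMM path, and an FFT path (channel mixing as batched complex
    matmuls in the frequency domain) that is far cheaper for long signals;
    ``method="auto"`` picks by problem size. Forward, input gradient and
    weight gradient are all correlations/convolutions, so both paths share
    one derivation.
    """

    #: switch to the FFT path when L_out * kernel exceeds this
    FFT_THRESHOLD = 4096

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, name: str = "conv",
                 padding: tuple[int, int] = (0, 0), bias: bool = True,
                 method: str = "auto"):
        if method not in ("auto", "direct", "fft"):
            raise ValueError(f"unknown conv method {method!r}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.padding = padding
        self.name = name
        self.method = method
        fan_in = in_channels * kernel
        self.weight = Parameter(f"{name}.weight",
                                uniform_init(rng, (out_channels, in_channels, kernel), fan_in))
        self.bias = Parameter(f"{name}.bias", uniform_init(rng, (out_channels,), fan_in)) if bias else None
        self._cols: np.ndarray | None = None
        self._xf: np.ndarray | None = None
        self._nfft = 0
        self._in_len = 0

    def _out_len(self, L: int) -> int:
        return L + sum(self.padding) - self.kernel + 1

    def _use_fft(self, lout: int) -> bool:
        if self.method == "fft":
            return True
        if self.method == "direct":
            return False
        return lout * self.kernel >= self.FFT_THRESHOLD

    def forward(self, x, training=False):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"{self.name}: expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        if sum(self.padding):
            x = np.pad(x, ((0, 0), (0, 0), self.padding))
        n, c, L = x.shape
        self._in_len = L
        lout = L - self.kernel + 1
        if self._use_fft(lout):
            return self._forward_fft(x, training, lout)
        win = sliding_window_view(x, self.kernel, axis=2)          # n, c, lout, k
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * lout, c * self.kernel)
        self._cols = cols if training else None
        w2 = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ w2.T
        if self.bias is not None:
            out += self.bias.data
        return np.ascontiguousarray(out.reshape(n, lout, self.out_channels).transpose(0, 2, 1))

    def backward(self, grad):
        if self._xf is not None:
            return self._backward_fft(grad)
        n, cout, lout = grad.shape
        k = self.kernel
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1)).reshape(n * lout, cout)
        self.weight.grad += (g2.T @ self._cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        self._cols = None
        # input gradient: distribute each output gradient over its window
        gcols = (g2 @ self.weight.data.reshape(cout, -1))           # n*lout, c*k
        gcols = gcols.reshape(n, lout, self.in_channels, k)
        gx = np.zeros((n, self.in_channels, self._in_len), dtype=grad.dtype)
        for j in range(k):
            gx[:, :, j:j + lout] += gcols[:, :, :, j].transpose(0, 2, 1)
        left, right = self.padding
        if left or right:
            gx = gx[:, :, left:self._in_len - right]
        return gx

    # -- FFT path ----------------------------------------------------------
    def _wf(self, nfft: int, dtype) -> np.ndarray:
        # weights are constant between a forward and its backward, so the
        # kernel spectrum computed in forward is reused by backward
        cache = getattr(self, "_wf_cache", None)
        if cache is not None and cache[0] == (nfft, np.dtype(dtype)):
            return cache[1]
        wf = sfft.rfft(self.weight.data.astype(dtype), nfft, axis=-1)
        self._wf_cache = ((nfft, np.dtype(dtype)), wf)
        return wf

    @staticmethod
    def _fmatmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Frequency-batched matmul: a (.., f), b (.., f) -> contraction.

        a has shape (A, C, F), b (C, B, F); returns (A, B, F).
        """
        prod = np.matmul(a.transpose(2, 0, 1), b.transpose(2, 0, 1))
        return prod.transpose(1, 2, 0)

    def _forward_fft(self, x, training, lout):
        # correlation theorem: out = irfft(X . conj(W)) on [0, lout)
        nfft = sfft.next_fast_len(self._in_len)
        xf = sfft.rfft(x, nfft, axis=-1)                   # n, c, f
        wf = self._wf(nfft, x.dtype)                       # o, c, f
        self._nfft = nfft
        self._xf = xf if training else None
        yf = self._fmatmul(xf, np.conj(wf).transpose(1, 0, 2))  # n, o, f
        out = sfft.irfft(yf, nfft, axis=-1)[..., :lout]
        if self.bias is not None:
            out = out + self.bias.data[None, :, None]
        return np.ascontiguousarray(out.astype(x.dtype, copy=False))

    def _backward_fft(self, grad):
        n, cout, lout = grad.shape
        k = self.kernel
        nfft = self._nfft
        xf = self._xf
        self._xf = None
        gf = sfft.rfft(grad, nfft, axis=-1)                # n, o, f
        # dL/dW[o,c,k] = sum_n correlate(g[n,o], x[n,c]) evaluated on [0, k)
        gwf = self._fmatmul(np.conj(gf).transpose(1, 0, 2), xf)  # o, c, f
        gw = sfft.irfft(gwf, nfft, axis=-1)[..., :k]
        self.weight.grad += gw.astype(self.weight.data.dtype, copy=False)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2))
        # dL/dx = full convolution of g with w (no conjugate)
        wf = self._wf(nfft, grad.dtype)                    # o, c, f
        self._wf_cache = None  # weights are about to change (optimizer step)
        gxf = self._fmatmul(gf, wf)                        # n, c, f
        gx = sfft.irfft(gxf, nfft, axis=-1)[..., :self._in_len]
        gx = np.ascontiguousarray(gx.astype(grad.dtype, copy=False))
        left, right = self.padding
        if left or right:
            gx = gx[:, :, left:self._in_len - right]
        return gx

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def param_count(self):
        n = self.out_channels * self.in_channels * self.kernel
        return n + (self.out_channels if self.bias is not None else 0)

    def flops(self, in_shape):
        c, L = in_shape
        lout = self._out_len(L)
        macs = self.in_channels * self.kernel * self.out_channels * lout
        elementwise = self.out_channels * lout if self.bias is not None else 0
        return 2 * macs + elementwise, (self.out_channels, lout)

    def describe(self):
        return {
            "op": "conv1d", "name": self.name,
            "in_channels": self.in_channels, "out_channels": self.out_channels,
            "kernel": self.kernel, "padding": list(self.padding),
            "weights": {"weight": self.weight.name,
                        **({"bias": self.bias.name} if self.bias is not None else {})},
        }


class BatchNorm(Layer):
    """Batch normalization over the feature axis (axis 1) of any N-D input."""

    def __init__(self, num_features: int, name: str = "bn",
                 eps: float = 1e-5, momentum: float = 0.1):
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.name = name
        self.gamma = Parameter(f"{name}.weight", np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(f"{name}.bias", np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self._cache = None

    def _shape(self, ndim):
        return (1, self.num_features) + (1,) * (ndim - 2)

    def forward(self, x, training=False):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._shape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size // self.num_features
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            unbiased = var * m / max(m - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if training:
            self._cache = (xhat, invstd, axes, shape)
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, grad):
        xhat, invstd, axes, shape = self._cache
        m = grad.size // self.num_features
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gxhat = grad * self.gamma.data.reshape(shape)
        gx = (gxhat - gxhat.mean(axis=axes, keepdims=True)
              - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True) / m)
        self._cache = None
        return gx * invstd.reshape(shape)

    def parameters(self):
        return [self.gamma, self.beta]

    def param_count(self):
        return 2 * self.num_features

    def flops(self, in_shape):
        n = int(np.prod(in_shape))
        return 2 * n, in_shape  # scale + shift per element (inference form)

    def describe(self):
        return {
            "op": "batchnorm", "name": self.name, "eps": self.eps,
            "num_features": self.num_features,
            "weights": {"weight": self.gamma.name, "bias": self.beta.name,
                        "running_mean": f"{self.name}.running_mean",
                        "running_var": f"{self.name}.running_var"},
        }

    def extra_state(self):
        return {f"{self.name}.running_mean": self.running_mean,
                f"{self.name}.running_var": self.running_var}

    def load_extra_state(self, state):
        self.running_mean = np.asarray(state[f"{self.name}.running_mean"], dtype=np.float32)
        self.running_var = np.asarray(state[f"{self.name}.running_var"], dtype=np.float32)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0, name: str = "elu"):
        self.alpha = alpha
        self.name = name
        self._cache = None

    def forward(self, x, training=False):
        neg = self.alpha * np.expm1(np.minimum(x, 0.0))
        y = np.where(x > 0, x, neg)
        if training:
            self._cache = (x > 0, neg)
        return y.astype(x.dtype)

    def backward(self, grad):
        pos, neg = self._cache
        self._cache = None
        return grad * np.where(pos, 1.0, neg + self.alpha).astype(grad.dtype)

    def flops(self, in_shape):
        return int(np.prod(in_shape)), in_shape

    def describe(self):
        return {"op": "elu", "name": self.name, "alpha": self.alpha, "weights": {}}


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g

    def flops(self, in_shape):
        return int(np.prod(in_shape)), in_shape

    def describe(self):
        return {"op": "relu", "name": self.name, "weights": {}}


class MaxPool1d(Layer):
    """Non-overlapping max pooling over the last axis (kernel == stride)."""

    def __init__(self, kernel: int, name: str = "maxpool"):
        self.kernel = kernel
        self.name = name
        self._cache = None

    def forward(self, x, training=False):
        k = self.kernel
        lout = x.shape[-1] // k
        xr = x[..., : lout * k].reshape(*x.shape[:-1], lout, k)
        idx = xr.argmax(axis=-1)
        if training:
            self._cache = (idx, x.shape)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        idx, in_shape = self._cache
        self._cache = None
        k = self.kernel
        lout = in_shape[-1] // k
        gx = np.zeros(in_shape[:-1] + (lout, k), dtype=grad.dtype)
        np.put_along_axis(gx, idx[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(*in_shape[:-1], lout * k)
        if lout * k < in_shape[-1]:
            gx = np.pad(gx, [(0, 0)] * (gx.ndim - 1) + [(0, in_shape[-1] - lout * k)])
        return gx

    def flops(self, in_shape):
        lout = in_shape[-1] // self.kernel
        out_shape = in_shape[:-1] + (lout,)
        comparisons = int(np.prod(out_shape)) * (self.kernel - 1)
        return comparisons, out_shape

    def describe(self):
        return {"op": "maxpool1d", "name": self.name, "kernel": self.kernel, "weights": {}}


class AvgPool1d(Layer):
    """Non-overlapping average pooling over the last axis."""

    def __init__(self, kernel: int, name: str = "avgpool"):
        self.kernel = kernel
        self.name = name
        self._in_shape = None

    def forward(self, x, training=False):
        k = self.kernel
        lout = x.shape[-1] // k
        self._in_shape = x.shape
        return x[..., : lout * k].reshape(*x.shape[:-1], lout, k).mean(axis=-1)

    def backward(self, grad):
        in_shape = self._in_shape
        self._in_shape = None
        k = self.kernel
        gx = np.repeat(grad[..., None] / k, k, axis=-1).reshape(*grad.shape[:-1], grad.shape[-1] * k)
        if gx.shape[-1] < in_shape[-1]:
            gx = np.pad(gx, [(0, 0)] * (gx.ndim - 1) + [(0, in_shape[-1] - gx.shape[-1])])
        return gx

    def flops(self, in_shape):
        lout = in_shape[-1] // self.kernel
        out_shape = in_shape[:-1] + (lout,)
        return int(np.prod(out_shape)) * self.kernel, out_shape

    def describe(self):
        return {"op": "avgpool1d", "name": self.name, "kernel": self.kernel, "weights": {}}


class Linear(Layer):
    """Affine map over the last axis; accepts any leading shape."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "linear", bias: bool = True,
                 max_norm: float | None = None):
        self.in_features = in_features
        self.out_features = out_features
        self.name = name
        self.weight = Parameter(f"{name}.weight",
                                uniform_init(rng, (out_features, in_features), in_features),
                                max_norm=max_norm, max_norm_axes=(1,))
        self.bias = Parameter(f"{name}.bias",
                              uniform_init(rng, (out_features,), in_features)) if bias else None
        self._x2d = None
        self._lead = None

    def forward(self, x, training=False):
        self._lead = x.shape[:-1]
        x2d = x.reshape(-1, self.in_features)
        if training:
            self._x2d = x2d
        y = x2d @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y.reshape(*self._lead, self.out_features)

    def backward(self, grad):
        g2d = grad.reshape(-1, self.out_features)
        self.weight.grad += g2d.T @ self._x2d
        if self.bias is not None:
            self.bias.grad += g2d.sum(axis=0)
        gx = g2d @ self.weight.data
        out = gx.reshape(*self._lead, self.in_features)
        self._x2d = None
        return out

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def param_count(self):
        return self.out_features * (self.in_features + (1 if self.bias is not None else 0))

    def flops(self, in_shape):
        lead = int(np.prod(in_shape[:-1])) if len(in_shape) > 1 else 1
        macs = lead * self.in_features * self.out_features
        elementwise = lead * self.out_features if self.bias is not None else 0
        out_shape = in_shape[:-1] + (self.out_features,)
        return 2 * macs + elementwise, out_shape

    def describe(self):
        return {
            "op": "linear", "name": self.name,
            "in_features": self.in_features, "out_features": self.out_features,
            "weights": {"weight": self.weight.name,
                        **({"bias": self.bias.name} if self.bias is not None else {})},
        }


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, name: str = "dropout"):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.name = name
        self.rng: np.random.Generator | None = None
        self._mask = None

    def set_rng(self, rng):
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.p).astype(x.dtype) / np.asarray(1 - self.p, dtype=x.dtype)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g

    def flops(self, in_shape):
        return 0, in_shape  # inference no-op

    def describe(self):
        return {"op": "dropout", "name": self.name, "p": self.p, "weights": {}}


class LayerNorm(Layer):
    """Normalization over the last axis with affine parameters."""

    def __init__(self, dim: int, name: str = "ln", eps: float = 1e-5):
        self.dim = dim
        self.eps = eps
        self.name = name
        self.gamma = Parameter(f"{name}.weight", np.ones(dim, dtype=np.float32))
        self.beta = Parameter(f"{name}.bias", np.zeros(dim, dtype=np.float32))
        self._cache = None

    def forward(self, x, training=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if training:
            self._cache = (xhat, invstd)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, grad):
        xhat, invstd = self._cache
        self._cache = None
        lead_axes = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=lead_axes)
        self.beta.grad += grad.sum(axis=lead_axes)
        gxhat = grad * self.gamma.data
        gx = (gxhat - gxhat.mean(axis=-1, keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
        return gx * invstd

    def parameters(self):
        return [self.gamma, self.beta]

    def param_count(self):
        return 2 * self.dim

    def flops(self, in_shape):
        return 5 * int(np.prod(in_shape)), in_shape

    def describe(self):
        return {"op": "layernorm", "name": self.name, "dim": self.dim, "eps": self.eps,
                "weights": {"weight": self.gamma.name, "bias": self.beta.name}}


class PermuteToSequence(Layer):
    """(N, channels, time) -> (N, time, channels) for the encoder."""

    def __init__(self, name: str = "permute"):
        self.name = name

    def forward(self, x, training=False):
        return np.ascontiguousarray(x.transpose(0, 2, 1))

    def backward(self, grad):
        return np.ascontiguousarray(grad.transpose(0, 2, 1))

    def flops(self, in_shape):
        c, t = in_shape
        return 0, (t, c)

    def describe(self):
        return {"op": "permute_ct_tc", "name": self.name, "weights": {}}


class TemporalMeanPool(Layer):
    """(N, T, d) -> (N, d): arithmetic mean over the time axis."""

    def __init__(self, name: str = "meanpool"):
        self.name = name
        self._t = None

    def forward(self, x, training=False):
        if x.shape[1] < 1:
            raise ValueError("cannot mean-pool an empty sequence")
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        t = self._t
        self._t = None
        return np.repeat(grad[:, None, :] / t, t, axis=1)

    def flops(self, in_shape):
        t, d = in_shape
        return t * d, (d,)

    def describe(self):
        return {"op": "temporal_mean_pool", "name": self.name, "weights": {}}


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name
        self._shape = None

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        shape = self._shape
        self._shape = None
        return grad.reshape(shape)

    def flops(self, in_shape):
        return 0, (int(np.prod(in_shape)),)

    def describe(self):
        return {"op": "flatten", "name": self.name, "weights": {}}
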