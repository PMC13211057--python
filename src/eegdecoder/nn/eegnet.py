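"""Layers specific to the compact EEGNet baseline.

EEGNet-8,2 factorizes EEG feature extraction into a temporal convolution
applied identically to every electrode, a depthwise spatial filter across
electrodes (with a max-norm constraint), and a separable temporal
convolution, each followed by batch normalization, ELU, average pooling and
dropout. Convolutions carry no biases (normalization follows immediately).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Layer, Parameter, uniform_init
from .layers import Conv1d


class ExpandFeatureDim(Layer):
    """(N, C, T) -> (N, 1, C, T)."""

    def __init__(self, name: str = "expand"):
        self.name = name

    def forward(self, x, training=False):
        return x[:, None, :, :]

    def backward(self, grad):
        return grad[:, 0]

    def flops(self, in_shape):
        return 0, (1,) + tuple(in_shape)

    def describe(self):
        return {"op": "expand_feature_dim", "name": self.name, "weights": {}}


class ChannelwiseTemporalConv(Layer):
    """Same temporal filters applied independently to every electrode.

    Input (N, F_in, C, T) -> output (N, F_out, C, T) with 'same' padding
    (even kernels pad one sample less on the left, as is conventional).
    """

    def __init__(self, in_maps: int, out_maps: int, kernel: int,
                 rng: np.random.Generator, name: str = "temporal_conv"):
        pad = ((kernel - 1) // 2, kernel // 2)
        self.conv = Conv1d(in_maps, out_maps, kernel, rng, name=name,
                           padding=pad, bias=False)
        self.name = name
        self._nc = None

    def forward(self, x, training=False):
        n, fin, c, t = x.shape
        self._nc = (n, c)
        flat = np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(n * c, fin, t)
        out = self.conv.forward(flat, training=training)
        fout = out.shape[1]
        return np.ascontiguousarray(out.reshape(n, c, fout, t).transpose(0, 2, 1, 3))

    def backward(self, grad):
        n, fout, c, t = grad.shape
        gflat = np.ascontiguousarray(grad.transpose(0, 2, 1, 3)).reshape(n * c, fout, t)
        gx = self.conv.backward(gflat)
        fin = gx.shape[1]
        return np.ascontiguousarray(gx.reshape(n, c, fin, t).transpose(0, 2, 1, 3))

    def parameters(self):
        return self.conv.parameters()

    def param_count(self):
        return self.conv.param_count()

    def flops(self, in_shape):
        fin, c, t = in_shape
        per_channel, (fout, tout) = self.conv.flops((fin, t))
        return per_channel * c, (fout, c, tout)

    def describe(self):
        d = self.conv.describe()
        d["op"] = "channelwise_temporal_conv"
        return d


class DepthwiseSpatialConv(Layer):
    """Depthwise spatial filtering across all electrodes.

    For each of the F_in temporal maps, learns D spatial filters spanning the
    full electrode montage; output has F_in * D maps and the electrode axis
    collapses: (N, F_in, C, T) -> (N, F_in*D, T). Weights are constrained to
    unit L2 norm across the electrode axis (max-norm 1.0).
    """

    def __init__(self, in_maps: int, depth_multiplier: int, n_channels: int,
                 rng: np.random.Generator, max_norm: float = 1.0,
                 name: str = "depthwise_spatial"):
        self.in_maps = in_maps
        self.depth = depth_multiplier
        self.n_channels = n_channels
        self.name = name
        self.weight = Parameter(
            f"{name}.weight",
            uniform_init(rng, (in_maps, depth_multiplier, n_channels), n_channels),
            max_norm=max_norm, max_norm_axes=(2,),
        )
        self._x = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        out = np.einsum("nfct,fdc->nfdt", x, self.weight.data)
        n, f, d, t = out.shape
        return out.reshape(n, f * d, t)

    def backward(self, grad):
        n, fd, t = grad.shape
        g = grad.reshape(n, self.in_maps, self.depth, t)
        self.weight.grad += np.einsum("nfct,nfdt->fdc", self._x, g)
        gx = np.einsum("nfdt,fdc->nfct", g, self.weight.data)
        self._x = None
        return gx

    def parameters(self):
        return [self.weight]

    def param_count(self):
        return self.in_maps * self.depth * self.n_channels

    def flops(self, in_shape):
        fin, c, t = in_shape
        macs = fin * self.depth * c * t
        return 2 * macs, (fin * self.depth, t)

    def describe(self):
        return {"op": "depthwise_spatial_conv", "name": self.name,
                "in_maps": self.in_maps, "depth_multiplier": self.depth,
                "n_channels": self.n_channels,
                "weights": {"weight": self.weight.name}}


class DepthwiseTemporalConv(Layer):
    """Per-map temporal convolution with 'same' padding: (N, F, T) -> (N, F, T)."""

    def __init__(self, n_maps: int, kernel: int, rng: np.random.Generator,
                 name: str = "depthwise_temporal"):
        self.n_maps = n_maps
        self.kernel = kernel
        self.padding = ((kernel - 1) // 2, kernel // 2)
        self.name = name
        self.weight = Parameter(f"{name}.weight",
                                uniform_init(rng, (n_maps, kernel), kernel))
        self._win = None
        self._padded_len = 0

    def forward(self, x, training=False):
        xp = np.pad(x, ((0, 0), (0, 0), self.padding))
        self._padded_len = xp.shape[-1]
        win = sliding_window_view(xp, self.kernel, axis=2)   # n, f, t, k
        if training:
            self._win = win
        return np.einsum("nftk,fk->nft", win, self.weight.data)

    def backward(self, grad):
        self.weight.grad += np.einsum("nftk,nft->fk", self._win, grad)
        self._win = None
        n, f, t = grad.shape
        gxp = np.zeros((n, f, self._padded_len), dtype=grad.dtype)
        w = self.weight.data
        for k in range(self.kernel):
            gxp[:, :, k:k + t] += grad * w[None, :, k, None]
        left, right = self.padding
        return gxp[:, :, left:self._padded_len - right]

    def parameters(self):
        return [self.weight]

    def param_count(self):
        return self.n_maps * self.kernel

    def flops(self, in_shape):
        f, t = in_shape
        return 2 * f * t * self.kernel, (f, t)

    def describe(self):
        return {"op": "depthwise_temporal_conv", "name": self.name,
                "n_maps": self.n_maps, "kernel": self.kernel,
                "padding": list(self.padding),
                "weights": {"weight": self.weight.name}}
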