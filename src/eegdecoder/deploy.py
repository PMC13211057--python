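"""Portable model export, numerical-equivalence verification and footprint
profiling.

``export_portable`` writes a single self-contained archive (a JSON
description of the op graph plus every weight tensor) that an independent
minimal executor — :class:`PortableModel`, which shares no code with the
training layers — can run for inference anywhere NumPy exists.
``check_equivalence`` then treats the exported artifact as an untrusted
re-implementation and compares its scores against the native network on a
battery of seeded random inputs; disagreement beyond tolerance is a hard
failure. ``profile_latency`` measures per-trial (batch-1) inference time and
reports it next to the exact parameter/FLOP counts, which are
backend-invariant by construction.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .model import (
    EEGNetConfig,
    FootprintReport,
    ModelConfig,
    build_model,
    count_flops,
    count_parameters,
)
from .nn import Network

PORTABLE_FORMAT = "eegdecoder-portable"
PORTABLE_VERSION = 1


# ---------------------------------------------------------------------------
# checkpoints (native)
# ---------------------------------------------------------------------------

def save_checkpoint(net: Network, path, extra_arrays: dict | None = None) -> None:
    """Native checkpoint: weights + normalization state + config echo.

    ``extra_arrays`` may carry auxiliary tensors (e.g. the train-fitted
    channel normalizer) that deployment-time inference needs.
    """
    arrays = dict(net.state_dict())  # parameters + buffers
    if extra_arrays:
        arrays.update(extra_arrays)
    meta = json.dumps({"architecture": net.architecture, "config": net.config})
    np.savez(path, __meta__=np.array(meta), **arrays)


def _config_from_meta(meta: dict):
    if meta["architecture"] == "eegdecoder":
        return ModelConfig(**meta["config"])
    return EEGNetConfig(**meta["config"])


def load_checkpoint(path) -> Network:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    net = build_model(meta["architecture"], seed=0, model_config=_config_from_meta(meta))
    expected = set(net.state_dict())
    net.load_state_dict({k: v for k, v in arrays.items() if k in expected})
    return net


# ---------------------------------------------------------------------------
# portable export
# ---------------------------------------------------------------------------

def export_portable(net: Network, path) -> Path:
    """Export an eval-mode model as a portable single-file archive.

    The archive holds a JSON op-graph (layer kinds, attributes and weight
    names, in execution order) and all tensors. Exporting the same weights
    twice yields an identical graph description.
    """
    path = Path(path)
    ops = []
    arrays: dict[str, np.ndarray] = {}
    for lyr in net.layers:
        if not hasattr(lyr, "describe"):
            raise ValueError(f"layer {lyr!r} is not exportable")
        ops.append(lyr.describe())
        for p in lyr.parameters():
            arrays[p.name] = p.data
        if hasattr(lyr, "extra_state"):
            arrays.update(lyr.extra_state())
    graph = {
        "format": PORTABLE_FORMAT,
        "version": PORTABLE_VERSION,
        "architecture": net.architecture,
        "config": net.config,
        "input_shape": [net.config["in_channels"], net.config["input_samples"]],
        "n_classes": net.config["n_classes"],
        "ops": ops,
    }
    np.savez(path, __graph__=np.array(json.dumps(graph, sort_keys=True)), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


class PortableModel:
    """Independent inference runtime for exported archives.

    Reconstructs the computation purely from the JSON graph and the stored
    tensors; every op is implemented here from its mathematical definition,
    deliberately sharing no code with the training-layer classes.
    """

    def __init__(self, graph: dict, arrays: dict[str, np.ndarray]):
        if graph.get("format") != PORTABLE_FORMAT:
            raise ValueError("not a portable model archive")
        self.graph = graph
        self.arrays = arrays
        self.input_shape = tuple(graph["input_shape"])

    @classmethod
    def load(cls, path) -> "PortableModel":
        with np.load(path, allow_pickle=False) as z:
            graph = json.loads(str(z["__graph__"]))
            arrays = {k: z[k] for k in z.files if k != "__graph__"}
        return cls(graph, arrays)

    # -- op implementations ------------------------------------------------
    def _w(self, op, key):
        return self.arrays[op["weights"][key]]

    def _run_op(self, op: dict, x: np.ndarray) -> np.ndarray:
        kind = op["op"]
        if kind == "conv1d":
            w = self._w(op, "weight")
            left, right = op.get("padding", [0, 0])
            if left or right:
                x = np.pad(x, ((0, 0), (0, 0), (left, right)))
            win = sliding_window_view(x, w.shape[-1], axis=2)  # n, c, l, k
            y = np.einsum("nclk,ock->nol", win, w, optimize=True)
            if "bias" in op["weights"]:
                y = y + self._w(op, "bias")[None, :, None]
            return y
        if kind == "batchnorm":
            g, b = self._w(op, "weight"), self._w(op, "bias")
            rm, rv = self._w(op, "running_mean"), self._w(op, "running_var")
            shape = (1, -1) + (1,) * (x.ndim - 2)
            return ((x - rm.reshape(shape)) / np.sqrt(rv.reshape(shape) + op["eps"])
                    * g.reshape(shape) + b.reshape(shape))
        if kind == "elu":
            a = op["alpha"]
            return np.where(x > 0, x, a * (np.exp(np.minimum(x, 0.0)) - 1.0))
        if kind == "relu":
            return np.maximum(x, 0.0)
        if kind == "maxpool1d":
            k = op["kernel"]
            l = x.shape[-1] // k
            return x[..., : l * k].reshape(*x.shape[:-1], l, k).max(axis=-1)
        if kind == "avgpool1d":
            k = op["kernel"]
            l = x.shape[-1] // k
            return x[..., : l * k].reshape(*x.shape[:-1], l, k).mean(axis=-1)
        if kind == "dropout":
            return x
        if kind == "linear":
            y = x @ self._w(op, "weight").T
            if "bias" in op["weights"]:
                y = y + self._w(op, "bias")
            return y
        if kind == "layernorm":
            g, b = self._w(op, "weight"), self._w(op, "bias")
            mu = x.mean(axis=-1, keepdims=True)
            var = x.var(axis=-1, keepdims=True)
            return (x - mu) / np.sqrt(var + op["eps"]) * g + b
        if kind == "permute_ct_tc":
            return x.transpose(0, 2, 1)
        if kind == "temporal_mean_pool":
            return x.mean(axis=1)
        if kind == "flatten":
            return x.reshape(x.shape[0], -1)
        if kind == "transformer_encoder_layer":
            return self._encoder_layer(op, x)
        if kind == "expand_feature_dim":
            return x[:, None, :, :]
        if kind == "channelwise_temporal_conv":
            w = self._w(op, "weight")  # (out, in, k)
            left, right = op["padding"]
            xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (left, right)))
            win = sliding_window_view(xp, w.shape[-1], axis=3)  # n, f, c, t, k
            return np.einsum("nfctk,ofk->noct", win, w, optimize=True)
        if kind == "depthwise_spatial_conv":
            w = self._w(op, "weight")  # (f, d, c)
            y = np.einsum("nfct,fdc->nfdt", x, w, optimize=True)
            n, f, d, t = y.shape
            return y.reshape(n, f * d, t)
        if kind == "depthwise_temporal_conv":
            w = self._w(op, "weight")  # (f, k)
            left, right = op["padding"]
            xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
            win = sliding_window_view(xp, w.shape[-1], axis=2)
            return np.einsum("nftk,fk->nft", win, w, optimize=True)
        raise ValueError(f"unknown op kind {kind!r}")

    def _encoder_layer(self, op: dict, x: np.ndarray) -> np.ndarray:
        subs = {s["name"].split(".")[-1]: s for s in op["sublayers"]}
        attn = subs["self_attn"]
        d = attn["d_model"]
        h = attn["n_heads"]
        dk = d // h
        n, t, _ = x.shape

        wq = self.arrays[attn["weights"]["in_proj.weight"]]
        bq = self.arrays[attn["weights"]["in_proj.bias"]]
        qkv = x @ wq.T + bq
        q, k, v = (a.reshape(n, t, h, dk).transpose(0, 2, 1, 3)
                   for a in (qkv[..., :d], qkv[..., d:2 * d], qkv[..., 2 * d:]))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dk)
        scores -= scores.max(axis=-1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=-1, keepdims=True)
        ctx = (w @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        a_out = ctx @ self.arrays[attn["weights"]["out_proj.weight"]].T \
            + self.arrays[attn["weights"]["out_proj.bias"]]

        def ln(sub, z):
            g = self.arrays[sub["weights"]["weight"]]
            b = self.arrays[sub["weights"]["bias"]]
            mu = z.mean(axis=-1, keepdims=True)
            var = z.var(axis=-1, keepdims=True)
            return (z - mu) / np.sqrt(var + sub["eps"]) * g + b

        y = ln(subs["norm1"], x + a_out)
        f = y @ self.arrays[subs["linear1"]["weights"]["weight"]].T \
            + self.arrays[subs["linear1"]["weights"]["bias"]]
        f = np.maximum(f, 0.0)
        f = f @ self.arrays[subs["linear2"]["weights"]["weight"]].T \
            + self.arrays[subs["linear2"]["weights"]["bias"]]
        return ln(subs["norm2"], y + f)

    # -- public API --------------------------------------------------------
    def __call__(self, batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim != 3 or x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected (N, {self.input_shape[0]}, {self.input_shape[1]}), got {x.shape}"
            )
        for op in self.graph["ops"]:
            x = self._run_op(op, x)
        return x


# ---------------------------------------------------------------------------
# equivalence
# ---------------------------------------------------------------------------

@dataclass
class EquivalenceReport:
    max_abs_diff: float
    argmax_agreement: float  # over inputs whose score margin exceeds tol
    n_inputs: int
    n_margin_inputs: int
    tol: float

    @property
    def passed(self) -> bool:
        return self.max_abs_diff < self.tol and self.argmax_agreement == 1.0


def check_equivalence(net: Network, exported_path, n: int = 100,
                      tol: float = 1e-4, seed: int = 0) -> EquivalenceReport:
    """Compare native and exported scores on seeded standard-normal inputs.

    Argmax agreement is asserted only on inputs whose top-two score margin
    exceeds ``tol`` (below that, either decision is numerically legitimate).
    """
    pm = PortableModel.load(exported_path)
    rng = np.random.default_rng(seed)
    c, t = pm.input_shape
    x = rng.standard_normal((n, c, t)).astype(np.float32)
    native = net.forward(x, training=False)
    ported = pm(x)
    if native.shape != ported.shape:
        raise ValueError("output shape mismatch between native and exported model")
    diff = float(np.max(np.abs(native - ported)))
    srt = np.sort(native, axis=1)
    margin = srt[:, -1] - srt[:, -2]
    keep = margin > tol
    agree = float(np.mean(native[keep].argmax(1) == ported[keep].argmax(1))) if keep.any() else 1.0
    return EquivalenceReport(diff, agree, n, int(keep.sum()), tol)


# ---------------------------------------------------------------------------
# latency profiling
# ---------------------------------------------------------------------------

def profile_latency(model, n_trials: int = 40, warmup: int = 5,
                    seed: int = 0) -> FootprintReport:
    """Per-trial (batch-1) inference latency plus exact footprint counts.

    ``model`` is either a native :class:`Network` or a path to a portable
    archive. Latency is hardware-dependent and therefore reported, never
    asserted against a reference value. Parameter and FLOP counts are taken
    from the architecture and are identical across backends.
    """
    if isinstance(model, Network):
        runner, backend, net = model, "native-numpy", model
    else:
        try:
            pm = PortableModel.load(model)
        except (KeyError, ValueError):
            net = load_checkpoint(model)
            runner, backend = net, "native-numpy"
        else:
            runner, backend = pm, "portable-numpy"
            net = build_model(pm.graph["architecture"], seed=0,
                              model_config=_config_from_meta(pm.graph))
    c, t = (net.config["in_channels"], net.config["input_samples"])
    rng = np.random.default_rng(seed)
    trials = rng.standard_normal((n_trials + warmup, 1, c, t)).astype(np.float32)
    times = []
    for i in range(n_trials + warmup):
        t0 = time.perf_counter()
        if isinstance(runner, Network):
            runner.forward(trials[i], training=False)
        else:
            runner(trials[i])
        if i >= warmup:
            times.append((time.perf_counter() - t0) * 1e3)
    times = np.array(times)
    return FootprintReport(
        parameter_count=count_parameters(net),
        flops_per_inference=count_flops(net),
        latency_ms_mean=float(times.mean()),
        latency_ms_median=float(np.median(times)),
        latency_ms_sd=float(times.std(ddof=1)) if len(times) > 1 else 0.0,
        n_timed_trials=n_trials,
        backend=backend,
    )
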