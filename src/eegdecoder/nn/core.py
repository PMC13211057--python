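"""Minimal neural-network substrate: parameters, layers, network container.

All computation is float32 NumPy. Every layer implements an explicit
``forward``/``backward`` pair (caching what the gradient needs), a
closed-form ``param_count`` (independent of the allocated arrays), an
analytic ``flops`` accounting, and a ``describe`` record used by the
portable export format.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "data", "grad", "max_norm", "max_norm_axes")

    def __init__(self, name: str, data: np.ndarray,
                 max_norm: float | None = None, max_norm_axes=None):
        self.name = name
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.max_norm = max_norm          # optional renorm constraint
        self.max_norm_axes = max_norm_axes

    @property
    def size(self) -> int:
        return int(self.data.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def apply_constraint(self) -> None:
        if self.max_norm is None:
            return
        norms = np.sqrt(np.sum(self.data**2, axis=self.max_norm_axes, keepdims=True))
        factor = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
        self.data *= factor.astype(np.float32)


class Layer:
    """Base layer; subclasses cache forward intermediates for backward."""

    name: str = ""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def param_count(self) -> int:
        """Closed-form count of trainable scalars from configuration alone."""
        return 0

    def flops(self, in_shape: tuple) -> tuple[int, tuple]:
        """(analytic per-forward FLOPs for one item, output shape)."""
        raise NotImplementedError

    def describe(self) -> dict:
        """Serializable op record for the portable export format."""
        raise NotImplementedError


class Network:
    """An ordered layer stack with training/eval semantics.

    ``architecture`` identifies the model family (e.g. ``eegdecoder`` or
    ``eegnet``); ``config`` echoes the build configuration for audit.
    """

    def __init__(self, layers: list[Layer], architecture: str, config: dict,
                 rng: np.random.Generator | None = None):
        self.layers = layers
        self.architecture = architecture
        self.config = dict(config)
        self.rng = rng or np.random.default_rng()
        for lyr in self.layers:
            if hasattr(lyr, "set_rng"):
                lyr.set_rng(self.rng)

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for lyr in self.layers:
            x = lyr.forward(x, training=training)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for lyr in reversed(self.layers):
            grad = lyr.backward(grad)
        return grad

    def set_rng(self, rng: np.random.Generator) -> None:
        self.rng = rng
        for lyr in self.layers:
            if hasattr(lyr, "set_rng"):
                lyr.set_rng(rng)

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for lyr in self.layers:
            for p in lyr.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in network")
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        """All trainable parameters plus non-trainable buffers (e.g. batch
        normalization running statistics)."""
        state = {p.name: p.data.copy() for p in self.parameters()}
        for lyr in self.layers:
            if hasattr(lyr, "extra_state"):
                state.update({k: v.copy() for k, v in lyr.extra_state().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = {p.name: p for p in self.parameters()}
        buffer_names: set[str] = set()
        for lyr in self.layers:
            if hasattr(lyr, "extra_state"):
                buffer_names.update(lyr.extra_state())
        expected = set(params) | buffer_names
        if set(state) != expected:
            raise KeyError(
                f"state mismatch: missing {sorted(expected - set(state))}, "
                f"unexpected {sorted(set(state) - expected)}"
            )
        for name, param in params.items():
            value = state[name]
            if param.data.shape != value.shape:
                raise ValueError(f"shape mismatch for {name}")
            param.data = np.asarray(value, dtype=np.float32).copy()
        for lyr in self.layers:
            if hasattr(lyr, "load_extra_state"):
                lyr.load_extra_state(state)
            if hasattr(lyr, "_wf_cache"):   # kernel-spectrum cache is stale
                lyr._wf_cache = None

    def apply_constraints(self) -> None:
        for p in self.parameters():
            p.apply_constraint()


def uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Kaiming-style uniform initialization, bound 1/sqrt(fan_in)."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def xavier_init(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)
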