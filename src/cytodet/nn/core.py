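"""Minimal layer library with hand-derived backward passes.

Every layer implements ``forward(x)`` and ``backward(dy)``; ``backward``
accumulates parameter gradients and returns the gradient with respect to the
layer input.  Layers cache whatever the backward pass needs on ``forward``,
so a layer instance processes one forward/backward pair at a time.  All
gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size


class Module:
    """Base class: parameter discovery, train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def children(self):
        for value in vars(self).items():
            yield from _iter_modules(value[1])

    def modules(self):
        yield self
        for child in self.children():
            yield from child.modules()

    def parameters(self):
        seen = set()
        for mod in self.modules():
            for value in vars(mod).values():
                for p in _iter_params(value):
                    if id(p) not in seen:
                        seen.add(id(p))
                        yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True):
        for mod in self.modules():
            mod.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- flat (de)serialization ------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for mod in self.modules():
            arrays.extend(getattr(mod, "_buffers", lambda: [])())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        targets = self.state_arrays()
        if len(targets) != len(arrays):
            raise ValueError(
                f"state mismatch: model has {len(targets)} arrays, "
                f"checkpoint has {len(arrays)}"
            )
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


def _iter_modules(value):
    if isinstance(value, Module):
        yield value
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _iter_modules(item)
    elif isinstance(value, dict):
        for item in value.values():
            yield from _iter_modules(item)


def _iter_params(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _iter_params(item)
    elif isinstance(value, dict):
        for item in value.values():
            yield from _iter_params(item)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def __iter__(self):
        return iter(self.layers)

    def __len__(self):
        return len(self.layers)


class SGD:
    """Stochastic gradient descent with momentum and decoupled-style L2 decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
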