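"""Trainable layers and the Adam optimizer, built on :mod:`watunet.autograd`.

Layers follow the familiar Module pattern: each owns its parameter
tensors, ``parameters()`` walks the tree, and ``train()``/``eval()``
toggle batch-norm statistics and dropout.  Convolutions are initialised
He-uniform from a seeded generator so two builds with the same seed are
bitwise identical.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, tensor: Tensor) -> Tensor:
        tensor.name = f"{type(self).__name__}.{name}"
        self._params[name] = tensor
        return tensor

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array view of all parameters and buffers (for checkpoints)."""
        out = {}

        def walk(mod: Module, prefix: str):
            for k, p in mod._params.items():
                out[f"{prefix}{k}"] = p.data
            for k, b in getattr(mod, "_buffers", {}).items():
                out[f"{prefix}{k}"] = b
            for k, sub in mod._modules.items():
                walk(sub, f"{prefix}{k}.")

        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        mine = self.state_arrays()
        missing = set(mine) ^ set(state)
        if missing:
            raise ValueError(f"checkpoint/model mismatch on keys: {sorted(missing)}")
        for k, arr in mine.items():
            arr[...] = state[k]


def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 convolution with 'same' zero padding (NHWC, weights khkwIO)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.w = self.register("w", Tensor(he_uniform(rng, (k, k, cin, cout), cin * k * k)))
        self.b = self.register("b", Tensor(np.zeros(cout, dtype=np.float32))) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b)


class ConvTranspose2d(Module):
    """3x3 stride-2 transposed convolution that exactly doubles H and W."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.register("w", Tensor(he_uniform(rng, (3, 3, cin, cout), cin * 9)))
        self.b = self.register("b", Tensor(np.zeros(cout, dtype=np.float32)))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d_s2(x, self.w, self.b)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", Tensor(np.ones(c, dtype=np.float32)))
        self.beta = self.register("beta", Tensor(np.zeros(c, dtype=np.float32)))
        self._buffers = {
            "running_mean": np.zeros(c, dtype=np.float32),
            "running_var": np.ones(c, dtype=np.float32),
        }
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self._buffers["running_mean"],
            self._buffers["running_var"],
            self.training,
            self.momentum,
            self.eps,
        )


class Dropout(Module):
    """Inverted dropout; draws from a generator supplied at call time for reproducibility."""

    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        return ag.dropout(x, self.p, rng, self.training)


class Adam:
    """Adam with bias correction; hyperparameters default to this project's protocol."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.9,
        eps: float = 1e-7,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
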