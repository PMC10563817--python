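"""Neural-network building blocks (layers, parameter containers, Adam).

Thin module system over :mod:`eegfusion.autograd`.  Parameters are plain
tensors with ``requires_grad=True``; modules expose ``parameters()``,
``state_dict()``/``load_state_dict()`` and a train/eval mode flag (the flag
only affects batch-norm statistics — there is no dropout, so eval-mode
forward passes are deterministic).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d


class Module:
    """Base class; child modules and parameters are discovered by attribute scan."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- (de)serialisation -------------------------------------------------
    def _named_tensors(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v._named_tensors(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item._named_tensors(f"{key}.{i}."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_tensors().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self._named_tensors()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor):
                v.data = np.array(state[name], dtype=np.float64).reshape(v.data.shape)
            elif isinstance(v, Module):
                v.load_state_dict(
                    {k[len(name) + 1:]: a for k, a in state.items()
                     if k.startswith(f"{name}.")}
                )
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        pre = f"{name}.{i}."
                        item.load_state_dict(
                            {k[len(pre):]: a for k, a in state.items()
                             if k.startswith(pre)}
                        )

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def glorot(rng: np.random.Generator, shape: tuple[int, ...],
           fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = glorot(rng, (in_features, out_features), in_features, out_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: tuple[int, int],
                 rng: np.random.Generator, stride: tuple[int, int] = (1, 1),
                 padding: tuple[int, int] = (0, 0), bias: bool = True):
        super().__init__()
        kh, kw = kernel_size
        fan_in = in_channels * kh * kw
        fan_out = out_channels * kh * kw
        self.weight = glorot(rng, (out_channels, in_channels, kh, kw), fan_in, fan_out)
        self.bias = (Tensor(np.zeros(out_channels), requires_grad=True)
                     if bias else None)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, stride=self.stride, padding=self.padding)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out


class InstanceNorm2d(Module):
    """Per-example channel normalisation over (H, W) of a (B, C, H, W) map.

    Stateless (no running statistics), so each example's activations are
    independent of its mini-batch companions and train/eval behaviour is
    identical — loss traces and eval-mode outputs are fully deterministic.
    """

    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mean) ** 2).mean(axis=(2, 3), keepdims=True)
        xhat = (x - mean) / (var + self.eps) ** 0.5
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    """Normalisation over the last axis (token embeddings)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / (var + self.eps) ** 0.5 * self.gamma + self.beta


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.data.max(axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimiser (Kingma & Ba) with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class SGD:
    """Plain stochastic gradient descent (swap-in alternative to Adam)."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
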