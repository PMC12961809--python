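"""Layer abstractions over the autograd engine: modules, conv, batch norm.

Parameters are Kaiming-uniform initialized from an explicit
``numpy.random.Generator`` so that model construction is reproducible from a
single seed.  ``state_dict``/``load_state_dict`` serialize every parameter and
batch-norm running statistic under slash-separated names.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

__all__ = ["Module", "Conv2d", "BatchNorm2d"]


class Module:
    """Base class: tracks sub-modules/parameters by attribute introspection."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}/")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}/")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -----------------------------------------------------
    def _named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._named_buffers(f"{full}/")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{full}.{i}/")
            elif isinstance(value, np.ndarray):
                yield full, value

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: buf.copy() for name, buf in self._named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(arr, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unexpected state entry {name}")
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = Tensor(
            _kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in),
            requires_grad=True,
        )
        if bias:
            bound = 1.0 / np.sqrt(fan_in)
            self.bias = Tensor(rng.uniform(-bound, bound, size=out_ch), requires_grad=True)
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics when training, running
    averages in eval mode."""

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 affine: bool = True):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.affine = affine
        if affine:
            self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
            self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            y = _bn_train(x, mean, var, self.eps)
        else:
            mean = self.running_mean.reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
            y = (x - Tensor(mean)) * Tensor(inv)
        if self.affine:
            y = y * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)
        return y


def _bn_train(x: Tensor, mean: np.ndarray, var: np.ndarray, eps: float) -> Tensor:
    """Batch normalization with full backward through the batch statistics."""
    n, c, h, w = x.shape
    m = mean.reshape(1, c, 1, 1)
    inv = 1.0 / np.sqrt(var.reshape(1, c, 1, 1) + eps)
    xhat = (x.data - m) * inv
    out = Tensor(xhat, _parents=(x,))
    count = n * h * w

    def bwd(g):
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = inv * (g - sum_g / count - xhat * sum_gx / count)
        x._accumulate(dx)

    out._backward = bwd
    return out
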