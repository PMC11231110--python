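"""Neural-network building blocks on top of the autodiff engine.

Layers follow the usual conventions: convolutions are cross-correlations with
Kaiming-normal initial weights, batch normalization keeps running statistics
for evaluation mode, and modules expose their trainable tensors through
``parameters()`` / ``named_parameters()``.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2d


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self._modules: dict[str, "Module"] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        object.__setattr__(self, name, module)
        return module

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield (f"{prefix}{name}", getattr(self, name))
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix=f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    # Analytic cost accounting: subclasses that transform shapes or own
    # parameters implement `_summary(in_shape) -> (rows, out_shape)` where
    # `in_shape` is a single-sample shape (C, H, W) or (F,) and each row is
    # (name, kind, n_params, n_macs, out_shape). MACs follow the convention
    # that convolutions and affine maps count, while normalization, pooling
    # and elementwise ops are free.
    def _summary(self, in_shape):
        rows = []
        shape = in_shape
        for name, m in self._modules.items():
            sub, shape = m._summary(shape)
            rows.extend((f"{name}.{r[0]}" if r[0] else name, *r[1:]) for r in sub)
        own = sum(p.size for p in self._params.values())
        if own:
            rows.append(("", type(self).__name__, own, 0, shape))
        return rows, shape


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self.register(str(i), layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.standard_normal(shape) * std


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel_size, stride=1, padding=0, bias=False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        k = kernel_size
        self.c_in, self.c_out, self.kernel_size = c_in, c_out, k
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.stride, self.padding)
        if self.bias is not None:
            out = out + self.bias.reshape(1, -1, 1, 1)
        return out

    def _summary(self, in_shape):
        c, h, w = in_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        h_out = (h + 2 * p - k) // s + 1
        w_out = (w + 2 * p - k) // s + 1
        params = self.c_out * self.c_in * k * k + (self.c_out if self.bias is not None else 0)
        macs = h_out * w_out * self.c_out * self.c_in * k * k
        shape = (self.c_out, h_out, w_out)
        return [("", f"Conv2d {k}x{k}/{s}", params, macs, shape)], shape


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features, self.out_features = in_features, out_features
        bound = 1.0 / math.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out

    def _summary(self, in_shape):
        params = self.in_features * self.out_features
        if self.bias is not None:
            params += self.out_features
        macs = self.in_features * self.out_features
        shape = (self.out_features,)
        return [("", "Linear", params, macs, shape)], shape


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) with affine parameters.

    Training mode normalizes by batch statistics and updates exponential
    running averages (momentum 0.1); evaluation mode uses the running values.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._buffer_names = ("running_mean", "running_var")
        self._collecting = False

    def start_stat_collection(self) -> None:
        """Begin accumulating exact input moments (for recalibration)."""
        self._collecting = True
        self._stat_count = 0
        self._stat_sum = np.zeros(self.channels)
        self._stat_sumsq = np.zeros(self.channels)

    def finish_stat_collection(self) -> None:
        """Replace running statistics with the accumulated exact moments."""
        self._collecting = False
        n = max(self._stat_count, 1)
        mean = self._stat_sum / n
        var = self._stat_sumsq / n - mean**2
        self.running_mean = mean
        self.running_var = np.maximum(var * (n / max(n - 1, 1)), 0.0)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        view = (1, -1, 1, 1) if x.ndim == 4 else (1, -1)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) * (x - mean)).mean(axis=axes, keepdims=True)
            count = x.size // self.channels
            unbias = count / max(count - 1, 1)
            if self._collecting:
                self._stat_count += count
                self._stat_sum += x.data.sum(axis=axes)
                self._stat_sumsq += (x.data**2).sum(axis=axes)
            self.running_mean += self.momentum * (mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) * unbias - self.running_var)
        else:
            mean = Tensor(self.running_mean.reshape(view))
            var = Tensor(self.running_var.reshape(view))
        inv = (var + self.eps) ** -0.5
        return (x - mean) * inv * self.weight.reshape(view) + self.bias.reshape(view)

    def _summary(self, in_shape):
        return [("", "BatchNorm2d", 2 * self.channels, 0, in_shape)], in_shape


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel_size, self.stride, self.padding)

    def _summary(self, in_shape):
        c, h, w = in_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        shape = (c, (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)
        return [("", f"MaxPool {k}x{k}/{s}", 0, 0, shape)], shape


class GlobalAvgPool(Module):
    """Average each channel's spatial map to a single value: N,C,H,W -> N,C."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))

    def _summary(self, in_shape):
        shape = (in_shape[0],)
        return [("", "GlobalAvgPool", 0, 0, shape)], shape


class SGD:
    """Plain stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
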