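"""Neural-network layers built on :mod:`medsrnet.nn.autograd`.

Layers follow the familiar ``Module`` idiom: parameters are discovered by
recursing over attributes, ``state_dict``/``load_state_dict`` use dotted
path names, and modules are callable. Weights are created by an explicit
:class:`Initializer` so that every build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "Identity",
    "UpsampleBilinear",
    "Initializer",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Initializer:
    """Seeded He-style (fan-in) weight initialiser."""

    def __init__(self, seed: int, dtype=np.float32):
        self.rng = np.random.default_rng(seed)
        self.dtype = dtype

    def he(self, shape, fan_in: int) -> Parameter:
        std = np.sqrt(2.0 / fan_in)
        w = self.rng.normal(0.0, std, size=shape).astype(self.dtype)
        return Parameter(w)

    def zeros(self, shape) -> Parameter:
        return Parameter(np.zeros(shape, dtype=self.dtype))

    def ones(self, shape) -> Parameter:
        return Parameter(np.ones(shape, dtype=self.dtype))


class Module:
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, init: Initializer,
                 stride: int = 1, pad: int | None = None, bias: bool = True):
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        self.weight = init.he((out_ch, in_ch, kernel, kernel),
                              fan_in=in_ch * kernel * kernel)
        self.bias = init.zeros((out_ch,)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 pad: int, output_padding: int, init: Initializer,
                 bias: bool = True):
        self.stride = stride
        self.pad = pad
        self.output_padding = output_padding
        self.weight = init.he((in_ch, out_ch, kernel, kernel),
                              fan_in=in_ch * kernel * kernel)
        self.bias = init.zeros((out_ch,)) if bias else None

    def forward(self, x):
        return ag.conv_transpose2d(x, self.weight, self.bias,
                                   stride=self.stride, pad=self.pad,
                                   output_padding=self.output_padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, init: Initializer,
                 bias: bool = True):
        self.weight = init.he((out_f, in_f), fan_in=in_f)
        self.bias = init.zeros((out_f,)) if bias else None

    def forward(self, x):
        return ag.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalisation with running statistics for inference."""

    def __init__(self, ch: int, init: Initializer, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = init.ones((ch,))
        self.beta = init.zeros((ch,))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(ch, dtype=init.dtype)
        self.running_var = np.ones(ch, dtype=init.dtype)
        self.training = True

    def forward(self, x):
        if self.training:
            out, mean, var = ag.batchnorm2d(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * np.atleast_1d(mean)
            self.running_var = (1 - m) * self.running_var + m * np.atleast_1d(var)
            return out
        x = ag.as_tensor(x)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.gamma.data * inv).reshape(1, -1, 1, 1)
        shift = (self.beta.data - self.gamma.data * self.running_mean * inv)
        return ag.add(ag.mul(x, ag.Tensor(scale)),
                      ag.Tensor(shift.reshape(1, -1, 1, 1)))


class UpsampleBilinear(Module):
    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x):
        return ag.bilinear_upsample(x, self.factor)


class Adam:
    """Adam optimiser with decoupled, externally scheduled learning rate."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
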