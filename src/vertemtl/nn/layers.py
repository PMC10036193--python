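"""Layer and optimizer primitives on top of the autodiff engine."""
from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class; tracks parameters, submodules and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        """Flat dict of every parameter / running-stat array, for checkpoints."""
        out = {}

        def visit(obj, prefix):
            for k, v in obj.__dict__.items():
                name = f"{prefix}{k}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[name] = v.data
                elif isinstance(v, np.ndarray):
                    out[name] = v
                elif isinstance(v, Module):
                    visit(v, name + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{name}.{i}.")

        visit(self, "")
        return out

    def load_state_arrays(self, state):
        for name, arr in self.state_arrays().items():
            arr[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng, in_ch, out_ch, k=3, stride=1, padding=None, bias=True):
        super().__init__()
        if padding is None:
            padding = k // 2
        self.stride, self.padding = stride, padding
        self.weight = _he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, rng, in_f, out_f, bias=True):
        super().__init__()
        self.weight = _he_init(rng, (in_f, out_f), in_f)
        self.bias = Tensor(np.zeros(out_f, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(ch, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, np.float32), requires_grad=True)
        self.running_mean = np.zeros(ch, np.float32)
        self.running_var = np.ones(ch, np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        return ad.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)


class GroupNorm2d(Module):
    """Per-sample group normalization: batch-size independent, identical in
    train and eval mode — the right choice for the tiny batches the
    classification path trains with."""

    def __init__(self, ch, groups=None, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(ch, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(ch, np.float32), requires_grad=True)
        self.groups = min(groups or 8, ch)
        self.eps = eps

    def forward(self, x):
        n, c, h, w = x.data.shape
        g = self.groups
        xg = ad.reshape(x, (n, g, (c // g) * h * w))
        mu = xg.mean(axis=2, keepdims=True)
        cent = xg - mu
        var = (cent * cent).mean(axis=2, keepdims=True)
        xn = cent * ad.power(var + self.eps, -0.5)
        out = ad.reshape(xn, (n, c, h, w))
        gamma = ad.reshape(self.gamma, (1, c, 1, 1))
        beta = ad.reshape(self.beta, (1, c, 1, 1))
        return out * gamma + beta


def _make_norm(kind: str, ch: int) -> Module:
    if kind == "batch":
        return BatchNorm2d(ch)
    if kind == "group":
        return GroupNorm2d(ch)
    raise ValueError(f"unknown norm kind: {kind!r}")


class ConvBNReLU(Module):
    def __init__(self, rng, in_ch, out_ch, k=3, stride=1, norm="batch"):
        super().__init__()
        self.conv = Conv2d(rng, in_ch, out_ch, k, stride, bias=False)
        self.bn = _make_norm(norm, out_ch)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


class ResidualBlock(Module):
    """conv-norm-ReLU -> conv-norm, identity add (1x1 projection when shape
    changes). Norm is batch (default) or group."""

    def __init__(self, rng, in_ch, out_ch, stride=1, norm="batch"):
        super().__init__()
        self.conv1 = Conv2d(rng, in_ch, out_ch, 3, stride, bias=False)
        self.bn1 = _make_norm(norm, out_ch)
        self.conv2 = Conv2d(rng, out_ch, out_ch, 3, 1, bias=False)
        self.bn2 = _make_norm(norm, out_ch)
        if in_ch != out_ch or stride != 1:
            self.proj = Conv2d(rng, in_ch, out_ch, 1, stride, padding=0, bias=False)
            self.proj_bn = _make_norm(norm, out_ch)
        else:
            self.proj = None

    def shortcut(self, x):
        if self.proj is None:
            return x
        return self.proj_bn(self.proj(x))

    def forward(self, x):
        h = ad.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        return ad.relu(h + self.shortcut(x))


class SGD:
    def __init__(self, params, lr=1e-3, momentum=0.0, clip_norm=None):
        self.params = list(params)
        self.lr, self.momentum, self.clip_norm = lr, momentum, clip_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            if self.momentum:
                v *= self.momentum
                v -= self.lr * p.grad
                p.data += v
            else:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None
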