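"""Trainable layers built on the autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ConvBlock", "ResidualBlock"]


class Module:
    """Base class: parameter collection plus a train/eval mode flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, t) for n, t in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [
            (prefix + n, getattr(self, n))
            for n in getattr(self, "_buffer_names", ())
        ]
        for cname, child in self._children.items():
            out.extend(child.buffers(prefix + cname + "."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for child in self._children.values():
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Conv2d(Module):
    """Stride-1 'same' convolution with He-normal initialisation."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = self.register("w", rng.standard_normal((cout, cin, k, k)) * std)
        self.b = self.register("b", np.zeros(cout))
        self.padding = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(c))
        self.beta = self.register("beta", np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self._buffer_names = ("running_mean", "running_var")
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.batchnorm2d(
            x, self.gamma, self.beta,
            self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ConvBlock(Module):
    """conv -> (BN) -> ReLU, twice; the standard U-Net stage."""

    def __init__(self, cin: int, cout: int, use_batchnorm: bool = True, rng=None):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, rng=rng)
        self.conv2 = Conv2d(cout, cout, rng=rng)
        self.use_batchnorm = use_batchnorm
        if use_batchnorm:
            self.bn1 = BatchNorm2d(cout)
            self.bn2 = BatchNorm2d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.conv1(x)
        if self.use_batchnorm:
            x = self.bn1(x)
        x = ad.relu(x)
        x = self.conv2(x)
        if self.use_batchnorm:
            x = self.bn2(x)
        return ad.relu(x)


class ResidualBlock(Module):
    """Basic two-conv residual block (the ResNet-18 building block).

    A 1x1 projection is inserted on the skip path when the channel count
    changes; spatial size is always preserved (downsampling is done by
    pooling outside the block).
    """

    def __init__(self, cin: int, cout: int, rng=None):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.project = None
        if cin != cout:
            self.project = Conv2d(cin, cout, k=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        identity = self.project(x) if self.project is not None else x
        y = ad.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return ad.relu(ad.add(y, identity))
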