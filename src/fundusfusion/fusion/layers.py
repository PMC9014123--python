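"""Parameterised layers built on the autodiff tensors."""

from __future__ import annotations

import math
from typing import Iterator, List, Optional

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Conv2d", "Linear", "Scalar"]


class Module:
    """Base class with recursive parameter collection and train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
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

    def named_modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.named_modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.named_modules()

    def train(self) -> None:
        for m in self.named_modules():
            m.training = True

    def eval(self) -> None:
        for m in self.named_modules():
            m.training = False

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: List[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.astype(np.float64)


class Conv2d(Module):
    """3x3 (or kxk) convolution with He-normal init and optional bias."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: Optional[int] = None,
                 bias_init: float = 0.0) -> None:
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.full(out_ch, float(bias_init)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        std = math.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, size=(in_features, out_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Scalar(Module):
    """A learnable non-negative fusion weight (rectified at use)."""

    def __init__(self, value: float = 1.0) -> None:
        super().__init__()
        self.value = Tensor(np.array(value), requires_grad=True)

    def __call__(self) -> Tensor:
        return self.value.relu()
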