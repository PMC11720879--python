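"""Layer/module abstractions over the autodiff ops (torch-like surface)."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor

__all__ = [
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "BilinearUpsample",
    "Sequential",
    "ConvBNReLU",
]


class Module:
    """Base class: submodule/parameter discovery, train/eval mode, state IO."""

    def __init__(self) -> None:
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def modules(self):
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for prefix, value in sorted(self.__dict__.items()):
            if isinstance(value, Tensor):
                yield prefix, value
            elif isinstance(value, Module):
                for name, p in value.named_parameters():
                    yield f"{prefix}.{name}", p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for name, p in item.named_parameters():
                            yield f"{prefix}.{i}.{name}", p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name]).astype(p.data.dtype)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"]).astype(
                    m.running_mean.dtype
                )
                m.running_var = np.asarray(state[f"__bn{i}.running_var"]).astype(
                    m.running_var.dtype
                )


class Conv2d(Module):
    """Stride-1 "same" convolution with Kaiming-uniform initialisation."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel_size: int = 3,
        dilation: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel_size * kernel_size
        bound = np.sqrt(6.0 / fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (out_ch, in_ch, kernel_size, kernel_size)).astype(
                dtype
            ),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True) if bias else None
        )
        self.dilation = dilation
        self.in_ch, self.out_ch, self.kernel_size = in_ch, out_ch, kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, dilation=self.dilation)

    def named_parameters(self):
        yield "weight", self.weight
        if self.bias is not None:
            yield "bias", self.bias


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(n_ch, dtype=np.float64)
        self.running_var = np.ones(n_ch, dtype=np.float64)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.sigmoid(x)


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.maxpool2x2(x)


class BilinearUpsample(Module):
    """Bilinear resize to a fixed size or by a scale factor (half-pixel
    centres convention)."""

    def __init__(self, size: tuple[int, int] | None = None, scale: int | None = None):
        super().__init__()
        if (size is None) == (scale is None):
            raise ValueError("give exactly one of size or scale")
        self.size, self.scale = size, scale

    def forward(self, x: Tensor) -> Tensor:
        out_hw = self.size or (x.shape[2] * self.scale, x.shape[3] * self.scale)
        return F.bilinear_resize(x, out_hw)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def ConvBNReLU(
    in_ch: int,
    out_ch: int,
    rng: np.random.Generator,
    kernel_size: int = 3,
    dilation: int = 1,
) -> Sequential:
    """The standard conv -> batch norm -> ReLU unit."""
    return Sequential(
        Conv2d(in_ch, out_ch, kernel_size, dilation=dilation, rng=rng),
        BatchNorm2d(out_ch),
        ReLU(),
    )
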