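"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray) and not isinstance(value, Tensor):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self) -> "Module":
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer::" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer::"):
                buf = buffers[key[len("buffer::"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                p.data[...] = value

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def he_init(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    """Kaiming-normal initialization for a conv weight feeding a ReLU."""
    std = np.sqrt(2.0 / (cin * k * k))
    return rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 padding: Optional[int] = None, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.weight = Parameter(he_init(rng, cout, cin, kernel))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.weight, self.bias,
                             self.running_mean, self.running_var,
                             self.training, self.momentum, self.eps)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x


class ConvBNReLU(Module):
    """3x3 convolution + batch normalization + ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))


class DoubleConv(Module):
    """The canonical U-Net stage: two 3x3 conv + BN + ReLU layers."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.block1 = ConvBNReLU(cin, cout, rng)
        self.block2 = ConvBNReLU(cout, cout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class ResBlock(Module):
    """Residual unit: conv3x3-BN-ReLU-conv3x3-BN, input added before final ReLU.

    When ``stride`` is 2 (or channel counts differ) the identity path uses a
    1x1 strided projection, as in the standard ResNet34 downsampling blocks.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, stride=stride, padding=0,
                               bias=False, rng=rng)
            self.proj_bn = BatchNorm2d(cout)
        else:
            self.proj = None
            self.proj_bn = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn2(self.conv2(ag.relu(self.bn1(self.conv1(x)))))
        skip = x if self.proj is None else self.proj_bn(self.proj(x))
        return ag.relu(ag.add(y, skip))


class AttentionGate(Module):
    """Additive attention on a skip connection.

    The gating signal ``g`` (decoder feature, already up-sampled to the skip
    resolution) and the skip feature ``x`` are each mapped to an intermediate
    width by 1x1 convolutions, summed, passed through ReLU and a 1x1
    single-channel sigmoid head; the skip is scaled by the resulting
    per-pixel attention coefficients.
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator,
                 inter_ch: Optional[int] = None):
        super().__init__()
        inter_ch = inter_ch or max(skip_ch // 2, 1)
        self.theta_x = Conv2d(skip_ch, inter_ch, 1, padding=0, bias=False, rng=rng)
        self.theta_g = Conv2d(gate_ch, inter_ch, 1, padding=0, bias=True, rng=rng)
        self.psi = Conv2d(inter_ch, 1, 1, padding=0, bias=True, rng=rng)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:  # type: ignore[override]
        att = ag.sigmoid(self.psi(ag.relu(ag.add(self.theta_x(x), self.theta_g(g)))))
        return ag.mul(x, att)

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:  # type: ignore[override]
        return self.forward(x, g)
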