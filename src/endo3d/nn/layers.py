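"""Layer modules built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "ReLU",
    "LeakyReLU",
    "Tanh",
    "Sigmoid",
    "Sequential",
    "ResidualBlock",
]


class Module:
    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data.copy()
            elif isinstance(v, Module):
                out.update(v.state_dict(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_dict(f"{key}.{i}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                if key not in state:
                    raise KeyError(f"missing parameter {key!r} in checkpoint")
                if state[key].shape != v.data.shape:
                    raise ValueError(
                        f"shape mismatch for {key!r}: checkpoint "
                        f"{state[key].shape} vs model {v.data.shape}"
                    )
                v.data = state[key].astype(np.float32).copy()
            elif isinstance(v, Module):
                v.load_state_dict(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, padding=0, rng=None,
                 init_std: float | None = 0.02, bias=True):
        rng = rng or np.random.default_rng(0)
        if init_std is None:  # He initialization
            init_std = float(np.sqrt(2.0 / (c_in * kernel * kernel)))
        self.weight = Tensor(
            rng.normal(0.0, init_std, size=(c_out, c_in, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Fractionally-strided ("stride 1/2") upsampling convolution."""

    def __init__(self, c_in, c_out, kernel, stride=2, padding=1, rng=None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(
            rng.normal(0.0, init_std, size=(c_in, c_out, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, self.stride, self.padding)


class InstanceNorm2d(Module):
    def __init__(self, c: int):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.instance_norm(self.gamma, self.beta)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ResidualBlock(Module):
    """conv-norm-relu-conv-norm with an identity shortcut."""

    def __init__(self, c: int, rng=None):
        self.conv1 = Conv2d(c, c, 3, 1, 1, rng)
        self.norm1 = InstanceNorm2d(c)
        self.conv2 = Conv2d(c, c, 3, 1, 1, rng)
        self.norm2 = InstanceNorm2d(c)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h
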