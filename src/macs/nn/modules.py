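"""Layer/module containers with named parameters and checkpointing."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autodiff import DTYPE, Tensor


class Module:
    """Base class; parameters are discovered by attribute walking."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, v in state.items():
            params[k].data[...] = np.asarray(v, dtype=DTYPE)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Convolution layer with He-normal initialisation from a seeded RNG."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, groups: int = 1,
                 bias: bool = True):
        if padding is None:
            padding = kernel // 2
        if cin % groups or cout % groups:
            raise ValueError("channels must divide groups")
        fan_in = cin // groups * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin // groups, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding, groups=self.groups)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(x, self.slope)
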