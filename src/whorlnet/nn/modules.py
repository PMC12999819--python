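"""Module/Parameter containers over the autodiff engine."""
from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, batch_norm2d, conv2d, layer_norm, upsample_nearest2x

_INIT_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Seed parameter initialization globally (call before building a model)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer." + name] = b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, val in state.items():
            if key.startswith("buffer."):
                target = bufs[key[len("buffer."):]]
                np.copyto(target, val)
            else:
                p = params[key]
                if p.data.shape != val.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: {p.data.shape} vs {val.shape}")
                p.data = val.astype(np.float32).copy()
        missing = set(params) - {k for k in state if not k.startswith("buffer.")}
        if missing:
            raise ValueError(f"missing parameters in state dict: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._seq = list(mods)

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """Bare convolution (no norm/activation). Kaiming-uniform init."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 g: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.groups = s, g
        self.padding = k // 2 if p is None else p
        fan_in = c1 // g * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(
            _INIT_RNG.uniform(-bound, bound, (c2, c1 // g, k, k)))
        self.bias = Parameter(_INIT_RNG.uniform(-bound, bound, c2)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.weight, self.bias, self.running_mean,
                            self.running_var, self.training, self.momentum,
                            self.eps)


class LayerNorm(Module):
    """Normalizes the last axis (token/channel-last layout)."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


class Linear(Module):
    def __init__(self, c1: int, c2: int, bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(c1)
        self.weight = Parameter(_INIT_RNG.uniform(-bound, bound, (c1, c2)))
        self.bias = Parameter(_INIT_RNG.uniform(-bound, bound, c2)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x.matmul(self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Upsample2x(Module):
    def forward(self, x):
        return upsample_nearest2x(x)


class ConvBNAct(Module):
    """conv -> batch norm -> activation, the detector's standard conv unit."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 g: int = 1, act: bool | str = True):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, g, bias=False)
        self.bn = BatchNorm2d(c2)
        if act is True or act == "silu":
            self.act: Module = SiLU()
        elif act == "relu":
            self.act = ReLU()
        else:
            self.act = Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class DWConvBNAct(ConvBNAct):
    """Depth-wise conv unit (groups == channels)."""

    def __init__(self, c: int, k: int = 3, s: int = 1, act: bool | str = True):
        super().__init__(c, c, k, s, g=c, act=act)
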