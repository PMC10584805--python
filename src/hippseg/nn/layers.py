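"""Layer abstractions over the autodiff core: conv, batch-norm, containers.

A :class:`Module` owns named parameters (:class:`~hippseg.nn.tensor.Tensor`
with ``requires_grad=True``) and child modules; ``state_dict`` /
``load_state_dict`` give bit-exact checkpointing, and ``train``/``eval``
toggle batch-norm statistics.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv3d

__all__ = ["Module", "Conv3d", "BatchNorm3d", "ConvBlock"]


class Module:
    """Base class: parameter registration, mode switching, checkpointing."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, p in self._params.items():
            out[prefix + k] = p.data.copy()
        for k, b in self._buffers.items():
            out[prefix + k] = np.asarray(b).copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k, p in self._params.items():
            p.data = np.asarray(state[prefix + k], dtype=np.float64).copy()
        for k in list(self._buffers):
            arr = np.asarray(state[prefix + k]).copy()
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3D convolution layer with optional bias; weights filled by the
    network-level initializer (He-normal by default)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 stride: int = 1, padding: int | None = None,
                 bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding = (kernel - 1) // 2 if padding is None else padding
        self.weight = Tensor(np.zeros((out_ch, in_ch, kernel, kernel, kernel)),
                             requires_grad=True, name="weight")
        self.bias = (Tensor(np.zeros(out_ch), requires_grad=True, name="bias")
                     if bias else None)

    @property
    def fan_in(self) -> int:
        return self.in_ch * self.kernel**3

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm3d(Module):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.ravel())
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.ravel())
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ConvBlock(Module):
    """Two (conv 3x3x3 -> BN -> ReLU) stages, the encoder/decoder unit."""

    def __init__(self, in_ch: int, out_ch: int):
        super().__init__()
        self.conv1 = Conv3d(in_ch, out_ch, 3)
        self.bn1 = BatchNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, 3)
        self.bn2 = BatchNorm3d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()
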