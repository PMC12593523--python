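"""Layer/module system on top of the autodiff tensor.

Conventions follow the common deep-learning layout: activations are
``(N, C, D1, D2, D3)`` for volumetric layers and ``(N, F)`` for dense layers.
Convolutions are bias-free by default (batch norm's shift makes a bias
redundant); batch norm keeps running statistics for inference mode.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "Linear",
    "Dropout",
    "Mish",
    "ReLU",
    "Sequential",
    "same_padding",
]


def same_padding(kernel: tuple[int, int, int]) -> tuple[int, int, int]:
    """Padding that preserves spatial size for odd kernels at stride 1."""
    if any(k % 2 == 0 for k in kernel):
        raise ValueError(f"same padding requires odd kernels, got {kernel}")
    return tuple((k - 1) // 2 for k in kernel)


class Module:
    """Minimal module base: parameter discovery, train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            for m in _collect_modules(value):
                mods.extend(m.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array view of all parameters (for checkpoints)."""
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"p{i}"], dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_modules(value) -> list["Module"]:
    if isinstance(value, Module):
        return [value]
    if isinstance(value, (list, tuple)):
        out: list[Module] = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        stride: tuple[int, int, int] = (1, 1, 1),
        pad: tuple[int, int, int] | str = "same",
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.pad = same_padding(self.kernel) if pad == "same" else tuple(pad)
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU-family activations
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels, *self.kernel)).astype(
                np.float32
            ),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_channels, np.float32), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = x.conv3d(self.weight, stride=self.stride, pad=self.pad)
        if self.bias is not None:
            y = y + self.bias.reshape(1, -1, 1, 1, 1)
        return y


class ConvTranspose3d(Module):
    """Transposed 3-D convolution: zero-insertion upsampling followed by a
    full correlation with the flipped kernel (the exact adjoint of Conv3d).

    Output size per axis: ``(M - 1)*stride - 2*pad + kernel``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        stride: tuple[int, int, int] = (1, 1, 1),
        pad: tuple[int, int, int] = (0, 0, 0),
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        self.pad = tuple(pad)
        fan_in = in_channels * int(np.prod(self.kernel))
        scale = np.sqrt(2.0 / fan_in)
        # stored in Conv3d orientation (in, out, k) so the adjoint is a plain conv
        self.weight = Tensor(
            rng.normal(0.0, scale, (in_channels, out_channels, *self.kernel)).astype(
                np.float32
            ),
            requires_grad=True,
        )

    def forward(self, x: Tensor) -> Tensor:
        k, p = self.kernel, self.pad
        z = x.zero_insert(self.stride)
        w = self.weight.flip((2, 3, 4)).swapaxes(0, 1)  # (out, in, k)
        return z.conv3d(w, stride=(1, 1, 1), pad=tuple(k[i] - 1 - p[i] for i in range(3)))


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D1, D2, D3).

    ``eps`` defaults to 1e-4 (the stability constant of the classifier's
    normalization layer); scale/shift are learnable, initialized to 1/0, and
    running statistics with the given momentum serve inference mode.
    """

    def __init__(self, channels: int, eps: float = 1e-4, momentum: float = 0.1) -> None:
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float64)
        self.running_var = np.ones(channels, np.float64)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = x.batchnorm(self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        mu = self.running_mean.reshape(1, -1, 1, 1, 1)
        var = self.running_var.reshape(1, -1, 1, 1, 1)
        xhat = (x - Tensor(mu.astype(x.data.dtype))) * Tensor(
            (1.0 / np.sqrt(var + self.eps)).astype(x.data.dtype)
        )
        return xhat * self.gamma.reshape(1, -1, 1, 1, 1) + self.beta.reshape(
            1, -1, 1, 1, 1
        )


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, (in_features, out_features)).astype(np.float32),
            requires_grad=True,
        )
        self.bias = (
            Tensor(np.zeros(out_features, np.float32), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Dropout(Module):
    def __init__(self, p: float = 0.3, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(x.data.dtype))


class Mish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mish()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
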