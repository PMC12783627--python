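"""Neural-network layers and the Adam optimizer on top of the autodiff engine.

Layers follow the familiar module pattern: parameters are leaf tensors with
``requires_grad=True``; ``forward`` builds the computation graph. Convolutions
are bias-free (batch normalization follows most of them and the architecture
tables' parameter counts assume no bias); dense layers carry a bias.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in vars(self).values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- state (de)serialization ---------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus buffers (e.g. batch-norm running statistics)."""
        arrays: list[np.ndarray] = []
        for m in self.modules():
            for value in vars(m).values():
                if isinstance(value, Tensor):
                    arrays.append(value.data)
                elif isinstance(value, np.ndarray):
                    arrays.append(value)
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for m in self.modules():
            for name, value in list(vars(m).items()):
                if isinstance(value, (Tensor, np.ndarray)):
                    src = np.asarray(next(it), dtype=np.float64)
                    target = value.data if isinstance(value, Tensor) else value
                    if src.shape != target.shape:
                        raise ValueError(
                            f"state shape mismatch: {src.shape} vs {target.shape}"
                        )
                    if isinstance(value, Tensor):
                        value.data = src
                    else:
                        setattr(m, name, src)


def _init_weights(rng: np.random.Generator, shape, fan_in: int,
                  init_std: float | None) -> np.ndarray:
    """He-scaled by default; fixed-std normal when ``init_std`` is given
    (the DCGAN convention, used by the discriminator)."""
    std = init_std if init_std is not None else np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 use_bias: bool = True, init_std: float | None = None):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(
            _init_weights(rng, (in_features, out_features), in_features,
                          init_std),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if use_bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """Bias-free 2-D convolution via explicit im2col gather + matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, padding: int, rng: np.random.Generator,
                 init_std: float | None = None):
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel * kernel
        self.weight = Tensor(
            _init_weights(rng, (out_channels, fan_in), fan_in, init_std),
            requires_grad=True)
        self._idx_cache: dict[tuple[int, int], tuple[np.ndarray, int, int]] = {}

    def _indices(self, hp: int, wp: int) -> tuple[np.ndarray, int, int]:
        key = (hp, wp)
        if key not in self._idx_cache:
            k, s = self.kernel, self.stride
            oh = (hp - k) // s + 1
            ow = (wp - k) // s + 1
            c = self.in_channels
            ci, ki, kj, oi, oj = np.meshgrid(
                np.arange(c), np.arange(k), np.arange(k),
                np.arange(oh), np.arange(ow), indexing="ij",
            )
            flat = ((ci * hp + oi * s + ki) * wp + oj * s + kj).reshape(-1)
            self._idx_cache[key] = (flat.astype(np.intp), oh, ow)
        return self._idx_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        xp = ag.pad2d(x, self.padding)
        hp, wp = h + 2 * self.padding, w + 2 * self.padding
        idx, oh, ow = self._indices(hp, wp)
        ckk = self.in_channels * self.kernel * self.kernel
        cols = ag.take_columns(xp.reshape(b, c * hp * wp), idx)
        cols = cols.reshape(b, ckk, oh * ow)
        out = ag.bmm(self.weight, cols)  # (B, O, OH*OW)
        return out.reshape(b, self.out_channels, oh, ow)


class ConvTranspose2d(Module):
    """Transposed convolution as zero-interleaving followed by convolution.

    Kernel 4, stride 2, padding 1 doubles the spatial dimensions exactly.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int, padding: int, rng: np.random.Generator,
                 init_std: float | None = None):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self.conv = Conv2d(in_channels, out_channels, kernel, 1,
                           kernel - 1 - padding, rng, init_std=init_std)
        self._idx_cache: dict[tuple[int, int], tuple[np.ndarray, int, int]] = {}

    def _up_indices(self, h: int, w: int) -> tuple[np.ndarray, int, int]:
        key = (h, w)
        if key not in self._idx_cache:
            s = self.stride
            hs = (h - 1) * s + 1
            ws = (w - 1) * s + 1
            c = self.in_channels
            ci, i, j = np.meshgrid(np.arange(c), np.arange(h), np.arange(w),
                                   indexing="ij")
            flat = ((ci * hs + i * s) * ws + j * s).reshape(-1)
            self._idx_cache[key] = (flat.astype(np.intp), hs, ws)
        return self._idx_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        idx, hs, ws = self._up_indices(h, w)
        flat = x.reshape(b, c * h * w)
        up = ag.scatter_columns(flat, idx, c * hs * ws).reshape(b, c, hs, ws)
        return self.conv(up)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - m
            v = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * m.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * v.data)
            xhat = centered * ag.power(v + self.eps, -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * ag.power(
                Tensor(self.running_var) + self.eps, -0.5)
        return self.gamma * xhat + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class Activation(Module):
    def __init__(self, name: str):
        self.name = name

    def forward(self, x: Tensor) -> Tensor:
        if self.name == "relu":
            return ag.relu(x)
        if self.name == "leaky_relu":
            return ag.leaky_relu(x, 0.2)
        if self.name == "tanh":
            return ag.tanh(x)
        if self.name == "sigmoid":
            return ag.sigmoid(x)
        if self.name == "none":
            return x
        raise ValueError(f"unknown activation {self.name!r}")


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with the conventional bias correction; operates on leaf tensors."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self, grads: list[Tensor]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
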