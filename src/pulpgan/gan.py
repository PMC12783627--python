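"""Generator and discriminator builders with exact parameter accounting.

The reference architecture maps a latent noise vector through a dense
projection to a 4x4 feature map, then alternates stride-2 transposed
convolutions (kernel 4 — the checkerboard-safe choice that doubles the
resolution exactly) with dense blocks of growth rates 64/32/16/8, finishing
with two refinement convolutions and a tanh head at 128x128x3. The
discriminator alternates stride-2 and stride-1 3x3 convolutions through a
64-128-256-512 channel schedule, then flatten, dense(512), dropout and a
single sigmoid unit. Convolutions are bias-free (their printed parameter
counts equal in*out*k^2 exactly and batch norm follows most of them); dense
layers carry a bias. A ``width_multiplier`` scales every channel count so the
same topology runs at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (Adam, BatchNorm2d, Conv2d, ConvTranspose2d, Dense,
                        Dropout, Module)

__all__ = [
    "LayerSpec",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "count_layer_parameters",
    "build_generator",
    "build_discriminator",
    "generate_batch",
    "to_unit_interval",
    "save_checkpoint",
    "load_checkpoint",
]

_ACTIVATIONS = ("relu", "leaky_relu", "tanh", "sigmoid", "none")
_KINDS = ("dense", "conv", "conv_transpose", "dense_block", "batch_norm",
          "flatten", "dropout")


@dataclass
class LayerSpec:
    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 1
    stride: int = 1
    activation: str = "none"
    use_bias: bool = False
    growth_rate: int | None = None   # dense_block only
    n_internal: int = 4              # dense_block internal conv layers

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")


def count_layer_parameters(layer: LayerSpec) -> int:
    """Exact trainable-parameter count under the package's conventions."""
    k2 = layer.kernel * layer.kernel
    if layer.kind in ("conv", "conv_transpose"):
        n = layer.in_channels * layer.out_channels * k2
        return n + (layer.out_channels if layer.use_bias else 0)
    if layer.kind == "dense":
        n = layer.in_channels * layer.out_channels
        return n + (layer.out_channels if layer.use_bias else 0)
    if layer.kind == "batch_norm":
        return 2 * layer.out_channels
    if layer.kind == "dense_block":
        if layer.growth_rate is None:
            raise ValueError("dense_block requires growth_rate")
        g = layer.growth_rate
        total = 0
        ch = layer.in_channels
        for i in range(layer.n_internal):
            total += (ch + i * g) * g * k2
        total += (ch + layer.n_internal * g) * layer.out_channels * k2
        return total
    return 0  # flatten, dropout


@dataclass
class GeneratorSpec:
    latent_dim: int = 128            # 100 also supported
    base_resolution: int = 4
    output_resolution: int = 128
    output_channels: int = 3
    width_multiplier: float = 1.0
    dense_block_growth_rates: tuple[int, ...] = (64, 32, 16, 8)
    identity_skips: bool = False
    base_channels: int = 1024

    def __post_init__(self):
        ratio = self.output_resolution / self.base_resolution
        k = np.log2(ratio)
        if ratio < 1 or abs(k - round(k)) > 1e-9:
            raise ValueError(
                "output_resolution must be base_resolution * 2^k")

    @property
    def n_upsamples(self) -> int:
        return int(round(np.log2(self.output_resolution
                                 / self.base_resolution)))


@dataclass
class DiscriminatorSpec:
    input_resolution: int = 128
    input_channels: int = 3
    channel_schedule: tuple[int, ...] = (64, 128, 256, 512)
    dropout_rate: float = 0.3        # 0.4 also appears in print; 0.3 default
    dense_units: int = 512
    width_multiplier: float = 1.0

    def __post_init__(self):
        if list(self.channel_schedule) != sorted(set(self.channel_schedule)):
            raise ValueError("channel_schedule must be strictly increasing")
        if self.input_resolution % 2 ** len(self.channel_schedule):
            raise ValueError(
                f"input resolution {self.input_resolution} not divisible by "
                f"2^{len(self.channel_schedule)}")


def _scaled(ch: int, width: float, floor: int = 4) -> int:
    return max(floor, int(round(ch * width)))


class DenseBlock(Module):
    """Densely connected 3x3 convolutions with a transition back to the
    stage width; optionally wrapped in an identity (residual) skip."""

    def __init__(self, channels: int, growth: int, rng, n_internal: int = 4,
                 identity_skip: bool = False):
        self.identity_skip = identity_skip
        self.convs = [Conv2d(channels + i * growth, growth, 3, 1, 1, rng)
                      for i in range(n_internal)]
        self.transition = Conv2d(channels + n_internal * growth, channels,
                                 3, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = x
        for conv in self.convs:
            new = ag.relu(conv(feats))
            feats = ag.concat([feats, new], axis=1)
        out = ag.relu(self.transition(feats))
        if self.identity_skip:
            out = out + x
        return out


class Generator(Module):
    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        ch = _scaled(spec.base_channels, spec.width_multiplier)
        self.project = Dense(spec.latent_dim,
                             spec.base_resolution**2 * ch, rng)
        self.project_bn = BatchNorm2d(ch)
        self._base_ch = ch
        self.ups: list[Module] = []
        self.bns: list[Module] = []
        self.blocks: list[Module] = []
        growths = spec.dense_block_growth_rates
        for i in range(spec.n_upsamples):
            nxt = max(4, ch // 2)
            self.ups.append(ConvTranspose2d(ch, nxt, 4, 2, 1, rng))
            self.bns.append(BatchNorm2d(nxt))
            if i < spec.n_upsamples - 1:
                g = _scaled(growths[i % len(growths)], spec.width_multiplier)
                self.blocks.append(DenseBlock(nxt, g, rng,
                                              identity_skip=spec.identity_skips))
            ch = nxt
        refine = max(4, ch // 2)
        self.refine = Conv2d(ch, refine, 3, 1, 1, rng)
        self.head = Conv2d(refine, spec.output_channels, 3, 1, 1, rng)

    def forward(self, z: Tensor) -> Tensor:
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(f"latent dim {z.shape[1]} != spec "
                             f"{self.spec.latent_dim}")
        b = z.shape[0]
        r = self.spec.base_resolution
        x = self.project(z).reshape(b, self._base_ch, r, r)
        x = ag.relu(self.project_bn(x))
        block_iter = iter(self.blocks)
        for i, (up, bn) in enumerate(zip(self.ups, self.bns)):
            x = ag.relu(bn(up(x)))
            if i < len(self.ups) - 1:
                x = next(block_iter)(x)
        x = ag.relu(self.refine(x))
        return ag.tanh(self.head(x))


class Discriminator(Module):
    """Strided-conv classifier; weights drawn N(0, 0.02) per the DCGAN
    convention so the critic's input-gradient norms start near the
    gradient-penalty target instead of orders of magnitude above it."""

    INIT_STD = 0.02

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0,
                 dropout_rng: np.random.Generator | None = None):
        rng = np.random.default_rng(seed)
        std = self.INIT_STD
        self.spec = spec
        self.convs: list[Module] = []
        self.bns: list[Module] = []
        prev = spec.input_channels
        for ch in spec.channel_schedule:
            c = _scaled(ch, spec.width_multiplier)
            self.convs.append(Conv2d(prev, c, 3, 2, 1, rng, init_std=std))
            self.convs.append(Conv2d(c, c, 3, 1, 1, rng, init_std=std))
            self.bns.append(BatchNorm2d(c))
            prev = c
        res = spec.input_resolution // 2 ** len(spec.channel_schedule)
        units = _scaled(spec.dense_units, spec.width_multiplier, floor=8)
        self._flat = prev * res * res
        self.dense = Dense(self._flat, units, rng, init_std=std)
        self.dropout = Dropout(spec.dropout_rate,
                               dropout_rng or np.random.default_rng(seed + 1))
        self.out = Dense(units, 1, rng, init_std=std)

    def forward_features(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (logit, penultimate feature vector)."""
        if x.shape[2] != self.spec.input_resolution:
            raise ValueError(f"input resolution {x.shape[2]} != spec "
                             f"{self.spec.input_resolution}")
        cur = x
        for i in range(len(self.bns)):
            cur = ag.leaky_relu(self.convs[2 * i](cur), 0.2)
            cur = ag.leaky_relu(self.convs[2 * i + 1](cur), 0.2)
            cur = self.bns[i](cur)
        flat = cur.reshape(x.shape[0], self._flat)
        feat = ag.leaky_relu(self.dense(flat), 0.2)
        logit = self.out(self.dropout(feat))
        return logit, feat

    def forward(self, x: Tensor) -> Tensor:
        """Logit output; apply sigmoid for a probability in (0, 1)."""
        return self.forward_features(x)[0]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with ag.no_grad():
                logit = self.forward(Tensor(images))
        finally:
            self.train(was_training)
        return 1.0 / (1.0 + np.exp(-logit.data[:, 0]))


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    return Generator(spec, seed=seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> Discriminator:
    return Discriminator(spec, seed=seed)


def to_unit_interval(images: np.ndarray) -> np.ndarray:
    """Affine map from the generator's tanh range [-1, 1] to [0, 1]."""
    return (np.asarray(images) + 1.0) / 2.0


def generate_batch(generator: Generator, noise: np.ndarray | None = None,
                   n: int | None = None, seed: int | None = None
                   ) -> np.ndarray:
    """Sample images in [-1, 1] from noise (or ``n`` seeded draws)."""
    if noise is None:
        if n is None or seed is None:
            raise ValueError("provide noise or both n and seed")
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((n, generator.spec.latent_dim))
    noise = np.asarray(noise, dtype=float)
    if noise.ndim != 2 or noise.shape[1] != generator.spec.latent_dim:
        raise ValueError(
            f"noise must be (n, {generator.spec.latent_dim}), got {noise.shape}")
    generator.eval()
    with ag.no_grad():
        out = generator(Tensor(noise))
    generator.train()
    return out.data


def save_checkpoint(path, generator: Generator,
                    discriminator: Discriminator | None = None,
                    rng_state: dict | None = None) -> None:
    """Single-file archive: specs as JSON, weights as arrays."""
    meta = {
        "generator_spec": asdict(generator.spec),
        "discriminator_spec": (asdict(discriminator.spec)
                               if discriminator else None),
        "rng_state": rng_state or {},
    }
    arrays = {"__meta__": np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)}
    for i, arr in enumerate(generator.state_arrays()):
        arrays[f"g_{i}"] = arr
    if discriminator is not None:
        for i, arr in enumerate(discriminator.state_arrays()):
            arrays[f"d_{i}"] = arr
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[Generator, Discriminator | None, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        g_arrays = [data[f"g_{i}"] for i in range(
            sum(1 for k in data.files if k.startswith("g_")))]
        d_arrays = [data[f"d_{i}"] for i in range(
            sum(1 for k in data.files if k.startswith("d_")))]
    gspec = GeneratorSpec(**{**meta["generator_spec"],
                             "dense_block_growth_rates": tuple(
                                 meta["generator_spec"]["dense_block_growth_rates"])})
    gen = Generator(gspec)
    gen.load_state_arrays(g_arrays)
    disc = None
    if meta["discriminator_spec"] is not None:
        dspec = DiscriminatorSpec(**{**meta["discriminator_spec"],
                                     "channel_schedule": tuple(
                                         meta["discriminator_spec"]["channel_schedule"])})
        disc = Discriminator(dspec)
        disc.load_state_arrays(d_arrays)
    return gen, disc, meta.get("rng_state", {})
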