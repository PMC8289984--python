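"""The four adversarial-autoencoder networks, with progressive growing.

The model couples an encoder and a generator into an autoencoder and trains
it adversarially with two critics: an image discriminator (real images vs
generated/reconstructed ones) and a code discriminator (standard-Gaussian
prior draws vs encoder outputs).  The code discriminator replaces the closed
form KL term of a variational autoencoder, so the encoder is deterministic.

Architecture (defaults, working resolution 256):

* generator: linear 128 -> 4x4x512, then per doubling nearest-neighbor x2
  upsampling and a 3x3 convolution (leaky-ReLU) halving the channel count
  down the ladder 512/256/128/64/32/16/8, finishing with a 1x1 convolution
  and tanh to a single channel;
* encoder: the mirror image - 1x1 convolution in, alternating 3x3
  convolutions (leaky-ReLU) and 2x2 average-pool downsamplings up the
  ladder to 4x4x512, then a linear map to the 128-D latent code;
* discriminator: the encoder trunk with a single linear logit out;
* code discriminator: a two-layer perceptron 128 -> 1500 -> 1.

Channel schedule: channels(r) = min(max_channels, base_channels *
max_resolution / r).

Progressive growing starts at 4x4 and doubles the working resolution in
stages.  Each resolution has its own 1x1 image head (to-image for the
generator, from-image for the encoder and discriminator); after a ``grow``
the new stage is blended with the upsampled/downsampled old pathway by
``fade_alpha`` in image space, so at fade_alpha=0 the grown generator
reproduces a naive upsampling of its pre-grow output exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import InvalidSpecError, ShapeError, StateError
from .nn import Conv2d, Linear, Module, Tensor

MIN_RESOLUTION = 4


@dataclass(frozen=True)
class NetworkConfig:
    latent_dim: int = 128
    max_resolution: int = 256
    base_channels: int = 8
    max_channels: int = 512
    lrelu_slope: float = 0.2
    code_disc_hidden: int = 1500

    def __post_init__(self):
        r = self.max_resolution
        if r < MIN_RESOLUTION or (r & (r - 1)) != 0:
            raise InvalidSpecError(
                f"max_resolution must be a power of two >= 4, got {r}")
        if min(self.latent_dim, self.base_channels, self.max_channels,
               self.code_disc_hidden) < 1:
            raise InvalidSpecError("network sizes must be positive")

    def channels(self, resolution: int) -> int:
        """Feature channels at a given resolution (doubles per halving, capped)."""
        return int(min(self.max_channels,
                       self.base_channels * self.max_resolution // resolution))

    @property
    def resolutions(self) -> list[int]:
        """All working resolutions, 4 up to max_resolution."""
        res, out = MIN_RESOLUTION, []
        while res <= self.max_resolution:
            out.append(res)
            res *= 2
        return out

    @property
    def n_doublings(self) -> int:
        return len(self.resolutions) - 1

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "latent_dim", "max_resolution", "base_channels", "max_channels",
            "lrelu_slope", "code_disc_hidden")}


def _check_latent(z: Tensor, latent_dim: int) -> None:
    if z.ndim != 2 or z.shape[1] != latent_dim:
        raise ShapeError(
            f"expected latent batch of shape (N, {latent_dim}), got {z.shape}")


def _check_image(x: Tensor, resolution: int) -> None:
    if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != (resolution, resolution):
        raise ShapeError(
            f"expected image batch (N, 1, {resolution}, {resolution}), "
            f"got {x.shape}")


class Generator(Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        slope = config.lrelu_slope
        c4 = config.channels(MIN_RESOLUTION)
        self.latent_linear = Linear(config.latent_dim, 16 * c4, rng, slope)
        # stage at resolution r: conv channels(r/2) -> channels(r) after upsampling
        self.stages = [Conv2d(config.channels(r // 2), config.channels(r), 3,
                              rng, slope)
                       for r in config.resolutions[1:]]
        self.heads = [Conv2d(config.channels(r), 1, 1, rng, slope)
                      for r in config.resolutions]

    def _head_image(self, h: Tensor, level: int) -> Tensor:
        return self.heads[level](h).tanh()

    def forward(self, z: Tensor, resolution: int, fade_alpha: float = 1.0) -> Tensor:
        cfg = self.config
        _check_latent(z, cfg.latent_dim)
        slope = cfg.lrelu_slope
        n = z.shape[0]
        h = self.latent_linear(z).leaky_relu(slope).reshape(
            n, cfg.channels(MIN_RESOLUTION), 4, 4)
        levels = cfg.resolutions
        if resolution not in levels:
            raise ShapeError(f"unsupported resolution {resolution}")
        target = levels.index(resolution)
        prev = h
        for level in range(1, target + 1):
            prev = h
            h = self.stages[level - 1](h.upsample2x()).leaky_relu(slope)
        img = self._head_image(h, target)
        if fade_alpha < 1.0 and target > 0:
            old = self._head_image(prev, target - 1).upsample2x()
            img = fade_alpha * img + (1.0 - fade_alpha) * old
        return img


class _ImageTrunk(Module):
    """Shared encoder/discriminator trunk: image -> flattened 4x4 features."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        slope = config.lrelu_slope
        # from-image head per resolution
        self.heads = [Conv2d(1, config.channels(r), 1, rng, slope)
                      for r in config.resolutions]
        # stage at resolution r: conv channels(r) -> channels(r/2), then pool
        self.stages = [Conv2d(config.channels(r), config.channels(r // 2), 3,
                              rng, slope)
                       for r in config.resolutions[1:]]

    def forward(self, x: Tensor, resolution: int, fade_alpha: float = 1.0) -> Tensor:
        cfg = self.config
        _check_image(x, resolution)
        slope = cfg.lrelu_slope
        levels = cfg.resolutions
        if resolution not in levels:
            raise ShapeError(f"unsupported resolution {resolution}")
        level = levels.index(resolution)
        h = self.heads[level](x).leaky_relu(slope)
        if level > 0:
            h = self.stages[level - 1](h).leaky_relu(slope).avgpool2x()
            if fade_alpha < 1.0:
                old = self.heads[level - 1](x.avgpool2x()).leaky_relu(slope)
                h = fade_alpha * h + (1.0 - fade_alpha) * old
            level -= 1
        while level > 0:
            h = self.stages[level - 1](h).leaky_relu(slope).avgpool2x()
            level -= 1
        n = h.shape[0]
        return h.reshape(n, 16 * cfg.channels(MIN_RESOLUTION))


class Encoder(Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.trunk = _ImageTrunk(config, rng)
        self.out = Linear(16 * config.channels(MIN_RESOLUTION),
                          config.latent_dim, rng, config.lrelu_slope)

    def forward(self, x: Tensor, resolution: int, fade_alpha: float = 1.0) -> Tensor:
        return self.out(self.trunk(x, resolution, fade_alpha))


class Discriminator(Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.trunk = _ImageTrunk(config, rng)
        self.out = Linear(16 * config.channels(MIN_RESOLUTION), 1, rng,
                          config.lrelu_slope)

    def forward(self, x: Tensor, resolution: int, fade_alpha: float = 1.0) -> Tensor:
        return self.out(self.trunk(x, resolution, fade_alpha))


class CodeDiscriminator(Module):
    def __init__(self, config: NetworkConfig, rng: np.random.Generator):
        self.config = config
        self.hidden = Linear(config.latent_dim, config.code_disc_hidden, rng,
                             config.lrelu_slope)
        self.out = Linear(config.code_disc_hidden, 1, rng, config.lrelu_slope)

    def forward(self, z: Tensor) -> Tensor:
        _check_latent(z, self.config.latent_dim)
        return self.out(self.hidden(z).leaky_relu(self.config.lrelu_slope))


# builder functions mirroring the module surface -----------------------------

def build_generator(config: NetworkConfig,
                    rng: np.random.Generator | None = None) -> Generator:
    return Generator(config, rng or np.random.default_rng(0))


def build_encoder(config: NetworkConfig,
                  rng: np.random.Generator | None = None) -> Encoder:
    return Encoder(config, rng or np.random.default_rng(0))


def build_discriminator(config: NetworkConfig,
                        rng: np.random.Generator | None = None) -> Discriminator:
    return Discriminator(config, rng or np.random.default_rng(0))


def build_code_discriminator(config: NetworkConfig,
                             rng: np.random.Generator | None = None
                             ) -> CodeDiscriminator:
    return CodeDiscriminator(config, rng or np.random.default_rng(0))


@dataclass
class AlphaGanModel:
    """The four networks plus the progressive-growing state."""

    config: NetworkConfig
    encoder: Encoder
    generator: Generator
    discriminator: Discriminator
    code_discriminator: CodeDiscriminator
    current_resolution: int = MIN_RESOLUTION
    fade_alpha: float = 1.0

    @staticmethod
    def build(config: NetworkConfig, seed: int = 0) -> "AlphaGanModel":
        rng = np.random.default_rng(seed)
        return AlphaGanModel(
            config=config,
            encoder=Encoder(config, rng),
            generator=Generator(config, rng),
            discriminator=Discriminator(config, rng),
            code_discriminator=CodeDiscriminator(config, rng),
        )

    # Tensor-level forward passes at the current progressive state ----------

    def encode(self, x: Tensor) -> Tensor:
        return self.encoder(x, self.current_resolution, self.fade_alpha)

    def generate(self, z: Tensor) -> Tensor:
        return self.generator(z, self.current_resolution, self.fade_alpha)

    def discriminate(self, x: Tensor) -> Tensor:
        return self.discriminator(x, self.current_resolution, self.fade_alpha)

    def discriminate_code(self, z: Tensor) -> Tensor:
        return self.code_discriminator(z)

    # NumPy conveniences (no gradients) --------------------------------------

    def _to_batch(self, images: np.ndarray) -> Tensor:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ShapeError(f"expected (N, H, W) images, got {arr.shape}")
        return Tensor(arr[:, None, :, :])

    def encode_images(self, images: np.ndarray) -> np.ndarray:
        return self.encode(self._to_batch(images)).data

    def reconstruct_images(self, images: np.ndarray) -> np.ndarray:
        x = self._to_batch(images)
        return self.generate(self.encode(x)).data[:, 0]

    def all_parameters(self):
        return (self.encoder.parameters() + self.generator.parameters()
                + self.discriminator.parameters()
                + self.code_discriminator.parameters())

    def state(self) -> dict:
        return {
            "encoder": self.encoder.state_arrays(),
            "generator": self.generator.state_arrays(),
            "discriminator": self.discriminator.state_arrays(),
            "code_discriminator": self.code_discriminator.state_arrays(),
            "current_resolution": self.current_resolution,
            "fade_alpha": self.fade_alpha,
        }

    def load_state(self, state: dict) -> None:
        self.encoder.load_state_arrays(state["encoder"])
        self.generator.load_state_arrays(state["generator"])
        self.discriminator.load_state_arrays(state["discriminator"])
        self.code_discriminator.load_state_arrays(state["code_discriminator"])
        self.current_resolution = int(state["current_resolution"])
        self.fade_alpha = float(state["fade_alpha"])


def grow(model: AlphaGanModel) -> AlphaGanModel:
    """Double the working resolution; the new stage starts fully faded out."""
    if model.current_resolution >= model.config.max_resolution:
        raise StateError("model is already at max_resolution")
    model.current_resolution *= 2
    model.fade_alpha = 0.0
    return model


# serialization ---------------------------------------------------------------

def save_model(model: AlphaGanModel, path) -> None:
    """Checkpoint the model (config + resolution state + all parameters)."""
    path = Path(path)
    state = model.state()
    arrays = {}
    for name in ("encoder", "generator", "discriminator", "code_discriminator"):
        for i, arr in enumerate(state[name]):
            arrays[f"{name}__{i}"] = arr
    meta = json.dumps({"config": model.config.to_dict(),
                       "current_resolution": state["current_resolution"],
                       "fade_alpha": state["fade_alpha"]})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path) -> AlphaGanModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = NetworkConfig(**meta["config"])
        model = AlphaGanModel.build(config, seed=0)
        state: dict = {"current_resolution": meta["current_resolution"],
                       "fade_alpha": meta["fade_alpha"]}
        for name in ("encoder", "generator", "discriminator",
                     "code_discriminator"):
            arrays = []
            i = 0
            while f"{name}__{i}" in data:
                arrays.append(data[f"{name}__{i}"])
                i += 1
            state[name] = arrays
        model.load_state(state)
    return model


def architecture_summary(config: NetworkConfig) -> dict[str, list[tuple]]:
    """Layer-by-layer (layer, activation, output shape) tables for all networks."""
    res_list = config.resolutions
    gen: list[tuple] = [("Latent vector", "", (config.latent_dim,)),
                        ("Linear", "LReLU", (4, 4, config.channels(4)))]
    for r in res_list[1:]:
        gen.append(("Upsampling", "", (r, r, config.channels(r // 2))))
        gen.append(("Convolution 3x3", "LReLU", (r, r, config.channels(r))))
    top = config.max_resolution
    gen.append(("Convolution 1x1", "Tanh", (top, top, 1)))

    enc: list[tuple] = [("Input Image", "", (top, top, 1)),
                        ("Convolution 1x1", "LReLU", (top, top, config.channels(top)))]
    for r in reversed(res_list[1:]):
        enc.append(("Convolution 3x3", "LReLU", (r, r, config.channels(r // 2))))
        enc.append(("Downsampling", "", (r // 2, r // 2, config.channels(r // 2))))
    disc = list(enc)
    enc.append(("Linear", "", (config.latent_dim,)))
    disc.append(("Linear", "", (1,)))

    code = [("Latent vector", "", (config.latent_dim,)),
            ("Linear", "LReLU", (config.code_disc_hidden,)),
            ("Linear", "", (1,))]
    return {"generator": gen, "encoder": enc, "discriminator": disc,
            "code_discriminator": code}


def format_summary(config: NetworkConfig) -> str:
    """Plain-text architecture summary."""
    tables = architecture_summary(config)
    lines = []
    for name, rows in tables.items():
        lines.append(name)
        for layer, act, shape in rows:
            shape_s = " x ".join(str(s) for s in shape)
            lines.append(f"  {layer:<18} {act:<6} {shape_s}")
    return "\n".join(lines)
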