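"""The continuity-aware segmentation network and its ablation variants.

The architecture is a 3D U-Net-style encoder-decoder over a volume treated
as a sequence of slices:

* **encoder** — time-distributed convolution blocks (3x3 in-plane kernels
  applied independently per slice; a config switch enables full volumetric
  3x3x3 kernels) with batch-norm/ReLU and 2x2x2 max-pooling, optionally
  concatenating a multi-scale average-pooled image pyramid at each level;
* **decoder** — bidirectional ConvLSTM blocks recurring along the slice
  axis (or plain convolution blocks for the non-recurrent variants), fed by
  nearest-neighbour 2x2x2 up-sampling and encoder skip connections;
* **output head** — one sigmoid side-output map per decoder level,
  up-sampled to full resolution and averaged, then passed through a final
  bidirectional ConvLSTM and a 1-channel sigmoid projection.

Four variants used for ablation are flag combinations of one config:
``canal_net`` (everything on), ``convlstm_only`` (recurrent decoder, no
multi-task extras), ``mpl_only`` (plain decoder, trained with projection
losses), and ``plain`` (baseline encoder-decoder).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import (BatchNorm, BiConvLSTM, Conv2dTD, Conv3d, Module, Tensor,
                 concat, maxpool2, relu, sigmoid, upsample2)

VARIANTS = ("canal_net", "convlstm_only", "mpl_only", "plain")


class ConfigError(ValueError):
    """Raised for an inconsistent NetworkConfig before any graph is built."""


@dataclass(frozen=True)
class ProbabilityVolume:
    """Network output: a [0,1]-valued grid sharing the input's geometry."""

    values: np.ndarray
    spacing_mm: float = 0.2

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError("probability volume must be 3D")
        if (v < 0).any() or (v > 1).any() or not np.isfinite(v).all():
            raise ValueError("probabilities must lie in [0, 1]")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self):
        return self.values.shape


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture switches; the four ablation variants are presets of it."""

    levels: int = 4
    encoder_channels: tuple[int, ...] = (16, 32, 64, 128)
    convlstm_decoder: bool = True
    side_outputs: bool = True
    multiscale_inputs: bool = True
    in_plane_kernel: int = 3
    volumetric_kernels: bool = False
    input_shape: tuple[int, int, int] = (16, 32, 32)
    seed: int = 0

    def __post_init__(self):
        if self.levels < 2:
            raise ConfigError("need at least two resolution levels")
        if len(self.encoder_channels) != self.levels:
            raise ConfigError("encoder_channels must list one count per level")
        if min(self.encoder_channels) < 1:
            raise ConfigError("channel counts must be >= 1")
        if self.in_plane_kernel % 2 == 0 or self.in_plane_kernel < 1:
            raise ConfigError("in-plane kernel must be a positive odd integer")
        t, h, w = self.input_shape
        div = 2 ** (self.levels - 1)
        if t < 1:
            raise ConfigError("input must have at least one slice")
        if t % div or h % div or w % div:
            raise ConfigError(
                f"input shape {self.input_shape} must be divisible by "
                f"2^(levels-1) = {div} on every axis (zero-pad the slice axis)")

    @classmethod
    def for_variant(cls, variant: str, **overrides) -> "NetworkConfig":
        if variant not in VARIANTS:
            raise ConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        flags = {
            "canal_net": dict(convlstm_decoder=True, side_outputs=True,
                              multiscale_inputs=True),
            "convlstm_only": dict(convlstm_decoder=True, side_outputs=False,
                                  multiscale_inputs=False),
            "mpl_only": dict(convlstm_decoder=False, side_outputs=False,
                             multiscale_inputs=False),
            "plain": dict(convlstm_decoder=False, side_outputs=False,
                          multiscale_inputs=False),
        }[variant]
        flags.update(overrides)
        return cls(**flags)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _conv(in_ch: int, out_ch: int, config: NetworkConfig,
          rng: np.random.Generator):
    if config.volumetric_kernels:
        return Conv3d(in_ch, out_ch, config.in_plane_kernel, rng)
    return Conv2dTD(in_ch, out_ch, config.in_plane_kernel, rng)


class EncoderBlock(Module):
    """Two (conv, batch-norm, ReLU) modules, then optional 2x2x2 max-pooling."""

    def __init__(self, in_ch: int, channels: int, config: NetworkConfig,
                 rng: np.random.Generator, pool: bool = True):
        self.conv1 = _conv(in_ch, channels, config, rng)
        self.bn1 = BatchNorm(channels)
        self.conv2 = _conv(channels, channels, config, rng)
        self.bn2 = BatchNorm(channels)
        self.pool = pool

    def features(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        return relu(self.bn2(self.conv2(x)))

    def __call__(self, x: Tensor) -> Tensor:
        f = self.features(x)
        return maxpool2(f) if self.pool else f


class DecoderBlock(Module):
    """Up-sample deeper features, concatenate the skip, then transform.

    The transform is a bidirectional ConvLSTM (recurrent variants) or a pair
    of convolutions (plain variants), each followed by batch-norm and ReLU.
    """

    def __init__(self, deep_ch: int, skip_ch: int, channels: int,
                 config: NetworkConfig, rng: np.random.Generator):
        in_ch = deep_ch + skip_ch
        self.recurrent = config.convlstm_decoder
        if self.recurrent:
            self.lstm = BiConvLSTM(in_ch, channels, 3, rng)
            self.bn1 = BatchNorm(2 * channels)
            self.conv = _conv(2 * channels, channels, config, rng)
            self.bn2 = BatchNorm(channels)
        else:
            self.conv1 = _conv(in_ch, channels, config, rng)
            self.bn1 = BatchNorm(channels)
            self.conv2 = _conv(channels, channels, config, rng)
            self.bn2 = BatchNorm(channels)

    def __call__(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = upsample2(deep)
        if up.shape[0] != skip.shape[0] or up.shape[2:] != skip.shape[2:]:
            raise ValueError(f"skip/up-sample shape mismatch: {up.shape} vs "
                             f"{skip.shape}")
        x = concat([up, skip], axis=1)
        if self.recurrent:
            x = relu(self.bn1(self.lstm(x)))
            return relu(self.bn2(self.conv(x)))
        x = relu(self.bn1(self.conv1(x)))
        return relu(self.bn2(self.conv2(x)))


class SideOutput(Module):
    """1x1 projection to one channel, up-sampled to full resolution, sigmoid."""

    def __init__(self, in_ch: int, n_upsamples: int, rng: np.random.Generator):
        self.proj = Conv2dTD(in_ch, 1, 1, rng)
        self.n_upsamples = n_upsamples

    def __call__(self, x: Tensor) -> Tensor:
        x = self.proj(x)
        for _ in range(self.n_upsamples):
            x = upsample2(x)
        return sigmoid(x)


class FinalHead(Module):
    """Map 1-or-more channels to the output probability volume."""

    def __init__(self, in_ch: int, config: NetworkConfig,
                 rng: np.random.Generator):
        hidden = config.encoder_channels[0]
        self.recurrent = config.convlstm_decoder
        if self.recurrent:
            self.lstm = BiConvLSTM(in_ch, hidden, 3, rng)
            self.proj = Conv2dTD(2 * hidden, 1, 1, rng)
        else:
            self.conv = Conv2dTD(in_ch, hidden, 3, rng)
            self.proj = Conv2dTD(hidden, 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if self.recurrent:
            x = self.lstm(x)
        else:
            x = relu(self.conv(x))
        return sigmoid(self.proj(x))


def build_encoder_block(in_ch: int, channels: int, config: NetworkConfig,
                        rng: np.random.Generator | int = 0,
                        pool: bool = True) -> EncoderBlock:
    """Standalone encoder block factory (seedable for direct use in tests)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return EncoderBlock(in_ch, channels, config, rng, pool=pool)


def build_convlstm_decoder_block(deep_ch: int, skip_ch: int, channels: int,
                                 config: NetworkConfig,
                                 rng: np.random.Generator | int = 0) -> DecoderBlock:
    """Standalone decoder block factory."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return DecoderBlock(deep_ch, skip_ch, channels, config, rng)


def build_multiscale_pyramid(volume: np.ndarray, levels: int) -> list[np.ndarray]:
    """Image pyramid by repeated 2x2x2 average pooling (level 0 = original).

    Each output voxel of level k+1 is the arithmetic mean of its 2x2x2 block
    in level k, so the intensity integral (sum times voxel volume) is
    conserved across levels.
    """
    vol = np.asarray(volume, dtype=float)
    pyramid = [vol]
    for _ in range(levels - 1):
        t, h, w = pyramid[-1].shape
        if t % 2 or h % 2 or w % 2:
            raise ValueError(f"cannot halve odd shape {pyramid[-1].shape} in "
                             "the multi-scale pyramid")
        pyramid.append(pyramid[-1].reshape(t // 2, 2, h // 2, 2, w // 2, 2)
                       .mean(axis=(1, 3, 5)))
    return pyramid


def _squeeze_channel(x: Tensor) -> Tensor:
    out = Tensor(x.data[:, 0], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g[:, None])

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class CanalNet(Module):
    """End-to-end segmentation network producing a probability volume."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.encoder_channels
        L = config.levels

        self.encoder_blocks = []
        for i in range(L):
            in_ch = 1 if i == 0 else ch[i - 1] + (1 if config.multiscale_inputs else 0)
            self.encoder_blocks.append(
                EncoderBlock(in_ch, ch[i], config, rng, pool=(i < L - 1)))

        self.decoder_blocks = []
        for i in range(L - 2, -1, -1):
            self.decoder_blocks.append(
                DecoderBlock(ch[i + 1], ch[i], ch[i], config, rng))

        if config.side_outputs:
            # heads at the bottleneck and at every decoder output, deepest first
            depths = [L - 1] + list(range(L - 2, -1, -1))
            chans = [ch[L - 1]] + [ch[i] for i in range(L - 2, -1, -1)]
            self.side_heads = [SideOutput(c, d, rng) for c, d in zip(chans, depths)]
            self.final_head = FinalHead(1, config, rng)
        else:
            self.side_heads = []
            self.final_head = FinalHead(ch[0], config, rng)

    # -- introspection ----------------------------------------------------
    @property
    def has_recurrent_blocks(self) -> bool:
        return any(isinstance(m, BiConvLSTM) for m in self.modules())

    @property
    def n_side_outputs(self) -> int:
        return len(self.side_heads)

    # -- forward -----------------------------------------------------------
    def __call__(self, volume) -> Tensor:
        """Forward pass: (T, H, W) volume in, (T, H, W) probabilities out."""
        arr = volume.data if isinstance(volume, Tensor) else np.asarray(volume,
                                                                        dtype=float)
        if arr.shape != tuple(self.config.input_shape):
            raise ValueError(f"input shape {arr.shape} does not match the "
                             f"configured {tuple(self.config.input_shape)}")
        x = Tensor(arr[:, None])  # (T, 1, H, W)
        pyramid = None
        if self.config.multiscale_inputs:
            pyramid = [Tensor(p[:, None])
                       for p in build_multiscale_pyramid(arr, self.config.levels)]

        skips: list[Tensor] = []
        feat = x
        for i, block in enumerate(self.encoder_blocks):
            if i > 0 and pyramid is not None:
                feat = concat([feat, pyramid[i]], axis=1)
            if block.pool:
                pre = block.features(feat)
                skips.append(pre)
                feat = maxpool2(pre)
            else:
                feat = block.features(feat)

        bottleneck = feat
        decoder_outs: list[Tensor] = []
        for block, skip in zip(self.decoder_blocks, reversed(skips)):
            feat = block(feat, skip)
            decoder_outs.append(feat)

        if self.config.side_outputs:
            maps = [head(t) for head, t in
                    zip(self.side_heads, [bottleneck] + decoder_outs)]
            avg = maps[0]
            for m in maps[1:]:
                avg = avg + m
            avg = avg * (1.0 / len(maps))
            out = self.final_head(avg)
        else:
            out = self.final_head(decoder_outs[-1])
        return _squeeze_channel(out)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm):
                state[f"{name}.running_mean"] = mod.running_mean
                state[f"{name}.running_var"] = mod.running_var
        return state

    def save(self, path) -> None:
        """Self-describing checkpoint: weights + embedded config."""
        state = self.state_arrays()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "CanalNet":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            for key in ("encoder_channels", "input_shape"):
                cfg[key] = tuple(cfg[key])
            model = cls(NetworkConfig(**cfg))
            params = dict(model.named_parameters())
            for name, mod in model.named_modules():
                if isinstance(mod, BatchNorm):
                    mod.running_mean = data[f"{name}.running_mean"]
                    mod.running_var = data[f"{name}.running_var"]
            for name, p in params.items():
                p.data = np.array(data[name])
        model.set_training(False)
        return model


def assemble_network(config: NetworkConfig) -> CanalNet:
    """Build the full network graph for a validated config."""
    return CanalNet(config)
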