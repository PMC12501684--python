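"""Configurable 3D encoder-decoder denoiser.

The architecture is a volumetric U-Net: each encoder level applies
``convs_per_block`` [3D conv -> batch norm -> leaky ReLU] layers and halves
the resolution with 2x max pooling; channel width starts at
``init_channels`` and doubles at every reduced resolution.  The central
block repeats the conv stack at the coarsest resolution with an additive
(residual) identity connection.  The decoder mirrors the encoder: a conv
block, a stride-2 transposed convolution that doubles the resolution, then
concatenation with the matching encoder output.  A final 1x1x1 linear
convolution combines the last feature maps into one output volume.  The
calibration (M0) volume, when enabled, enters as a second input channel.

With the defaults (64x64x32 input, 4 levels, 16 initial channels) the
central tensor is 4 x 4 x 2 spatial with 128 channels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn.layers import (BatchNorm3d, Conv3d, ConvTranspose3d, Dropout,
                        LeakyReLU, MaxPool3d)

__all__ = ["DenoiserConfig", "Denoiser3D", "IdentityDenoiser",
           "build_denoiser", "denoise"]


@dataclass
class DenoiserConfig:
    input_shape: tuple[int, int, int] = (64, 64, 32)
    levels: int = 4
    init_channels: int = 16
    convs_per_block: int = 3
    dropout_rate: float = 0.05
    include_m0: bool = False
    leaky_slope: float = 0.01
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        self.input_shape = tuple(int(n) for n in self.input_shape)
        if self.levels < 1 or self.init_channels < 1:
            raise ValueError("levels and init_channels must be >= 1")
        step = 2 ** self.levels
        if any(n % step for n in self.input_shape):
            raise ValueError(
                f"input shape {self.input_shape} must be divisible by "
                f"2^levels = {step} in every dimension")

    @property
    def in_channels(self) -> int:
        return 2 if self.include_m0 else 1

    @property
    def bottleneck_shape(self) -> tuple[int, int, int]:
        step = 2 ** self.levels
        return tuple(n // step for n in self.input_shape)

    @property
    def bottleneck_channels(self) -> int:
        return self.init_channels * 2 ** (self.levels - 1)


def micro_config(**kwargs) -> DenoiserConfig:
    """Small preset for CPU-scale experiments and CI."""
    defaults = dict(input_shape=(16, 16, 8), levels=2, init_channels=4,
                    convs_per_block=2, dropout_rate=0.05)
    defaults.update(kwargs)
    return DenoiserConfig(**defaults)


def desk_config(**kwargs) -> DenoiserConfig:
    """Desk-scale preset (32x32x16 volumes, 2 levels)."""
    defaults = dict(input_shape=(32, 32, 16), levels=2, init_channels=4,
                    convs_per_block=3, dropout_rate=0.05)
    defaults.update(kwargs)
    return DenoiserConfig(**defaults)


class _ConvBlock:
    """convs_per_block x [conv -> BN -> leaky ReLU], then dropout."""

    def __init__(self, in_ch, out_ch, cfg: DenoiserConfig, rng, dtype):
        self.layers = []
        ch = in_ch
        for _ in range(cfg.convs_per_block):
            self.layers += [Conv3d(ch, out_ch, 3, rng=rng, dtype=dtype),
                            BatchNorm3d(out_ch, dtype=dtype),
                            LeakyReLU(cfg.leaky_slope)]
            ch = out_ch
        if cfg.dropout_rate > 0:
            self.layers.append(Dropout(cfg.dropout_rate, rng=rng))

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training=True):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Denoiser3D:
    """The wired U-Net; weights are deterministic given ``config.seed``."""

    def __init__(self, config: DenoiserConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        c0, L = config.init_channels, config.levels
        enc_ch = [c0 * 2 ** i for i in range(L)]
        cm = config.bottleneck_channels

        self.enc = []
        in_ch = config.in_channels
        for ch in enc_ch:
            self.enc.append(_ConvBlock(in_ch, ch, config, rng, dtype))
            in_ch = ch
        self.pools = [MaxPool3d() for _ in range(L)]
        self.center = _ConvBlock(cm, cm, config, rng, dtype)
        self.ups, self.dec = [], []
        for j in range(L):
            up_in = cm if j == L - 1 else enc_ch[j + 1]
            self.ups.append(ConvTranspose3d(up_in, enc_ch[j],
                                            rng=rng, dtype=dtype))
            self.dec.append(_ConvBlock(2 * enc_ch[j], enc_ch[j],
                                       config, rng, dtype))
        self.final = Conv3d(c0, 1, k=1, rng=rng, dtype=dtype)
        self._enc_ch = enc_ch
        self.last_bottleneck_shape: tuple | None = None
        self._bwd_cache = None

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        blocks = (self.enc + [self.center] + self.ups + self.dec
                  + [self.final])
        return [p for b in blocks for p in b.params()]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    @property
    def uses_m0(self) -> bool:
        return self.config.include_m0

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, D, H, W) input, "
                f"got {x.shape}")
        L = self.config.levels
        skips = []
        h = x
        for i in range(L):
            h = self.enc[i].forward(h, training)
            skips.append(h)
            h = self.pools[i].forward(h, training)
        hc = self.center.forward(h, training)
        h = hc + h  # residual connection at the center
        self.last_bottleneck_shape = (h.shape[1],) + h.shape[2:]
        for j in range(L - 1, -1, -1):
            h = self.ups[j].forward(h, training)
            h = np.concatenate([h, skips[j]], axis=1)
            h = self.dec[j].forward(h, training)
        return self.final.forward(h, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self.config.levels
        dh = self.final.backward(dy)
        dskip = [None] * L
        for j in range(L):
            dh = self.dec[j].backward(dh)
            split = self._enc_ch[j]
            dup, dskip[j] = dh[:, :split], dh[:, split:]
            dh = self.ups[j].backward(dup)
        dcenter_in = self.center.backward(dh)
        dh = dh + dcenter_in  # residual: gradient flows both ways
        for i in range(L - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + dskip[i]
            dh = self.enc[i].backward(dh)
        return dh

    # -- inference ----------------------------------------------------------
    def _stack_inputs(self, volumes: np.ndarray,
                      m0: np.ndarray | None) -> np.ndarray:
        dtype = np.dtype(self.config.dtype)
        x = np.asarray(volumes, dtype)[:, None]
        if self.config.include_m0:
            if m0 is None:
                raise ValueError("model was built with include_m0=True; "
                                 "an M0 volume is required")
            m = np.broadcast_to(np.asarray(m0, dtype),
                                volumes.shape)[:, None]
            x = np.concatenate([x, m], axis=1)
        elif m0 is not None:
            raise ValueError("model was built without M0; got an M0 volume")
        return x

    def denoise(self, volumes: np.ndarray, m0: np.ndarray | None = None,
                batch_size: int = 4) -> np.ndarray:
        """Denoise each volume independently (inference mode, deterministic)."""
        single = volumes.ndim == 3
        if single:
            volumes = volumes[None]
        x = self._stack_inputs(volumes, m0)
        out = np.empty(volumes.shape, dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = self.forward(
                x[i:i + batch_size], training=False)[:, 0]
        return out[0] if single else out

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = {}
        for i, p in enumerate(self.params()):
            state[f"p{i}"] = p.value
        bns = [l for b in self._all_blocks() for l in getattr(b, "layers", [b])
               if isinstance(l, BatchNorm3d)]
        for i, bn in enumerate(bns):
            state[f"rm{i}"] = bn.running_mean
            state[f"rv{i}"] = bn.running_var
        np.savez(path.with_suffix(".npz"), **state)
        path.with_suffix(".json").write_text(
            json.dumps(asdict(self.config), indent=2))

    def _all_blocks(self):
        return self.enc + [self.center] + self.ups + self.dec + [self.final]

    @classmethod
    def load(cls, path: str | Path) -> "Denoiser3D":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = cls(DenoiserConfig(**cfg))
        state = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model.params()):
            p.value[...] = state[f"p{i}"]
        bns = [l for b in model._all_blocks()
               for l in getattr(b, "layers", [b])
               if isinstance(l, BatchNorm3d)]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = state[f"rm{i}"]
            bn.running_var[...] = state[f"rv{i}"]
        return model


class IdentityDenoiser:
    """Pass-through model, useful as a pipeline control."""

    uses_m0 = False

    def denoise(self, volumes, m0=None, batch_size=4):
        return np.asarray(volumes, float).copy()


def build_denoiser(config: DenoiserConfig) -> Denoiser3D:
    """Construct the denoiser; invalid shape/level combinations raise."""
    return Denoiser3D(config)


def denoise(denoiser, volumes: np.ndarray,
            m0: np.ndarray | None = None) -> np.ndarray:
    """Functional wrapper around ``denoiser.denoise``."""
    return denoiser.denoise(volumes, m0=m0)
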