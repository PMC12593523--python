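"""Spectral–spatial–temporal pyramid network (SST-PNet).

An 8-s segment is turned into a 3-D feature volume by taking a log-magnitude
STFT, averaging frequency bins down to ``n_bins``, and tiling the time frames
row-major into an ``H x W`` grid (edge-padded with replicas of the last
frame), spectral axis last.  This makes ``(1,1,k)`` kernels act purely on
frequency while ``(k,k,1)`` / ``(k,1,1)`` kernels act on the time-frame grid.

Three parallel branches — spectral, spatial, temporal — each apply an initial
3-D convolution followed by a *pyramidal block*: three Conv3D+BN+Mish layers
with a descending kernel ladder, densely concatenated with the block input.
With block input channels ``eta`` and per-layer channels ``gamma_prime`` the
block output has ``gamma = eta + 3*gamma_prime`` channels; branch outputs are
concatenated along channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import nn
from .preprocess import minmax_normalize

__all__ = [
    "FeatureVolume",
    "StftConfig",
    "SSTPNetConfig",
    "build_volume",
    "pyramidal_block_channels",
    "PyramidalBlock",
    "Branch",
    "SSTPNet",
    "KERNEL_LADDERS",
]

#: Per-branch kernel ladders (descending), one axis varying per branch.
KERNEL_LADDERS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "spectral": ((1, 1, 7), (1, 1, 5), (1, 1, 3)),
    "spatial": ((3, 3, 1), (5, 5, 1), (7, 7, 1)),
    "temporal": ((7, 1, 1), (5, 1, 1), (3, 1, 1)),
}

#: Initial-convolution kernel per branch (stride 1, same padding).
INITIAL_KERNELS: dict[str, tuple[int, int, int]] = {
    "spectral": (1, 1, 7),
    "spatial": (3, 3, 1),
    "temporal": (3, 1, 1),
}


@dataclass
class StftConfig:
    n_fft: int = 256
    hop: int = 128
    n_bins: int = 32

    @staticmethod
    def desk_scale() -> "StftConfig":
        """Coarser volumes (8x8x16 for an 8-s segment at 2 kHz) for
        CPU-scale training runs."""
        return StftConfig(n_fft=256, hop=256, n_bins=16)


@dataclass
class FeatureVolume:
    """H x W x B volume from one segment (time-frame grid x spectral axis)."""

    values: np.ndarray  # (H, W, B), min-max normalized to [0, 1]
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def pyramidal_block_channels(eta: int, gamma_prime: int) -> int:
    """Output channels of a pyramidal block: ``eta + 3*gamma_prime``."""
    if eta < 1 or gamma_prime < 1:
        raise ValueError("eta and gamma_prime must be >= 1")
    return eta + 3 * gamma_prime


def build_volume(
    segment: np.ndarray,
    fs: float,
    stft: StftConfig | None = None,
    window_s: float = 8.0,
) -> FeatureVolume:
    """Log-magnitude STFT, bin-averaged and tiled into an H x W x B volume.

    * frames: ``T = floor((L - n_fft)/hop) + 1`` Hann-windowed frames;
    * frequency: the ``n_fft//2`` non-Nyquist rfft bins are averaged in
      ``n_bins`` uniform groups;
    * tiling: frames laid row-major on an ``H x W`` grid with
      ``H = W = ceil(sqrt(T))``; the unused trailing cells replicate the last
      frame (edge padding);
    * scaling: the whole volume is min-max normalized to [0, 1]; an all-zero
      segment stays all zero (degenerate-range guard).
    """
    cfg = stft or StftConfig()
    segment = np.asarray(segment, dtype=np.float64).ravel()
    expected = int(round(window_s * fs))
    if segment.size != expected:
        raise ValueError(
            f"segment length {segment.size} != round(window_s*fs) = {expected}"
        )
    if cfg.n_fft > segment.size:
        raise ValueError("n_fft larger than the segment")

    win = np.hanning(cfg.n_fft)
    T = (segment.size - cfg.n_fft) // cfg.hop + 1
    starts = np.arange(T) * cfg.hop
    frames = np.stack([segment[a : a + cfg.n_fft] for a in starts]) * win
    spec = np.abs(np.fft.rfft(frames, axis=1))  # (T, n_fft//2 + 1)
    spec = spec[:, : cfg.n_fft // 2]  # drop Nyquist for uniform grouping
    if cfg.n_fft // 2 % cfg.n_bins:
        raise ValueError("n_fft//2 must be divisible by n_bins")
    group = (cfg.n_fft // 2) // cfg.n_bins
    spec = spec.reshape(T, cfg.n_bins, group).mean(axis=2)
    logspec = np.log1p(spec)  # (T, B)

    H = W = int(np.ceil(np.sqrt(T)))
    n_pad = H * W - T
    tiled = np.concatenate([logspec, np.repeat(logspec[-1:], n_pad, axis=0)], axis=0)
    vol = tiled.reshape(H, W, cfg.n_bins)
    vol = minmax_normalize(vol) if vol.max() > vol.min() else np.zeros_like(vol)
    return FeatureVolume(
        values=vol,
        meta={
            "n_fft": cfg.n_fft,
            "hop": cfg.hop,
            "n_bins": cfg.n_bins,
            "n_frames": int(T),
            "n_padded": int(n_pad),
            "fs": float(fs),
            "bin_width_hz": fs / cfg.n_fft * group,
        },
    )


# --------------------------------------------------------------------------- #
# network                                                                     #
# --------------------------------------------------------------------------- #

@dataclass
class SSTPNetConfig:
    initial_channels: int = 16  # eta: channels after each branch's initial conv
    gamma_prime: int = 8  # per-layer channels inside a pyramidal block
    kernel_ladders: dict[str, tuple[tuple[int, int, int], ...]] = field(
        default_factory=lambda: dict(KERNEL_LADDERS)
    )
    seed: int = 0

    @property
    def branch_channels(self) -> int:
        return pyramidal_block_channels(self.initial_channels, self.gamma_prime)

    @property
    def fused_channels(self) -> int:
        return 3 * self.branch_channels


class PyramidalBlock(nn.Module):
    """Three Conv3D+BN+Mish layers with dense concatenation.

    Layer ``i`` sees the block input concatenated with all previous layer
    outputs; the block output concatenates the input with all three layer
    outputs, so out_channels = ``eta + 3*gamma_prime`` exactly.
    """

    def __init__(
        self,
        eta: int,
        gamma_prime: int,
        ladder: tuple[tuple[int, int, int], ...],
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if len(ladder) != 3:
            raise ValueError("a pyramidal block has exactly three layers")
        self.eta = eta
        self.gamma_prime = gamma_prime
        self.convs = []
        self.bns = []
        in_ch = eta
        for kernel in ladder:
            self.convs.append(nn.Conv3d(in_ch, gamma_prime, kernel, pad="same", rng=rng))
            self.bns.append(nn.BatchNorm3d(gamma_prime))
            in_ch += gamma_prime

    @property
    def out_channels(self) -> int:
        return pyramidal_block_channels(self.eta, self.gamma_prime)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        feats = [x]
        for conv, bn in zip(self.convs, self.bns):
            h = nn.concat(feats, axis=1) if len(feats) > 1 else feats[0]
            feats.append(bn(conv(h)).mish())
        return nn.concat(feats, axis=1)


class Branch(nn.Module):
    """Initial Conv3D+BN+Mish followed by a pyramidal block."""

    def __init__(
        self,
        name: str,
        in_channels: int,
        cfg: SSTPNetConfig,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.name = name
        self.initial = nn.Conv3d(
            in_channels, cfg.initial_channels, INITIAL_KERNELS[name], pad="same", rng=rng
        )
        self.initial_bn = nn.BatchNorm3d(cfg.initial_channels)
        self.block = PyramidalBlock(
            cfg.initial_channels, cfg.gamma_prime, cfg.kernel_ladders[name], rng
        )

    @property
    def out_channels(self) -> int:
        return self.block.out_channels

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.block(self.initial_bn(self.initial(x)).mish())


class SSTPNet(nn.Module):
    """Three parallel pyramidal branches, channel-concatenated.

    Input ``(N, in_channels, H, W, B)`` -> output ``(N, K, H, W, B)`` with
    ``K = 3 * (initial_channels + 3*gamma_prime)``.  Same padding preserves
    H, W and B throughout.
    """

    def __init__(self, cfg: SSTPNetConfig | None = None, in_channels: int = 1) -> None:
        super().__init__()
        self.cfg = cfg or SSTPNetConfig()
        rng = np.random.default_rng(self.cfg.seed)
        self.branches = [
            Branch(name, in_channels, self.cfg, rng)
            for name in ("spectral", "spatial", "temporal")
        ]

    @property
    def out_channels(self) -> int:
        return sum(b.out_channels for b in self.branches)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        outs = [b(x) for b in self.branches]
        fused = nn.concat(outs, axis=1)
        expected = self.out_channels
        if fused.shape[1] != expected:
            raise RuntimeError(
                f"channel accounting violated: got {fused.shape[1]}, expected {expected}"
            )
        return fused


def volumes_to_batch(volumes: list[FeatureVolume]) -> np.ndarray:
    """Stack feature volumes into an (N, 1, H, W, B) float32 batch."""
    return np.stack([v.values for v in volumes]).astype(np.float32)[:, None]
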