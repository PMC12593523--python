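"""EnDe-CNN: 3-D convolutional encoder–decoder classifier.

The encoder applies three Conv3D+BN+ReLU stages (spectral ``(1,1,k)``
kernels by default) with 3-D max pooling between stages; the outputs of the
tapped stages are pooled to the deepest spectral size and concatenated into
the latent ``D`` (multilayer feature concatenation).  The decoder mirrors
the encoder with transposed 3-D convolutions and reconstructs the encoder
input; its reconstruction loss

    L_rec = (1/k) * sum_j || x_j - f(x_j; n) ||_2^2

(k = number of 3-D feature patches, one per sample by default) provides the
self-supervised term that is added to cross-entropy with weight
``lambda_rec``.  The detection head flattens ``D``, applies dropout, a dense
layer and softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "ConvSpec",
    "EnDeCNNConfig",
    "conv_output_size",
    "Encoder",
    "Decoder",
    "EnDeCNN",
    "reconstruction_loss",
]


def conv_output_size(m_prev: int, pad: int, kernel: int, stride: int) -> int:
    """Convolution output length: ``floor((M + 2*pad - kernel)/stride) + 1``."""
    if m_prev < 0 or pad < 0:
        raise ValueError("sizes must be non-negative")
    if stride < 1 or kernel < 1:
        raise ValueError("stride and kernel must be >= 1")
    if kernel > m_prev + 2 * pad:
        raise ValueError(
            f"kernel {kernel} exceeds padded input {m_prev + 2 * pad}"
        )
    return (m_prev + 2 * pad - kernel) // stride + 1


@dataclass
class ConvSpec:
    """Declarative convolution geometry (used for structural assertions)."""

    in_channels: int
    out_channels: int
    kernel: tuple[int, int, int]
    pad: tuple[int, int, int] = (0, 0, 0)
    stride: tuple[int, int, int] = (1, 1, 1)
    bias: bool = False

    def output_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(
            conv_output_size(spatial[i], self.pad[i], self.kernel[i], self.stride[i])
            for i in range(3)
        )


@dataclass
class EnDeCNNConfig:
    stage_channels: tuple[int, ...] = (16, 32, 64)
    stage_kernels: tuple[tuple[int, int, int], ...] = ((1, 1, 7), (1, 1, 5), (1, 1, 3))
    taps: tuple[int, ...] = (1, 2, 3)  # 1-based encoder stages feeding the latent
    pool_between: tuple[int, int, int] = (1, 1, 2)
    n_classes: int = 2
    dropout: float = 0.3
    lambda_rec: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        ns = len(self.stage_channels)
        if len(self.stage_kernels) != ns:
            raise ValueError("stage_kernels must match stage_channels")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for t in self.taps:
            if not 1 <= t <= ns:
                raise ValueError(f"tap depth {t} out of range 1..{ns}")

    @property
    def latent_channels(self) -> int:
        return sum(self.stage_channels[t - 1] for t in self.taps)


class Encoder(nn.Module):
    """Conv3D+BN+ReLU stages with inter-stage pooling and tapped concatenation."""

    def __init__(self, in_channels: int, cfg: EnDeCNNConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        self.convs, self.bns = [], []
        ch = in_channels
        for out_ch, kernel in zip(cfg.stage_channels, cfg.stage_kernels):
            self.convs.append(nn.Conv3d(ch, out_ch, kernel, pad="same", rng=rng))
            self.bns.append(nn.BatchNorm3d(out_ch))
            ch = out_ch

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, list[nn.Tensor]]:
        stages: list[nn.Tensor] = []
        h = x
        n_stages = len(self.convs)
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            h = bn(conv(h)).relu()
            stages.append(h)
            if i < n_stages - 1:
                h = h.maxpool3d(self.cfg.pool_between)
        deepest = stages[-1].shape[2:]
        tapped = []
        for t in self.cfg.taps:
            s = stages[t - 1]
            factors = tuple(max(s.shape[2 + i] // deepest[i], 1) for i in range(3))
            tapped.append(s.maxpool3d(factors) if factors != (1, 1, 1) else s)
        D = nn.concat(tapped, axis=1)
        if D.shape[1] != self.cfg.latent_channels:
            raise RuntimeError(
                f"latent channel accounting violated: {D.shape[1]} != {self.cfg.latent_channels}"
            )
        return D, stages


class Decoder(nn.Module):
    """Mirror of the encoder: transposed convolutions + BN + ReLU back to the
    encoder input shape."""

    def __init__(
        self,
        latent_channels: int,
        out_channels: int,
        cfg: EnDeCNNConfig,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.cfg = cfg
        n_up = len(cfg.stage_channels) - 1  # one upsample per inter-stage pool
        chans = list(cfg.stage_channels[::-1])[1:] + [out_channels]
        self.ups, self.bns = [], []
        ch = latent_channels
        s = cfg.pool_between
        k = tuple(2 * si if si > 1 else 3 for si in s)
        p = tuple(si // 2 if si > 1 else 1 for si in s)
        for i in range(n_up):
            # (M-1)*s - 2p + k = M*s exactly inverts a stride-s pool
            self.ups.append(nn.ConvTranspose3d(ch, chans[i], k, stride=s, pad=p, rng=rng))
            self.bns.append(nn.BatchNorm3d(chans[i]))
            ch = chans[i]
        self.final = nn.Conv3d(ch, out_channels, (1, 1, 3), pad="same", rng=rng)

    def forward(self, D: nn.Tensor) -> nn.Tensor:
        h = D
        for up, bn in zip(self.ups, self.bns):
            h = bn(up(h)).relu()
        return self.final(h)


def reconstruction_loss(reconstruction: nn.Tensor, target: nn.Tensor | np.ndarray) -> nn.Tensor:
    """Mean-over-patches squared reconstruction error (one patch per sample)."""
    t = target if isinstance(target, nn.Tensor) else nn.Tensor(target)
    if reconstruction.shape != t.shape:
        raise ValueError(
            f"reconstruction shape {reconstruction.shape} != target {t.shape}"
        )
    d = reconstruction - t.detach()
    k = reconstruction.shape[0]
    return (d * d).sum() * (1.0 / float(k))


class EnDeCNN(nn.Module):
    """Encoder–decoder classifier over fused attention features.

    ``forward`` returns ``(logits, reconstruction, D)``; ``loss`` combines
    cross-entropy with ``lambda_rec`` times the reconstruction error.
    The dense head is lazily sized on the first forward pass.
    """

    def __init__(self, in_channels: int, cfg: EnDeCNNConfig | None = None) -> None:
        super().__init__()
        self.cfg = cfg or EnDeCNNConfig()
        self.in_channels = in_channels
        self._rng = np.random.default_rng(self.cfg.seed)
        self.encoder = Encoder(in_channels, self.cfg, self._rng)
        self.decoder = Decoder(self.cfg.latent_channels, in_channels, self.cfg, self._rng)
        self.dropout = nn.Dropout(self.cfg.dropout, rng=np.random.default_rng(self.cfg.seed + 1))
        self.head: nn.Linear | None = None

    def _ensure_head(self, n_features: int) -> None:
        if self.head is None:
            self.head = nn.Linear(n_features, self.cfg.n_classes, rng=self._rng)

    def forward(self, x: nn.Tensor, with_reconstruction: bool = True):
        D, _ = self.encoder(x)
        recon = self.decoder(D) if with_reconstruction else None
        flat = D.reshape(D.shape[0], -1)
        self._ensure_head(flat.shape[1])
        logits = self.head(self.dropout(flat))
        return logits, recon, D

    def classify(self, x: nn.Tensor) -> np.ndarray:
        """Class probability vectors (rows sum to 1)."""
        logits, _, _ = self.forward(x, with_reconstruction=False)
        return logits.softmax(axis=1).data

    def loss(self, logits: nn.Tensor, recon: nn.Tensor | None, x: nn.Tensor, labels: np.ndarray):
        ce = nn.cross_entropy(logits, labels)
        if self.cfg.lambda_rec > 0 and recon is not None:
            rec = reconstruction_loss(recon, x)
            return ce + rec * self.cfg.lambda_rec, ce, rec
        return ce, ce, None
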