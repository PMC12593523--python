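"""The full multimodal classification network.

Per modality: feature volume -> SST-PNet -> TPAM/WCM-AM.  The per-modality
attention outputs are concatenated channel-wise ("fusion") and classified by
the EnDe-CNN encoder–decoder with a joint cross-entropy + reconstruction
objective.  Single-modality operation is supported by listing only one
modality in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attention import TPAM, TPAMConfig
from .endecnn import EnDeCNN, EnDeCNNConfig
from .sstpnet import SSTPNet, SSTPNetConfig

__all__ = ["ModelConfig", "MultiModalNet"]


@dataclass
class ModelConfig:
    modalities: tuple[str, ...] = ("ECG", "PCG")
    sstpnet: SSTPNetConfig = field(default_factory=SSTPNetConfig)
    tpam: TPAMConfig = field(default_factory=TPAMConfig)
    ende: EnDeCNNConfig = field(default_factory=EnDeCNNConfig)

    @staticmethod
    def desk_scale(n_classes: int = 2, seed: int = 0) -> "ModelConfig":
        """Reduced widths for CPU-scale training runs."""
        return ModelConfig(
            sstpnet=SSTPNetConfig(initial_channels=3, gamma_prime=1, seed=seed),
            tpam=TPAMConfig(conv_out_channels=4, seed=seed + 1),
            ende=EnDeCNNConfig(
                stage_channels=(8, 8, 8),
                stage_kernels=((1, 1, 7), (1, 1, 5), (1, 1, 3)),
                n_classes=n_classes,
                # the reconstruction term sums over ~2e4 patch elements; at
                # desk scale a small weight keeps it from drowning the CE term
                lambda_rec=1e-3,
                seed=seed + 2,
            ),
        )


class MultiModalNet(nn.Module):
    """SST-PNet + TPAM per modality, channel-fused, EnDe-CNN classifier."""

    def __init__(self, cfg: ModelConfig | None = None) -> None:
        super().__init__()
        self.cfg = cfg or ModelConfig()
        self.sstp = {}
        self.tpam = {}
        branches = []
        for i, mod in enumerate(self.cfg.modalities):
            scfg = SSTPNetConfig(**{**self.cfg.sstpnet.__dict__, "seed": self.cfg.sstpnet.seed + i})
            net = SSTPNet(scfg, in_channels=1)
            tcfg = TPAMConfig(**{**self.cfg.tpam.__dict__, "seed": self.cfg.tpam.seed + i})
            att = TPAM(net.out_channels, tcfg)
            self.sstp[mod] = net
            self.tpam[mod] = att
            branches.extend([net, att])
        self._branches = branches  # parameter discovery over dict values
        fused_channels = sum(self.tpam[m].out_channels for m in self.cfg.modalities)
        self.ende = EnDeCNN(fused_channels, self.cfg.ende)

    def forward(self, batches: dict[str, np.ndarray | nn.Tensor], with_reconstruction: bool = True):
        """``batches`` maps modality -> (N, 1, H, W, B) volume batch.

        Returns ``(logits, reconstruction, fused)`` where ``fused`` is the
        channel-concatenated TPAM output (the reconstruction target).
        """
        feats = []
        for mod in self.cfg.modalities:
            x = batches[mod]
            x = x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, np.float32))
            feats.append(self.tpam[mod](self.sstp[mod](x)))
        fused = nn.concat(feats, axis=1) if len(feats) > 1 else feats[0]
        logits, recon, _ = self.ende(fused, with_reconstruction=with_reconstruction)
        return logits, recon, fused

    def loss(self, logits, recon, fused, labels):
        return self.ende.loss(logits, recon, fused, labels)

    def predict_proba(self, batches: dict[str, np.ndarray]) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits, _, _ = self.forward(batches, with_reconstruction=False)
            return logits.softmax(axis=1).data
        finally:
            self.train(was_training)
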