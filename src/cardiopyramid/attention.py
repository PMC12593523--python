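"""Tri-pattern attention (TPAM) with weight correction (WCM-AM).

Three softmax-normalized coefficient maps are computed from a feature map:

* **spectral** — a dense projection of the channel vector at each grid
  position ``(i, j)``, softmax over all positions (an ``H x W`` map);
* **temporal** — the same computation on the transposed grid (a ``W x H``
  map, aligned back by transposition when combined);
* **spatial** — a dense score of each feature map's global-average
  descriptor, softmax over the channel index ``k`` (a length-``K`` vector).

Two correction strategies combine them:

* weight addition: ``att_add(i,j,k) = att_spe(i,j) + att_tem^T(i,j) + att_spa(k)``
  (broadcast over the missing axes);
* weight maximization: ``att_max(i,j,k) = max(att_spe(i,j) * att_tem^T(i,j),
  att_spa(k))``.

Fusion: ``I_add = Conv3D(att_add * beta)``; ``I_max = concat(att_max * beta,
beta)`` along channels; ``I_TPAM = maxpool(concat(I_max, I_add))`` with
(2, 2, 1) pooling, giving ``2K + K_add`` output channels on a halved grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import nn

log = logging.getLogger(__name__)

__all__ = [
    "AttentionMaps",
    "CorrectedWeights",
    "TPAMConfig",
    "TPAM",
    "compute_attention_maps",
    "weight_correction",
    "tpam_fuse",
]


@dataclass
class AttentionMaps:
    """The three TPAM coefficient maps (each sums to 1)."""

    att_spe: np.ndarray  # (H, W)
    att_tem: np.ndarray  # (W, H) — on the transposed grid
    att_spa: np.ndarray  # (K,)
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class CorrectedWeights:
    att_add: np.ndarray  # (H, W, K)
    att_max: np.ndarray  # (H, W, K)
    i_add: np.ndarray | None = None
    i_max: np.ndarray | None = None
    i_tpam: np.ndarray | None = None


@dataclass
class TPAMConfig:
    mode: str = "both"  # add | max | both
    conv_out_channels: int = 8  # K_add: channels of the Eq-14 convolution
    conv_kernel: tuple[int, int, int] = (3, 3, 3)
    pool: tuple[int, int, int] = (2, 2, 1)
    double_axes: bool = False  # optional 2x on the positional coefficients
    tie_temporal: bool = False  # share the spectral dense parameters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("add", "max", "both"):
            raise ValueError(f"mode must be add|max|both, got {self.mode!r}")


# --------------------------------------------------------------------------- #
# trainable module                                                            #
# --------------------------------------------------------------------------- #

class TPAM(nn.Module):
    """Trainable tri-pattern attention over ``(N, K, H, W, B)`` feature maps.

    The per-position channel descriptor is the spectral-axis mean, so the
    positional maps are defined on the ``H x W`` grid regardless of B; the
    resulting coefficients broadcast back over B.
    """

    def __init__(self, in_channels: int, cfg: TPAMConfig | None = None) -> None:
        super().__init__()
        self.cfg = cfg or TPAMConfig()
        self.in_channels = in_channels
        rng = np.random.default_rng(self.cfg.seed)
        K = in_channels

        def dense_vec():
            return nn.Tensor(
                (rng.normal(0, 1.0 / np.sqrt(K), K)).astype(np.float32),
                requires_grad=True,
            )

        self.w_spe = dense_vec()
        self.b_spe = nn.Tensor(np.zeros(1, np.float32), requires_grad=True)
        self.w_tem = dense_vec()
        self.b_tem = nn.Tensor(np.zeros(1, np.float32), requires_grad=True)
        self.w_spa = nn.Tensor(np.ones(1, np.float32), requires_grad=True)
        self.b_spa = nn.Tensor(np.zeros(1, np.float32), requires_grad=True)
        self.conv = nn.Conv3d(
            K, self.cfg.conv_out_channels, self.cfg.conv_kernel, pad="same", rng=rng
        )

    @property
    def out_channels(self) -> int:
        K, Ka = self.in_channels, self.cfg.conv_out_channels
        return {"add": Ka, "max": 2 * K, "both": 2 * K + Ka}[self.cfg.mode]

    # -- attention maps ----------------------------------------------------- #

    def attention(self, beta: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        """Return (att_spe (N,H,W), att_temT (N,H,W), att_spa (N,K))."""
        N, K, H, W, _ = beta.shape
        desc = beta.mean(axis=4)  # (N, K, H, W)

        def grid_softmax(d: nn.Tensor, w: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
            score = (d * w.reshape(1, K, 1, 1)).sum(axis=1) + b.reshape(1, 1, 1)
            flat = score.reshape(N, -1).softmax(axis=1)
            return flat.reshape(N, score.shape[1], score.shape[2])

        att_spe = grid_softmax(desc, self.w_spe, self.b_spe)  # (N, H, W)
        w_t = self.w_spe if self.cfg.tie_temporal else self.w_tem
        b_t = self.b_spe if self.cfg.tie_temporal else self.b_tem
        att_tem = grid_softmax(desc.swapaxes(2, 3), w_t, b_t)  # (N, W, H)
        att_tem_t = att_tem.swapaxes(1, 2)  # aligned back to (N, H, W)

        gap = beta.mean(axis=(2, 3, 4))  # (N, K)
        att_spa = (gap * self.w_spa + self.b_spa).softmax(axis=1)
        return att_spe, att_tem_t, att_spa

    # -- correction + fusion ------------------------------------------------ #

    def forward(self, beta: nn.Tensor, return_maps: bool = False):
        N, K, H, W, B = beta.shape
        att_spe, att_tem_t, att_spa = self.attention(beta)
        if self.cfg.double_axes:
            att_spe = att_spe * 2.0
            att_tem_t = att_tem_t * 2.0

        spe = att_spe.reshape(N, 1, H, W, 1)
        tem = att_tem_t.reshape(N, 1, H, W, 1)
        spa = att_spa.reshape(N, K, 1, 1, 1)
        att_add = spe + tem + spa  # (N, K, H, W, 1) by broadcast
        att_max = nn.maximum(spe * tem, spa)

        parts = []
        i_max = i_add = None
        if self.cfg.mode in ("max", "both"):
            i_max = nn.concat([att_max * beta, beta], axis=1)  # (N, 2K, H, W, B)
            parts.append(i_max)
        if self.cfg.mode in ("add", "both"):
            i_add = self.conv(att_add * beta)  # (N, K_add, H, W, B)
            parts.append(i_add)
        fused = nn.concat(parts, axis=1) if len(parts) > 1 else parts[0]

        q = self.cfg.pool
        if any(fused.shape[2 + i] < q[i] for i in range(3)):
            log.warning("TPAM pooling skipped on axes smaller than the pool size")
        i_tpam = fused.maxpool3d(q)
        if return_maps:
            return i_tpam, {
                "att_spe": att_spe,
                "att_tem_t": att_tem_t,
                "att_spa": att_spa,
                "att_add": att_add,
                "att_max": att_max,
                "i_add": i_add,
                "i_max": i_max,
            }
        return i_tpam


# --------------------------------------------------------------------------- #
# functional single-map API                                                   #
# --------------------------------------------------------------------------- #

def _softmax(a: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(a)):
        raise FloatingPointError("non-finite attention scores")
    z = a - np.max(a)
    e = np.exp(z)
    return e / e.sum()


def compute_attention_maps(
    beta: np.ndarray,
    w_spe: np.ndarray | None = None,
    b_spe: float = 0.0,
    w_tem: np.ndarray | None = None,
    b_tem: float = 0.0,
    w_spa: float = 1.0,
    b_spa: float = 0.0,
) -> AttentionMaps:
    """Attention maps for one ``(H, W, K)`` feature map.

    Dense weights default to the identity-sum projection (all-ones weight,
    zero bias), under which the score at a position is the sum of its channel
    vector.  Each returned map is softmax-normalized (sums to 1).
    """
    beta = np.asarray(beta, dtype=np.float64)
    if beta.ndim != 3:
        raise ValueError("beta must be (H, W, K)")
    H, W, K = beta.shape
    w_spe = np.ones(K) if w_spe is None else np.asarray(w_spe, float)
    w_tem = np.ones(K) if w_tem is None else np.asarray(w_tem, float)

    score_spe = beta @ w_spe + b_spe  # (H, W)
    att_spe = _softmax(score_spe.ravel()).reshape(H, W)
    score_tem = beta.transpose(1, 0, 2) @ w_tem + b_tem  # (W, H)
    att_tem = _softmax(score_tem.ravel()).reshape(W, H)
    gap = beta.mean(axis=(0, 1))  # (K,)
    att_spa = _softmax(w_spa * gap + b_spa)
    return AttentionMaps(
        att_spe=att_spe,
        att_tem=att_tem,
        att_spa=att_spa,
        params={
            "w_spe": w_spe, "b_spe": b_spe,
            "w_tem": w_tem, "b_tem": b_tem,
            "w_spa": w_spa, "b_spa": b_spa,
        },
    )


def weight_correction(maps: AttentionMaps) -> CorrectedWeights:
    """Broadcast addition and pairwise maximization of the three maps."""
    att_spe = np.asarray(maps.att_spe, float)
    att_tem_t = np.asarray(maps.att_tem, float).T  # (H, W)
    att_spa = np.asarray(maps.att_spa, float)
    if att_spe.shape != att_tem_t.shape:
        raise ValueError(
            f"transpose alignment failed: {att_spe.shape} vs {att_tem_t.shape}"
        )
    att_add = att_spe[:, :, None] + att_tem_t[:, :, None] + att_spa[None, None, :]
    att_max = np.maximum((att_spe * att_tem_t)[:, :, None], att_spa[None, None, :])
    return CorrectedWeights(att_add=att_add, att_max=att_max)


def _identity_kernel(K: int, kernel=(3, 3, 3)) -> np.ndarray:
    w = np.zeros((K, K, *kernel), dtype=np.float64)
    c = tuple(k // 2 for k in kernel)
    for i in range(K):
        w[i, i, c[0], c[1], c[2]] = 1.0
    return w


def tpam_fuse(
    beta: np.ndarray,
    cw: CorrectedWeights,
    conv_weight: np.ndarray | None = None,
    pool: tuple[int, int, int] = (2, 2, 1),
) -> CorrectedWeights:
    """Fuse one ``(H, W, K)`` feature map with its corrected weights.

    ``conv_weight`` is a ``(K_add, K, k1, k2, k3)`` kernel for the addition
    path; ``None`` uses the identity kernel (K_add = K), under which
    ``att_add == 1`` everywhere implies ``I_add == beta``.  Returns the input
    ``CorrectedWeights`` with ``i_add`` (H, W, K_add), ``i_max`` (H, W, 2K)
    and ``i_tpam`` (H//2, W//2, 2K + K_add) filled in.
    """
    beta = np.asarray(beta, dtype=np.float64)
    H, W, K = beta.shape
    w = _identity_kernel(K) if conv_weight is None else np.asarray(conv_weight, float)
    # run through the batched channel-first machinery with a singleton B axis
    bt = nn.Tensor(beta.transpose(2, 0, 1)[None, :, :, :, None])  # (1, K, H, W, 1)
    add_t = nn.Tensor(cw.att_add.transpose(2, 0, 1)[None, :, :, :, None])
    max_t = nn.Tensor(cw.att_max.transpose(2, 0, 1)[None, :, :, :, None])

    i_add = (add_t * bt).conv3d(nn.Tensor(w), pad=tuple((k - 1) // 2 for k in w.shape[2:]))
    i_max = nn.concat([max_t * bt, bt], axis=1)
    fused = nn.concat([i_max, i_add], axis=1)
    if fused.shape[2] < pool[0] or fused.shape[3] < pool[1]:
        log.warning("tpam_fuse: pooling skipped on axes smaller than the pool size")
    i_tpam = fused.maxpool3d(pool)

    def to_hwk(t: nn.Tensor) -> np.ndarray:
        return t.data[0, :, :, :, 0].transpose(1, 2, 0)

    cw.i_add = to_hwk(i_add)
    cw.i_max = to_hwk(i_max)
    cw.i_tpam = to_hwk(i_tpam)
    return cw
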