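"""From an 8-s segment to a feature volume, through attention correction.

Shows the spectrogram-volume construction (12x12 grid of time frames x 32
spectral bins), the three softmax-normalized attention maps, and the two
weight-correction combinations.  Each map sums to exactly 1; the
maximization map dominates both of its constituents pointwise.
"""

import numpy as np

import cardiopyramid as cp
from cardiopyramid.attention import compute_attention_maps, tpam_fuse, weight_correction

cfg = cp.SynthConfig(seed=5)
ecg = cp.generate_ecg(cfg, subject_seed=0, label="negative", duration_s=10.0)
segment = ecg.samples[: 8 * 2000]

vol = cp.build_volume(segment, 2000.0)
print(f"volume shape H x W x B = {vol.shape}; "
      f"{vol.meta['n_frames']} real frames, {vol.meta['n_padded']} edge-padded")

# a small random feature map stands in for the pyramid-network output
rng = np.random.default_rng(0)
beta = rng.standard_normal((6, 6, 8))
maps = compute_attention_maps(beta)
print(f"attention sums: spectral {maps.att_spe.sum():.6f}, "
      f"temporal {maps.att_tem.sum():.6f}, spatial {maps.att_spa.sum():.6f}")

cw = weight_correction(maps)
out = tpam_fuse(beta, cw)
print(f"addition map range [{cw.att_add.min():.4f}, {cw.att_add.max():.4f}] "
      f"(uniform maps would give exactly 1/36 + 1/36 + 1/8 everywhere)")
print(f"fused output: {out.i_tpam.shape} = (grid halved by pooling, 2K+K_add channels)")
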