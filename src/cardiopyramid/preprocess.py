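"""Denoising, normalization, false-peak elimination and segmentation.

The preprocessing chain mirrors the standard quality-enhancement path for
ECG/PCG classification:

1. **Wiener filtering** — a length-``p`` FIR filter whose taps solve the
   Wiener–Hopf equations ``R_xx Psi = r_xd``, where ``R_xx`` is the Toeplitz
   autocorrelation matrix of the noisy input and ``r_xd`` the cross-correlation
   with the (unknown) clean signal.  Under the additive-uncorrelated-noise
   model ``x = d + v`` the cross-correlation is ``r_xd = r_xx - r_vv``; for
   white noise this only changes lag 0, with the noise variance estimated
   robustly from the median absolute first difference.
2. **Min–max normalization** — linear map of the sample range onto
   ``[new_min, new_max]``.
3. **False-peak elimination** — candidate peaks above an adaptive
   median + c·MAD amplitude threshold are scored with robust statistical
   features (interval and amplitude z-scores, local moments, out-of-band
   power) and removed by cubic reinterpolation when enough features vote
   "artifact".
4. **Sliding-window segmentation** — fixed 8-s windows with class-dependent
   stride (8 s positive / 3 s negative) so the segment-level class ratio is
   approximately rebalanced to 1:1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.linalg import solve_toeplitz, toeplitz
from scipy.signal import find_peaks, lfilter
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .records import SegmentArchive, SignalRecord, is_positive

log = logging.getLogger(__name__)

__all__ = [
    "WienerConfig",
    "NormalizationConfig",
    "FalsePeakConfig",
    "SegmentationConfig",
    "PeakSet",
    "wiener_filter",
    "wiener_taps",
    "minmax_normalize",
    "false_peak_elimination",
    "segment_signal",
    "preprocess_record",
]

#: Physiological pass-bands (Hz) used by the out-of-band power feature.
PHYSIO_BAND = {"ECG": (0.5, 40.0), "PCG": (25.0, 400.0)}


# --------------------------------------------------------------------------- #
# configs                                                                     #
# --------------------------------------------------------------------------- #

@dataclass
class WienerConfig:
    """Wiener denoiser parameters.

    order_p : FIR tap count (filter order).
    noise_model : ``"white_mad"`` (variance from the MAD of first differences)
        or ``"reference_segment"`` (autocorrelation of a user-marked
        noise-only slice).
    frame_len : samples per local autocorrelation frame; 0 = whole signal.
    noise_segment : (start, stop) sample slice of noise-only data, required
        for ``noise_model="reference_segment"``.
    """

    order_p: int = 32
    noise_model: str = "white_mad"
    frame_len: int = 0
    noise_segment: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.order_p < 1:
            raise ValueError("order_p must be >= 1")
        if self.frame_len and self.frame_len < 4 * self.order_p:
            raise ValueError("frame_len must be 0 or >= 4*order_p")
        if self.noise_model not in ("white_mad", "reference_segment"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class NormalizationConfig:
    new_min: float = 0.0
    new_max: float = 1.0

    def __post_init__(self) -> None:
        if not self.new_max > self.new_min:
            raise ValueError("new_max must be > new_min")


@dataclass
class FalsePeakConfig:
    """Adaptive-threshold false-peak elimination parameters.

    The amplitude threshold is ``median_w(|x|) + c * MAD_w(|x|)`` over sliding
    windows of ``window_s`` seconds.  A candidate peak is flagged false when at
    least ``votes`` features exceed their robust cutoffs.
    """

    c: float = 4.0
    window_s: float = 2.0
    z_cutoff: float = 3.0
    kurtosis_cutoff: float = 8.0
    band_ratio_cutoff: float = 0.5
    votes: int = 2
    repair_halfwidth_s: float = 0.100  # samples replaced around a false peak


@dataclass
class SegmentationConfig:
    window_s: float = 8.0
    stride_positive_s: float = 8.0
    stride_negative_s: float = 3.0

    def __post_init__(self) -> None:
        if min(self.window_s, self.stride_positive_s, self.stride_negative_s) <= 0:
            raise ValueError("window and strides must be > 0")


@dataclass
class PeakSet:
    """Candidate peaks with per-peak features and false flags."""

    indices: np.ndarray
    amplitudes: np.ndarray
    features: dict[str, np.ndarray] = field(default_factory=dict)
    is_false: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        if self.is_false.size == 0:
            self.is_false = np.zeros(self.indices.size, dtype=bool)
        for name, v in self.features.items():
            if len(v) != self.indices.size:
                raise ValueError(f"feature {name!r} length mismatch")
        if self.is_false.size != self.indices.size:
            raise ValueError("is_false length mismatch")

    @property
    def n_false(self) -> int:
        return int(np.sum(self.is_false))

    @staticmethod
    def empty() -> "PeakSet":
        return PeakSet(indices=np.zeros(0, int), amplitudes=np.zeros(0))


# --------------------------------------------------------------------------- #
# Wiener filtering                                                            #
# --------------------------------------------------------------------------- #

def _autocorr(x: np.ndarray, nlags: int) -> np.ndarray:
    """Biased autocorrelation r(0..nlags-1) via FFT."""
    n = x.size
    x0 = x - np.mean(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    X = np.fft.rfft(x0, nfft)
    r = np.fft.irfft(X * np.conj(X), nfft)[:nlags].real / n
    return r


def estimate_noise_variance(x: np.ndarray) -> float:
    """White-noise variance via the MAD of first differences.

    ``sigma = MAD(diff(x)) / (sqrt(2) * 0.6745)`` — differencing suppresses the
    (smooth) signal, and each difference of two i.i.d. noise samples has
    standard deviation ``sqrt(2)*sigma``.
    """
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return float((mad / (np.sqrt(2) * 0.6745)) ** 2)


def wiener_taps(
    r_xx: np.ndarray,
    r_xd: np.ndarray,
    cond_limit: float = 1e12,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Solve the Toeplitz Wiener–Hopf system ``toeplitz(r_xx) @ taps = r_xd``.

    Ill-conditioned systems (condition number above ``cond_limit``) get a
    ridge of ``ridge * r_xx[0]`` added to the diagonal, with a logged warning.
    """
    r_xx = np.asarray(r_xx, dtype=float)
    r_xd = np.asarray(r_xd, dtype=float)
    if r_xx.shape != r_xd.shape or r_xx.ndim != 1:
        raise ValueError("r_xx and r_xd must be 1-D arrays of equal length")
    R = toeplitz(r_xx)
    if np.linalg.cond(R) > cond_limit:
        log.warning("Wiener system ill-conditioned; applying ridge %g*r_xx[0]", ridge)
        r_xx = r_xx.copy()
        r_xx[0] += ridge * abs(r_xx[0])
    return solve_toeplitz(r_xx, r_xd)


def _wiener_once(x: np.ndarray, cfg: WienerConfig, r_vv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = cfg.order_p
    r_xx = _autocorr(x, p)
    r_xd = r_xx - r_vv[:p]
    taps = wiener_taps(r_xx, r_xd)
    return lfilter(taps, 1.0, x), taps


def wiener_filter(
    x: np.ndarray,
    cfg: WienerConfig | None = None,
    return_taps: bool = False,
):
    """FIR Wiener denoising with taps from the Wiener–Hopf equations.

    The output is ``y(n) = sum_k taps[k] x(n-k)`` with zero-padded history, so
    the output length equals the input length.  In the noiseless limit
    (estimated noise variance 0) the solution is the identity tap vector
    ``e0`` and the signal passes through unchanged.
    """
    cfg = cfg or WienerConfig()
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= 4 * cfg.order_p:
        raise ValueError(f"input length {x.size} too short for order {cfg.order_p}")

    p = cfg.order_p
    if cfg.noise_model == "reference_segment":
        if cfg.noise_segment is None:
            raise ValueError("noise_model='reference_segment' requires noise_segment")
        a, b = cfg.noise_segment
        seg = x[a:b]
        if seg.size < 4 * p:
            raise ValueError("noise_segment too short for the filter order")
        r_vv = _autocorr(seg, p)
    else:
        r_vv = np.zeros(p)
        r_vv[0] = estimate_noise_variance(x)

    if cfg.frame_len:
        ys, taps = [], None
        zi = np.zeros(p - 1) if p > 1 else None
        for start in range(0, x.size, cfg.frame_len):
            frame = x[start : start + cfg.frame_len]
            if frame.size < 4 * p:  # tail too short: reuse previous taps
                if taps is None:
                    taps = np.eye(p)[0]
            else:
                r_xx = _autocorr(frame, p)
                taps = wiener_taps(r_xx, r_xx - r_vv[:p])
            if p > 1:
                y, zi = lfilter(taps, 1.0, frame, zi=zi)
            else:
                y = lfilter(taps, 1.0, frame)
            ys.append(y)
        out = np.concatenate(ys)
    else:
        out, taps = _wiener_once(x, cfg, r_vv)

    return (out, taps) if return_taps else out


# --------------------------------------------------------------------------- #
# normalization                                                               #
# --------------------------------------------------------------------------- #

def minmax_normalize(x: np.ndarray, cfg: NormalizationConfig | None = None) -> np.ndarray:
    """Map the sample range linearly onto ``[new_min, new_max]``.

    Constant input is degenerate (zero range); it maps to ``new_min``
    everywhere with a logged warning instead of dividing by zero.
    """
    cfg = cfg or NormalizationConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one sample")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        log.warning("minmax_normalize: constant input; returning new_min everywhere")
        return np.full_like(x, cfg.new_min, dtype=float)
    return (x - lo) / (hi - lo) * (cfg.new_max - cfg.new_min) + cfg.new_min


# --------------------------------------------------------------------------- #
# false-peak elimination                                                      #
# --------------------------------------------------------------------------- #

def _rolling_median_mad(a: np.ndarray, win: int, hop: int) -> tuple[np.ndarray, np.ndarray]:
    """Block median/MAD at hop spacing, linearly interpolated to sample grid."""
    n = a.size
    centers, med, mad = [], [], []
    for start in range(0, max(n - win + 1, 1), hop):
        blk = a[start : start + win]
        m = np.median(blk)
        centers.append(start + blk.size / 2)
        med.append(m)
        mad.append(np.median(np.abs(blk - m)))
    if len(centers) == 1:
        return np.full(n, med[0]), np.full(n, mad[0])
    idx = np.arange(n)
    return (
        np.interp(idx, centers, med),
        np.interp(idx, centers, mad),
    )


def _robust_z(v: np.ndarray) -> np.ndarray:
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(v, dtype=float)
    return (v - med) / scale


def _band_power_ratio(seg: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Fraction of spectral power outside the physiological band."""
    if seg.size < 8:
        return 0.0
    w = seg - np.mean(seg)
    spec = np.abs(np.fft.rfft(w * np.hanning(w.size))) ** 2
    freqs = np.fft.rfftfreq(w.size, d=1.0 / fs)
    total = float(np.sum(spec))
    if total == 0:
        return 0.0
    inband = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.sum(spec[~inband]) / total)


def false_peak_elimination(
    x: np.ndarray,
    fs: float,
    modality: str = "ECG",
    cfg: FalsePeakConfig | None = None,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, PeakSet]:
    """Detect and repair artifact peaks with adaptive amplitude thresholding.

    Candidate peaks are local maxima of ``|x|`` above the sliding
    median + c·MAD threshold.  Each candidate is scored with:

    * ``interval_z`` — robust z of its shortest inter-peak gap;
    * ``amplitude_z`` — robust z of its |amplitude| across candidates;
    * ``local_variance`` / ``local_skewness`` / ``local_kurtosis`` — moments
      in a ±100 ms window;
    * ``band_power_ratio`` — power outside the modality's physiological band;
    * ``channel_corr`` — correlation with the paired modality (only when a
      ``reference`` signal is supplied).

    A peak with at least ``cfg.votes`` features past their cutoffs is flagged
    false and its ±100 ms neighborhood re-drawn by a cubic spline fitted to
    flanking samples.  With fewer than two candidates the input is returned
    unchanged with an empty :class:`PeakSet`.
    """
    cfg = cfg or FalsePeakConfig()
    x = np.asarray(x, dtype=float).ravel()
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if x.size < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    if modality not in PHYSIO_BAND:
        raise ValueError(f"modality must be one of {tuple(PHYSIO_BAND)}")

    absx = np.abs(x)
    win = max(int(round(cfg.window_s * fs)), 16)
    med, mad = _rolling_median_mad(absx, win, hop=max(win // 2, 1))
    theta = med + cfg.c * mad

    min_dist = max(int(0.05 * fs), 1)  # refractory spacing between candidates
    idx, _ = find_peaks(absx, height=theta, distance=min_dist)
    if idx.size < 2:
        log.warning("false_peak_elimination: <2 candidate peaks; returning input unchanged")
        return x.copy(), PeakSet.empty()

    amps = x[idx]
    half = int(round(cfg.repair_halfwidth_s * fs))

    # interval feature: shortest adjacent gap per peak
    gaps = np.diff(idx).astype(float)
    nearest = np.empty(idx.size)
    nearest[0] = gaps[0]
    nearest[-1] = gaps[-1]
    if idx.size > 2:
        nearest[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    interval_z = _robust_z(nearest)
    amplitude_z = _robust_z(np.abs(amps))

    var = np.empty(idx.size)
    skw = np.empty(idx.size)
    kur = np.empty(idx.size)
    bpr = np.empty(idx.size)
    band = PHYSIO_BAND[modality]
    for i, k in enumerate(idx):
        seg = x[max(k - half, 0) : k + half + 1]
        var[i] = np.var(seg)
        skw[i] = _skew(seg) if seg.size > 2 else 0.0
        kur[i] = _kurtosis(seg, fisher=False) if seg.size > 3 else 0.0
        bpr[i] = _band_power_ratio(seg, fs, band)
    variance_z = _robust_z(var)

    features = {
        "interval_z": interval_z,
        "amplitude_z": amplitude_z,
        "local_variance": var,
        "local_skewness": skw,
        "local_kurtosis": kur,
        "band_power_ratio": bpr,
    }
    votes = (
        (np.abs(interval_z) > cfg.z_cutoff).astype(int)
        + (np.abs(amplitude_z) > cfg.z_cutoff).astype(int)
        + (np.abs(variance_z) > cfg.z_cutoff).astype(int)
        + (kur > cfg.kurtosis_cutoff).astype(int)
        + (bpr > cfg.band_ratio_cutoff).astype(int)
    )
    if reference is not None and reference.size == x.size:
        cc = np.empty(idx.size)
        for i, k in enumerate(idx):
            a = x[max(k - half, 0) : k + half + 1]
            b = reference[max(k - half, 0) : k + half + 1]
            sa, sb = np.std(a), np.std(b)
            cc[i] = float(np.corrcoef(a, b)[0, 1]) if sa > 0 and sb > 0 else 0.0
        features["channel_corr"] = cc
        votes += (np.abs(_robust_z(cc)) > cfg.z_cutoff).astype(int)

    is_false = votes >= cfg.votes
    peaks = PeakSet(indices=idx, amplitudes=amps, features=features, is_false=is_false)

    cleaned = x.copy()
    for k in idx[is_false]:
        lo, hi = max(k - half, 0), min(k + half + 1, x.size)
        # fit a cubic to flank samples on both sides and redraw the window
        flank = half
        left = np.arange(max(lo - flank, 0), lo)
        right = np.arange(hi, min(hi + flank, x.size))
        if left.size < 2 or right.size < 2:
            # peak at a signal edge: no bracketing flanks, so a polynomial
            # would extrapolate; hold the median of whatever flank exists
            support = np.concatenate([left, right])
            fill = np.median(cleaned[support]) if support.size else 0.0
            cleaned[lo:hi] = fill
            continue
        # shape-preserving cubic (PCHIP) on the bracketing flanks: no
        # overshoot beyond the flank range, which matters for oscillatory
        # heart-sound flanks
        support = np.concatenate([left, right])
        spline = PchipInterpolator(support, cleaned[support])
        cleaned[lo:hi] = spline(np.arange(lo, hi))
    return cleaned, peaks


# --------------------------------------------------------------------------- #
# segmentation                                                                #
# --------------------------------------------------------------------------- #

def segment_signal(rec: SignalRecord, cfg: SegmentationConfig | None = None) -> SegmentArchive:
    """Cut a record into fixed windows with class-dependent stride.

    Positive-class records (including AD/MVP/MPC subtypes) use
    ``stride_positive_s``; everything else uses ``stride_negative_s``.  The
    number of segments is ``floor((L - w)/s) + 1`` in samples.  Records
    shorter than the window yield an empty archive with a logged skip.
    """
    cfg = cfg or SegmentationConfig()
    w = int(round(cfg.window_s * rec.fs))
    stride_s = cfg.stride_positive_s if is_positive(rec.label) else cfg.stride_negative_s
    s = int(round(stride_s * rec.fs))
    L = rec.n_samples
    if L < w:
        log.info("segment_signal: record %s shorter than window; skipped", rec.record_id)
        return SegmentArchive.empty(rec.fs, cfg.window_s)
    n = (L - w) // s + 1
    starts = np.arange(n) * s
    segments = np.stack([rec.samples[a : a + w] for a in starts]).astype(np.float32)
    return SegmentArchive(
        segments=segments,
        fs=rec.fs,
        window_s=cfg.window_s,
        labels=[rec.label] * n,
        provenance=[(rec.record_id, int(a)) for a in starts],
    )


# --------------------------------------------------------------------------- #
# full chain                                                                  #
# --------------------------------------------------------------------------- #

def preprocess_record(
    rec: SignalRecord,
    wiener: WienerConfig | None = None,
    fpe: FalsePeakConfig | None = None,
    seg: SegmentationConfig | None = None,
    norm: NormalizationConfig | None = None,
    apply_wiener: bool = True,
    apply_fpe: bool = True,
) -> SegmentArchive:
    """Denoise, clean, segment and per-segment normalize one record."""
    x = rec.samples
    if apply_wiener:
        x = wiener_filter(x, wiener)
    if apply_fpe:
        x, _ = false_peak_elimination(x, rec.fs, rec.modality, fpe)
    arc = segment_signal(rec.replace_samples(x), seg)
    ncfg = norm or NormalizationConfig()
    if len(arc):
        arc.segments = np.stack(
            [minmax_normalize(s, ncfg) for s in arc.segments]
        ).astype(np.float32)
    return arc
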