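"""Synthetic labeled ECG/PCG cohorts for exercising the full pipeline.

The generator emulates the structure of paired stethoscope/ECG recordings
from a screening population:

* quasi-periodic ECG built from per-beat Gaussian components (P, Q, R, S, T)
  placed on a jittered RR sequence, with ground-truth R-peak positions;
* PCG with S1 bursts time-locked to each R peak and S2 bursts at
  ``R + 0.35*RR`` (end of systole), both modulated sinusoids;
* a positive-class effect: band-limited (120–400 Hz) murmur noise in the
  systolic interval between S1 and S2, at a configurable power relative to S1;
* corruption stages: baseline wander, 50 Hz powerline interference, white
  noise at a target SNR, and Poisson-placed spike artifacts (the ground truth
  for false-peak elimination tests).

Recording durations follow a clipped lognormal targeting a ~31.7 s mean
inside a [9, 36] s envelope, matching a screening-database duration profile.
Everything is driven by ``numpy.random.Generator`` (PCG64) seeded from
``SynthConfig.seed``; one seed yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .records import SignalRecord

__all__ = [
    "SynthConfig",
    "generate_ecg",
    "generate_pcg",
    "corrupt_signal",
    "generate_cohort",
    "murmur_band_power",
]

#: Per-beat ECG morphology: (amplitude mV, width s, offset s relative to R).
DEFAULT_ECG_MORPHOLOGY = {
    "P": (0.12, 0.025, -0.20),
    "Q": (-0.10, 0.010, -0.035),
    "R": (1.00, 0.012, 0.0),
    "S": (-0.15, 0.010, 0.035),
    "T": (0.30, 0.060, 0.30),
}

MURMUR_BAND = (120.0, 400.0)


@dataclass
class SynthConfig:
    """Full parameterization of a synthetic cohort."""

    n_positive: int = 50
    n_negative: int = 50
    fs: float = 2000.0
    # clipped lognormal duration distribution, [9, 36] s envelope
    duration_log_mean: float = float(np.log(31.7))
    duration_log_sd: float = 0.15
    duration_min_s: float = 9.0
    duration_max_s: float = 36.0
    heart_rate_bpm: tuple[float, float] = (70.0, 7.0)  # between-subject mean, sd
    rr_jitter_frac: float = 0.03  # within-subject RR jitter (fraction of RR)
    ecg_morphology: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ECG_MORPHOLOGY)
    )
    # PCG burst parameters: (center Hz, bandwidth-as-decay s, duration s)
    s1_freq: float = 90.0
    s2_freq: float = 120.0
    burst_duration_s: float = 0.100
    s2_fraction: float = 0.35  # S2 at R + s2_fraction * RR
    # positive-class effect: murmur power relative to S1 burst power
    murmur_rel_power: float = 0.5
    rr_irregularity_positive: float = 0.0  # extra RR jitter for positives
    subtype_labels: bool = False  # cycle AD/MVP/MPC over positives
    # corruption levels
    baseline_wander_amp: float = 0.1  # amplitude, units of the clean signal
    powerline_amp: float = 0.05
    white_snr_db: float | None = 15.0  # None = no white noise
    spike_rate_hz: float = 0.1  # Poisson spikes per second
    spike_amplitude_rel: float = 5.0  # x max |clean|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("subject counts must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.duration_min_s < 8.0:
            raise ValueError("duration_min_s must respect the 8-s analysis window")


def _subject_rng(cfg: SynthConfig, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed) % (2**31), int(subject_seed) % (2**31)])


def _draw_duration(cfg: SynthConfig, rng: np.random.Generator) -> float:
    d = float(rng.lognormal(cfg.duration_log_mean, cfg.duration_log_sd))
    return float(np.clip(d, cfg.duration_min_s, cfg.duration_max_s))


# --------------------------------------------------------------------------- #
# ECG                                                                         #
# --------------------------------------------------------------------------- #

def generate_ecg(
    cfg: SynthConfig,
    subject_seed: int,
    label: str = "negative",
    duration_s: float | None = None,
    record_id: str | None = None,
) -> SignalRecord:
    """Clean synthetic ECG: Gaussian P/Q/R/S/T components on a jittered RR grid.

    Ground-truth R-peak sample indices are stored in ``meta["r_peaks"]`` and
    the per-beat RR intervals in ``meta["rr_s"]``.
    """
    rng = _subject_rng(cfg, subject_seed)
    dur = duration_s if duration_s is not None else _draw_duration(cfg, rng)
    n = int(round(dur * cfg.fs))
    t = np.arange(n) / cfg.fs

    hr = rng.normal(cfg.heart_rate_bpm[0], cfg.heart_rate_bpm[1])
    hr = float(np.clip(hr, 45.0, 120.0))
    rr_mean = 60.0 / hr
    jitter = cfg.rr_jitter_frac + (
        cfg.rr_irregularity_positive if label in ("positive", "AD", "MVP", "MPC") else 0.0
    )

    r_times = []
    tr = rr_mean / 2  # first R half a beat in
    while tr < dur:
        r_times.append(tr)
        tr += rr_mean * max(1.0 + jitter * rng.standard_normal(), 0.4)
    r_times = np.asarray(r_times)

    x = np.zeros(n)
    rr_seq = np.diff(np.concatenate([r_times, [r_times[-1] + rr_mean]])) if r_times.size else np.zeros(0)
    for tr_i in r_times:
        for amp, width, offset in cfg.ecg_morphology.values():
            mu = tr_i + offset
            lo = np.searchsorted(t, mu - 5 * width)
            hi = np.searchsorted(t, mu + 5 * width)
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / width) ** 2)

    r_peaks = np.round(r_times * cfg.fs).astype(int)
    r_peaks = r_peaks[r_peaks < n]
    rid = record_id or f"ecg{subject_seed:04d}"
    return SignalRecord(
        record_id=rid,
        modality="ECG",
        samples=x,
        fs=cfg.fs,
        label=label,
        meta={"r_peaks": r_peaks, "rr_s": rr_seq, "heart_rate_bpm": hr},
    )


# --------------------------------------------------------------------------- #
# PCG                                                                         #
# --------------------------------------------------------------------------- #

def _burst(t: np.ndarray, center: float, freq: float, dur: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-windowed sinusoid centered at ``center`` seconds."""
    sigma = dur / 4.0
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    phase = rng.uniform(0, 2 * np.pi)
    return env * np.sin(2 * np.pi * freq * (t - center) + phase)


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def murmur_band_power(x: np.ndarray, fs: float, band: tuple[float, float] = MURMUR_BAND) -> float:
    """Mean power of the signal restricted to the murmur band (Welch-free
    band-pass estimate; used as the class-separability statistic)."""
    return float(np.mean(_bandpass(np.asarray(x, float), fs, band) ** 2))


def generate_pcg(ecg_rec: SignalRecord, cfg: SynthConfig, subject_seed: int | None = None) -> SignalRecord:
    """PCG time-locked to an ECG record's ground-truth R peaks.

    S1 bursts land on each R peak, S2 at ``R + s2_fraction*RR``.  For
    positive-class records, band-limited murmur noise fills the systolic
    interval between S1 and S2 at ``murmur_rel_power`` times the S1 power.
    """
    if "r_peaks" not in ecg_rec.meta:
        raise ValueError("ECG record lacks r_peaks ground truth (dependency error)")
    seed = subject_seed if subject_seed is not None else 1_000_000 + hash(ecg_rec.record_id) % 65536
    rng = _subject_rng(cfg, seed)
    fs = ecg_rec.fs
    n = ecg_rec.n_samples
    t = np.arange(n) / fs
    r_times = ecg_rec.meta["r_peaks"] / fs
    rr = np.diff(np.concatenate([r_times, [r_times[-1] + (r_times[-1] - r_times[-2] if r_times.size > 1 else 0.8)]])) if r_times.size else np.zeros(0)

    x = np.zeros(n)
    s2_times = []
    for tr_i, rr_i in zip(r_times, rr):
        x += _burst(t, tr_i, cfg.s1_freq, cfg.burst_duration_s, rng)
        ts2 = tr_i + cfg.s2_fraction * rr_i
        if ts2 < t[-1]:
            x += 0.7 * _burst(t, ts2, cfg.s2_freq, 0.8 * cfg.burst_duration_s, rng)
            s2_times.append(ts2)

    positive = ecg_rec.label in ("positive", "AD", "MVP", "MPC")
    if positive and cfg.murmur_rel_power > 0 and r_times.size:
        s1_power = np.mean(_burst(t, t[n // 2], cfg.s1_freq, cfg.burst_duration_s, rng) ** 2) * (
            cfg.burst_duration_s * r_times.size / t[-1] if t[-1] > 0 else 1.0
        )
        # reference S1 power measured on the built signal inside burst windows
        mask = np.zeros(n, bool)
        h = int(cfg.burst_duration_s * fs / 2)
        for tr_i in (r_times * fs).astype(int):
            mask[max(tr_i - h, 0) : tr_i + h] = True
        s1_power = float(np.mean(x[mask] ** 2)) if mask.any() else 1.0
        band = MURMUR_BAND
        if cfg.subtype_labels and ecg_rec.label in ("AD", "MVP", "MPC"):
            band = {"AD": (120.0, 250.0), "MVP": (200.0, 350.0), "MPC": (250.0, 400.0)}[ecg_rec.label]
        noise = _bandpass(rng.standard_normal(n), fs, band)
        sys_mask = np.zeros(n, bool)
        for tr_i, ts2 in zip(r_times, s2_times):
            a = int((tr_i + cfg.burst_duration_s / 2) * fs)
            b = int((ts2 - 0.4 * cfg.burst_duration_s) * fs)
            if b > a:
                sys_mask[a:b] = True
        if sys_mask.any():
            target = cfg.murmur_rel_power * s1_power
            cur = float(np.mean(noise[sys_mask] ** 2))
            if cur > 0:
                noise *= np.sqrt(target / cur)
            x[sys_mask] += noise[sys_mask]

    return SignalRecord(
        record_id=ecg_rec.record_id.replace("ecg", "pcg") if "ecg" in ecg_rec.record_id else ecg_rec.record_id + "_pcg",
        modality="PCG",
        samples=x,
        fs=fs,
        label=ecg_rec.label,
        meta={
            "r_peaks": ecg_rec.meta["r_peaks"].copy(),
            "s1_times_s": r_times.copy(),
            "s2_times_s": np.asarray(s2_times),
        },
    )


# --------------------------------------------------------------------------- #
# corruption                                                                  #
# --------------------------------------------------------------------------- #

def corrupt_signal(rec: SignalRecord, cfg: SynthConfig, subject_seed: int = 0) -> SignalRecord:
    """Add baseline wander, powerline, white noise and spike artifacts.

    Spike positions (ground truth for false-peak tests) are stored in
    ``meta["artifact_positions"]``.  With all levels zero the record is
    returned unchanged (new object, identical samples).
    """
    rng = _subject_rng(cfg, 2_000_000 + subject_seed)
    x = rec.samples.copy()
    n = x.size
    t = np.arange(n) / rec.fs
    clean_power = float(np.mean(x**2)) if n else 0.0
    peak = float(np.max(np.abs(x))) if n else 1.0

    if cfg.baseline_wander_amp > 0:
        f = rng.uniform(0.2, 0.5)
        x += cfg.baseline_wander_amp * peak * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if cfg.powerline_amp > 0:
        x += cfg.powerline_amp * peak * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    if cfg.white_snr_db is not None and clean_power > 0:
        noise_power = clean_power / 10 ** (cfg.white_snr_db / 10)
        x += np.sqrt(noise_power) * rng.standard_normal(n)

    spikes = np.zeros(0, dtype=int)
    if cfg.spike_rate_hz > 0 and n:
        n_spikes = rng.poisson(cfg.spike_rate_hz * n / rec.fs)
        if n_spikes:
            guard = int(0.25 * rec.fs)
            pos = rng.integers(guard, max(n - guard, guard + 1), size=n_spikes)
            pos = np.unique(pos)
            amp = cfg.spike_amplitude_rel * peak
            width = max(int(0.004 * rec.fs), 1)  # 4 ms impulse
            for p in pos:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                lo, hi = max(p - 2 * width, 0), min(p + 2 * width + 1, n)
                k = np.arange(lo, hi)
                x[lo:hi] += sign * amp * np.exp(-0.5 * ((k - p) / width) ** 2)
            spikes = pos

    meta = dict(rec.meta)
    meta["artifact_positions"] = spikes
    out = rec.replace_samples(x)
    out.meta = meta
    return out


# --------------------------------------------------------------------------- #
# cohort                                                                      #
# --------------------------------------------------------------------------- #

def generate_cohort(
    cfg: SynthConfig,
    out_dir: str | Path | None = None,
    corrupt: bool = True,
) -> tuple[list[tuple[SignalRecord, SignalRecord]], pd.DataFrame]:
    """Generate ``n_positive + n_negative`` paired (ECG, PCG) records.

    Returns the list of pairs and a manifest DataFrame with columns
    ``record_id,label,duration_s,heart_rate_bpm,n_r_peaks``.  When ``out_dir``
    is given, signals are written as WAV, the manifest as CSV, and ground
    truth (R peaks, artifact positions) as JSON sidecars.
    """
    from . import io as sio  # local import to avoid cycle at module import

    subtypes = ("AD", "MVP", "MPC")
    pairs: list[tuple[SignalRecord, SignalRecord]] = []
    rows = []
    for i in range(cfg.n_positive + cfg.n_negative):
        if i < cfg.n_positive:
            label = subtypes[i % 3] if cfg.subtype_labels else "positive"
        else:
            label = "negative"
        rid = f"rec{i:04d}"
        ecg = generate_ecg(cfg, subject_seed=i, label=label, record_id=rid)
        pcg = generate_pcg(ecg, cfg, subject_seed=i)
        pcg.record_id = rid
        if corrupt:
            ecg = corrupt_signal(ecg, cfg, subject_seed=2 * i)
            pcg = corrupt_signal(pcg, cfg, subject_seed=2 * i + 1)
        pairs.append((ecg, pcg))
        rows.append(
            {
                "record_id": rid,
                "label": label,
                "duration_s": round(ecg.duration_s, 4),
                "heart_rate_bpm": round(ecg.meta.get("heart_rate_bpm", float("nan")), 2),
                "n_r_peaks": int(ecg.meta["r_peaks"].size),
            }
        )
    manifest = pd.DataFrame(rows, columns=["record_id", "label", "duration_s", "heart_rate_bpm", "n_r_peaks"])

    if out_dir is not None:
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for ecg, pcg in pairs:
            ep = out / f"{ecg.record_id}_ecg.wav"
            pp = out / f"{pcg.record_id}_pcg.wav"
            tp = out / f"{ecg.record_id}_truth.json"
            # WAV is unit-scaled; normalize ECG into [-1, 1] for the container
            sio.write_record_wav(ecg, ep)
            sio.write_record_wav(pcg, pp)
            truth = {
                "r_peaks": ecg.meta["r_peaks"].tolist(),
                "ecg_artifacts": np.asarray(ecg.meta.get("artifact_positions", [])).tolist(),
                "pcg_artifacts": np.asarray(pcg.meta.get("artifact_positions", [])).tolist(),
            }
            tp.write_text(json.dumps(truth))
            paths.append((str(ep), str(pp), str(tp)))
        manifest = manifest.assign(
            ecg_path=[p[0] for p in paths],
            pcg_path=[p[1] for p in paths],
            truth_path=[p[2] for p in paths],
        )
        manifest.to_csv(out / "manifest.csv", index=False)

    return pairs, manifest
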