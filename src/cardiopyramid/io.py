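"""Reading, resampling and persisting biosignal records and segment archives.

Supported on-disk formats:

* WAV — PCM mono (16/32-bit int or float), via :mod:`scipy.io.wavfile`.
* CSV — two columns ``time_s,value`` (header optional); the sampling rate is
  inferred from the median inter-sample interval.
* WFDB — header/data record pairs as distributed with the 2016 PhysioNet/CinC
  challenge; only format 16 (little-endian int16) is supported, signal 0 is
  read and the header's gain/baseline are applied to yield physical units.
* HDF5 — the segment-archive container (datasets ``segments``, ``labels``,
  ``provenance``; attributes ``fs``, ``window_s``).
"""

from __future__ import annotations

import csv
import logging
import os
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile
from scipy.signal import firwin, resample_poly
from fractions import Fraction

from .records import SegmentArchive, SignalRecord

log = logging.getLogger(__name__)

__all__ = [
    "read_record",
    "write_record_wav",
    "write_record_csv",
    "resample_record",
    "write_archive",
    "read_archive",
]


class FormatError(ValueError):
    """File did not parse in the named dialect."""


class CorruptArchiveError(ValueError):
    """HDF5 archive is missing required datasets or attributes."""


# --------------------------------------------------------------------------- #
# record reading                                                              #
# --------------------------------------------------------------------------- #

def read_record(
    path: str | os.PathLike,
    format: str | None = None,
    modality: str = "ECG",
    label: str = "unlabeled",
    record_id: str | None = None,
) -> SignalRecord:
    """Read a single-channel recording from WAV, CSV or WFDB.

    ``format`` defaults to the file extension (``.wav``, ``.csv``, ``.hea``/
    ``.dat`` for WFDB).  Multi-channel inputs are reduced to channel 0 with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        ext = path.suffix.lower()
        format = {".wav": "wav", ".csv": "csv", ".hea": "wfdb", ".dat": "wfdb"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format from extension {ext!r}")
    rid = record_id if record_id is not None else path.stem

    if format == "wav":
        samples, fs = _read_wav(path)
    elif format == "csv":
        samples, fs = _read_csv(path)
    elif format == "wfdb":
        samples, fs = _read_wfdb(path)
    else:
        raise FormatError(f"unknown format {format!r}")

    if samples.size == 0:
        raise ValueError(f"{path}: empty signal")
    return SignalRecord(record_id=rid, modality=modality, samples=samples, fs=fs, label=label)


def _read_wav(path: Path) -> tuple[np.ndarray, float]:
    try:
        fs, data = wavfile.read(str(path))
    except Exception as e:  # noqa: BLE001 - re-raise as dialect error
        raise FormatError(f"{path}: not a readable WAV file ({e})") from e
    if data.ndim > 1:
        log.warning("%s: %d channels; taking channel 0", path, data.shape[1])
        data = data[:, 0]
    # integer PCM -> [-1, 1] float; divisor matches the writer's full scale
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / float(info.max)
    else:
        data = data.astype(np.float64)
    return data, float(fs)


def _read_csv(path: Path) -> tuple[np.ndarray, float]:
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                t, v = float(row[0]), float(row[1])
            except (ValueError, IndexError) as e:
                if lineno == 1:  # optional header
                    continue
                raise FormatError(f"{path}: line {lineno}: {e}") from e
            times.append(t)
            values.append(v)
    if not values:
        raise ValueError(f"{path}: empty signal")
    t = np.asarray(times)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 2
            raise FormatError(f"{path}: time column not strictly increasing at line {bad}")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise FormatError(f"{path}: sample-time jitter exceeds 1% of the median interval")
        fs = 1.0 / med
    else:
        fs = 1.0
    return np.asarray(values, dtype=np.float64), fs


def _read_wfdb(path: Path) -> tuple[np.ndarray, float]:
    """Minimal WFDB reader: header + format-16 data file, signal 0 only."""
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"{hea}: WFDB header not found")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    try:
        n_sig = int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as e:
        raise FormatError(f"{hea}: malformed record line {lines[0]!r}") from e
    if n_sig < 1 or len(lines) < 2:
        raise FormatError(f"{hea}: no signal specification lines")
    if n_sig > 1:
        log.warning("%s: %d signals; taking signal 0", hea, n_sig)

    sig = lines[1].split()
    dat_name, fmt_field = sig[0], sig[1]
    fmt = fmt_field.split("x")[0].split(":")[0].split("+")[0]
    if fmt != "16":
        raise FormatError(f"{hea}: unsupported WFDB format {fmt!r} (only 16)")
    gain, baseline = 200.0, 0.0
    if len(sig) > 2:
        g = sig[2].split("/")[0]
        if "(" in g:
            g, b = g.split("(")
            baseline = float(b.rstrip(")"))
        gain = float(g) if float(g) != 0 else 200.0

    dat = path.parent / dat_name
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size == 0:
        raise ValueError(f"{dat}: empty signal")
    raw = raw[: (raw.size // n_sig) * n_sig].reshape(-1, n_sig)[:, 0]
    if n_samp:
        raw = raw[:n_samp]
    return (raw.astype(np.float64) - baseline) / gain, fs


# --------------------------------------------------------------------------- #
# record writing (WAV / CSV round trips used by the synthetic cohort)         #
# --------------------------------------------------------------------------- #

def write_record_wav(rec: SignalRecord, path: str | os.PathLike) -> None:
    """Write as 16-bit PCM mono WAV, scaling to 90% full scale if |x| > 1."""
    x = rec.samples
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if peak > 1.0:
        x = x / peak * 0.9
    pcm = np.clip(np.round(x * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(rec.fs)), pcm)


def write_record_csv(rec: SignalRecord, path: str | os.PathLike) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        for ti, vi in zip(t, rec.samples):
            w.writerow([repr(float(ti)), repr(float(vi))])


# --------------------------------------------------------------------------- #
# resampling                                                                  #
# --------------------------------------------------------------------------- #

def resample_record(rec: SignalRecord, target_fs: float = 2000.0) -> SignalRecord:
    """Polyphase resampling to ``target_fs`` (default 2000 Hz).

    Identity when the rates already match.  Band content below
    ``min(fs, target_fs)/2`` is preserved by the polyphase anti-aliasing
    filter.  Output length is ``round(n * target_fs / fs)`` within one sample.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be > 0, got {target_fs}")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    # sharper-than-default Kaiser anti-aliasing filter so a down/up round trip
    # of band-limited content stays below 1e-3 relative RMS error
    maxud = max(up, down)
    h = firwin(2 * 20 * maxud + 1, 1.0 / maxud, window=("kaiser", 8.0))
    y = resample_poly(rec.samples, up, down, window=h)
    meta = dict(rec.meta)
    ratio = target_fs / rec.fs
    for key in ("r_peaks", "artifact_positions"):
        if key in meta:
            meta[key] = np.round(np.asarray(meta[key]) * ratio).astype(int)
    out = rec.replace_samples(y, fs=target_fs)
    out.meta = meta
    return out


# --------------------------------------------------------------------------- #
# segment archive persistence (HDF5)                                          #
# --------------------------------------------------------------------------- #

_PROV_DTYPE = np.dtype([("record_id", h5py.string_dtype()), ("start_sample", np.int64)])


def write_archive(arc: SegmentArchive, path: str | os.PathLike) -> None:
    """Persist a segment archive as a single HDF5 file (bit-exact round trip)."""
    prov = np.array(
        [(rid, start) for rid, start in arc.provenance], dtype=_PROV_DTYPE
    ) if arc.provenance else np.zeros((0,), dtype=_PROV_DTYPE)
    with h5py.File(path, "w") as f:
        f.create_dataset("segments", data=arc.segments.astype(np.float32))
        f.create_dataset("labels", data=np.array(arc.labels, dtype=h5py.string_dtype()))
        f.create_dataset("provenance", data=prov)
        f.attrs["fs"] = float(arc.fs)
        f.attrs["window_s"] = float(arc.window_s)


def read_archive(path: str | os.PathLike) -> SegmentArchive:
    with h5py.File(path, "r") as f:
        for name in ("segments", "labels", "provenance"):
            if name not in f:
                raise CorruptArchiveError(f"{path}: missing dataset {name!r}")
        for attr in ("fs", "window_s"):
            if attr not in f.attrs:
                raise CorruptArchiveError(f"{path}: missing attribute {attr!r}")
        segments = f["segments"][...]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][...]]
        prov_raw = f["provenance"][...]
        provenance = [
            (r.decode() if isinstance(r, bytes) else str(r), int(s))
            for r, s in zip(prov_raw["record_id"], prov_raw["start_sample"])
        ]
        fs = float(f.attrs["fs"])
        window_s = float(f.attrs["window_s"])
    return SegmentArchive(
        segments=segments, fs=fs, window_s=window_s, labels=labels, provenance=provenance
    )
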