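"""Core data containers for labeled biosignals and fixed-length segment sets.

A :class:`SignalRecord` is one single-channel recording (ECG in mV, PCG in
normalized arbitrary units) together with its sampling rate, label and any
ground-truth metadata attached by the synthetic generator (R-peak positions,
artifact positions).  A :class:`SegmentArchive` is the result of sliding-window
segmentation: equal-length windows with per-window labels and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

ECG = "ECG"
PCG = "PCG"
MODALITIES = (ECG, PCG)

#: Recognized class labels.  AD / MVP / MPC are the pathological subtypes of
#: the positive class; they count as "positive" wherever a binary view is taken.
LABELS = ("positive", "negative", "AD", "MVP", "MPC", "unlabeled")
POSITIVE_LABELS = frozenset({"positive", "AD", "MVP", "MPC"})


def is_positive(label: str) -> bool:
    return label in POSITIVE_LABELS


@dataclass
class SignalRecord:
    """One labeled, uniformly sampled biosignal.

    Parameters
    ----------
    record_id : str
        Stable identifier, used for provenance and subject-level splitting.
    modality : str
        ``"ECG"`` or ``"PCG"``.
    samples : ndarray
        1-D float array.  Must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        One of :data:`LABELS`.
    meta : dict
        Free-form metadata; the synthetic generator stores ``r_peaks``
        (sample indices) and ``artifact_positions`` here.
    """

    record_id: str
    modality: str
    samples: np.ndarray
    fs: float
    label: str = "unlabeled"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError(f"record {self.record_id!r}: samples contain NaN/Inf")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def replace_samples(self, samples: np.ndarray, fs: float | None = None) -> "SignalRecord":
        """Return a copy of this record with new samples (and optionally fs)."""
        return SignalRecord(
            record_id=self.record_id,
            modality=self.modality,
            samples=samples,
            fs=self.fs if fs is None else fs,
            label=self.label,
            meta=dict(self.meta),
        )


@dataclass
class SegmentArchive:
    """Fixed-length windows cut from one or more records.

    All segments share length ``round(window_s * fs)``.  ``provenance`` keeps
    ``(record_id, start_sample)`` per segment so subject-level cross-validation
    can group segments back to their source recording.
    """

    segments: np.ndarray  # (n, L) float32
    fs: float
    window_s: float
    labels: list[str]
    provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=np.float32)
        if self.segments.ndim == 1 and self.segments.size == 0:
            self.segments = self.segments.reshape(0, self.expected_length)
        if self.segments.ndim != 2:
            raise ValueError("segments must be a 2-D (n, L) array")
        n = self.segments.shape[0]
        if len(self.labels) != n or len(self.provenance) != n:
            raise ValueError("labels and provenance must match the number of segments")
        if n and self.segments.shape[1] != self.expected_length:
            raise ValueError(
                f"segment length {self.segments.shape[1]} != round(window_s*fs) = "
                f"{self.expected_length}"
            )
        for rid, start in self.provenance:
            if start < 0:
                raise ValueError(f"negative start_sample in provenance for {rid!r}")

    @property
    def expected_length(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    def __len__(self) -> int:
        return self.n_segments

    @staticmethod
    def empty(fs: float, window_s: float) -> "SegmentArchive":
        L = int(round(window_s * fs))
        return SegmentArchive(
            segments=np.zeros((0, L), dtype=np.float32),
            fs=fs,
            window_s=window_s,
            labels=[],
            provenance=[],
        )

    @staticmethod
    def concatenate(archives: list["SegmentArchive"]) -> "SegmentArchive":
        """Stack archives that share fs and window length."""
        if not archives:
            raise ValueError("need at least one archive")
        fs, w = archives[0].fs, archives[0].window_s
        for a in archives:
            if a.fs != fs or a.window_s != w:
                raise ValueError("archives differ in fs or window_s")
        return SegmentArchive(
            segments=np.concatenate([a.segments for a in archives], axis=0)
            if any(len(a) for a in archives)
            else np.zeros((0, archives[0].expected_length), np.float32),
            fs=fs,
            window_s=w,
            labels=[l for a in archives for l in a.labels],
            provenance=[p for a in archives for p in a.provenance],
        )
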