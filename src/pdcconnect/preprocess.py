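"""Recording containers and signal conditioning.

Normalizes heterogeneous resting-state EEG recordings to a common
representation — 256 Hz, microvolts, band-passed 0.1–70 Hz with a 50 Hz
mains notch — and cuts them into contiguous, non-overlapping 2-second
analysis segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

TARGET_FS = 256.0
WINDOW_S = 2.0

#: 18 network electrodes in fixed order, plus the Cz reference.
NODE_LABELS = ("FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
               "F7", "F8", "T3", "T4", "T5", "T6", "FZ", "PZ")
REFERENCE_LABEL = "CZ"
MONTAGE_19 = NODE_LABELS + (REFERENCE_LABEL,)


@dataclass
class EEGRecording:
    """Labelled multichannel time series.

    ``data`` is channels × samples in ``unit`` (µV after standardization),
    with one label per row.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    class_label: str | None = None
    unit: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one channel label per data row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One contiguous 2-s analysis window of a preprocessed recording."""

    data: np.ndarray
    fs: float
    index: int
    channel_labels: tuple[str, ...] = field(default_factory=tuple)
    subject_id: str = ""
    class_label: str | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def standardize(rec: EEGRecording, target_fs: float = TARGET_FS,
                target_unit: str = "uV") -> EEGRecording:
    """Resample to ``target_fs`` (anti-aliased polyphase) and convert to µV.

    Only downsampling is supported; recordings already at the target rate and
    unit pass through unchanged. Nanovolt inputs are scaled by 1e-3.
    """
    if rec.unit not in ("uV", "nV"):
        raise ValueError(f"unknown unit {rec.unit!r}; expected 'uV' or 'nV'")
    if target_unit != "uV":
        raise ValueError("only microvolt output is supported")
    data = rec.data
    if rec.unit == "nV":
        data = data * 1e-3
    if rec.fs < target_fs:
        raise ValueError(
            f"upsampling from {rec.fs} Hz to {target_fs} Hz is not supported"
        )
    if rec.fs != target_fs:
        ratio = Fraction(target_fs / rec.fs).limit_denominator(10000)
        data = signal.resample_poly(data, ratio.numerator, ratio.denominator, axis=1)
    return replace(rec, data=data, fs=float(target_fs), unit="uV")


def filter_signal(rec: EEGRecording, band: tuple[float, float] = (0.1, 70.0),
                  notch: float | None = 50.0, order: int = 4,
                  notch_q: float = 30.0) -> EEGRecording:
    """Zero-phase Butterworth band-pass followed by an IIR mains notch.

    Both filters run forward-backward per channel, so the output has no
    phase distortion and the same length as the input.
    """
    nyq = rec.fs / 2.0
    lo, hi = band
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band edges {band} must satisfy 0 < lo < hi < Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None:
        if not 0 < notch < nyq:
            raise ValueError(f"notch frequency {notch} Hz must lie below Nyquist")
        b, a = signal.iirnotch(notch, notch_q, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return replace(rec, data=data)


def segment(rec: EEGRecording, window_s: float = WINDOW_S) -> list[Segment]:
    """Cut into floor(duration / window) contiguous non-overlapping segments.

    The trailing remainder is discarded; a recording shorter than one window
    yields an empty list (with a warning), not an error.
    """
    n_win = int(round(window_s * rec.fs))
    count = rec.n_samples // n_win
    if count == 0:
        logger.warning("recording %s shorter than one %.1f-s window; 0 segments",
                       rec.subject_id or "<unnamed>", window_s)
    return [
        Segment(data=rec.data[:, i * n_win:(i + 1) * n_win], fs=rec.fs, index=i,
                channel_labels=rec.channel_labels, subject_id=rec.subject_id,
                class_label=rec.class_label)
        for i in range(count)
    ]


def reject_segments(segments: list[Segment], amplitude_limit: float = 100.0) -> list[Segment]:
    """Drop segments whose max absolute amplitude (µV) exceeds the limit.

    A coarse stand-in for manual artifact screening; order is preserved and
    ``amplitude_limit=inf`` is the identity.
    """
    if not amplitude_limit > 0:
        raise ValueError("amplitude_limit must be positive")
    if math.isinf(amplitude_limit):
        return list(segments)
    kept = [s for s in segments if np.abs(s.data).max() <= amplitude_limit]
    dropped = len(segments) - len(kept)
    if dropped:
        logger.info("rejected %d/%d segments above %.1f uV", dropped, len(segments),
                    amplitude_limit)
    return kept


def preprocess_recording(rec: EEGRecording, band=(0.1, 70.0), notch=50.0,
                         window_s: float = WINDOW_S,
                         amplitude_limit: float | None = None) -> list[Segment]:
    """standardize → filter → segment → (optional) amplitude rejection."""
    rec = standardize(rec)
    rec = filter_signal(rec, band=band, notch=notch)
    segs = segment(rec, window_s=window_s)
    if amplitude_limit is not None:
        segs = reject_segments(segs, amplitude_limit)
    return segs
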