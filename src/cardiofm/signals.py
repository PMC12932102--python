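"""Signal records, preprocessing and patch segmentation.

A :class:`SignalRecord` is a C×T multichannel waveform with named channels
from the canonical 13-channel set.  Records are band-pass filtered and
z-scored per channel, then cut into non-overlapping fixed-duration patches
(default w = 0.1 s) which become the transformer's signal tokens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .channels import CANONICAL_CHANNELS, channel_id

DEFAULT_SAMPLING_RATE = 100.0  # Hz; a 0.1-s patch is then 10 samples
DEFAULT_PATCH_SECONDS = 0.1

# 4th-order Butterworth band edges (Hz) per modality, applied before z-scoring
ECG_BAND = (0.5, 40.0)
PPG_BAND = (0.4, 10.0)


@dataclass
class SignalRecord:
    """Multichannel waveform with canonical channel names and a sampling rate."""

    values: np.ndarray            # (C, T) float
    channel_names: list[str]      # canonical spellings, unique
    sampling_rate: float          # Hz

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a (channels, samples) matrix")
        if len(self.channel_names) != self.values.shape[0]:
            raise ValueError("channel_names length must match number of rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        for name in self.channel_names:
            channel_id(name)  # raises on non-canonical names

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_ids(self) -> np.ndarray:
        return np.array([channel_id(c) for c in self.channel_names])

    def select_channels(self, names: list[str]) -> "SignalRecord":
        """Return a copy restricted to `names` (all must be present)."""
        rows = []
        for n in names:
            if n not in self.channel_names:
                raise ValueError(f"record has no channel {n!r}")
            rows.append(self.channel_names.index(n))
        return SignalRecord(self.values[rows], list(names), self.sampling_rate)

    def reorder_canonical(self) -> "SignalRecord":
        """Return a copy with channels sorted into canonical order."""
        order = np.argsort(self.channel_ids)
        return SignalRecord(
            self.values[order],
            [self.channel_names[i] for i in order],
            self.sampling_rate,
        )


@dataclass
class PatchSet:
    """Non-overlapping patches tiling the first n_time * window_w seconds."""

    patches: np.ndarray           # (C, N_S, patch_len)
    channel_names: list[str]
    window_w: float               # seconds
    sampling_rate: float

    @property
    def n_time(self) -> int:
        return self.patches.shape[1]

    @property
    def patch_len(self) -> int:
        return self.patches.shape[2]

    @property
    def channel_ids(self) -> np.ndarray:
        return np.array([channel_id(c) for c in self.channel_names])


def _bandpass(x: np.ndarray, fs: float, low: float, high: float) -> np.ndarray:
    nyq = fs / 2.0
    high = min(high, 0.99 * nyq)
    sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, x)


def preprocess_signal(raw: SignalRecord, bandpass: bool = True,
                      tol: float = 1e-12) -> SignalRecord:
    """Filter and z-score each channel independently.

    ECG channels get a 0.5–40 Hz 4th-order Butterworth band-pass, PPG
    0.4–10 Hz, both zero-phase; each channel is then z-scored with its own
    record-level mean and standard deviation.  A constant channel cannot be
    z-scored and is mapped to all-zeros with a warning.

    Raises ``ValueError`` on non-finite input.
    """
    if not np.all(np.isfinite(raw.values)):
        bad = [raw.channel_names[i] for i in
               np.unique(np.nonzero(~np.isfinite(raw.values))[0])]
        raise ValueError(f"non-finite samples in channels {bad}")
    out = np.empty_like(raw.values, dtype=np.float64)
    for i, name in enumerate(raw.channel_names):
        x = raw.values[i].astype(np.float64)
        if bandpass and raw.n_samples > 30:
            low, high = PPG_BAND if name == "PPG" else ECG_BAND
            x = _bandpass(x, raw.sampling_rate, low, high)
        sd = x.std()
        if sd < tol:
            warnings.warn(f"channel {name} is constant; normalized to zeros",
                          stacklevel=2)
            out[i] = 0.0
        else:
            out[i] = (x - x.mean()) / sd
    return SignalRecord(out, list(raw.channel_names), raw.sampling_rate)


def resample_record(record: SignalRecord, target_rate: float) -> SignalRecord:
    """Polyphase resampling of every channel to `target_rate`."""
    if abs(record.sampling_rate - target_rate) < 1e-9:
        return record
    from fractions import Fraction
    frac = Fraction(target_rate / record.sampling_rate).limit_denominator(1000)
    vals = sps.resample_poly(record.values, frac.numerator, frac.denominator, axis=1)
    return SignalRecord(vals, list(record.channel_names), target_rate)


def segment_signal(record: SignalRecord,
                   w: float = DEFAULT_PATCH_SECONDS) -> PatchSet:
    """Cut each channel into N_S = floor(duration / w) non-overlapping patches.

    Patch k covers the half-open sample interval [k·w·fs, (k+1)·w·fs); any
    trailing remainder shorter than w is dropped.
    """
    patch_len_f = w * record.sampling_rate
    patch_len = int(round(patch_len_f))
    if patch_len <= 0 or abs(patch_len_f - patch_len) > 1e-9:
        raise ValueError(
            f"w={w}s at fs={record.sampling_rate}Hz is not an integer number of samples")
    n_time = record.n_samples // patch_len
    if n_time == 0:
        raise ValueError("empty patch set: record shorter than one patch window")
    trimmed = record.values[:, : n_time * patch_len]
    patches = trimmed.reshape(record.n_channels, n_time, patch_len)
    return PatchSet(patches, list(record.channel_names), w, record.sampling_rate)


def unpatchify(patches: PatchSet) -> np.ndarray:
    """Inverse of :func:`segment_signal` — reconstructs the cropped (C, N_S·w·fs)
    signal bit-exactly."""
    C, n, p = patches.patches.shape
    return patches.patches.reshape(C, n * p)


__all__ = [
    "SignalRecord", "PatchSet", "preprocess_signal", "segment_signal",
    "unpatchify", "resample_record", "DEFAULT_SAMPLING_RATE",
    "DEFAULT_PATCH_SECONDS", "CANONICAL_CHANNELS",
]
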