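"""Signal conditioning for referential intracranial recordings.

The recording chain assumed here: referential ICEEG sampled at a high rate
(3052 Hz clinical-research amplifiers), anti-alias low-pass filtered below
255 Hz, resampled to 512 Hz, mains notch filtered at 60 Hz and harmonics,
and stripped of channels with poor signal. The pipeline order is fixed —
resample, then notch (designed at the final rate), then bad-channel
exclusion — and all filters are zero-phase so seizure-onset latencies are
not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "PreprocessError",
    "antialias_resample",
    "notch_filter",
    "exclude_bad_channels",
    "preprocess_pipeline",
    "save_recording",
    "load_recording",
]

ANTIALIAS_CUTOFF_HZ = 255.0
NOTCH_Q = 30.0


class PreprocessError(ValueError):
    """Raised for invalid preprocessing inputs."""


@dataclass(frozen=True)
class Recording:
    """Multichannel referential recording.

    ``data`` is channels x samples in microvolts. ``onset_sample`` marks
    electrographic seizure onset; ``baseline_window`` is a pre-onset
    (start, end) sample range used for per-channel normalisation.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    onset_sample: int
    baseline_window: tuple[int, int]
    reference_label: str = "subgaleal"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise PreprocessError("data must be channels x samples")
        if len(self.channel_labels) != data.shape[0]:
            raise PreprocessError("one label per channel required")
        if self.fs_hz <= 0:
            raise PreprocessError("fs_hz must be positive")
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1 <= self.onset_sample):
            raise PreprocessError("baseline_window must lie entirely pre-onset")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise PreprocessError(f"no channel labelled {label!r}") from None


def antialias_resample(
    rec: Recording,
    target_fs: float = 512.0,
    cutoff_hz: float = ANTIALIAS_CUTOFF_HZ,
) -> Recording:
    """Zero-phase low-pass below ``cutoff_hz`` then polyphase resampling.

    Onset and baseline indices are re-scaled by ``target_fs / fs``.
    """
    if target_fs >= rec.fs_hz:
        raise PreprocessError("target_fs must be below the current rate")
    nyq = rec.fs_hz / 2
    # steep zero-phase FIR: passband to cutoff, >=40 dB stopband
    numtaps = int(8 * rec.fs_hz / cutoff_hz) | 1
    taps = signal.firwin(numtaps, cutoff_hz, fs=rec.fs_hz, window=("kaiser", 9.0))
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=1)
    frac = Fraction(target_fs / rec.fs_hz).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    # kaiser beta 14 keeps passband ripple ~1e-6 so DC passes unchanged
    data = signal.resample_poly(filtered, up, down, axis=1, window=("kaiser", 14.0))
    scale = target_fs / rec.fs_hz
    b0, b1 = rec.baseline_window
    onset = int(round(rec.onset_sample * scale))
    baseline = (int(round(b0 * scale)), int(round(b1 * scale)))
    return replace(
        rec, data=data, fs_hz=target_fs, onset_sample=onset, baseline_window=baseline
    )


def notch_filter(rec: Recording, base_hz: float = 60.0, q: float = NOTCH_Q) -> Recording:
    """Zero-phase IIR notches at ``base_hz`` and every harmonic below Nyquist."""
    nyq = rec.fs_hz / 2
    if base_hz >= nyq:
        raise PreprocessError("notch frequency must be below Nyquist")
    data = rec.data
    freq = base_hz
    while freq < nyq:
        b, a = signal.iirnotch(freq, q, fs=rec.fs_hz)
        data = signal.filtfilt(b, a, data, axis=1)
        freq += base_hz
    return replace(rec, data=data)


def exclude_bad_channels(
    rec: Recording,
    flat_sd_uv: float = 1e-6,
    outlier_factor: float = 10.0,
) -> tuple[Recording, list[str]]:
    """Drop flat channels and gross amplitude outliers.

    A channel is flat if its whole-record SD is below ``flat_sd_uv`` and an
    outlier if its baseline SD exceeds ``outlier_factor`` times the median
    baseline SD across channels. Returns the cleaned recording and the
    excluded labels.
    """
    if rec.n_channels < 2:
        raise PreprocessError("need >= 2 channels for exclusion statistics")
    b0, b1 = rec.baseline_window
    whole_sd = rec.data.std(axis=1)
    base_sd = rec.data[:, b0:b1].std(axis=1)
    med = np.median(base_sd)
    flat = whole_sd < flat_sd_uv
    outlier = base_sd > outlier_factor * med if med > 0 else np.zeros_like(flat)
    bad = flat | outlier
    if bad.all():
        raise PreprocessError("all channels excluded; check the recording")
    keep = ~bad
    excluded = [lab for lab, b in zip(rec.channel_labels, bad) if b]
    cleaned = replace(
        rec,
        data=rec.data[keep],
        channel_labels=tuple(np.array(rec.channel_labels)[keep]),
    )
    return cleaned, excluded


def preprocess_pipeline(
    rec: Recording,
    target_fs: float = 512.0,
    notch_base_hz: float = 60.0,
) -> tuple[Recording, list[str]]:
    """resample -> notch -> bad-channel exclusion, in that fixed order."""
    rec = antialias_resample(rec, target_fs)
    rec = notch_filter(rec, notch_base_hz)
    return exclude_bad_channels(rec)


# ---------------------------------------------------------------------------
# HDF5 container

def save_recording(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.attrs["fs_hz"] = rec.fs_hz
        f.attrs["onset_sample"] = rec.onset_sample
        f.attrs["baseline_window"] = rec.baseline_window
        f.attrs["reference_label"] = rec.reference_label
        f.create_dataset(
            "channel_labels",
            data=np.array(rec.channel_labels, dtype=h5py.string_dtype()),
        )


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            data=f["data"][...],
            fs_hz=float(f.attrs["fs_hz"]),
            channel_labels=tuple(s.decode() if isinstance(s, bytes) else str(s)
                                 for s in f["channel_labels"][...]),
            onset_sample=int(f.attrs["onset_sample"]),
            baseline_window=tuple(int(v) for v in f.attrs["baseline_window"]),
            reference_label=str(f.attrs["reference_label"]),
        )
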