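"""Shared data model, filtering, windowing, energy and file I/O.

All downstream modules operate on :class:`EEGRecording` (channels x samples,
microvolts) and :class:`EEGWindow` (one 30-channel x 100-sample decoding
unit, i.e. 100 ms at the native 1000 Hz rate).  The 30-channel montage order
is canonical and every matrix in the package follows it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

#: Canonical 30-channel montage order used throughout the package.
MONTAGE_30: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5",
    "FC6", "Cz", "C3", "C4", "T3", "T4", "CP1", "CP2", "CP5", "CP6",
    "Pz", "P3", "P4", "T5", "T6", "PO3", "PO4", "Oz", "O1", "O2",
)

#: Reference channels closest to the facial muscles; carry most EMG energy.
REFERENCE_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F8", "T3", "T4")

#: Decoding band (Hz): the typical EEG band the classifiers operate on.
DECODING_BAND: tuple[float, float] = (5.0, 50.0)
#: Screening band (Hz): high-frequency band where EMG artifact dominates.
SCREENING_BAND: tuple[float, float] = (55.0, 95.0)

#: Decoding unit length in samples (100 ms at 1000 Hz).
WINDOW_SAMPLES: int = 100

#: The eight slight facial expression classes, in canonical one-hot order.
#: s-RB (slight raise-brow) is the designated state-switching class.
SFE_CLASSES: tuple[str, ...] = (
    "s-RB", "s-FB", "s-LS", "s-RS", "s-OM", "s-S", "s-PM", "s-DM",
)

#: Hold-on class: decoded NON issues no device command.
NON_LABEL: str = "NON"

#: Full 9-way target space (8 sFEs + NON) in one-hot order.
ALL_LABELS: tuple[str, ...] = SFE_CLASSES + (NON_LABEL,)


class MontageMismatchError(ValueError):
    """Raised when a file or array does not carry the expected montage."""


class InvalidBandError(ValueError):
    """Raised when a band specification is not realizable at a given rate."""


@dataclass(frozen=True)
class BandSpec:
    """Pass-band in Hz; must sit strictly inside (0, Nyquist)."""

    low: float
    high: float

    def validate(self, rate: float) -> None:
        if not (0.0 < self.low < self.high):
            raise InvalidBandError(f"band edges must satisfy 0 < low < high, got {self}")
        if self.high >= rate / 2.0:
            raise InvalidBandError(
                f"band edge {self.high} Hz is at/above Nyquist for rate {rate} Hz"
            )


@dataclass(frozen=True)
class StateInterval:
    """Annotated state segment ``[start, end)`` in seconds.

    Labels follow the session vocabulary: ``rest``, ``sfe:<class>``,
    ``relax`` and ``regularFE:<class>``.
    """

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start must precede end, got {self}")


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    channels: list[str]
    annotations: list[StateInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel names"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise MontageMismatchError(f"channel {name!r} not in recording") from None


@dataclass(frozen=True)
class EEGWindow:
    """One decoding unit: channels x 100 samples with band provenance."""

    data: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 2:
            raise ValueError("window data must be 2-D channels x samples")
        if not np.all(np.isfinite(arr)):
            raise ValueError("window contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Filtering / resampling
# ---------------------------------------------------------------------------

def _butter_sos(band: BandSpec, rate: float, order: int = 4) -> np.ndarray:
    return sps.butter(order, [band.low, band.high], btype="bandpass",
                      fs=rate, output="sos")


def bandpass(rec: EEGRecording, band: BandSpec | tuple[float, float],
             order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass; shape and rate preserved.

    A 4th-order design applied forward-backward keeps the 100 ms window
    alignment (no group delay), which the streaming decoder relies on.
    """
    if not isinstance(band, BandSpec):
        band = BandSpec(*band)
    band.validate(rec.rate)
    sos = _butter_sos(band, rec.rate, order)
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=out)


def bandpass_array(data: np.ndarray, band: tuple[float, float], rate: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase band-pass on a raw channels x samples array."""
    spec = BandSpec(*band)
    spec.validate(rate)
    return sps.sosfiltfilt(_butter_sos(spec, rate, order), data, axis=-1)


def downsample(rec: EEGRecording, target_rate: float) -> EEGRecording:
    """Anti-aliased decimation to ``target_rate`` (< current rate).

    A zero-phase low-pass at 0.45 x target rate precedes index selection so
    no energy folds back into the bands the connectivity analysis reads.
    """
    if target_rate >= rec.rate:
        raise ValueError(
            f"target rate {target_rate} must be below current rate {rec.rate}"
        )
    cutoff = 0.45 * target_rate
    sos = sps.butter(8, cutoff, btype="lowpass", fs=rec.rate, output="sos")
    smooth = sps.sosfiltfilt(sos, rec.data, axis=1)
    n_out = int(np.floor(rec.n_samples * target_rate / rec.rate))
    idx = np.round(np.arange(n_out) * rec.rate / target_rate).astype(int)
    idx = np.clip(idx, 0, rec.n_samples - 1)
    return EEGRecording(smooth[:, idx], target_rate, list(rec.channels),
                        list(rec.annotations))


# ---------------------------------------------------------------------------
# Windowing / energy
# ---------------------------------------------------------------------------

def slice_windows(rec: EEGRecording, length: int = WINDOW_SAMPLES,
                  stride: int = WINDOW_SAMPLES,
                  band: tuple[float, float] | None = None) -> list[EEGWindow]:
    """Slice ``rec`` into windows of ``length`` samples every ``stride``.

    Windows are 0-based half-open ``[start, start+length)``; a recording
    shorter than ``length`` yields an empty list.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if length < 1:
        raise ValueError("length must be >= 1")
    n = rec.n_samples
    if n < length:
        return []
    starts = range(0, n - length + 1, stride)
    return [EEGWindow(rec.data[:, s:s + length], band=band) for s in starts]


def window_starts(n_samples: int, length: int, stride: int) -> np.ndarray:
    """Start indices produced by :func:`slice_windows` for a given length."""
    if n_samples < length:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - length + 1, stride)


def temporal_energy(samples: Sequence[float] | np.ndarray) -> float:
    """Sum of squared samples (uV^2) of one channel segment."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("temporal_energy requires a non-empty sequence")
    return float(np.sum(x * x))


def window_energies(window: EEGWindow | np.ndarray) -> np.ndarray:
    """Per-channel temporal energy of a window."""
    data = window.data if isinstance(window, EEGWindow) else np.asarray(window)
    return np.sum(data * data, axis=-1)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_csv(rec: EEGRecording, path: str | Path) -> None:
    """CSV fixture dialect: one header row of channel names, one row per
    sample, '.' decimal, UTF-8."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(rec.channels)
        for row in rec.data.T:
            writer.writerow([format(v, ".10g") for v in row])


def read_csv(path: str | Path, rate: float = 1000.0,
             expect_montage: Sequence[str] | None = None) -> EEGRecording:
    """Read the CSV fixture dialect back into a recording."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        channels = next(reader)
        rows = [[float(v) for v in row] for row in reader if row]
    data = np.asarray(rows, dtype=float).T
    rec = EEGRecording(data, rate, list(channels))
    if expect_montage is not None:
        rec = normalize_montage(rec, expect_montage)
    return rec


def write_annotations_csv(annotations: Sequence[StateInterval],
                          path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "label"])
        for iv in annotations:
            writer.writerow([format(iv.start, ".6f"), format(iv.end, ".6f"),
                             iv.label])


def read_annotations_csv(path: str | Path) -> list[StateInterval]:
    out: list[StateInterval] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            if row:
                out.append(StateInterval(float(row[0]), float(row[1]), row[2]))
    return out


def normalize_montage(rec: EEGRecording,
                      montage: Sequence[str] = MONTAGE_30) -> EEGRecording:
    """Reorder channels to the canonical montage; missing names are an error."""
    try:
        idx = [rec.channels.index(name) for name in montage]
    except ValueError as exc:
        missing = [n for n in montage if n not in rec.channels]
        raise MontageMismatchError(
            f"recording lacks montage channels {missing}"
        ) from exc
    return EEGRecording(rec.data[idx], rec.rate, list(montage),
                        list(rec.annotations))


def read_edf(path: str | Path,
             expect_montage: Sequence[str] | None = MONTAGE_30) -> EEGRecording:
    """Read an EDF file; channel order normalized to the canonical montage.

    Values are returned in microvolts regardless of the EDF physical unit
    (mne yields volts for EEG channel types).
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    rec = EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    if expect_montage is not None:
        if len(rec.channels) != len(expect_montage):
            raise MontageMismatchError(
                f"expected {len(expect_montage)} channels, file has "
                f"{len(rec.channels)}"
            )
        rec = normalize_montage(rec, expect_montage)
    return rec
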