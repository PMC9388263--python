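"""EEG data model, file I/O, band-pass filtering and fixed-length segmentation.

The pipeline works on resting-state scalp EEG in the 10-20 montage.  A
recording is a channels x samples array of amplitudes in microvolts together
with its sampling rate, channel labels, a subject identifier and a diagnostic
class label (MCI / healthy control / unknown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CANONICAL_CHANNELS",
    "Label",
    "EEGRecording",
    "BandDef",
    "DEFAULT_BANDS",
    "ShortRecordingWarning",
    "read_eeg",
    "write_csv",
    "bandpass_filter",
    "segment",
]

#: The 19 channels of the 10-20 system in canonical order.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


class Label:
    """Diagnostic class labels."""

    MCI = "MCI"
    HC = "HC"
    UNKNOWN = "UNKNOWN"


class ShortRecordingWarning(UserWarning):
    """Raised when a recording is too short to yield a single segment."""


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``, amplitudes in microvolts.
    fs:
        Sampling rate in Hz.
    channels:
        Ordered channel labels, one per row of ``data``.
    subject_id:
        Opaque participant identifier.
    label:
        ``"MCI"``, ``"HC"`` or ``"UNKNOWN"``.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...] = CANONICAL_CHANNELS
    subject_id: str = ""
    label: str = Label.UNKNOWN

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must all be finite")
        self.channels = tuple(self.channels)
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.label not in (Label.MCI, Label.HC, Label.UNKNOWN):
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the sample vector of a single channel by label."""
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def reordered(self, order: tuple[str, ...] = CANONICAL_CHANNELS) -> "EEGRecording":
        """Return a copy with rows rearranged into ``order``."""
        idx = [self.channels.index(ch) for ch in order]
        return replace(self, data=self.data[idx], channels=tuple(order))


@dataclass(frozen=True)
class BandDef:
    """A frequency subband ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"invalid band edges [{self.lo}, {self.hi})")


#: Conventional EEG subbands; delta's low edge matches the filter low cutoff.
DEFAULT_BANDS: tuple[BandDef, ...] = (
    BandDef("delta", 0.5, 4.0),
    BandDef("theta", 4.0, 8.0),
    BandDef("alpha", 8.0, 13.0),
    BandDef("beta", 13.0, 32.0),
)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_eeg(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    subject_id: str | None = None,
    label: str = Label.UNKNOWN,
) -> EEGRecording:
    """Read a recording from an EDF file or a CSV sample matrix.

    CSV files carry one column per channel with a header row of labels; the
    sampling rate is not stored in the file and must be supplied via ``fs``.
    EDF files carry their own rate.  When all 19 canonical 10-20 labels are
    present the channels are reordered into canonical order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        channels = tuple(raw.ch_names)
        fs = float(raw.info["sfreq"])
    elif format == "csv":
        if fs is None:
            raise ValueError("fs is required when reading a CSV matrix")
        frame = pd.read_csv(path)
        try:
            data = frame.to_numpy(dtype=float).T
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
        channels = tuple(str(c) for c in frame.columns)
    else:
        raise ValueError(f"unknown format {format!r}")

    rec = EEGRecording(
        data=data,
        fs=fs,
        channels=channels,
        subject_id=subject_id if subject_id is not None else path.stem,
        label=label,
    )
    if set(CANONICAL_CHANNELS) <= set(rec.channels):
        extra = tuple(c for c in rec.channels if c not in CANONICAL_CHANNELS)
        rec = rec.reordered(CANONICAL_CHANNELS + extra)
    return rec


def write_csv(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a CSV sample matrix (columns = channels)."""
    path = Path(path)
    pd.DataFrame(rec.data.T, columns=list(rec.channels)).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def bandpass_filter(
    rec: EEGRecording, lo: float = 0.5, hi: float = 32.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass applied to every channel.

    The defaults retain 0.5-32 Hz, the range holding the conventional
    delta through beta rhythms, and suppress EMG and line interference.
    Forward-backward application (``sosfiltfilt``) cancels group delay so
    waveform morphology is preserved.
    """
    nyq = rec.fs / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz must lie below Nyquist {nyq} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default edge padding
    if rec.n_samples <= padlen:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than the "
            f"filter warm-up length ({padlen} samples)"
        )
    return replace(rec, data=sps.sosfiltfilt(sos, rec.data, axis=1))


def segment(rec: EEGRecording, window_s: float = 60.0) -> list[EEGRecording]:
    """Slice a recording into contiguous non-overlapping fixed windows.

    Each segment has exactly ``round(window_s * fs)`` samples and inherits
    the parent's subject id and class label; a trailing partial window is
    discarded.  A recording shorter than one window yields an empty list and
    a :class:`ShortRecordingWarning`.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    win = int(round(window_s * rec.fs))
    n_full = rec.n_samples // win
    if n_full == 0:
        warnings.warn(
            f"recording {rec.subject_id!r} ({rec.n_samples} samples) is "
            f"shorter than one {window_s} s window; no segments produced",
            ShortRecordingWarning,
            stacklevel=2,
        )
        return []
    return [
        replace(rec, data=rec.data[:, k * win : (k + 1) * win])
        for k in range(n_full)
    ]
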