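"""Welch band powers and interhemispheric asymmetry.

The spectral feature set summarises each segment by the absolute power of
the delta, theta, alpha and beta subbands on every channel (4 x 19 = 76
features) plus the log-ratio band-power asymmetry of the eight homologous
right-left electrode pairs in each band (4 x 8 = 32), 108 features in all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import CANONICAL_CHANNELS, DEFAULT_BANDS, BandDef, EEGRecording

__all__ = [
    "PSDEstimate",
    "ASYMMETRY_PAIRS",
    "welch_psd",
    "band_power",
    "interhemispheric_asymmetry",
    "spectral_feature_vector",
    "spectral_feature_names",
]

#: Homologous right-left electrode pairs used for the asymmetry features.
ASYMMETRY_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp2", "Fp1"),
    ("F4", "F3"),
    ("F8", "F7"),
    ("C4", "C3"),
    ("T4", "T3"),
    ("P4", "P3"),
    ("T6", "T5"),
    ("O2", "O1"),
)


@dataclass(frozen=True)
class PSDEstimate:
    """One-sided power spectral density on a common frequency grid.

    ``psd`` has one row per channel in microvolts squared per Hz, so the
    integral of a row over frequency approximates that channel's variance.
    """

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if f.ndim != 1 or np.any(np.diff(f) <= 0) or f[0] != 0:
            raise ValueError("freqs must be strictly increasing from 0")
        if p.shape[1] != f.size:
            raise ValueError("psd rows must match the frequency grid")
        if np.any(p < 0):
            raise ValueError("psd must be nonnegative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "psd", p)


def welch_psd(
    x: np.ndarray,
    fs: float,
    win_len: int = 512,
    overlap_frac: float = 0.5,
) -> PSDEstimate:
    """Welch periodogram of one or more channels (Hamming taper).

    The default 512-sample window (2 s at 256 Hz) holds at least two cycles
    of the lowest theta frequency; 50% overlap is the conventional choice.
    Density normalization: the PSD integrates to the signal variance.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if win_len > x.shape[-1]:
        raise ValueError(
            f"win_len={win_len} exceeds signal length {x.shape[-1]}"
        )
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=win_len,
        noverlap=int(win_len * overlap_frac),
        detrend=False,
        scaling="density",
        axis=-1,
    )
    return PSDEstimate(freqs=freqs, psd=psd)


def band_power(psd: PSDEstimate, band: BandDef, channel: int = 0) -> float:
    """Integrated PSD over ``[band.lo, band.hi)`` for one channel (µV²).

    Trapezoidal integration over the grid points falling in the half-open
    interval; half-open bands prevent shared edges from being counted twice.
    """
    f = psd.freqs
    if band.lo < f[0] or band.hi > f[-1] + (f[1] - f[0]):
        raise ValueError(
            f"band [{band.lo}, {band.hi}) outside frequency grid "
            f"[{f[0]}, {f[-1]}]"
        )
    mask = (f >= band.lo) & (f < band.hi)
    if mask.sum() < 2:
        raise ValueError(f"band [{band.lo}, {band.hi}) spans <2 grid points")
    return float(np.trapezoid(psd.psd[channel, mask], f[mask]))


def interhemispheric_asymmetry(p_right: float, p_left: float) -> float:
    """Log band-power ratio ``ln(P_right) - ln(P_left)`` (dimensionless).

    Positive values mean more power over the right hemisphere; the measure
    is antisymmetric under swapping hemispheres and invariant to a common
    amplitude rescaling of both channels.
    """
    if p_right <= 0 or p_left <= 0:
        raise ValueError("band powers must be positive for the log-ratio")
    return float(np.log(p_right) - np.log(p_left))


def spectral_feature_names(
    bands: tuple[BandDef, ...] = DEFAULT_BANDS,
) -> list[str]:
    """Deterministic names/order of the spectral features."""
    names = [
        f"bp_{band.name}_{ch}" for band in bands for ch in CANONICAL_CHANNELS
    ]
    names += [
        f"ia_{band.name}_{right}-{left}"
        for band in bands
        for right, left in ASYMMETRY_PAIRS
    ]
    return names


def spectral_feature_vector(
    seg: EEGRecording,
    bands: tuple[BandDef, ...] = DEFAULT_BANDS,
    win_len: int = 512,
    overlap_frac: float = 0.5,
) -> dict[str, float]:
    """The 108-element spectral feature vector of one segment.

    Returns an ordered mapping ``bp_<band>_<channel>`` then
    ``ia_<band>_<right>-<left>`` (4 bands x 19 channels + 4 bands x 8 pairs).
    """
    missing = set(CANONICAL_CHANNELS) - set(seg.channels)
    if missing:
        raise ValueError(f"segment lacks canonical channels: {sorted(missing)}")
    if seg.channels[: len(CANONICAL_CHANNELS)] != CANONICAL_CHANNELS:
        seg = seg.reordered()

    win_len = min(win_len, seg.n_samples)
    psd = welch_psd(seg.data, seg.fs, win_len=win_len, overlap_frac=overlap_frac)
    ch_index = {ch: k for k, ch in enumerate(seg.channels)}

    powers: dict[tuple[str, str], float] = {}
    feats: dict[str, float] = {}
    for band in bands:
        for ch in CANONICAL_CHANNELS:
            p = band_power(psd, band, ch_index[ch])
            powers[band.name, ch] = p
            feats[f"bp_{band.name}_{ch}"] = p
    for band in bands:
        for right, left in ASYMMETRY_PAIRS:
            feats[f"ia_{band.name}_{right}-{left}"] = interhemispheric_asymmetry(
                powers[band.name, right], powers[band.name, left]
            )
    return feats
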