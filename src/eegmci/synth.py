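"""Seeded synthetic EEG cohorts and known-answer test signals.

The cohort generator emulates 19-channel resting EEG: each channel is a sum
of band-limited oscillations (delta/theta/alpha/beta) with group-specific
amplitudes, 1/f background noise, and - for designated channel pairs - a
shared lagged latent source whose mixing coefficient controls functional
connectivity.  Group differences in band amplitude and coupling are the
ground truth the extraction/classification stages are tested against.

Defaults mimic the usual MCI-versus-control contrast: reduced alpha and
beta power, slightly elevated theta, and weakened fronto-central coupling
in the patient group, on a cohort of 18 MCI and 16 control subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CANONICAL_CHANNELS, EEGRecording, Label, write_csv

__all__ = [
    "BAND_CENTER_HZ",
    "DEFAULT_BAND_AMP",
    "CohortSpec",
    "KnownSignalSpec",
    "gen_cohort",
    "gen_known_signal",
    "write_fixtures",
]

#: Oscillation carrier frequencies placed firmly inside each subband.
BAND_CENTER_HZ: dict[str, float] = {
    "delta": 2.0,
    "theta": 6.0,
    "alpha": 10.0,
    "beta": 20.0,
}

#: Per-group oscillation amplitudes (µV): MCI shows lower alpha/beta,
#: mildly higher theta.
DEFAULT_BAND_AMP: dict[str, dict[str, float]] = {
    Label.HC: {"delta": 10.0, "theta": 8.0, "alpha": 20.0, "beta": 6.0},
    Label.MCI: {"delta": 10.0, "theta": 11.0, "alpha": 12.0, "beta": 4.0},
}

#: Channel pairs receiving the shared lagged source.
DEFAULT_COUPLED_PAIRS: tuple[tuple[str, str], ...] = (("F3", "C3"), ("Fp1", "F3"))


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters of a synthetic two-group EEG cohort."""

    n_mci: int = 18
    n_hc: int = 16
    duration_s: float = 120.0
    fs: float = 256.0
    band_amp: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(a) for g, a in DEFAULT_BAND_AMP.items()}
    )
    coupling: dict[str, float] = field(
        default_factory=lambda: {Label.HC: 0.6, Label.MCI: 0.2}
    )
    coupling_lag: int = 10
    coupled_pairs: tuple[tuple[str, str], ...] = DEFAULT_COUPLED_PAIRS
    noise_exp: float = 1.0
    noise_amp: float = 10.0
    freq_jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mci < 1 or self.n_hc < 1:
            raise ValueError("group sizes must be >= 1")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        for group, c in self.coupling.items():
            if not 0 <= c <= 1:
                raise ValueError(f"coupling for {group} must lie in [0, 1]")


@dataclass(frozen=True)
class KnownSignalSpec:
    """A signal with a known-answer nonlinear/spectral signature."""

    kind: str
    length: int
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be >= 2")
        kinds = (
            "white", "brownian", "pink", "sine",
            "logistic_map", "henon_map", "impulse", "constant",
        )
        if self.kind not in kinds:
            raise ValueError(f"unknown kind {self.kind!r}")


def _one_over_f_noise(
    rng: np.random.Generator, n: int, exponent: float, rms: float
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with a 1/f^exponent amplitude profile."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    shaped = np.fft.irfft(spectrum * shape, n=n)
    scale = shaped.std()
    return shaped * (rms / scale) if scale > 0 else shaped


def _one_channel(
    rng: np.random.Generator, spec: CohortSpec, amps: dict[str, float]
) -> np.ndarray:
    """One channel of oscillations-plus-1/f-noise EEG-like signal."""
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    sig = _one_over_f_noise(rng, n, spec.noise_exp, spec.noise_amp)
    for band, f0 in BAND_CENTER_HZ.items():
        amp = amps.get(band, 0.0)
        if amp == 0:
            continue
        f_jit = f0 * (1 + spec.freq_jitter * (2 * rng.random() - 1))
        phase = 2 * np.pi * rng.random()
        sig = sig + amp * np.sin(2 * np.pi * f_jit * t + phase)
    return sig


def _subject_signal(
    rng: np.random.Generator, spec: CohortSpec, amps: dict[str, float]
) -> np.ndarray:
    """One subject's uncoupled 19-channel signal (oscillations + 1/f noise)."""
    return np.stack(
        [_one_channel(rng, spec, amps) for _ in CANONICAL_CHANNELS]
    )


def gen_cohort(spec: CohortSpec = CohortSpec()) -> list[EEGRecording]:
    """Generate the labelled synthetic cohort; bit-reproducible from seed.

    Coupled channel pairs (A, B) are mixed with a shared latent source z:
    A gets ``(1-c)*own + c*z(t)``, B gets ``(1-c)*own + c*z(t-lag)``, so at
    c=1 the pair is an exactly lagged copy and at c=0 fully independent.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    ch_index = {ch: k for k, ch in enumerate(CANONICAL_CHANNELS)}
    recordings: list[EEGRecording] = []
    groups = [(Label.MCI, spec.n_mci), (Label.HC, spec.n_hc)]
    for label, count in groups:
        amps = spec.band_amp[label]
        c = spec.coupling[label]
        for s in range(count):
            data = _subject_signal(rng, spec, amps)
            for ch_a, ch_b in spec.coupled_pairs:
                latent = _one_channel(rng, spec, amps)
                a, b = ch_index[ch_a], ch_index[ch_b]
                lagged = np.roll(latent, spec.coupling_lag)
                data[a] = (1 - c) * data[a] + c * latent
                data[b] = (1 - c) * data[b] + c * lagged
            recordings.append(
                EEGRecording(
                    data=data,
                    fs=spec.fs,
                    channels=CANONICAL_CHANNELS,
                    subject_id=f"{label.lower()}_{s:02d}",
                    label=label,
                )
            )
    return recordings


def gen_known_signal(spec: KnownSignalSpec) -> np.ndarray:
    """Deterministic single-channel signal with a known analytic signature.

    Kinds: ``white`` (sigma), ``brownian`` (integrated white), ``pink``
    (exponent), ``sine`` (freq, fs, amp), ``logistic_map`` (r, x0),
    ``henon_map`` (a, b, x0, y0, discard), ``impulse``, ``constant`` (value).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    p = spec.params
    if spec.kind == "white":
        return p.get("sigma", 1.0) * rng.standard_normal(n)
    if spec.kind == "brownian":
        return np.cumsum(p.get("sigma", 1.0) * rng.standard_normal(n))
    if spec.kind == "pink":
        return _one_over_f_noise(rng, n, p.get("exponent", 1.0), p.get("rms", 1.0))
    if spec.kind == "sine":
        fs = p.get("fs", 256.0)
        t = np.arange(n) / fs
        return p.get("amp", 1.0) * np.sin(
            2 * np.pi * p.get("freq", 10.0) * t + p.get("phase", 0.0)
        )
    if spec.kind == "logistic_map":
        r, x = p.get("r", 4.0), p.get("x0", 0.3)
        if not 0 < x < 1:
            raise ValueError("logistic map needs x0 in (0, 1)")
        out = np.empty(n)
        for i in range(n):
            x = r * x * (1 - x)
            out[i] = x
        return out
    if spec.kind == "henon_map":
        a, b = p.get("a", 1.4), p.get("b", 0.3)
        x, y = p.get("x0", 0.1), p.get("y0", 0.1)
        discard = p.get("discard", 100)
        out = np.empty(n)
        for i in range(n + discard):
            x, y = 1 - a * x * x + y, b * x
            if not np.isfinite(x):
                raise ValueError("Hénon orbit diverged (initial condition "
                                 "outside the basin of attraction)")
            if i >= discard:
                out[i - discard] = x
        return out
    if spec.kind == "impulse":
        out = np.zeros(n)
        out[p.get("position", 0)] = p.get("amp", 1.0)
        return out
    # constant
    return np.full(n, p.get("value", 1.0))


def write_fixtures(
    recordings: list[EEGRecording], directory: str | Path
) -> list[Path]:
    """Write one CSV per recording plus a ``manifest.csv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    paths = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        paths.append(write_csv(rec, directory / fname))
        rows.append(
            {
                "file": fname,
                "subject_id": rec.subject_id,
                "label": rec.label,
                "fs": rec.fs,
                "duration_s": rec.duration,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return paths + [manifest]
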