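"""Synchronization likelihood (SL) functional connectivity.

SL measures generalized synchronization between two signals from
coincidences of state-space recurrences.  Each signal is time-delay
embedded; for every reference time ``i`` a per-channel critical distance
``eps_{k,i}`` is chosen so that a fixed small fraction ``p_ref`` of the
temporally valid neighbours (Theiler window ``w1`` < |i-j| < sharpening
window ``w2``) recur within it.  The likelihood that the other channel
recurs at the same moments, averaged over reference times and both
channels, is the SL value: it equals 1 for identical signals and has
expectation ``p_ref`` for independent ones.

The connectivity feature set is the SL of all C(19,2) = 171 unordered
channel pairs; the SL of a channel with itself is not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .core import CANONICAL_CHANNELS, EEGRecording

__all__ = [
    "SLParams",
    "SLMatrix",
    "embed",
    "critical_distance",
    "sync_likelihood_pair",
    "sl_matrix",
    "sl_feature_names",
]


@dataclass(frozen=True)
class SLParams:
    """Synchronization-likelihood parameters.

    Defaults follow common resting-EEG practice at 256 Hz: reference
    recurrence probability 0.01, lag 10 samples, embedding dimension 10,
    Theiler half-width 100 samples, sharpening half-width 410 samples.
    """

    p_ref: float = 0.01
    l: int = 10
    m: int = 10
    w1: int = 100
    w2: int = 410

    def __post_init__(self) -> None:
        if not 0 < self.p_ref < 1:
            raise ValueError("p_ref must lie in (0, 1)")
        if self.m < 1 or self.l < 1:
            raise ValueError("embedding dimension and lag must be >= 1")
        if not 0 < self.w1 < self.w2:
            raise ValueError("need 0 < w1 < w2")


@dataclass(frozen=True)
class SLMatrix:
    """Symmetric channel x channel SL matrix; the diagonal is NaN."""

    values: np.ndarray
    channels: tuple[str, ...]


def embed(x: np.ndarray, m: int, l: int) -> np.ndarray:
    """Time-delay embedding: row i = (x_i, x_{i+l}, ..., x_{i+(m-1)l}).

    Returns an ``(N - (m-1)*l, m)`` array of state vectors.
    """
    x = np.asarray(x, dtype=float)
    n_vec = x.size - (m - 1) * l
    if n_vec < 1:
        raise ValueError(
            f"signal of {x.size} samples too short for m={m}, l={l} embedding"
        )
    idx = np.arange(n_vec)[:, None] + l * np.arange(m)[None, :]
    return x[idx]


def _window_offsets(w1: int, w2: int) -> np.ndarray:
    """Relative indices j-i with w1 < |i-j| < w2."""
    right = np.arange(w1 + 1, w2)
    return np.concatenate([-right[::-1], right])


def critical_distance(
    vectors: np.ndarray, i: int, p_ref: float, w1: int, w2: int
) -> float:
    """Distance to the ceil(p_ref*W)-th nearest temporally valid neighbour.

    This is the smallest epsilon for which the fraction of neighbours j
    (w1 < |i-j| < w2) lying within epsilon of vector i reaches ``p_ref``.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    n = vectors.shape[0]
    j = i + _window_offsets(w1, w2)
    j = j[(j >= 0) & (j < n)]
    if j.size == 0:
        raise ValueError(f"no valid neighbours for index {i} (W=0)")
    d = np.linalg.norm(vectors[j] - vectors[i], axis=1)
    k = max(1, ceil(p_ref * j.size))
    return float(np.partition(d, k - 1)[k - 1])


def _recurrence_band(
    emb: np.ndarray,
    p_ref: float,
    w1: int,
    w2: int,
    stride: int = 1,
    block: int = 256,
) -> np.ndarray:
    """Boolean recurrence band for every stride-th reference index.

    Entry ``[i, o]`` says whether the neighbour at relative offset
    ``offsets[o]`` lies within the critical distance of reference vector
    ``i``; temporally invalid offsets are False.  Computed blockwise so
    memory stays proportional to ``n * 2*(w2 - w1 - 1)`` booleans.
    """
    n = emb.shape[0]
    if n <= w1 + 1:
        raise ValueError(
            f"embedded orbit of {n} points has no neighbours beyond the "
            f"Theiler window w1={w1}"
        )
    offsets = _window_offsets(w1, w2)
    ref = np.arange(0, n, stride)
    rec = np.empty((ref.size, offsets.size), dtype=bool)
    for s in range(0, ref.size, block):
        r = ref[s : s + block]
        j = r[:, None] + offsets[None, :]
        valid = (j >= 0) & (j < n)
        d2 = ((emb[np.clip(j, 0, n - 1)] - emb[r, None, :]) ** 2).sum(-1)
        d2[~valid] = np.inf
        w = valid.sum(1)
        k = np.maximum(1, np.ceil(p_ref * w).astype(int))
        d2s = np.sort(d2, axis=1)
        eps2 = d2s[np.arange(r.size), k - 1]
        rec[s : s + block] = d2 <= eps2[:, None]
    return rec


def _pair_sl(rec_a: np.ndarray, rec_b: np.ndarray) -> float:
    """SL from two channels' recurrence bands (joint over marginal counts)."""
    joint = (rec_a & rec_b).sum(1)
    na = rec_a.sum(1)
    nb = rec_b.sum(1)
    return float(0.5 * np.mean(joint / na + joint / nb))


def sync_likelihood_pair(
    x: np.ndarray,
    y: np.ndarray,
    params: SLParams = SLParams(),
    stride: int = 1,
) -> float:
    """Synchronization likelihood of two equal-length signals, in [0, 1].

    ``stride`` subsamples the reference times (the candidate-neighbour
    window stays dense); stride 1 is the reference computation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have identical length")
    ea = embed(x, params.m, params.l)
    eb = embed(y, params.m, params.l)
    ra = _recurrence_band(ea, params.p_ref, params.w1, params.w2, stride)
    rb = _recurrence_band(eb, params.p_ref, params.w1, params.w2, stride)
    return _pair_sl(ra, rb)


def sl_feature_names(channels: tuple[str, ...] = CANONICAL_CHANNELS) -> list[str]:
    """`sl_<A>-<B>` for all unordered pairs, A before B in canonical order."""
    return [
        f"sl_{channels[a]}-{channels[b]}"
        for a in range(len(channels))
        for b in range(a + 1, len(channels))
    ]


def sl_matrix(
    seg: EEGRecording,
    params: SLParams = SLParams(),
    stride: int = 1,
) -> tuple[SLMatrix, dict[str, float]]:
    """Pairwise SL over all channels: matrix plus named feature vector.

    Per-channel recurrence bands are computed once and reused across the
    C(n,2) pairs, which makes the full matrix only marginally more
    expensive than the per-channel critical-distance search.
    """
    missing = set(CANONICAL_CHANNELS) - set(seg.channels)
    if missing:
        raise ValueError(f"segment lacks canonical channels: {sorted(missing)}")
    if seg.channels[: len(CANONICAL_CHANNELS)] != CANONICAL_CHANNELS:
        seg = seg.reordered()
    chans = CANONICAL_CHANNELS
    bands = [
        _recurrence_band(
            embed(seg.channel(ch), params.m, params.l),
            params.p_ref,
            params.w1,
            params.w2,
            stride,
        )
        for ch in chans
    ]
    n = len(chans)
    values = np.full((n, n), np.nan)
    feats: dict[str, float] = {}
    for a in range(n):
        for b in range(a + 1, n):
            s = _pair_sl(bands[a], bands[b])
            values[a, b] = values[b, a] = s
            feats[f"sl_{chans[a]}-{chans[b]}"] = s
    return SLMatrix(values=values, channels=chans), feats
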