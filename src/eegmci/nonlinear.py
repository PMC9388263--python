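"""Nonlinear time-series descriptors, one value per EEG channel.

Eight complexity/chaoticity measures summarise each channel: the detrended
fluctuation scaling exponent, Higuchi fractal dimension, correlation
dimension (Grassberger-Procaccia), largest Lyapunov exponent (Rosenstein
divergence method), C0-complexity, correlation (K2) entropy as a practical
Kolmogorov-entropy estimate, Shannon amplitude-histogram entropy, and
approximate entropy.  Across 19 channels this yields the 152-element
nonlinear feature set.

Slope-based estimators (DFA, Higuchi, D2, LLE, K2) require choices of
scales and scaling regions that no closed formula dictates; the defaults
below are stated per estimator and are plain algorithm parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core import CANONICAL_CHANNELS, EEGRecording
from .connectivity import embed

__all__ = [
    "EmbeddingSpec",
    "ApEnParams",
    "HiguchiParams",
    "dfa",
    "higuchi_fd",
    "correlation_dimension",
    "largest_lyapunov",
    "lyapunov_from_divergence",
    "c0_complexity",
    "kolmogorov_entropy",
    "shannon_entropy",
    "approximate_entropy",
    "nonlinear_feature_vector",
    "nonlinear_feature_names",
    "autocorr_delay",
]

#: Descriptor keys in feature-vector order.
DESCRIPTORS: tuple[str, ...] = (
    "dfa", "higuchi", "corrdim", "lyap", "c0", "kolmogorov", "shannon", "apen",
)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Time-delay embedding: dimension ``m`` and delay ``tau`` in samples.

    ``tau=None`` selects the delay from the first zero crossing of the
    autocorrelation (capped at 20 samples).
    """

    m: int = 5
    tau: int | None = None

    def __post_init__(self) -> None:
        if self.m < 1 or (self.tau is not None and self.tau < 1):
            raise ValueError("m and tau must be >= 1")


@dataclass(frozen=True)
class ApEnParams:
    """Approximate-entropy pattern length and tolerance.

    ``r=None`` uses ``r_coeff`` times the standard deviation of the signal
    (the universal convention); ``r_mode='var'`` multiplies the variance
    instead, reproducing a literal 0.2*var(x) reading.
    """

    m: int = 2
    r: float | None = None
    r_coeff: float = 0.2
    r_mode: str = "sd"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r is not None and self.r <= 0:
            raise ValueError("tolerance r must be positive")
        if self.r_mode not in ("sd", "var"):
            raise ValueError("r_mode must be 'sd' or 'var'")

    def tolerance(self, x: np.ndarray) -> float:
        if self.r is not None:
            return self.r
        scale = np.std(x) if self.r_mode == "sd" else np.var(x)
        r = self.r_coeff * scale
        if r <= 0:
            raise ValueError("tolerance is zero for a constant signal")
        return float(r)


@dataclass(frozen=True)
class HiguchiParams:
    """Scale range (in samples) for the Higuchi curve-length sweep."""

    t_min: int = 1
    t_max: int = 30

    def __post_init__(self) -> None:
        if not 1 <= self.t_min < self.t_max:
            raise ValueError("need 1 <= t_min < t_max")


def autocorr_delay(x: np.ndarray, cap: int = 20) -> int:
    """First zero crossing of the autocorrelation, capped (embedding delay)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 1
    for lag in range(1, min(cap, x.size - 1) + 1):
        if float(x[:-lag] @ x[lag:]) / denom <= 0:
            return lag
    return cap


def _loglog_slope(log_x: np.ndarray, log_y: np.ndarray) -> float:
    return float(np.polyfit(log_x, log_y, 1)[0])


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa(x: np.ndarray, scales: np.ndarray | None = None) -> float:
    """Detrended fluctuation scaling exponent alpha.

    The signal is integrated into a profile, split into non-overlapping
    windows of each scale, linearly detrended per window, and the RMS
    fluctuation F(n) regressed against n on log-log axes.  White noise
    gives alpha ~ 0.5, Brownian motion ~ 1.5.  Default scales: >= 10
    log-spaced sizes from 4 to N/4.
    """
    x = np.asarray(x, dtype=float)
    n_samp = x.size
    if scales is None:
        if n_samp < 16:
            raise ValueError("signal too short for DFA")
        n_scales = max(10, int(np.log2(n_samp)))
        scales = np.unique(
            np.floor(np.logspace(np.log10(4), np.log10(n_samp // 4), n_scales))
        ).astype(int)
    else:
        scales = np.asarray(scales, dtype=int)
    if scales.size < 4 or n_samp < 4 * scales.max():
        raise ValueError("need >= 4 scales and length >= 4x the largest scale")
    if np.ptp(x) == 0:
        raise ValueError("DFA undefined for a constant signal")

    profile = np.cumsum(x - x.mean())
    fluct = np.empty(scales.size)
    for s_i, n in enumerate(scales):
        n_win = n_samp // n
        seg = profile[: n_win * n].reshape(n_win, n)
        t = np.arange(n)
        coef = np.polyfit(t, seg.T, 1)  # per-window linear trend
        resid = seg - (np.outer(coef[0], t) + coef[1][:, None])
        fluct[s_i] = np.sqrt(np.mean(resid**2))
    if np.any(fluct == 0):
        raise ValueError("zero fluctuation at some scale (degenerate signal)")
    return _loglog_slope(np.log(scales), np.log(fluct))


# ---------------------------------------------------------------------------
# Higuchi fractal dimension
# ---------------------------------------------------------------------------

def higuchi_fd(x: np.ndarray, params: HiguchiParams = HiguchiParams()) -> float:
    """Higuchi fractal dimension from mean curve lengths at scales T.

    For each scale T and offset tau the decimated curve length is computed
    with the standard end-correction; lengths are averaged over offsets and
    FD is the slope of ln L(T) versus ln(1/T).  A straight line gives
    exactly 1, white noise about 2.
    """
    x = np.asarray(x, dtype=float)
    n_samp = x.size
    if n_samp <= 2 * params.t_max:
        raise ValueError("signal too short for the requested t_max")
    if np.ptp(x) == 0:
        raise ValueError("Higuchi FD undefined for a constant signal")

    log_inv_t, log_len = [], []
    for t_scale in range(params.t_min, params.t_max + 1):
        lengths = []
        for tau in range(1, t_scale + 1):
            n_steps = (n_samp - tau) // t_scale
            if n_steps < 1:
                continue
            idx = (tau - 1) + t_scale * np.arange(n_steps + 1)
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n_samp - 1) / (n_steps * t_scale)
            lengths.append(dist * norm / t_scale)
        mean_len = float(np.mean(lengths))
        if mean_len > 0:
            log_inv_t.append(np.log(1.0 / t_scale))
            log_len.append(np.log(mean_len))
    if len(log_len) < 2:
        raise ValueError("not enough valid scales for Higuchi FD")
    return _loglog_slope(np.asarray(log_inv_t), np.asarray(log_len))


# ---------------------------------------------------------------------------
# Correlation integral machinery (shared by D2 and K2)
# ---------------------------------------------------------------------------

def _sampled_orbit(emb: np.ndarray, max_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Evenly strided subsample of the orbit with original time indices."""
    n = emb.shape[0]
    step = max(1, int(np.ceil(n / max_points)))
    idx = np.arange(0, n, step)
    return emb[idx], idx


def _correlation_sums(
    emb: np.ndarray, r_grid: np.ndarray, theiler: int, max_points: int = 1200
) -> np.ndarray:
    """C(r): fraction of Theiler-separated point pairs closer than r."""
    pts, tidx = _sampled_orbit(emb, max_points)
    d = cdist(pts, pts)
    sep = np.abs(tidx[:, None] - tidx[None, :])
    mask = np.triu(sep > theiler, k=1)
    dist = d[mask]
    if dist.size == 0:
        raise ValueError("no Theiler-separated pairs available")
    return np.searchsorted(np.sort(dist), r_grid, side="right") / dist.size


def _scaling_region(log_r: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Boolean mask for the central ``frac`` of the log-r span."""
    lo, hi = log_r.min(), log_r.max()
    pad = (1 - frac) / 2 * (hi - lo)
    return (log_r >= lo + pad) & (log_r <= hi - pad)


def _r_grid(emb: np.ndarray, theiler: int, max_points: int, n_r: int = 24
            ) -> np.ndarray:
    pts, tidx = _sampled_orbit(emb, max_points)
    d = cdist(pts, pts)
    sep = np.abs(tidx[:, None] - tidx[None, :])
    dist = d[np.triu(sep > theiler, k=1)]
    dist = dist[dist > 0]
    if dist.size < 10:
        raise ValueError("degenerate point cloud (all points coincide)")
    lo = np.quantile(dist, 0.01)
    hi = np.quantile(dist, 0.5)
    if lo <= 0 or hi <= lo:
        raise ValueError("cannot build a distance grid for this signal")
    return np.geomspace(lo, hi, n_r)


def correlation_dimension(
    x: np.ndarray,
    spec: EmbeddingSpec | None = None,
    m_max: int = 10,
    saturation_rtol: float = 0.05,
    max_points: int = 1200,
) -> float:
    """Correlation dimension D2 via the Grassberger-Procaccia integral.

    For embedding dimensions m = 1..m_max the correlation integral C(r) is
    computed with Theiler exclusion and D(m) taken as the ln C / ln r slope
    over the central half of the scaling range; the estimate is declared
    saturated once successive D(m) agree within ``saturation_rtol``.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("correlation dimension undefined for constant signal")
    tau = spec.tau if spec is not None and spec.tau is not None else autocorr_delay(x)
    if spec is not None:
        m_max = max(m_max, spec.m)
    theiler = max(tau, 1)

    prev_d = None
    estimates = []
    for m in range(1, m_max + 1):
        emb = embed(x, m, tau)
        if emb.shape[0] < 100:
            break
        r_grid = _r_grid(emb, theiler, max_points)
        c_of_r = _correlation_sums(emb, r_grid, theiler, max_points)
        keep = (c_of_r > 0) & _scaling_region(np.log(r_grid))
        if keep.sum() < 3:
            continue
        d_m = _loglog_slope(np.log(r_grid[keep]), np.log(c_of_r[keep]))
        estimates.append(d_m)
        if prev_d is not None and abs(d_m - prev_d) <= saturation_rtol * abs(prev_d):
            return d_m
        prev_d = d_m
    if not estimates:
        raise ValueError("could not estimate a correlation dimension")
    return estimates[-1]  # no clear saturation: report the largest-m slope


# ---------------------------------------------------------------------------
# Largest Lyapunov exponent (Rosenstein divergence method)
# ---------------------------------------------------------------------------

def lyapunov_from_divergence(log_div: np.ndarray, dt: float = 1.0,
                             fit_points: int | None = None) -> float:
    """Slope of a mean log-divergence curve versus step index.

    ``log_div[i]`` is the average ln separation after i steps; the exponent
    is the least-squares slope over the initial region (all points by
    default, or the first ``fit_points``), divided by ``dt``.
    """
    log_div = np.asarray(log_div, dtype=float)
    if fit_points is not None:
        log_div = log_div[:fit_points]
    if log_div.size < 2:
        raise ValueError("need at least two divergence points")
    steps = np.arange(log_div.size)
    return float(np.polyfit(steps, log_div, 1)[0]) / dt


def largest_lyapunov(
    x: np.ndarray,
    spec: EmbeddingSpec = EmbeddingSpec(),
    horizon: int = 30,
    dt: float = 1.0,
    max_refs: int = 1000,
) -> float:
    """Largest Lyapunov exponent from nearest-neighbour divergence.

    Each embedded point is paired with its nearest neighbour at a temporal
    separation beyond the signal's mean period (dominant spectral peak);
    the mean ln distance between the pair after i steps forms the
    divergence curve, and the exponent is its initial slope.  The fit stops
    where the curve comes within 0.5 nats of its saturation plateau.
    Reported per sample when ``dt=1``.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("Lyapunov exponent undefined for a constant signal")
    tau = spec.tau if spec.tau is not None else autocorr_delay(x)
    emb = embed(x, spec.m, tau)
    n = emb.shape[0]
    if n < 100 + horizon:
        raise ValueError("embedded orbit too short for the divergence fit")

    # mean period from the dominant spectral peak (Theiler-style exclusion)
    # capped so low-frequency-dominated signals keep admissible neighbours
    spec_mag = np.abs(np.fft.rfft(x - x.mean()))
    peak = int(np.argmax(spec_mag[1:]) + 1)
    mean_period = max(1, int(round(x.size / peak)))
    mean_period = min(mean_period, max(1, (n - horizon) // 10))

    refs = np.arange(0, n - horizon, max(1, (n - horizon) // max_refs))
    d = cdist(emb[refs], emb[: n - horizon])
    sep = np.abs(refs[:, None] - np.arange(n - horizon)[None, :])
    d[sep <= mean_period] = np.inf
    nbr = np.argmin(d, axis=1)
    finite = np.isfinite(d[np.arange(refs.size), nbr])
    refs, nbr = refs[finite], nbr[finite]
    if refs.size == 0:
        raise ValueError("no admissible neighbour pairs")

    tiny = 1e-12
    log_div = np.empty(horizon + 1)
    for i in range(horizon + 1):
        gaps = np.linalg.norm(emb[refs + i] - emb[nbr + i], axis=1)
        log_div[i] = np.mean(np.log(np.maximum(gaps, tiny)))

    plateau = log_div[-max(3, horizon // 5):].mean()
    usable = np.nonzero(log_div < plateau - 0.5)[0]
    n_fit = max(3, usable.size) if usable.size else max(3, horizon // 3)
    return lyapunov_from_divergence(log_div, dt=dt, fit_points=n_fit)


# ---------------------------------------------------------------------------
# C0-complexity
# ---------------------------------------------------------------------------

def c0_complexity(x: np.ndarray) -> float:
    """Fraction of power left after removing above-average spectral lines.

    Spectral components whose squared magnitude strictly exceeds the mean
    squared magnitude are kept as the 'regular' part; C0 is the power of
    the residual over the power of the signal, in [0, 1].  A pure tone is
    nearly 0; a flat spectrum (where the strict comparison keeps nothing)
    is exactly 1.
    """
    x = np.asarray(x, dtype=float)
    total = float(np.sum(x**2))
    if x.size < 2 or total == 0:
        raise ValueError("C0-complexity undefined for an all-zero signal")
    spec_x = np.fft.fft(x)
    mean_sq = np.mean(np.abs(spec_x) ** 2)
    kept = np.where(np.abs(spec_x) ** 2 > mean_sq, spec_x, 0.0)
    regular = np.fft.ifft(kept).real
    return float(np.sum((x - regular) ** 2) / total)


# ---------------------------------------------------------------------------
# Kolmogorov (K2 / correlation) entropy
# ---------------------------------------------------------------------------

def kolmogorov_entropy(
    x: np.ndarray,
    spec: EmbeddingSpec = EmbeddingSpec(m=2),
    r: float | None = None,
    delta_m: int = 1,
    max_points: int = 1200,
) -> float:
    """K2 correlation-entropy estimate of the Kolmogorov entropy (nats/step).

    The defining triple limit is not computable from data; the
    Grassberger-Procaccia K2 bound is used instead:
    K2 ~ (1/(delta_m * tau)) * ln(C_m(r) / C_{m+delta_m}(r)), averaged over
    the central scaling region of r (or evaluated at a given ``r``).
    Zero for regular (periodic) dynamics; ln 2 for the fully chaotic
    logistic map.  Clipped below at 0.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("K2 undefined for a constant signal")
    tau = spec.tau if spec.tau is not None else autocorr_delay(x)
    theiler = max(tau, 1)
    emb_lo = embed(x, spec.m, tau)
    emb_hi = embed(x, spec.m + delta_m, tau)
    n_hi = emb_hi.shape[0]
    emb_lo = emb_lo[:n_hi]  # align the two orbits on common time indices

    if r is not None:
        r_grid = np.asarray([r], dtype=float)
        keep = np.ones(1, dtype=bool)
    else:
        r_grid = _r_grid(emb_lo, theiler, max_points)
        keep = _scaling_region(np.log(r_grid))
    c_lo = _correlation_sums(emb_lo, r_grid, theiler, max_points)
    c_hi = _correlation_sums(emb_hi, r_grid, theiler, max_points)
    ok = keep & (c_hi > 0) & (c_lo > 0)
    if not np.any(ok):
        raise ValueError("correlation sums vanish at every candidate radius")
    k2 = np.log(c_lo[ok] / c_hi[ok]) / (delta_m * tau)
    return float(max(0.0, np.median(k2)))


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

def shannon_entropy(x: np.ndarray, n_bins: int = 16) -> float:
    """Amplitude-histogram Shannon entropy in nats.

    Equal-width bins over [min, max]; empty bins are skipped, so
    0 <= H <= ln(n_bins), with a constant signal giving exactly 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

def approximate_entropy(
    x: np.ndarray, params: ApEnParams = ApEnParams(), block: int = 2048
) -> float:
    """Approximate entropy ApEn(m, r) = Phi^m(r) - Phi^{m+1}(r).

    Pattern similarity uses the Chebyshev (maximum coordinate) distance
    with tolerance r; self-matches are counted, so the pattern frequencies
    are strictly positive and a perfectly regular signal gives 0.  Higher
    values mean more irregular fluctuations.
    """
    x = np.asarray(x, dtype=float)
    r = params.tolerance(x)

    def phi(m: int) -> float:
        templ = embed(x, m, 1)
        n_t = templ.shape[0]
        counts = np.empty(n_t)
        for s in range(0, n_t, block):
            cheb = cdist(templ[s : s + block], templ, "chebyshev")
            counts[s : s + block] = (cheb <= r).sum(1)
        return float(np.mean(np.log(counts / n_t)))

    return phi(params.m) - phi(params.m + 1)


# ---------------------------------------------------------------------------
# Per-channel assembly
# ---------------------------------------------------------------------------

def nonlinear_feature_names() -> list[str]:
    """Deterministic names/order of the nonlinear features."""
    return [f"{d}_{ch}" for d in DESCRIPTORS for ch in CANONICAL_CHANNELS]


def nonlinear_feature_vector(
    seg: EEGRecording,
    apen_params: ApEnParams = ApEnParams(),
    higuchi_params: HiguchiParams = HiguchiParams(),
    max_samples: int | None = 4096,
) -> dict[str, float]:
    """The 152-element nonlinear feature vector (8 descriptors x 19 channels).

    ``max_samples`` truncates each channel before estimation to bound the
    quadratic-cost estimators; None uses the full segment.
    """
    missing = set(CANONICAL_CHANNELS) - set(seg.channels)
    if missing:
        raise ValueError(f"segment lacks canonical channels: {sorted(missing)}")

    funcs = {
        "dfa": lambda s: dfa(s),
        "higuchi": lambda s: higuchi_fd(s, higuchi_params),
        "corrdim": lambda s: correlation_dimension(s),
        "lyap": lambda s: largest_lyapunov(s),
        "c0": c0_complexity,
        "kolmogorov": lambda s: kolmogorov_entropy(s),
        "shannon": lambda s: shannon_entropy(s),
        "apen": lambda s: approximate_entropy(s, apen_params),
    }
    feats: dict[str, float] = {}
    per_channel: dict[str, np.ndarray] = {
        ch: (seg.channel(ch)[:max_samples] if max_samples else seg.channel(ch))
        for ch in CANONICAL_CHANNELS
    }
    for name in DESCRIPTORS:
        for ch in CANONICAL_CHANNELS:
            try:
                feats[f"{name}_{ch}"] = float(funcs[name](per_channel[ch]))
            except ValueError as exc:
                raise ValueError(
                    f"descriptor {name!r} failed on channel {ch!r}: {exc}"
                ) from exc
    return feats
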