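import math
from dataclasses import replace

import numpy as np
import pytest

from eegmci import (
    ApEnParams,
    EmbeddingSpec,
    HiguchiParams,
    KnownSignalSpec,
    approximate_entropy,
    c0_complexity,
    correlation_dimension,
    dfa,
    gen_known_signal,
    higuchi_fd,
    kolmogorov_entropy,
    largest_lyapunov,
    lyapunov_from_divergence,
    nonlinear_feature_names,
    nonlinear_feature_vector,
    shannon_entropy,
)

from conftest import make_recording


def known(kind, length, params=None, seed=0):
    return gen_known_signal(KnownSignalSpec(kind, length, params or {}, seed))


def incommensurate_sine(n, period=40 * math.sqrt(2), noise=0.0, seed=0):
    x = np.sin(2 * np.pi * np.arange(n) / period)
    if noise:
        x = x + noise * np.random.default_rng(seed).standard_normal(n)
    return x


# ---------------------------------------------------------------------------
# Independent brute-force oracles (explicit sums, no shared code paths)
# ---------------------------------------------------------------------------

def c0_oracle(x):
    n = len(x)
    k = np.arange(n)
    dft = np.array([np.sum(x * np.exp(-2j * np.pi * kk * k / n)) for kk in k])
    mean_sq = sum(abs(v) ** 2 for v in dft) / n
    kept = np.array([v if abs(v) ** 2 > mean_sq else 0.0 for v in dft])
    regular = np.array(
        [np.sum(kept * np.exp(2j * np.pi * nn * k / n)) / n for nn in k]
    ).real
    return sum((x - regular) ** 2) / sum(x**2)


def shannon_oracle(x, n_bins=16):
    lo, hi = min(x), max(x)
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in x:
        b = min(int((v - lo) / width), n_bins - 1)
        counts[b] += 1
    return -sum(
        (c / len(x)) * math.log(c / len(x)) for c in counts if c > 0
    )


def apen_oracle(x, m=2, r=None):
    n = len(x)
    r = 0.2 * np.std(x) if r is None else r

    def phi(mm):
        n_t = n - mm + 1
        logs = []
        for i in range(n_t):
            count = 0
            for j in range(n_t):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    count += 1
            logs.append(math.log(count / n_t))
        return sum(logs) / n_t

    return phi(m) - phi(m + 1)


def dfa_oracle(x, scales):
    prof = np.cumsum(np.asarray(x) - np.mean(x))
    logs_n, logs_f = [], []
    for n_w in scales:
        resids = []
        for start in range(0, len(prof) - n_w + 1, n_w):
            seg = prof[start : start + n_w]
            t = np.arange(n_w)
            a, b = np.polyfit(t, seg, 1)
            resids.extend((seg - (a * t + b)) ** 2)
        logs_n.append(math.log(n_w))
        logs_f.append(0.5 * math.log(np.mean(resids)))
    return np.polyfit(logs_n, logs_f, 1)[0]


def gp_slope_oracle(orbit, theiler, r_lo, r_hi, n_r=12):
    """Naive Grassberger-Procaccia slope on an explicit orbit."""
    n = len(orbit)
    dists = [
        np.linalg.norm(orbit[i] - orbit[j])
        for i in range(n)
        for j in range(i + 1, n)
        if j - i > theiler
    ]
    rs = np.geomspace(r_lo, r_hi, n_r)
    cs = np.array([np.mean(np.asarray(dists) <= r) for r in rs])
    keep = cs > 0
    return np.polyfit(np.log(rs[keep]), np.log(cs[keep]), 1)[0]


# ---------------------------------------------------------------------------
# Known-answer behaviour
# ---------------------------------------------------------------------------

class TestDFA:
    def test_white_noise_alpha_half(self):
        assert dfa(known("white", 4096, seed=1)) == pytest.approx(0.5, abs=0.1)

    def test_brownian_alpha_three_halves(self):
        assert dfa(known("brownian", 4096, seed=2)) == pytest.approx(1.5, abs=0.1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dfa(np.ones(4096))

    def test_matches_naive_implementation(self):
        x = known("pink", 2000, seed=3)
        scales = np.array([8, 16, 32, 64, 128])
        assert dfa(x, scales) == pytest.approx(dfa_oracle(x, scales), abs=1e-9)


class TestHiguchi:
    def test_straight_line_dimension_one(self):
        assert higuchi_fd(np.arange(4096.0)) == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_dimension_two(self):
        assert higuchi_fd(known("white", 4096, seed=4)) == pytest.approx(
            2.0, abs=0.1
        )

    def test_slow_sine_near_one(self):
        x = incommensurate_sine(4096, period=128 * math.sqrt(2))
        assert higuchi_fd(x) <= 1.2

    def test_scale_range_validation(self):
        with pytest.raises(ValueError):
            higuchi_fd(np.sin(np.arange(30.0)), HiguchiParams(1, 30))
        with pytest.raises(ValueError):
            HiguchiParams(5, 5)


class TestCorrelationDimension:
    def test_henon_attractor(self):
        x = known("henon_map", 5000)
        assert correlation_dimension(x) == pytest.approx(1.22, abs=0.15)

    def test_noisy_circle_dimension_one(self):
        x = incommensurate_sine(3000, noise=1e-3, seed=3)
        assert correlation_dimension(x) == pytest.approx(1.0, abs=0.2)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            correlation_dimension(np.zeros(2000))

    def test_consistent_with_naive_gp_slope(self):
        x = known("henon_map", 1200)
        orbit = np.stack([x[:-1], x[1:]], axis=1)
        d_oracle = gp_slope_oracle(orbit, theiler=1, r_lo=0.02, r_hi=0.3)
        assert correlation_dimension(x) == pytest.approx(d_oracle, abs=0.25)


class TestLargestLyapunov:
    def test_logistic_map_ln2(self):
        x = known("logistic_map", 2000, {"r": 4.0, "x0": 0.3})
        lam = largest_lyapunov(x, EmbeddingSpec(m=2, tau=1), horizon=15)
        assert lam == pytest.approx(math.log(2), abs=0.10)

    def test_sine_not_chaotic(self):
        lam = largest_lyapunov(incommensurate_sine(2000), EmbeddingSpec(m=5))
        assert lam <= 0.05

    def test_exact_exponential_divergence_slope(self):
        log_div = math.log(1e-3) + 0.1 * np.arange(12)
        assert lyapunov_from_divergence(log_div) == pytest.approx(0.1)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            largest_lyapunov(np.zeros(2000))


class TestC0Complexity:
    def test_pure_tone_nearly_regular(self):
        n = np.arange(1024)
        assert c0_complexity(np.sin(2 * np.pi * 8 * n / 1024)) < 0.01

    def test_impulse_flat_spectrum_gives_one(self):
        x = known("impulse", 64)
        assert c0_complexity(x) == 1.0  # strict inequality keeps nothing

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            x = rng.standard_normal(256)
            assert 0.0 <= c0_complexity(x) <= 1.0 + 1e-12

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            c0_complexity(np.zeros(64))


class TestKolmogorovEntropy:
    def test_periodic_signal_near_zero(self):
        assert kolmogorov_entropy(incommensurate_sine(3000)) <= 0.05

    def test_logistic_map_ln2(self):
        x = known("logistic_map", 5000, {"r": 4.0, "x0": 0.3})
        k2 = kolmogorov_entropy(x, EmbeddingSpec(m=2, tau=1))
        assert k2 == pytest.approx(math.log(2), abs=0.2)

    def test_equal_correlation_sums_give_zero(self, rng):
        # a radius catching every pair makes C_m = C_{m+1} = 1
        x = rng.standard_normal(1500)
        assert kolmogorov_entropy(x, EmbeddingSpec(m=2, tau=1), r=100.0) == 0.0


class TestShannonEntropy:
    def test_constant_signal_zero(self):
        assert shannon_entropy(np.full(100, 3.3)) == 0.0

    def test_uniformly_filled_bins_reach_log_nbins(self):
        x = np.repeat(np.linspace(0.0, 1.0, 16), 10)
        assert shannon_entropy(x) == pytest.approx(math.log(16))

    def test_upper_bound(self, rng):
        for _ in range(5):
            assert shannon_entropy(rng.standard_normal(500)) <= math.log(16)


class TestApproximateEntropy:
    def test_constant_signal_zero(self):
        assert approximate_entropy(np.ones(300), ApEnParams(r=0.5)) == 0.0

    def test_alternating_sequence_regular(self):
        x = np.tile([1.0, -1.0], 150)
        assert approximate_entropy(x) < 0.05

    def test_ordering_sine_less_than_noisy_less_than_noise(self, rng):
        sine = incommensurate_sine(800)
        noise = rng.standard_normal(800)
        noisy = sine + 0.5 * rng.standard_normal(800)
        assert (
            approximate_entropy(sine)
            < approximate_entropy(noisy)
            < approximate_entropy(noise)
        )

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            ApEnParams(r=-1.0)


@pytest.fixture(scope="module")
def signals():
    out = []
    for seed in range(10):
        kind = ["white", "pink", "sine", "logistic_map", "brownian"][seed % 5]
        params = {"freq": 7.3, "fs": 200.0} if kind == "sine" else {}
        out.append(known(kind, 400 + 60 * seed, params, seed=seed))
    return out


class TestOracleEquivalence:
    """Closed-formula descriptors against independent brute-force code."""

    def test_c0_matches_bruteforce(self, signals):
        for x in signals:
            assert c0_complexity(x) == pytest.approx(c0_oracle(x), abs=1e-9)

    def test_shannon_matches_bruteforce(self, signals):
        for x in signals:
            assert shannon_entropy(x) == pytest.approx(
                shannon_oracle(x), abs=1e-9
            )

    def test_apen_matches_bruteforce(self, signals):
        for x in signals:
            short = x[:250]
            assert approximate_entropy(short) == pytest.approx(
                apen_oracle(short), abs=1e-9
            )


class TestScaleInvariance:
    @pytest.mark.parametrize("gain", [0.05, 20.0])
    def test_descriptors_invariant_to_amplitude_gain(self, gain):
        x = known("pink", 2500, seed=9)
        pairs = [
            (dfa, 0.02),
            (higuchi_fd, 0.02),
            (lambda s: correlation_dimension(s), 0.05),
            (lambda s: shannon_entropy(s), 1e-9),
            (lambda s: approximate_entropy(s), 1e-6),
        ]
        for f, tol in pairs:
            assert f(gain * x) == pytest.approx(f(x), abs=tol)


class TestFeatureVector:
    def test_width_names_and_channel_independence(self, rng):
        row = known("pink", 900, seed=13)
        rec = make_recording(np.tile(row, (19, 1)))
        feats = nonlinear_feature_vector(rec, max_samples=900)
        assert len(feats) == 152  # 8 descriptors x 19 channels
        assert list(feats) == nonlinear_feature_names()
        by_desc = {}
        for name, v in feats.items():
            by_desc.setdefault(name.rsplit("_", 1)[0], set()).add(round(v, 12))
        assert all(len(vals) == 1 for vals in by_desc.values())

    def test_degenerate_channel_reported_with_context(self, rng):
        data = rng.standard_normal((19, 900))
        data[3] = 0.0  # F3 flat
        rec = make_recording(data)
        with pytest.raises(ValueError, match="F3"):
            nonlinear_feature_vector(rec, max_samples=900)
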