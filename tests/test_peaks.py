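"""Envelope smoothing and mu+sigma peak detection against brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acoustemp import EnvelopeParams, detect_peaks, peak_rate, smooth_envelope
from acoustemp.peaks import PeakList


# ---------------------------------------------------------------------------
# brute-force oracles (loop-based, independent of the vectorised code paths)


def brute_envelope(x, taps: int, passes: int) -> np.ndarray:
    y = [abs(float(v)) for v in x]
    for _ in range(passes):
        full = [0.0] * (len(y) + taps - 1)
        for i, v in enumerate(y):
            for j in range(taps):
                full[i + j] += v / taps
        start = (taps - 1) // 2
        y = full[start : start + len(y)]
    return np.array(y)


def brute_candidates(env) -> list[int]:
    """Interior local maxima; the first sample of a plateau counts."""
    n = len(env)
    out = []
    for i in range(1, n - 1):
        if env[i] <= env[i - 1]:
            continue
        j = i
        while j + 1 < n and env[j + 1] == env[i]:
            j += 1
        if j + 1 < n and env[j + 1] < env[i]:
            out.append(i)
    return out


def brute_detect(env, sample_rate: float):
    cand = brute_candidates(env)
    if not cand:
        return [], 0.0, 0.0, 0.0
    amps = [env[i] for i in cand]
    mu = sum(amps) / len(amps)
    sigma = math.sqrt(sum((a - mu) ** 2 for a in amps) / len(amps))
    theta = mu + sigma
    kept = [i for i in cand if env[i] >= theta]
    return kept, mu, sigma, theta


# ---------------------------------------------------------------------------
# smooth_envelope


class TestSmoothEnvelope:
    def test_zero_input_stays_zero(self):
        assert np.all(smooth_envelope(np.zeros(100)) == 0.0)

    def test_empty_input_is_rejected(self):
        with pytest.raises(ValueError):
            smooth_envelope(np.empty(0))

    def test_impulse_single_pass_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        env = smooth_envelope(x, EnvelopeParams(taps=20, passes=1))
        assert np.isclose(env.max(), 1.0 / 20.0)
        assert np.count_nonzero(np.isclose(env, 1.0 / 20.0)) == 20

    def test_impulse_four_passes_matches_direct_convolution(self):
        x = np.zeros(201)
        x[100] = 1.0
        env = smooth_envelope(x, EnvelopeParams(taps=20, passes=4))
        oracle = brute_envelope(x, 20, 4)
        np.testing.assert_allclose(env, oracle, atol=1e-14)
        # 4-fold self-convolution of a 20-point kernel has 77-sample support
        assert np.count_nonzero(oracle > 1e-15) == 77
        assert np.isclose(env.max(), oracle.max())

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=200),
           st.integers(1, 25), st.integers(1, 4))
    def test_length_preserved_and_rectification_symmetric(self, xs, taps, passes):
        x = np.array(xs)
        p = EnvelopeParams(taps=taps, passes=passes)
        env = smooth_envelope(x, p)
        assert env.shape == x.shape
        assert np.all(env >= 0)
        np.testing.assert_array_equal(env, smooth_envelope(-x, p))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=100),
           st.floats(-7, 7, allow_nan=False).filter(lambda c: c != 0))
    def test_scale_equivariance(self, xs, c):
        x = np.array(xs)
        np.testing.assert_allclose(
            smooth_envelope(c * x), abs(c) * smooth_envelope(x), rtol=1e-9, atol=1e-12
        )


# ---------------------------------------------------------------------------
# detect_peaks


class TestDetectPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        pl = detect_peaks(np.linspace(0, 1, 50), 100.0)
        assert len(pl) == 0 and pl.n_candidates == 0
        assert pl.mu == pl.sigma == pl.theta == 0.0

    def test_too_short_input_is_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(np.array([1.0, 2.0]), 100.0)

    def test_negative_envelope_is_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            detect_peaks(np.array([0.0, -1.0, 0.0, 1.0, 0.0]), 100.0)

    @pytest.mark.parametrize("ddof,sigma,theta", [(0, 3.6, 6.4), (1, 4.0249, 6.8249)])
    def test_worked_five_candidate_example(self, ddof, sigma, theta):
        """Candidates {1,1,1,1,10}: mu = 2.8; one survivor either way."""
        env = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 10, 0.0])
        pl = detect_peaks(env, 1000.0, ddof=ddof)
        assert pl.n_candidates == 5
        assert pl.mu == pytest.approx(2.8)
        assert pl.sigma == pytest.approx(sigma, abs=1e-4)
        assert pl.theta == pytest.approx(theta, abs=1e-4)
        np.testing.assert_array_equal(pl.amplitudes, [10.0])

    def test_plateau_first_sample_is_the_peak(self):
        env = np.array([0.0, 1.0, 2.0, 2.0, 2.0, 1.0, 0.0])
        pl = detect_peaks(env, 1.0, ddof=0)
        assert pl.n_candidates == 1
        np.testing.assert_array_equal(pl.indices, [2])

    def test_threshold_contract_on_random_signals(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            env = smooth_envelope(rng.normal(0, 1, 500))
            pl = detect_peaks(env, 1000.0)
            assert pl.theta == pl.mu + pl.sigma
            if len(pl):
                assert pl.amplitudes.min() >= pl.theta
                assert np.all(np.diff(pl.times) > 0)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(10, 400))
            env = smooth_envelope(rng.normal(0, 1, n), EnvelopeParams(taps=7, passes=2))
            pl = detect_peaks(env, 100.0)
            kept, mu, sigma, theta = brute_detect(env, 100.0)
            np.testing.assert_array_equal(pl.indices, kept)
            assert pl.mu == pytest.approx(mu, rel=1e-12)
            assert pl.sigma == pytest.approx(sigma, rel=1e-12)


# ---------------------------------------------------------------------------
# peak_rate


class TestPeakRate:
    def _peaklist(self, times):
        t = np.asarray(times, dtype=float)
        return PeakList(times=t, amplitudes=np.ones_like(t),
                        indices=(t * 100).astype(int), mu=0.0, sigma=0.0,
                        theta=0.0, n_candidates=len(t), sample_rate=100.0)

    def test_no_peaks_is_zero_rate(self):
        assert peak_rate(self._peaklist([]), (0.0, 1.0), 7.0) == 0.0

    def test_thirty_peaks_over_one_and_a_half_cm(self):
        # 30 peaks in a 3 s window at 5 mm/s -> 1.5 cm -> 20 peaks/cm
        pl = self._peaklist(np.linspace(0.05, 2.95, 30))
        assert peak_rate(pl, (0.0, 3.0), 5.0) == pytest.approx(20.0)

    def test_degenerate_windows_are_rejected(self):
        pl = self._peaklist([0.5])
        with pytest.raises(ValueError):
            peak_rate(pl, (1.0, 1.0), 5.0)
        with pytest.raises(ValueError):
            peak_rate(pl, (0.0, 1.0), 0.0)
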