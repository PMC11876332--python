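"""Envelope smoothing, amplitude-thresholded peak detection, peaks-per-cm.

The detector follows a simple, robust recipe: rectify the waveform, smooth
it with repeated short moving-average passes, locate all interior local
maxima of the envelope, and keep only those whose amplitude reaches

    theta = mu + sigma

where mu and sigma are the mean and standard deviation of *all* candidate
maxima of the recording.  The rationale: candidate amplitudes are roughly
normal with noise maxima near the mean, while true needle-bubble events sit
far in the upper tail, so one sigma above the mean separates them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EnvelopeParams", "PeakList", "smooth_envelope", "detect_peaks", "peak_rate"]


@dataclass(frozen=True)
class EnvelopeParams:
    """Moving-average envelope: `passes` convolutions with a `taps`-point
    uniform kernel (each weight 1/taps), zero-padded to preserve length."""

    taps: int = 20
    passes: int = 4

    def __post_init__(self) -> None:
        if self.taps < 1 or self.passes < 1:
            raise ValueError("taps and passes must both be >= 1")


@dataclass
class PeakList:
    """Retained peaks plus the threshold statistics that produced them."""

    times: np.ndarray          # seconds, strictly increasing
    amplitudes: np.ndarray     # envelope amplitude at each retained peak
    indices: np.ndarray        # sample index of each retained peak
    mu: float                  # mean of all candidate (local-max) amplitudes
    sigma: float               # their standard deviation
    theta: float               # retention threshold, mu + sigma
    n_candidates: int          # local maxima before thresholding
    sample_rate: float = field(default=0.0)

    def __len__(self) -> int:
        return len(self.times)

    def in_window(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean mask of retained peaks inside [t_start, t_end]."""
        return (self.times >= t_start) & (self.times <= t_end)


def smooth_envelope(waveform: np.ndarray, params: EnvelopeParams = EnvelopeParams()) -> np.ndarray:
    """Rectify and repeatedly average a waveform; length-preserving.

    Each pass is a "same"-mode convolution with the uniform kernel; with an
    even ``taps`` the window extends taps//2 samples into the past and
    taps//2 - 1 into the future of each output sample.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("waveform must be a non-empty 1-D sequence")
    kernel = np.full(params.taps, 1.0 / params.taps)
    start = (params.taps - 1) // 2
    env = np.abs(x)
    for _ in range(params.passes):
        # "same" slice of the full convolution; unlike mode="same" this
        # preserves length even when the kernel outruns the signal
        env = np.convolve(env, kernel, mode="full")[start : start + x.size]
    return env


def _candidate_maxima(env: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima; the first sample of a flat plateau
    counts as the maximum."""
    # run-length compress equal neighbours, then compare run values
    diff = np.diff(env)
    boundaries = np.flatnonzero(diff != 0)
    starts = np.concatenate(([0], boundaries + 1))
    vals = env[starts]
    if len(vals) < 3:
        return np.empty(0, dtype=np.intp)
    is_max = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    return starts[1:-1][is_max]


def detect_peaks(
    envelope: np.ndarray, sample_rate: float, ddof: int = 0
) -> PeakList:
    """Threshold the interior local maxima of an envelope at mu + sigma.

    mu and sigma are computed over all candidate maxima of this recording;
    sigma uses the population convention by default (``ddof=0``).  With no
    candidates an empty PeakList with mu = sigma = theta = 0 is returned.
    """
    env = np.asarray(envelope, dtype=np.float64)
    if env.ndim != 1 or env.size < 3:
        raise ValueError("envelope must be 1-D with at least 3 samples")
    if np.any(env < 0):
        raise ValueError("envelope must be non-negative (rectify first)")

    cand = _candidate_maxima(env)
    if cand.size == 0:
        z = np.empty(0)
        return PeakList(z, z.copy(), np.empty(0, dtype=np.intp),
                        0.0, 0.0, 0.0, 0, float(sample_rate))

    amps = env[cand]
    mu = float(np.mean(amps))
    sigma = float(np.std(amps, ddof=ddof)) if amps.size > ddof else 0.0
    theta = mu + sigma
    keep = amps >= theta
    idx = cand[keep]
    return PeakList(
        times=idx / float(sample_rate),
        amplitudes=amps[keep],
        indices=idx,
        mu=mu,
        sigma=sigma,
        theta=theta,
        n_candidates=int(cand.size),
        sample_rate=float(sample_rate),
    )


def peak_rate(
    peaks: PeakList, window: tuple[float, float], speed_mm_s: float
) -> float:
    """Peaks per cm of needle travel inside a time window.

    The travel distance is ``speed_mm_s * (t_end - t_start) / 10`` cm.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError("window must satisfy t_end > t_start")
    if speed_mm_s <= 0:
        raise ValueError("speed_mm_s must be > 0")
    distance_cm = speed_mm_s * (t_end - t_start) / 10.0
    if distance_cm <= 0:
        raise ValueError("zero travel distance")
    count = int(np.count_nonzero(peaks.in_window(t_start, t_end)))
    return count / distance_cm
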