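"""Chunking of recordings and mel-spectrogram features.

Two chunk datasets are supported:

* sliding — consecutive 100 ms windows with 25% overlap over the forward
  motion [L1, L2] (the initial experiment);
* peak-centered — one 100 ms window per detected peak, with the peak placed
  at the chunk centre plus a uniform integer displacement of up to +-25% of
  the chunk width (the primary dataset; the displacement doubles as data
  augmentation and desensitises the model to annotation error).

Chunks are converted to mel spectrograms: magnitude STFT (FFT 2048, hop
512, centred Hann frames), a 256-filter Slaney-style mel bank spanning
1 Hz - 20 kHz, then dB relative to the chunk maximum with a -80 dB floor.
The per-chunk dB reference makes features gain-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal import get_window

from .peaks import PeakList
from .synth import AnnotatedRecording

__all__ = [
    "Chunk",
    "MelSpec",
    "CHUNK_SECONDS",
    "OVERLAP_FRACTION",
    "chunk_length",
    "slice_sliding",
    "slice_peak_centered",
    "mel_filterbank",
    "stft_magnitude",
    "mel_spectrogram",
]

CHUNK_SECONDS = 0.100
OVERLAP_FRACTION = 0.25
DB_FLOOR = -80.0


def chunk_length(sample_rate: float) -> int:
    """Samples in one 100 ms chunk."""
    return int(round(CHUNK_SECONDS * sample_rate))


@dataclass
class Chunk:
    """A fixed-length waveform slice tagged with its provenance."""

    samples: np.ndarray
    recording_id: str
    center_time: float           # seconds, centre of the slice
    label_degc: float            # the source recording's measured temperature
    source: str                  # "sliding" | "peak_centered"
    sample_rate: float = 48_000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.source not in ("sliding", "peak_centered"):
            raise ValueError(f"unknown chunk source {self.source!r}")


@dataclass
class MelSpec:
    """Mel spectrogram in dB; exactly ``n_mels`` rows, one column per frame."""

    values: np.ndarray
    sample_rate: float
    n_mels: int = 256
    fft_size: int = 2048
    hop: int = 512
    fmin: float = 1.0
    fmax: float = 20_000.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != self.n_mels:
            raise ValueError("mel spectrogram must have n_mels rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mel spectrogram contains non-finite values")


def slice_sliding(
    recording: AnnotatedRecording,
    window: tuple[float, float] | None = None,
) -> list[Chunk]:
    """Consecutive 100 ms chunks with 25% overlap (hop 75 ms).

    Slicing starts at the window start (default [L1, L2]); a final partial
    window is discarded.  A window shorter than one chunk yields no chunks.
    """
    sr = recording.sample_rate
    t0, t1 = window if window is not None else (recording.L1, recording.L2)
    if t1 <= t0:
        raise ValueError("window must have positive length")
    w = chunk_length(sr)
    hop = int(round(w * (1.0 - OVERLAP_FRACTION)))
    start = int(round(t0 * sr))
    end = min(int(round(t1 * sr)), len(recording.waveform))
    n_avail = end - start
    if n_avail < w:
        return []
    n_chunks = (n_avail - w) // hop + 1
    chunks = []
    for i in range(n_chunks):
        s = start + i * hop
        chunks.append(
            Chunk(
                samples=recording.waveform[s : s + w],
                recording_id=recording.recording_id,
                center_time=(s + w / 2) / sr,
                label_degc=recording.measured_temperature,
                source="sliding",
                sample_rate=sr,
            )
        )
    return chunks


def slice_peak_centered(
    recording: AnnotatedRecording,
    peaks: PeakList,
    rng: np.random.Generator,
    jitter_fraction: float = 0.25,
    window: tuple[float, float] | None = None,
) -> list[Chunk]:
    """One 100 ms chunk per retained peak, peak near the chunk centre.

    The peak sample lands at ``W//2 + d`` inside the chunk, with d drawn as a
    uniform integer in [-jitter_fraction*W, +jitter_fraction*W].  Peaks whose
    chunk would cross the recording boundary are discarded with a warning.
    Peaks are restricted to ``window`` (default the forward motion [L1, L2]).
    """
    sr = recording.sample_rate
    w = chunk_length(sr)
    half_span = int(jitter_fraction * w)
    t0, t1 = window if window is not None else (recording.L1, recording.L2)
    sel = peaks.in_window(t0, t1)
    chunks = []
    n_dropped = 0
    for peak_idx in np.asarray(peaks.indices)[sel]:
        d = int(rng.integers(-half_span, half_span + 1))
        start = int(peak_idx) - (w // 2 + d)
        if start < 0 or start + w > len(recording.waveform):
            n_dropped += 1
            continue
        chunks.append(
            Chunk(
                samples=recording.waveform[start : start + w],
                recording_id=recording.recording_id,
                center_time=(start + w / 2) / sr,
                label_degc=recording.measured_temperature,
                source="peak_centered",
                sample_rate=sr,
            )
        )
    if n_dropped:
        warnings.warn(
            f"{recording.recording_id}: discarded {n_dropped} boundary chunk(s)",
            stacklevel=2,
        )
    return chunks


# ---------------------------------------------------------------------------
# mel spectrogram


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    """Slaney mel scale: linear below 1 kHz, logarithmic above."""
    f = np.asarray(f, dtype=np.float64)
    min_log_hz = 1000.0
    min_log_mel = 15.0
    logstep = np.log(6.4) / 27.0
    mel = 3.0 * f / 200.0
    above = f >= min_log_hz
    mel = np.where(above, min_log_mel + np.log(np.maximum(f, 1e-12) / min_log_hz) / logstep, mel)
    return mel


def _mel_to_hz(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    min_log_mel = 15.0
    logstep = np.log(6.4) / 27.0
    f = 200.0 * m / 3.0
    above = m >= min_log_mel
    return np.where(above, 1000.0 * np.exp(logstep * (m - min_log_mel)), f)


@lru_cache(maxsize=8)
def mel_filterbank(
    sample_rate: float,
    n_fft: int = 2048,
    n_mels: int = 256,
    fmin: float = 1.0,
    fmax: float = 20_000.0,
) -> np.ndarray:
    """Slaney-style triangular mel filterbank, area-normalised.

    Returns an (n_mels, 1 + n_fft//2) weight matrix mapping an rfft magnitude
    spectrum onto mel bins.
    """
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    weights = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        tri = np.maximum(0.0, np.minimum(up, down))
        weights[i] = tri * (2.0 / (hi - lo))  # Slaney area normalisation
    return weights


def stft_magnitude(
    samples: np.ndarray, n_fft: int = 2048, hop: int = 512
) -> np.ndarray:
    """Magnitude STFT with centred Hann frames and reflect padding.

    The frame count is ``1 + len(samples)//hop``.
    """
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 1:
        raise ValueError("empty input")
    pad = n_fft // 2
    if x.size > 1:
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = np.pad(x, pad, mode="constant")
    n_frames = 1 + x.size // hop
    win = get_window("hann", n_fft, fftbins=True)
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = xp[idx] * win
    return np.abs(np.fft.rfft(frames, axis=1)).T  # (1 + n_fft//2, n_frames)


def mel_spectrogram(
    chunk: Chunk | np.ndarray,
    sample_rate: float | None = None,
    n_mels: int = 256,
    n_fft: int = 2048,
    hop: int = 512,
    fmin: float = 1.0,
    fmax: float = 20_000.0,
) -> MelSpec:
    """Mel spectrogram of a chunk, in dB relative to the chunk maximum.

    Values are floored at -80 dB; an all-zero chunk maps to a spectrogram
    identically at the floor.
    """
    if isinstance(chunk, Chunk):
        samples = chunk.samples
        sr = chunk.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required when passing raw samples")
        samples = np.asarray(chunk, dtype=np.float64)
        sr = float(sample_rate)
    if sr < 2.0 * fmax:
        raise ValueError(
            f"sample rate {sr} Hz cannot represent fmax={fmax} Hz (need >= 2*fmax)"
        )
    spec = stft_magnitude(samples, n_fft=n_fft, hop=hop)
    mel = mel_filterbank(sr, n_fft, n_mels, fmin, fmax) @ spec
    ref = mel.max()
    if ref <= 0:
        db = np.full_like(mel, DB_FLOOR)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mel / ref)
        db = np.maximum(db, DB_FLOOR)
    return MelSpec(
        values=db, sample_rate=sr, n_mels=n_mels,
        fft_size=n_fft, hop=hop, fmin=fmin, fmax=fmax,
    )
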