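"""Waveform augmentation: time stretch, pitch shift, gain.

Augmentation operates on the waveform before spectrogram conversion (pitch
and tempo manipulation need the raw signal) in the fixed order
time-stretch -> pitch-shift -> gain, then the result is centre-cropped or
zero-padded back to the original chunk length.  Labels are never touched.

Time stretch uses a standard phase vocoder (STFT, per-bin phase
accumulation, overlap-add resynthesis); pitch shift combines a phase-vocoder
stretch with linear-interpolation resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.signal import get_window

from .segmentation import Chunk

__all__ = ["AugmentationSpec", "augment", "apply_gain", "time_stretch", "pitch_shift"]


@dataclass(frozen=True)
class AugmentationSpec:
    """Uniform draw ranges for each augmentation.

    Pitch shift is in semitones (a logarithmic pitch unit; +12 doubles the
    frequency).  A zero-width range pinned at the identity value disables
    the corresponding transform exactly.
    """

    gain_db: tuple[float, float] = (-5.0, 5.0)
    pitch_semitones: tuple[float, float] = (-3.0, 3.0)
    time_stretch: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        for name in ("gain_db", "pitch_semitones", "time_stretch"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range reversed")
        if self.time_stretch[0] <= 0:
            raise ValueError("time_stretch factors must be positive")


def apply_gain(x: np.ndarray, gain_db: float) -> np.ndarray:
    """Scale amplitudes by 10^(gain_db/20)."""
    if gain_db == 0.0:
        return np.asarray(x, dtype=np.float64).copy()
    return np.asarray(x, dtype=np.float64) * 10.0 ** (gain_db / 20.0)


def _stft(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    pad = n_fft // 2
    xp = np.pad(x, pad, mode="reflect") if x.size > 1 else np.pad(x, pad)
    n_frames = 1 + x.size // hop
    win = get_window("hann", n_fft, fftbins=True)
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    return np.fft.rfft(xp[idx] * win, axis=1).T


def _istft(spec: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    win = get_window("hann", n_fft, fftbins=True)
    frames = np.fft.irfft(spec.T, n=n_fft, axis=1) * win
    n_frames = frames.shape[0]
    out_len = n_fft + hop * (n_frames - 1)
    out = np.zeros(out_len)
    wsum = np.zeros(out_len)
    for i in range(n_frames):
        out[i * hop : i * hop + n_fft] += frames[i]
        wsum[i * hop : i * hop + n_fft] += win**2
    out = np.where(wsum > 1e-10, out / np.maximum(wsum, 1e-10), out)
    pad = n_fft // 2
    return out[pad : out_len - pad]


def time_stretch(
    x: np.ndarray, rate: float, n_fft: int = 2048, hop: int = 512
) -> np.ndarray:
    """Phase-vocoder time stretch; rate > 1 shortens (plays faster),
    preserving pitch.  ``rate == 1`` returns an exact copy."""
    x = np.asarray(x, dtype=np.float64)
    if rate <= 0:
        raise ValueError("rate must be positive")
    if rate == 1.0:
        return x.copy()
    spec = _stft(x, n_fft, hop)
    n_bins, n_frames = spec.shape
    steps = np.arange(0, n_frames, rate)
    expected = 2.0 * np.pi * hop * np.arange(n_bins) / n_fft

    out = np.empty((n_bins, len(steps)), dtype=complex)
    phase = np.angle(spec[:, 0])
    spec_pad = np.concatenate([spec, np.zeros((n_bins, 2), dtype=complex)], axis=1)
    for t, step in enumerate(steps):
        i = int(step)
        frac = step - i
        mag = (1.0 - frac) * np.abs(spec_pad[:, i]) + frac * np.abs(spec_pad[:, i + 1])
        out[:, t] = mag * np.exp(1j * phase)
        dphi = np.angle(spec_pad[:, i + 1]) - np.angle(spec_pad[:, i]) - expected
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        phase += expected + dphi
    return _istft(out, n_fft, hop)


def _resample_linear(x: np.ndarray, n_out: int) -> np.ndarray:
    if n_out == len(x):
        return x.copy()
    src = np.linspace(0.0, len(x) - 1.0, n_out)
    return np.interp(src, np.arange(len(x)), x)


def pitch_shift(
    x: np.ndarray, sample_rate: float, semitones: float,
    n_fft: int = 2048, hop: int = 512,
) -> np.ndarray:
    """Shift pitch by ``semitones`` while preserving duration."""
    x = np.asarray(x, dtype=np.float64)
    if semitones == 0.0:
        return x.copy()
    rate = 2.0 ** (-semitones / 12.0)
    stretched = time_stretch(x, rate, n_fft=n_fft, hop=hop)
    return _resample_linear(stretched, len(x))


def _fix_length(x: np.ndarray, n: int) -> np.ndarray:
    """Centre-crop or zero-pad to exactly n samples."""
    if len(x) == n:
        return x
    if len(x) > n:
        start = (len(x) - n) // 2
        return x[start : start + n]
    pad = n - len(x)
    left = pad // 2
    return np.pad(x, (left, pad - left))


def augment(chunk: Chunk, spec: AugmentationSpec, rng: np.random.Generator) -> Chunk:
    """Randomly augmented copy of a chunk; label and length are unchanged."""
    rate = float(rng.uniform(*spec.time_stretch))
    semis = float(rng.uniform(*spec.pitch_semitones))
    gain = float(rng.uniform(*spec.gain_db))
    y = np.asarray(chunk.samples, dtype=np.float64)
    if rate != 1.0:
        y = time_stretch(y, rate)
    if semis != 0.0:
        y = pitch_shift(y, chunk.sample_rate, semis)
    if gain != 0.0:
        y = apply_gain(y, gain)
    y = _fix_length(y, len(chunk.samples))
    return _dc_replace(chunk, samples=y)
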