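"""Synthetic needle-insertion recordings.

Emulates the laboratory protocol behind the real dataset: a needle with a
proximally mounted microphone is pushed through a water-saturated open-cell
foam held in a water bath.  Each crossing of a foam bubble produces a short
vibroacoustic impulse; a recording therefore contains an initiation pulse,
a quiet approach, a dense burst train during forward motion (annotated
[L1, L2]), a quiet dwell, and a mirrored burst train during retraction
([L3, L4]), all over a white-noise floor.

Temperature enters through a parameterised spectral effect on the bursts
(centre frequency and, optionally, decay time drift linearly with the
phantom temperature).  The real physical mechanism is unknown; this module
provides a controllable stand-in so that the downstream detection,
segmentation and regression stages can be validated end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoamSpec",
    "InsertionProfile",
    "TemperatureEffect",
    "SynthConfig",
    "AnnotatedRecording",
    "event_waveform",
    "simulate_insertion",
    "generate_dataset",
]

#: Duration of the initiation pulse placed right after the pre-roll, seconds.
INITIATION_PULSE_S = 0.05

#: Silence appended after the needle exits the foam, seconds.
TAIL_S = 0.5

#: Fractional jitter applied to the (otherwise uniform) bubble spacing.
EVENT_JITTER_FRACTION = 0.20


@dataclass(frozen=True)
class FoamSpec:
    """Reference foam: bubbles per cm of needle travel and slab thickness."""

    bubble_density: float  # events per cm of travel
    thickness_cm: float

    def __post_init__(self) -> None:
        if self.bubble_density < 0:
            raise ValueError("bubble_density must be >= 0")
        if self.thickness_cm <= 0:
            raise ValueError("thickness_cm must be > 0")

    @property
    def n_events(self) -> int:
        """Number of bubble crossings in one pass through the slab."""
        return int(round(self.bubble_density * self.thickness_cm))


@dataclass(frozen=True)
class InsertionProfile:
    """Timing of one manual insertion.

    ``speed_mm_s`` is the forward speed inside the foam; the forward-motion
    duration is ``10 * thickness_cm / speed_mm_s`` seconds.  Retraction may
    run at a different speed (manual pull-out is typically faster).
    """

    speed_mm_s: float
    retraction_speed_mm_s: float | None = None  # None -> same as forward
    pre_roll_s: float = 0.5
    approach_s: float = 1.5
    dwell_s: float = 1.0

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0:
            raise ValueError("speed_mm_s must be > 0")
        r = self.retraction_speed_mm_s
        if r is not None and r <= 0:
            raise ValueError("retraction_speed_mm_s must be > 0")
        for name in ("pre_roll_s", "approach_s", "dwell_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def retraction_mm_s(self) -> float:
        return self.retraction_speed_mm_s or self.speed_mm_s


@dataclass(frozen=True)
class TemperatureEffect:
    """Linear temperature dependence injected into each acoustic event.

    An event at temperature T (degrees C) is a damped sinusoid with

        centre frequency  f(T)   = base_frequency_hz + slope_hz_per_degc * (T - reference_degc)
        decay constant    tau(T) = decay_tau_s + decay_slope_s_per_degc * (T - reference_degc)

    With a nonzero frequency slope the event spectral centroid is strictly
    monotone in temperature, which is the signal the regressor must recover.
    """

    base_frequency_hz: float = 4000.0
    slope_hz_per_degc: float = 50.0
    decay_tau_s: float = 0.001
    decay_slope_s_per_degc: float = 0.0
    amplitude: float = 0.08
    reference_degc: float = 37.5

    def frequency(self, temperature: float) -> float:
        return self.base_frequency_hz + self.slope_hz_per_degc * (
            temperature - self.reference_degc
        )

    def decay(self, temperature: float) -> float:
        return self.decay_tau_s + self.decay_slope_s_per_degc * (
            temperature - self.reference_degc
        )


def _default_groups() -> tuple[float, ...]:
    return tuple(float(t) for t in range(20, 56, 5))


@dataclass(frozen=True)
class SynthConfig:
    """Global generator settings.

    ``within_group_drift_degc`` bounds the cool-down of the water bath inside
    one temperature group; the drawn offset is scaled down for cold groups
    (the bath cools faster when hot) and never exceeds 1.4 degrees C.
    """

    sample_rate: int = 48_000
    noise_sigma: float = 0.01
    seed: int = 0
    temp_groups: tuple[float, ...] = field(default_factory=_default_groups)
    recordings_per_group: int = 22
    within_group_drift_degc: float = 1.4
    max_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 40_000:
            raise ValueError(
                "sample_rate must exceed twice the 20 kHz analysis band"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.within_group_drift_degc <= 1.4):
            raise ValueError("within_group_drift_degc must be in [0, 1.4]")
        if self.recordings_per_group < 0:
            raise ValueError("recordings_per_group must be >= 0")


@dataclass
class AnnotatedRecording:
    """One mono recording with its annotations.

    L1..L4 are, in order: foam entry, end of forward motion, start of
    retraction, and foam exit, in seconds from the start of the recording.
    """

    waveform: np.ndarray
    sample_rate: int
    L1: float
    L2: float
    L3: float
    L4: float
    temperature_group: float
    measured_temperature: float
    true_event_times: np.ndarray
    recording_id: str

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        self.true_event_times = np.asarray(self.true_event_times, dtype=np.float64)
        self.validate()

    @property
    def duration_s(self) -> float:
        return len(self.waveform) / self.sample_rate

    def validate(self) -> None:
        if not (0 < self.L1 < self.L2 <= self.L3 < self.L4 < self.duration_s):
            raise ValueError(
                f"annotation ordering violated for {self.recording_id!r}: "
                f"need 0 < L1 < L2 <= L3 < L4 < duration, got "
                f"{self.L1:.3f}, {self.L2:.3f}, {self.L3:.3f}, {self.L4:.3f}, "
                f"duration {self.duration_s:.3f}"
            )
        t = self.true_event_times
        inside = ((t >= self.L1) & (t <= self.L2)) | ((t >= self.L3) & (t <= self.L4))
        if not np.all(inside):
            raise ValueError(
                f"{self.recording_id!r}: event times outside [L1,L2] u [L3,L4]"
            )

    def forward_event_times(self) -> np.ndarray:
        t = self.true_event_times
        return t[(t >= self.L1) & (t <= self.L2)]


def event_waveform(
    temperature: float,
    effect: TemperatureEffect,
    sample_rate: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One bubble-crossing burst: an exponentially damped sinusoid.

    The burst carries a random phase and a small uniform amplitude jitter
    (+-20%); its centre frequency and decay constant follow ``effect``.
    Deterministic given the state of ``rng``.
    """
    tau = effect.decay(temperature)
    if tau <= 0:
        raise ValueError(
            f"non-positive decay constant tau={tau:.6g} s at {temperature} degC"
        )
    freq = effect.frequency(temperature)
    n = max(1, int(round(6.0 * tau * sample_rate)))  # decay to e^-6
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amp = effect.amplitude * rng.uniform(0.8, 1.2)
    t = np.arange(n) / sample_rate
    return amp * np.exp(-t / tau) * np.sin(2.0 * np.pi * freq * t + phase)


def _event_positions_cm(foam: FoamSpec, rng: np.random.Generator) -> np.ndarray:
    """Bubble positions along the travel path, quasi-regular with jitter."""
    n = foam.n_events
    if n == 0:
        return np.empty(0)
    spacing = foam.thickness_cm / n
    centers = (np.arange(n) + 0.5) * spacing
    jitter = rng.uniform(-EVENT_JITTER_FRACTION, EVENT_JITTER_FRACTION, n) * spacing
    pos = centers + jitter
    # keep strictly inside the slab so event times stay inside [L1, L2]
    return np.clip(pos, 1e-4 * spacing, foam.thickness_cm - 1e-4 * spacing)


def _add_burst(waveform: np.ndarray, burst: np.ndarray, start_idx: int) -> None:
    end = min(start_idx + len(burst), len(waveform))
    if end > start_idx:
        waveform[start_idx:end] += burst[: end - start_idx]


def simulate_insertion(
    foam: FoamSpec,
    profile: InsertionProfile,
    temperature: float,
    effect: TemperatureEffect,
    cfg: SynthConfig,
    rng: np.random.Generator,
    recording_id: str = "synthetic",
    temperature_group: float | None = None,
) -> AnnotatedRecording:
    """Simulate one full insertion and return the annotated recording.

    Forward-motion events number exactly ``round(bubble_density * thickness)``
    regardless of speed; retraction crosses the same bubbles in reverse at the
    retraction speed.
    """
    sr = cfg.sample_rate
    pulse_t = profile.pre_roll_s
    L1 = pulse_t + INITIATION_PULSE_S + profile.approach_s
    forward_s = 10.0 * foam.thickness_cm / profile.speed_mm_s
    L2 = L1 + forward_s
    L3 = L2 + profile.dwell_s
    L4 = L3 + 10.0 * foam.thickness_cm / profile.retraction_mm_s
    duration = L4 + TAIL_S
    if duration > cfg.max_duration_s:
        raise ValueError(
            f"simulated duration {duration:.1f} s exceeds the configured "
            f"maximum {cfg.max_duration_s:.1f} s"
        )

    n = int(round(duration * sr))
    waveform = rng.normal(0.0, cfg.noise_sigma, n) if cfg.noise_sigma > 0 else np.zeros(n)

    # initiation pulse: a louder broadband (noise-carried) burst before L1
    m = int(round(INITIATION_PULSE_S * sr))
    env = np.exp(-np.arange(m) / (0.010 * sr))
    pulse = 4.0 * effect.amplitude * env * rng.uniform(-1.0, 1.0, m)
    _add_burst(waveform, pulse, int(round(pulse_t * sr)))

    positions = _event_positions_cm(foam, rng)
    fwd_times = L1 + 10.0 * positions / profile.speed_mm_s
    # same bubbles crossed in reverse order on the way out
    ret_times = L3 + 10.0 * (foam.thickness_cm - positions) / profile.retraction_mm_s
    event_times = np.sort(np.concatenate([fwd_times, ret_times]))
    for t_ev in event_times:
        burst = event_waveform(temperature, effect, sr, rng)
        _add_burst(waveform, burst, int(round(t_ev * sr)))

    return AnnotatedRecording(
        waveform=waveform,
        sample_rate=sr,
        L1=L1,
        L2=L2,
        L3=L3,
        L4=L4,
        temperature_group=float(
            temperature if temperature_group is None else temperature_group
        ),
        measured_temperature=float(temperature),
        true_event_times=event_times,
        recording_id=recording_id,
    )


def _drift_bound(group: float, groups: Sequence[float], max_drift: float) -> float:
    """Cool-down drift bound for a group: larger for hotter groups."""
    lo, hi = min(groups), max(groups)
    if hi == lo:
        return max_drift
    frac = 0.2 + 0.8 * (group - lo) / (hi - lo)
    return max_drift * frac


def generate_dataset(
    cfg: SynthConfig,
    foam: FoamSpec | None = None,
    effect: TemperatureEffect | None = None,
    speed_range_mm_s: tuple[float, float] = (5.0, 10.0),
    motion_time_range_s: tuple[float, float] = (7.0, 12.0),
    profile: InsertionProfile | None = None,
    out_dir: str | Path | None = None,
    return_recordings: bool | None = None,
) -> tuple[list[AnnotatedRecording], pd.DataFrame]:
    """Generate the full grouped dataset and its manifest.

    For every temperature group ``cfg.recordings_per_group`` recordings are
    produced.  The measured temperature is the group value minus a cool-down
    offset drawn uniformly in [0, drift_bound(group)].  Per-recording forward
    speeds are drawn uniformly from ``speed_range_mm_s``; the total L1->L4
    motion time is drawn uniformly from ``motion_time_range_s`` and the
    retraction speed derived from it, so the annotated motion span always
    falls inside the configured range.

    If ``out_dir`` is given, audio (WAV), per-recording annotation JSON and a
    ``manifest.csv`` are written there; ``return_recordings`` then defaults to
    False to keep memory bounded.  Returns ``(recordings, manifest)``.
    """
    from . import io as _io  # local import to avoid a cycle at package init

    if len(cfg.temp_groups) == 0:
        raise ValueError("temp_groups must not be empty")
    foam = foam if foam is not None else FoamSpec(bubble_density=20.0, thickness_cm=3.0)
    effect = effect if effect is not None else TemperatureEffect()
    base_profile = profile if profile is not None else InsertionProfile(speed_mm_s=7.0)
    if return_recordings is None:
        return_recordings = out_dir is None

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    n_total = len(cfg.temp_groups) * cfg.recordings_per_group
    children = ss.spawn(n_total)

    rows: list[dict] = []
    recordings: list[AnnotatedRecording] = []
    idx = 0
    for group in cfg.temp_groups:
        bound = _drift_bound(group, cfg.temp_groups, cfg.within_group_drift_degc)
        for k in range(cfg.recordings_per_group):
            rng = np.random.default_rng(children[idx])
            rec_id = f"rec_{group:04.0f}C_{k:03d}"
            measured = group - rng.uniform(0.0, bound)
            speed = rng.uniform(*speed_range_mm_s)
            forward_s = 10.0 * foam.thickness_cm / speed
            lo = max(motion_time_range_s[0], forward_s + base_profile.dwell_s + 1.0)
            hi = max(motion_time_range_s[1], lo)
            total_motion = rng.uniform(lo, hi)
            retr_s = total_motion - forward_s - base_profile.dwell_s
            retr_speed = 10.0 * foam.thickness_cm / retr_s
            prof = replace(
                base_profile, speed_mm_s=speed, retraction_speed_mm_s=retr_speed
            )
            rec = simulate_insertion(
                foam, prof, measured, effect, cfg, rng,
                recording_id=rec_id, temperature_group=group,
            )
            row = {
                "format_version": _io.FORMAT_VERSION,
                "recording_id": rec_id,
                "temperature_group": group,
                "measured_temperature": measured,
                "L1": rec.L1,
                "L2": rec.L2,
                "L3": rec.L3,
                "L4": rec.L4,
                "speed_mm_s": speed,
                "retraction_speed_mm_s": retr_speed,
                "sample_rate": cfg.sample_rate,
                "n_events": len(rec.true_event_times),
                "seed": cfg.seed,
                "audio_path": "",
                "annotation_path": "",
            }
            if out_path is not None:
                audio_path = out_path / f"{rec_id}.wav"
                ann_path = out_path / f"{rec_id}.json"
                _io.write_wav(audio_path, rec.waveform, cfg.sample_rate)
                ann = dict(row)
                ann["true_event_times"] = rec.true_event_times.tolist()
                ann_path.write_text(json.dumps(ann, indent=1, sort_keys=True))
                row["audio_path"] = audio_path.name
                row["annotation_path"] = ann_path.name
            rows.append(row)
            if return_recordings:
                recordings.append(rec)
            idx += 1

    manifest = pd.DataFrame(
        rows,
        columns=[
            "format_version", "recording_id", "temperature_group",
            "measured_temperature", "L1", "L2", "L3", "L4", "speed_mm_s",
            "retraction_speed_mm_s", "sample_rate", "n_events", "seed",
            "audio_path", "annotation_path",
        ],
    )
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return recordings, manifest
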