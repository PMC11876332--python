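"""Foam calibration: detected peaks per cm versus known bubble density.

The reference foams have a known bubble count per cm, so running the
envelope/threshold detector over insertions into them checks the whole
acquisition-plus-detection chain: the detected peak rate should match the
foam's bubble density, independent of insertion speed.
"""

from __future__ import annotations

import numpy as np

from .peaks import EnvelopeParams, detect_peaks, peak_rate, smooth_envelope
from .synth import FoamSpec, InsertionProfile, SynthConfig, TemperatureEffect, simulate_insertion

__all__ = ["foam_peak_density", "FOAM1_DENSITY", "FOAM2_DENSITY"]

#: Bubbles per cm of the two reference foams.
FOAM1_DENSITY = 20.0
FOAM2_DENSITY = 9.0


def foam_peak_density(
    bubble_density: float,
    n_runs: int = 20,
    seed: int = 0,
    speed_mm_s: float = 7.0,
    thickness_cm: float = 3.0,
    temperature: float = 35.0,
    envelope: EnvelopeParams = EnvelopeParams(),
) -> float:
    """Mean detected peaks/cm over ``n_runs`` seeded simulated insertions.

    Each run simulates a full insertion at the given event density, smooths
    the rectified waveform, applies the mu + sigma threshold, and counts the
    retained peaks inside the forward-motion window [L1, L2].
    """
    foam = FoamSpec(bubble_density=bubble_density, thickness_cm=thickness_cm)
    profile = InsertionProfile(speed_mm_s=speed_mm_s)
    cfg = SynthConfig(seed=seed)
    effect = TemperatureEffect()
    children = np.random.SeedSequence(seed).spawn(n_runs)
    rates = []
    for child in children:
        rng = np.random.default_rng(child)
        rec = simulate_insertion(foam, profile, temperature, effect, cfg, rng)
        env = smooth_envelope(rec.waveform, envelope)
        plist = detect_peaks(env, rec.sample_rate)
        rates.append(peak_rate(plist, (rec.L1, rec.L2), speed_mm_s))
    return float(np.mean(rates))
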