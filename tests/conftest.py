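"""Shared fixtures.

The expensive end-to-end training run (synthetic temperature recovery under
grouped cross-validation) is session-scoped so that the acceptance test and
the evaluation-level property tests share one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from acoustemp import (
    FoamSpec,
    InsertionProfile,
    SynthConfig,
    TemperatureEffect,
    detect_peaks,
    generate_dataset,
    simulate_insertion,
    slice_peak_centered,
    smooth_envelope,
)
from acoustemp.model import TrainConfig, make_folds, train


@pytest.fixture(scope="session")
def quick_profile() -> InsertionProfile:
    """Short pre/approach/dwell phases to keep simulated audio small."""
    return InsertionProfile(speed_mm_s=7.0, pre_roll_s=0.2, approach_s=0.5, dwell_s=0.5)


@pytest.fixture(scope="session")
def small_recording(quick_profile):
    cfg = SynthConfig(seed=11)
    rng = np.random.default_rng(11)
    return simulate_insertion(
        FoamSpec(bubble_density=15.0, thickness_cm=1.0),
        quick_profile,
        35.0,
        TemperatureEffect(),
        cfg,
        rng,
        recording_id="fixture_rec",
    )


@pytest.fixture(scope="session")
def recovery_run(quick_profile):
    """One reduced-budget recovery experiment: 8 temperature groups x 4
    recordings, peak-centered chunks, small CNN, 10 epochs, 5-fold grouped CV.

    Returns (chunks, split, result, label_std).
    """
    cfg = SynthConfig(seed=7, recordings_per_group=4)
    foam = FoamSpec(bubble_density=20.0, thickness_cm=1.0)
    recs, _ = generate_dataset(
        cfg, foam=foam, profile=quick_profile, motion_time_range_s=(2.0, 4.0)
    )
    rng = np.random.default_rng(7)
    chunks = []
    for rec in recs:
        pl = detect_peaks(smooth_envelope(rec.waveform), rec.sample_rate)
        chunks.extend(slice_peak_centered(rec, pl, rng))
    assert len(chunks) >= 600
    labels = np.array([c.label_degc for c in chunks])
    split = make_folds([c.recording_id for c in chunks], n_folds=5, rng=rng)
    result = train(
        chunks,
        split,
        TrainConfig(epochs=10, arch="small", pretrained=False, augmentation=None, seed=7),
    )
    return chunks, split, result, float(labels.std())
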