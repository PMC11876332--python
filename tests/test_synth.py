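"""Synthetic recording generator: events, phase structure, dataset assembly."""

from __future__ import annotations

import filecmp
from pathlib import Path

import numpy as np
import pytest

from acoustemp import (
    FoamSpec,
    InsertionProfile,
    SynthConfig,
    TemperatureEffect,
    event_waveform,
    generate_dataset,
    simulate_insertion,
)


def fft_centroid(burst: np.ndarray, sample_rate: float) -> float:
    """Independent oracle: discrete-Fourier spectral centroid."""
    mag = np.abs(np.fft.rfft(burst))
    freqs = np.fft.rfftfreq(len(burst), 1.0 / sample_rate)
    return float((mag * freqs).sum() / mag.sum())


class TestEventWaveform:
    def test_zero_amplitude_gives_silent_burst(self):
        eff = TemperatureEffect(amplitude=0.0)
        burst = event_waveform(35.0, eff, 48_000, np.random.default_rng(0))
        assert np.all(burst == 0.0)

    def test_centroid_increases_with_temperature(self):
        eff = TemperatureEffect(slope_hz_per_degc=50.0)
        cold = event_waveform(25.0, eff, 48_000, np.random.default_rng(3))
        hot = event_waveform(55.0, eff, 48_000, np.random.default_rng(3))
        assert fft_centroid(hot, 48_000) > fft_centroid(cold, 48_000)

    def test_no_effect_means_temperature_invariant_bursts(self):
        eff = TemperatureEffect(slope_hz_per_degc=0.0, decay_slope_s_per_degc=0.0)
        a = event_waveform(25.0, eff, 48_000, np.random.default_rng(5))
        b = event_waveform(55.0, eff, 48_000, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_decay_is_rejected(self):
        eff = TemperatureEffect(decay_tau_s=0.001, decay_slope_s_per_degc=-0.001)
        with pytest.raises(ValueError, match="decay"):
            event_waveform(50.0, eff, 48_000, np.random.default_rng(0))


class TestSimulateInsertion:
    def test_zero_density_gives_no_events(self, quick_profile):
        rec = simulate_insertion(
            FoamSpec(0.0, 3.0), quick_profile, 30.0, TemperatureEffect(),
            SynthConfig(seed=0), np.random.default_rng(0),
        )
        assert len(rec.true_event_times) == 0
        assert len(rec.forward_event_times()) == 0

    def test_event_count_and_motion_duration(self, quick_profile):
        rec = simulate_insertion(
            FoamSpec(20.0, 3.0), quick_profile, 30.0, TemperatureEffect(),
            SynthConfig(seed=0), np.random.default_rng(1),
        )
        assert len(rec.forward_event_times()) == 60  # round(20 * 3)
        assert rec.L2 - rec.L1 == pytest.approx(30.0 / quick_profile.speed_mm_s)

    def test_event_count_is_speed_invariant(self):
        eff = TemperatureEffect()
        counts = set()
        for speed in (5.0, 7.5, 10.0):
            prof = InsertionProfile(speed_mm_s=speed, pre_roll_s=0.2,
                                    approach_s=0.3, dwell_s=0.3)
            rec = simulate_insertion(
                FoamSpec(13.0, 2.0), prof, 40.0, eff,
                SynthConfig(seed=0), np.random.default_rng(2),
            )
            counts.add(len(rec.forward_event_times()))
        assert counts == {26}  # round(13 * 2), independent of speed

    def test_envelope_shows_phase_structure(self, small_recording):
        """Initiation pulse, quiet approach, active forward motion, quiet
        dwell, active retraction."""
        rec = small_recording
        sr = rec.sample_rate
        x = np.abs(rec.waveform)

        def seg_peak(t0, t1):
            return x[int(t0 * sr) : int(t1 * sr)].max()

        noise = 0.01
        pulse = seg_peak(0.0, rec.L1 - 0.3)          # contains initiation pulse
        approach = seg_peak(rec.L1 - 0.25, rec.L1 - 0.05)
        forward = seg_peak(rec.L1, rec.L2)
        dwell = seg_peak(rec.L2 + 0.05, rec.L3 - 0.05)
        retract = seg_peak(rec.L3, rec.L4)
        assert pulse > 5 * noise
        assert forward > 2 * approach
        assert retract > 2 * dwell
        assert approach < 6 * noise
        assert dwell < 6 * noise

    def test_duration_overflow_is_rejected(self, quick_profile):
        with pytest.raises(ValueError, match="duration"):
            simulate_insertion(
                FoamSpec(5.0, 3.0), quick_profile, 30.0, TemperatureEffect(),
                SynthConfig(seed=0, max_duration_s=3.0), np.random.default_rng(0),
            )


class TestGenerateDataset:
    def test_default_group_structure_yields_176_recordings(self, quick_profile):
        cfg = SynthConfig(seed=3)  # 8 groups x 22 recordings
        _, manifest = generate_dataset(
            cfg, foam=FoamSpec(10.0, 1.0), profile=quick_profile,
            motion_time_range_s=(2.0, 4.0), return_recordings=False,
        )
        assert len(manifest) == 176
        assert manifest["recording_id"].is_unique

    def test_zero_recordings_per_group_gives_empty_manifest(self, tmp_path):
        cfg = SynthConfig(seed=0, recordings_per_group=0)
        recs, manifest = generate_dataset(cfg, out_dir=tmp_path)
        assert len(manifest) == 0 and recs == []
        assert not list(tmp_path.glob("*.wav"))

    def test_empty_temp_groups_is_rejected(self):
        with pytest.raises(ValueError, match="temp_groups"):
            generate_dataset(SynthConfig(seed=0, temp_groups=()))

    def test_same_seed_regenerates_byte_identical_files(self, tmp_path, quick_profile):
        cfg = SynthConfig(seed=42, temp_groups=(25.0, 45.0), recordings_per_group=2)
        kwargs = dict(foam=FoamSpec(10.0, 1.0), profile=quick_profile,
                      motion_time_range_s=(2.0, 4.0))
        a, b = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg, out_dir=a, **kwargs)
        generate_dataset(cfg, out_dir=b, **kwargs)
        names = sorted(p.name for p in a.iterdir())
        assert names == sorted(p.name for p in b.iterdir())
        for name in names:
            assert filecmp.cmp(a / name, b / name, shallow=False), name

    def test_annotation_ordering_and_drift_bounds(self, quick_profile):
        cfg = SynthConfig(seed=9, recordings_per_group=3)
        recs, manifest = generate_dataset(
            cfg, foam=FoamSpec(8.0, 1.0), profile=quick_profile,
            motion_time_range_s=(2.0, 4.0),
        )
        for rec in recs:
            assert 0 < rec.L1 < rec.L2 <= rec.L3 < rec.L4 < rec.duration_s
            offset = rec.temperature_group - rec.measured_temperature
            assert 0.0 <= offset <= 1.4
        # hotter groups may drift more; the configured cap always holds
        assert (manifest["temperature_group"] - manifest["measured_temperature"]).max() <= 1.4

    def test_centroid_of_events_increases_across_groups(self, quick_profile):
        """Group-mean event spectral centroid is strictly increasing in
        temperature when the injected frequency slope is positive."""
        cfg = SynthConfig(seed=21, recordings_per_group=10,
                          temp_groups=(20.0, 30.0, 40.0, 50.0))
        recs, _ = generate_dataset(
            cfg, foam=FoamSpec(10.0, 1.0), profile=quick_profile,
            motion_time_range_s=(2.0, 4.0),
        )
        sr = cfg.sample_rate
        means = []
        for group in cfg.temp_groups:
            cents = []
            for rec in recs:
                if rec.temperature_group != group:
                    continue
                for t in rec.forward_event_times():
                    i = int(t * sr)
                    seg = rec.waveform[i : i + int(0.002 * sr)]
                    mag = np.abs(np.fft.rfft(seg))
                    freqs = np.fft.rfftfreq(len(seg), 1.0 / sr)
                    cents.append((mag * freqs).sum() / mag.sum())
            means.append(np.mean(cents))
        assert np.all(np.diff(means) > 0)
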