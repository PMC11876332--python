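"""Evaluation: RMSE, per-group summary table, violin data, prediction traces.

All quantities derive from held-out-fold predictions only; the group table
mirrors the per-temperature-range comparison of measured versus predicted
means, with absolute deltas summarised over groups (max / min / mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import predict as _predict
from .peaks import PeakList
from .segmentation import Chunk, chunk_length
from .synth import AnnotatedRecording

__all__ = [
    "GroupSummary",
    "rmse",
    "group_table",
    "violin_data",
    "recording_trace",
]


@dataclass(frozen=True)
class GroupSummary:
    group: float
    n: int
    measured_min: float
    measured_max: float
    measured_mean: float
    measured_std: float
    predicted_mean: float
    delta: float  # |measured_mean - predicted_mean|


def rmse(predictions: np.ndarray, truths: np.ndarray) -> float:
    """Root mean squared error, degrees C."""
    p = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("predictions and truths must have equal length")
    if p.size == 0:
        raise ValueError("empty inputs")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def group_table(
    results: pd.DataFrame, group_col: str = "group"
) -> tuple[list[GroupSummary], dict[str, float]]:
    """Per-group comparison of measured and predicted temperatures.

    ``results`` needs columns ``truth``, ``prediction`` and a group column.
    Returns one summary row per group plus overall delta statistics
    (max / min / mean across groups).
    """
    if len(results) == 0:
        raise ValueError("empty results")
    for col in ("truth", "prediction", group_col):
        if col not in results.columns:
            raise ValueError(f"results missing column {col!r}")
    rows = []
    for group, sub in results.groupby(group_col, sort=True):
        measured = sub["truth"].to_numpy(dtype=float)
        predicted = sub["prediction"].to_numpy(dtype=float)
        rows.append(
            GroupSummary(
                group=float(group),
                n=len(sub),
                measured_min=float(measured.min()),
                measured_max=float(measured.max()),
                measured_mean=float(measured.mean()),
                measured_std=float(measured.std()),
                predicted_mean=float(predicted.mean()),
                delta=float(abs(measured.mean() - predicted.mean())),
            )
        )
    deltas = np.array([r.delta for r in rows])
    overall = {
        "delta_max": float(deltas.max()),
        "delta_min": float(deltas.min()),
        "delta_mean": float(deltas.mean()),
    }
    return rows, overall


def violin_data(
    results: pd.DataFrame, group_col: str = "group"
) -> dict[float, dict[str, object]]:
    """Per-group prediction distributions with mean and quartiles.

    Quartiles use linear interpolation between order statistics.
    """
    out: dict[float, dict[str, object]] = {}
    for group, sub in results.groupby(group_col, sort=True):
        preds = np.sort(sub["prediction"].to_numpy(dtype=float))
        if preds.size == 0:
            continue
        out[float(group)] = {
            "predictions": preds,
            "mean": float(preds.mean()),
            "q1": float(np.quantile(preds, 0.25)),
            "q3": float(np.quantile(preds, 0.75)),
        }
    return out


def recording_trace(
    model,
    recording: AnnotatedRecording,
    peaks: PeakList,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-peak temperature predictions along one recording.

    Every retained peak gets a centred (un-jittered) 100 ms chunk and a
    prediction; each point is flagged ``in_motion`` when it lies inside
    [L1, L2].  Out-of-motion points (e.g. the initiation pulse) are kept in
    the trace but must be excluded from recording-level aggregates.
    """
    sr = recording.sample_rate
    w = chunk_length(sr)
    rows = []
    chunks = []
    for peak_idx, t in zip(peaks.indices, peaks.times):
        start = int(peak_idx) - w // 2
        if start < 0 or start + w > len(recording.waveform):
            continue
        chunks.append(
            Chunk(
                samples=recording.waveform[start : start + w],
                recording_id=recording.recording_id,
                center_time=float(t),
                label_degc=recording.measured_temperature,
                source="peak_centered",
                sample_rate=sr,
            )
        )
        rows.append(
            {"time_s": float(t),
             "in_motion": bool(recording.L1 <= t <= recording.L2)}
        )
    if not rows:
        return pd.DataFrame(columns=["time_s", "prediction", "in_motion"])
    preds = _predict(model, chunks)
    df = pd.DataFrame(rows)
    df.insert(1, "prediction", preds)
    return df.sort_values("time_s", ignore_index=True)
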