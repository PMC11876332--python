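"""File I/O: WAV audio, annotation records, manifests, run configuration.

Formats are deliberately plain: RIFF WAV for audio (16-bit PCM or 32-bit
float), one JSON annotation file per recording, a CSV manifest with one row
per recording, and YAML run configuration.  Every file carries a
``format_version``; loaders reject unknown major versions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile
from scipy.signal import resample_poly

from . import __version__

FORMAT_VERSION = "1.0"

__all__ = [
    "FORMAT_VERSION",
    "AnnotationRecord",
    "RunConfig",
    "read_wav",
    "write_wav",
    "write_annotation",
    "load_annotation",
    "load_annotations",
    "load_manifest",
    "load_deposited_layout",
    "write_run_record",
]


def _check_version(version: str, where: str) -> None:
    major = str(version).split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise ValueError(
            f"{where}: unsupported format_version {version!r} "
            f"(this package reads major version {FORMAT_VERSION.split('.')[0]})"
        )


# ---------------------------------------------------------------------------
# WAV


def read_wav(
    path: str | Path,
    expect_sr: int | None = None,
    resample: bool = False,
    channel: int | None = None,
) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 in [-1, 1].

    Multi-channel files require an explicit ``channel`` (the CLI flag
    ``--channel``).  If ``expect_sr`` is given and differs from the file,
    the signal is resampled when ``resample`` is true, otherwise an error
    is raised.
    """
    sr, data = wavfile.read(str(path))
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel file; select a channel with --channel"
            )
        data = data[:, channel]
    if data.dtype == np.int16:
        x = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV encoding {data.dtype}")
    if expect_sr is not None and sr != expect_sr:
        if not resample:
            raise ValueError(
                f"{path}: sample rate {sr} != required {expect_sr}; "
                "pass resample=True (--resample) to convert"
            )
        from math import gcd

        g = gcd(expect_sr, sr)
        x = resample_poly(x, expect_sr // g, sr // g)
        sr = expect_sr
    return x, int(sr)


def write_wav(
    path: str | Path, waveform: np.ndarray, sample_rate: int, encoding: str = "pcm16"
) -> None:
    """Write mono WAV; ``encoding`` is ``pcm16`` or ``float32``."""
    x = np.asarray(waveform, dtype=np.float64)
    if encoding == "pcm16":
        # scale matches read_wav's divisor so int16-representable data
        # round-trips sample-exactly
        q = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(str(path), int(sample_rate), q)
    elif encoding == "float32":
        wavfile.write(str(path), int(sample_rate), x.astype(np.float32))
    else:
        raise ValueError(f"unsupported encoding {encoding!r}")


# ---------------------------------------------------------------------------
# annotations / manifest


@dataclass(frozen=True)
class AnnotationRecord:
    recording_id: str
    audio_path: str
    temperature_group: float
    measured_temperature: float
    L1: float
    L2: float
    L3: float
    L4: float

    def __post_init__(self) -> None:
        if not (0 < self.L1 < self.L2 <= self.L3 < self.L4):
            raise ValueError(
                f"record {self.recording_id!r}: annotations must satisfy "
                f"0 < L1 < L2 <= L3 < L4, got "
                f"{self.L1}, {self.L2}, {self.L3}, {self.L4}"
            )


_REQUIRED_ANN_FIELDS = (
    "recording_id", "temperature_group", "measured_temperature",
    "L1", "L2", "L3", "L4",
)


def write_annotation(path: str | Path, record: AnnotationRecord) -> None:
    payload = {"format_version": FORMAT_VERSION, **asdict(record)}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_annotation(path: str | Path) -> AnnotationRecord:
    raw = json.loads(Path(path).read_text())
    _check_version(raw.get("format_version", FORMAT_VERSION), str(path))
    missing = [f for f in _REQUIRED_ANN_FIELDS if f not in raw]
    if missing:
        raise ValueError(f"{path}: annotation missing fields {missing}")
    return AnnotationRecord(
        recording_id=str(raw["recording_id"]),
        audio_path=str(raw.get("audio_path", "")),
        temperature_group=float(raw["temperature_group"]),
        measured_temperature=float(raw["measured_temperature"]),
        L1=float(raw["L1"]),
        L2=float(raw["L2"]),
        L3=float(raw["L3"]),
        L4=float(raw["L4"]),
    )


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load a manifest CSV and validate its records."""
    df = pd.read_csv(path)
    if "format_version" in df.columns and len(df):
        _check_version(str(df["format_version"].iloc[0]), str(path))
    for _, row in df.iterrows():
        AnnotationRecord(
            recording_id=str(row["recording_id"]),
            audio_path=str(row.get("audio_path", "")),
            temperature_group=float(row["temperature_group"]),
            measured_temperature=float(row["measured_temperature"]),
            L1=float(row["L1"]), L2=float(row["L2"]),
            L3=float(row["L3"]), L4=float(row["L4"]),
        )
    return df


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Load annotation records from a manifest CSV or a directory of JSON."""
    p = Path(path)
    if p.is_dir():
        return [load_annotation(f) for f in sorted(p.glob("*.json"))]
    df = load_manifest(p)
    return [
        AnnotationRecord(
            recording_id=str(row["recording_id"]),
            audio_path=str(row.get("audio_path", "")),
            temperature_group=float(row["temperature_group"]),
            measured_temperature=float(row["measured_temperature"]),
            L1=float(row["L1"]), L2=float(row["L2"]),
            L3=float(row["L3"]), L4=float(row["L4"]),
        )
        for _, row in df.iterrows()
    ]


def load_deposited_layout(root: str | Path) -> pd.DataFrame:
    """Adapter for the published dataset layout.

    The deposited corpus groups recordings in temperature-range folders
    named 20, 25, ..., 55; each audio file is paired with an annotation file
    of the same stem.  Returns an internal-style manifest.  The adapter is
    deliberately isolated here: the published schema may evolve.
    """
    root = Path(root)
    rows = []
    for folder in sorted(root.iterdir() if root.is_dir() else []):
        if not folder.is_dir():
            continue
        try:
            group = float(folder.name)
        except ValueError:
            continue
        if group not in {20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0}:
            continue
        for wav in sorted(folder.glob("*.wav")):
            ann = wav.with_suffix(".json")
            row = {
                "format_version": FORMAT_VERSION,
                "recording_id": f"{folder.name}_{wav.stem}",
                "temperature_group": group,
                "audio_path": str(wav),
                "annotation_path": str(ann) if ann.exists() else "",
            }
            if ann.exists():
                rec = load_annotation(ann)
                row.update(
                    measured_temperature=rec.measured_temperature,
                    L1=rec.L1, L2=rec.L2, L3=rec.L3, L4=rec.L4,
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration / reproducibility record


@dataclass
class RunConfig:
    """All tunable pipeline parameters in one serialisable block."""

    seed: int = 0
    out_dir: str = "runs"
    synth: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        payload = {"format_version": FORMAT_VERSION, **asdict(self)}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        _check_version(raw.pop("format_version", FORMAT_VERSION), str(path))
        return cls(**raw)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


def write_run_record(
    out_dir: str | Path,
    config: dict,
    seed: int,
    inputs: list[str | Path] | None = None,
    extra: dict | None = None,
) -> Path:
    """Write the reproducibility record for a CLI run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {
        "format_version": FORMAT_VERSION,
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "input_checksums": {
            str(p): _checksum(Path(p)) for p in (inputs or []) if Path(p).is_file()
        },
    }
    if extra:
        record.update(extra)
    path = out / "run_record.json"
    path.write_text(json.dumps(record, indent=1, sort_keys=True, default=str))
    return path
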