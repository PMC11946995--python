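"""Sine-sweep excitation and recording I/O.

The measurement protocol excites the spinous process of the instrumented
vertebra with a sine sweep (10--500 Hz, 2.5 s) and captures the structure-borne
response at each screw head with a piezo contact microphone, stored as
lossless mono WAV at 44.1 kHz / 24 bit.  This module generates the excitation
waveform, reads and writes recordings in that capture format, and maintains a
CSV manifest that maps each file to its provenance (specimen, screw, sensor,
condition, sweep index).
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import chirp, periodogram

__all__ = [
    "ExcitationConfig",
    "Recording",
    "DatasetManifest",
    "ConfigurationError",
    "FormatError",
    "ManifestError",
    "generate_sweep",
    "write_recording",
    "read_recording",
    "build_manifest",
    "MANIFEST_COLUMNS",
]

Condition = Literal["fixed", "loose"]

MANIFEST_COLUMNS = [
    "path",
    "specimen_id",
    "screw_id",
    "sensor_id",
    "condition",
    "sweep_index",
]


class ConfigurationError(ValueError):
    """An excitation or pipeline configuration violates its invariants."""


class FormatError(IOError):
    """A file does not conform to the expected capture format."""


class ManifestError(ValueError):
    """A dataset manifest violates its uniqueness/consistency invariants."""


@dataclass(frozen=True)
class ExcitationConfig:
    """Parameters of the standardized sine-sweep excitation.

    Defaults follow the measurement protocol: a 10--500 Hz sweep lasting
    2.5 s, sampled at 44.1 kHz, with a peak amplitude of 0.8 full scale to
    leave headroom for resonant gain in simulated transfer paths.
    """

    f_start: float = 10.0
    f_end: float = 500.0
    duration: float = 2.5
    sample_rate: float = 44100.0
    amplitude: float = 0.8
    method: Literal["linear", "logarithmic"] = "linear"

    def __post_init__(self) -> None:
        if not self.f_start < self.f_end:
            raise ConfigurationError(
                f"f_start ({self.f_start}) must be < f_end ({self.f_end})"
            )
        if self.f_start <= 0:
            raise ConfigurationError(f"f_start must be positive, got {self.f_start}")
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration}")
        if self.sample_rate < 2 * self.f_end:
            raise ConfigurationError(
                f"sample_rate ({self.sample_rate}) below Nyquist for "
                f"f_end={self.f_end}"
            )
        if not 0 < self.amplitude <= 1:
            raise ConfigurationError(
                f"amplitude must be in (0, 1], got {self.amplitude}"
            )
        if self.method not in ("linear", "logarithmic"):
            raise ConfigurationError(f"unknown sweep method {self.method!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass
class RecordingMeta:
    """Provenance of one captured sweep response."""

    specimen_id: int = 0
    screw_id: int = 1
    sensor_id: int = 1
    condition: Condition = "fixed"
    sweep_index: int = 0

    def key(self) -> tuple:
        return (
            self.specimen_id,
            self.screw_id,
            self.sensor_id,
            self.condition,
            self.sweep_index,
        )


@dataclass
class Recording:
    """A single sweep-response waveform with capture metadata.

    ``samples`` is a 1-D float array in [-1, 1]; ``bit_depth`` records the
    quantization used (or intended) on disk.
    """

    samples: np.ndarray
    sample_rate: float
    bit_depth: int = 24
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise FormatError(f"samples must be 1-D, got shape {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples contain non-finite values")
        peak = np.max(np.abs(self.samples)) if self.samples.size else 0.0
        if peak > 1.0 + 1e-9:
            raise FormatError(f"samples exceed full scale (peak {peak:.4f})")
        if self.sample_rate <= 0:
            raise FormatError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.meta.condition not in ("fixed", "loose"):
            raise FormatError(f"unknown condition label {self.meta.condition!r}")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate


def generate_sweep(config: ExcitationConfig | None = None) -> Recording:
    """Generate the standardized sine-sweep excitation waveform.

    Returns a linear (default) or exponential chirp whose instantaneous
    frequency rises monotonically from ``f_start`` to ``f_end`` over
    ``duration`` seconds, with zero initial phase (first sample is 0) and
    peak amplitude ``config.amplitude``.
    """
    config = config or ExcitationConfig()
    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    # phi=-90 turns scipy's cosine convention into a sine starting at zero
    x = chirp(
        t,
        f0=config.f_start,
        t1=config.duration,
        f1=config.f_end,
        method=config.method,
        phi=-90,
    )
    return Recording(samples=config.amplitude * x, sample_rate=config.sample_rate)


def sweep_band_energy_fraction(rec: Recording, above_hz: float = 600.0) -> float:
    """Fraction of periodogram power above ``above_hz`` (leakage check)."""
    f, p = periodogram(rec.samples, fs=rec.sample_rate)
    total = float(np.sum(p))
    if total == 0:
        return 0.0
    return float(np.sum(p[f > above_hz]) / total)


# --- WAV round-trip ---------------------------------------------------------

_INT24_FULL_SCALE = 2**23  # signed 24-bit: [-2^23, 2^23 - 1]


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as mono PCM WAV at the recording's bit depth.

    24-bit files (the capture default) are packed manually; 16- and 32-bit
    integer depths are also supported.
    """
    path = Path(path)
    x = np.clip(rec.samples, -1.0, 1.0)
    rate = int(round(rec.sample_rate))
    if rec.bit_depth == 24:
        q = np.clip(
            np.round(x * _INT24_FULL_SCALE), -_INT24_FULL_SCALE, _INT24_FULL_SCALE - 1
        ).astype(np.int32)
        # little-endian int32 -> drop the high byte to get packed int24
        raw = q.astype("<i4").tobytes()
        frames = b"".join(raw[i : i + 3] for i in range(0, len(raw), 4))
        with wave.open(str(path), "wb") as w:
            w.setnchannels(1)
            w.setsampwidth(3)
            w.setframerate(rate)
            w.writeframes(frames)
    elif rec.bit_depth == 16:
        wavfile.write(path, rate, np.clip(np.round(x * 2**15), -(2**15), 2**15 - 1).astype(np.int16))
    elif rec.bit_depth == 32:
        wavfile.write(path, rate, np.clip(np.round(x * 2**31), -(2**31), 2**31 - 1).astype(np.int32))
    else:
        raise FormatError(f"unsupported bit depth {rec.bit_depth}")
    return path


def read_recording(path: str | Path, meta: RecordingMeta | None = None) -> Recording:
    """Read a mono WAV file back into a float recording in [-1, 1].

    Accepts 16/24/32-bit PCM and 32/64-bit float encodings; any other
    encoding, a non-mono channel layout, or a truncated file raises
    :class:`FormatError`.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise FormatError(
            f"{path}: expected mono, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data / 2**15
        depth = 16
    elif data.dtype == np.int32:
        # scipy widens 24-bit PCM into the high bytes of int32
        with wave.open(str(path), "rb") as w:
            width = w.getsampwidth()
        if width == 3:
            samples = (data >> 8) / _INT24_FULL_SCALE
            depth = 24
        else:
            samples = data / 2**31
            depth = 32
    elif data.dtype in (np.float32, np.float64):
        samples = np.asarray(data, dtype=np.float64)
        depth = 32
    else:
        raise FormatError(f"{path}: unsupported sample encoding {data.dtype}")
    return Recording(
        samples=np.clip(samples, -1.0, 1.0),
        sample_rate=float(rate),
        bit_depth=depth,
        meta=meta or RecordingMeta(),
    )


# --- Manifest ---------------------------------------------------------------


@dataclass
class DatasetManifest:
    """Table of recordings with provenance, one row per WAV file.

    The (specimen, screw, sensor, condition, sweep_index) tuple is unique per
    row.  ``seed`` and ``config_digest`` record how a synthetic dataset was
    generated; both are empty for manifests built from found files.
    """

    rows: pd.DataFrame
    seed: int | None = None
    config_digest: str = ""

    def __post_init__(self) -> None:
        if list(self.rows.columns) != MANIFEST_COLUMNS:
            self.rows = self.rows.reindex(columns=MANIFEST_COLUMNS)
        self._check_unique()

    def _check_unique(self) -> None:
        key_cols = MANIFEST_COLUMNS[1:]
        if len(self.rows) == 0:
            return
        dup = self.rows.duplicated(subset=key_cols, keep=False)
        if dup.any():
            dupes = self.rows.loc[dup, key_cols].to_dict("records")
            raise ManifestError(f"duplicate metadata tuples in manifest: {dupes}")

    def __len__(self) -> int:
        return len(self.rows)

    def meta_for(self, idx: int) -> RecordingMeta:
        r = self.rows.iloc[idx]
        return RecordingMeta(
            specimen_id=int(r.specimen_id),
            screw_id=int(r.screw_id),
            sensor_id=int(r.sensor_id),
            condition=str(r.condition),
            sweep_index=int(r.sweep_index),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            if self.seed is not None:
                fh.write(f"# seed={self.seed}\n")
            if self.config_digest:
                fh.write(f"# config_digest={self.config_digest}\n")
            self.rows.to_csv(fh, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        seed: int | None = None
        digest = ""
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("seed="):
                    seed = int(body.split("=", 1)[1])
                elif body.startswith("config_digest="):
                    digest = body.split("=", 1)[1]
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            rows = pd.read_csv(fh, dtype={"condition": str})
        return cls(rows=rows, seed=seed, config_digest=digest)


def _meta_from_filename(path: Path) -> RecordingMeta | None:
    """Parse ``spec{S}_screw{W}_sensor{N}_{condition}_sweep{I}.wav`` names."""
    stem = path.stem
    parts = stem.split("_")
    if len(parts) != 5:
        return None
    try:
        return RecordingMeta(
            specimen_id=int(parts[0].removeprefix("spec")),
            screw_id=int(parts[1].removeprefix("screw")),
            sensor_id=int(parts[2].removeprefix("sensor")),
            condition=parts[3],
            sweep_index=int(parts[4].removeprefix("sweep")),
        )
    except ValueError:
        return None


def manifest_from_records(
    records: Iterable[tuple[str, RecordingMeta]],
    seed: int | None = None,
    config_digest: str = "",
) -> DatasetManifest:
    rows = pd.DataFrame(
        [
            {
                "path": str(p),
                "specimen_id": m.specimen_id,
                "screw_id": m.screw_id,
                "sensor_id": m.sensor_id,
                "condition": m.condition,
                "sweep_index": m.sweep_index,
            }
            for p, m in records
        ],
        columns=MANIFEST_COLUMNS,
    )
    return DatasetManifest(rows=rows, seed=seed, config_digest=config_digest)


def build_manifest(directory: str | Path) -> DatasetManifest:
    """Scan a directory of WAV files into a manifest.

    Metadata is taken from the sidecar ``manifest.csv`` if present, else
    parsed from the ``spec*_screw*_sensor*_{fixed|loose}_sweep*.wav`` naming
    scheme.  Duplicate metadata tuples raise :class:`ManifestError`.
    """
    directory = Path(directory)
    sidecar = directory / "manifest.csv"
    if sidecar.exists():
        return DatasetManifest.load(sidecar)
    records = []
    for p in sorted(directory.glob("*.wav")):
        meta = _meta_from_filename(p)
        if meta is not None:
            records.append((str(p), meta))
    return manifest_from_records(records)
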