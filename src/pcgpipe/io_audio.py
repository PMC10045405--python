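"""WAV and manifest I/O for phonocardiogram (PCG) corpora.

A corpus is a directory of mono WAV recordings plus a manifest CSV with
columns ``id,path,label`` (label in {normal, abnormal}).  Recordings are
held in memory as float64 arrays scaled to [-1, 1]; multi-channel audio is
averaged down to mono on read.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

LABELS = ("normal", "abnormal")

__all__ = [
    "LABELS",
    "Recording",
    "ManifestEntry",
    "Manifest",
    "read_wav",
    "write_wav",
    "load_manifest",
    "save_manifest",
    "resample",
]


@dataclass(frozen=True)
class Recording:
    """One PCG signal: samples in [-1, 1], its sampling rate, and a label."""

    id: str
    samples: np.ndarray
    sample_rate: int
    label: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError(f"recording {self.id!r}: samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"recording {self.id!r}: samples contain non-finite values")
        if self.sample_rate <= 0:
            raise ValueError(f"recording {self.id!r}: sample_rate must be positive")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"recording {self.id!r}: unknown label {self.label!r}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class ManifestEntry:
    id: str
    path: str
    label: str


@dataclass
class Manifest:
    """Ordered list of (id, path, label) rows describing a corpus."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate manifest ids: {dupes}")
        bad = [e.id for e in self.entries if e.label not in LABELS]
        if bad:
            raise ValueError(f"unknown labels for ids: {bad}")

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.entries]

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    def label_of(self, rec_id: str) -> str:
        for e in self.entries:
            if e.id == rec_id:
                return e.label
        raise KeyError(rec_id)

    def __len__(self) -> int:
        return len(self.entries)


def _to_float(samples: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; pass float data through."""
    if samples.dtype == np.int16:
        return np.maximum(samples.astype(np.float64) / 32767.0, -1.0)
    if samples.dtype == np.int32:
        return np.maximum(samples.astype(np.float64) / 2147483647.0, -1.0)
    if samples.dtype == np.uint8:
        return (samples.astype(np.float64) - 128.0) / 128.0
    return samples.astype(np.float64)


def read_wav(path: str | Path) -> Recording:
    """Read a WAV file as a mono, [-1, 1]-scaled :class:`Recording`.

    Multi-channel files are averaged across channels.  The recording id is
    the file stem; the label is left unset (labels live in the manifest).
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on corrupt files
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path} contains no audio")
    samples = _to_float(np.asarray(data))
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Recording(id=path.stem, samples=samples, sample_rate=int(rate))


def write_wav(path: str | Path, rec: Recording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    path = Path(path)
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, rec.sample_rate, pcm)


def load_manifest(path: str | Path, check_paths: bool = True) -> Manifest:
    """Load a manifest CSV (columns ``id,path,label``, header required).

    Relative paths are resolved against the manifest's directory.  Unknown
    labels, duplicate ids, and (optionally) unresolvable paths raise
    ``ValueError`` naming the offending rows.
    """
    path = Path(path)
    base = path.parent
    entries: list[ManifestEntry] = []
    bad_labels: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "path", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"manifest {path} must have header columns id,path,label")
        for row in reader:
            rec_path = Path(row["path"])
            if not rec_path.is_absolute():
                rec_path = (base / rec_path).resolve()
            if row["label"] not in LABELS:
                bad_labels.append(f"{row['id']} -> {row['label']!r}")
            entries.append(ManifestEntry(id=row["id"], path=str(rec_path), label=row["label"]))
    if bad_labels:
        raise ValueError(f"manifest {path}: unknown labels: {bad_labels}")
    manifest = Manifest(entries=entries)
    if check_paths:
        missing = [e.id for e in manifest.entries if not Path(e.path).exists()]
        if missing:
            raise ValueError(f"manifest {path}: unresolvable paths for ids: {missing}")
    return manifest


def save_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "path", "label"])
        for e in manifest.entries:
            writer.writerow([e.id, e.path, e.label])


def resample(rec: Recording, target_rate: int) -> Recording:
    """Resample to ``target_rate`` Hz by polyphase filtering.

    Duration is preserved to within one sample period of the coarser rate.
    Identity when the rate already matches.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate == rec.sample_rate:
        return rec
    ratio = Fraction(target_rate, rec.sample_rate)
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    n_target = int(round(len(rec.samples) * target_rate / rec.sample_rate))
    if len(out) > n_target:
        out = out[:n_target]
    elif len(out) < n_target:
        out = np.pad(out, (0, n_target - len(out)))
    out = np.clip(out, -1.0, 1.0)
    return replace(rec, samples=out, sample_rate=int(target_rate))
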