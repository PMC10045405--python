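"""Per-recording duration and signal-to-noise statistics.

These two numbers — duration in seconds and an SNR estimate in dB — are the
features all three data-selection procedures consume.  They are computed at
a recording's native rate (both are rate-invariant) without any filtering
or denoising of the waveform.

SNR estimator
-------------
Heart sounds are sparse, high-energy transients (S1/S2 and any murmur) over
a quasi-stationary noise floor, so a single unlabeled recording can be
split into "signal" and "noise" frames by energy alone:

1. frame the waveform (default 25 ms frames, 50% hop) and compute each
   frame's mean power;
2. partition at the median frame power — frames strictly above the median
   are signal-bearing, the rest are noise;
3. signal frames contain signal *plus* noise, so the noise floor is
   subtracted before forming the ratio::

       SNR_dB = 10 * log10((P_signal - P_noise) / P_noise)

The noise-floor subtraction makes the estimate sign-symmetric: a recording
whose transients barely clear the floor scores deeply negative, a clean
recording scores positive, and homogeneous-energy input degenerates to
0 dB by contract.  The estimate is invariant under global amplitude
scaling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np

from .io_audio import Manifest, Recording, read_wav

__all__ = [
    "SignalStats",
    "compute_duration",
    "frame_powers",
    "estimate_snr",
    "stats_table",
    "save_stats",
    "load_stats",
]

# dB ceiling applied when the noise floor underflows (e.g. half-silent input)
_SNR_CAP_DB = 120.0


@dataclass(frozen=True)
class SignalStats:
    id: str
    duration_s: float
    snr_db: float


def compute_duration(rec: Recording) -> float:
    """Recording length in seconds (sample count over sampling rate)."""
    return len(rec.samples) / rec.sample_rate


def frame_powers(
    samples: np.ndarray, sample_rate: int, frame_ms: float = 25.0, hop_ms: float = 12.5
) -> np.ndarray:
    """Mean power of each (possibly overlapping) analysis frame."""
    frame_len = max(1, int(round(sample_rate * frame_ms / 1000.0)))
    hop = max(1, int(round(sample_rate * hop_ms / 1000.0)))
    x = np.asarray(samples, dtype=np.float64)
    if len(x) < frame_len:
        return np.empty(0)
    n_frames = 1 + (len(x) - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    return np.mean(frames * frames, axis=1)


def estimate_snr(
    rec: Recording, frame_ms: float = 25.0, hop_ms: float = 12.5
) -> float:
    """Frame-energy SNR estimate in dB (see module docstring).

    Raises ``ValueError`` if the recording yields fewer than 4 frames.
    Returns exactly 0 dB when every frame has identical power (no
    signal/noise contrast to measure).
    """
    powers = frame_powers(rec.samples, rec.sample_rate, frame_ms, hop_ms)
    if len(powers) < 4:
        raise ValueError(
            f"recording {rec.id!r}: need at least 4 frames for SNR estimation, got {len(powers)}"
        )
    if np.ptp(powers) == 0.0:
        return 0.0
    median = np.median(powers)
    signal = powers[powers > median]
    noise = powers[powers <= median]
    if signal.size == 0:  # ptp > 0 yet nothing above median cannot happen, but be safe
        return 0.0
    p_sig = float(signal.mean())
    p_noise = float(noise.mean())
    excess = p_sig - p_noise
    if excess <= 0.0:
        return 0.0
    if p_noise <= 0.0:
        return _SNR_CAP_DB
    snr = 10.0 * np.log10(excess / p_noise)
    return float(np.clip(snr, -_SNR_CAP_DB, _SNR_CAP_DB))


def stats_table(
    manifest: Manifest,
    reader: Callable[[str], Recording] = read_wav,
    frame_ms: float = 25.0,
    hop_ms: float = 12.5,
) -> list[SignalStats]:
    """One :class:`SignalStats` row per manifest entry, in manifest order."""
    rows: list[SignalStats] = []
    for entry in manifest.entries:
        try:
            rec = reader(entry.path)
        except Exception as exc:
            raise IOError(f"failed to read recording {entry.id!r}: {exc}") from exc
        rows.append(
            SignalStats(
                id=entry.id,
                duration_s=compute_duration(rec),
                snr_db=estimate_snr(rec, frame_ms=frame_ms, hop_ms=hop_ms),
            )
        )
    return rows


def stats_from_recordings(
    recordings: Iterable[Recording], frame_ms: float = 25.0, hop_ms: float = 12.5
) -> list[SignalStats]:
    """Stats for in-memory recordings (no manifest / disk round trip)."""
    return [
        SignalStats(
            id=rec.id,
            duration_s=compute_duration(rec),
            snr_db=estimate_snr(rec, frame_ms=frame_ms, hop_ms=hop_ms),
        )
        for rec in recordings
    ]


def save_stats(stats: list[SignalStats], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "duration_s", "snr_db"])
        for s in stats:
            writer.writerow([s.id, repr(s.duration_s), repr(s.snr_db)])


def load_stats(path: str | Path) -> list[SignalStats]:
    rows: list[SignalStats] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                SignalStats(
                    id=row["id"],
                    duration_s=float(row["duration_s"]),
                    snr_db=float(row["snr_db"]),
                )
            )
    return rows
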