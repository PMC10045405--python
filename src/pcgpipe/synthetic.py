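"""Synthetic phonocardiogram corpora for end-to-end testing.

Each recording is a train of damped-sinusoid S1/S2 bursts (the two valve
sounds, ~40-90 Hz) at a sampled heart rate, plus, for the abnormal class,
a systolic murmur modeled as band-limited (150-400 Hz) noise between S1
and S2.  Broadband Gaussian noise is then added and its gain calibrated by
bisection so that :func:`pcgpipe.signal_stats.estimate_snr` of the final
waveform hits a sampled per-recording target — i.e. SNR is defined against
this package's own estimator, which keeps parameter-recovery tests
well-posed.  Requested SNRs below the estimator's pure-noise floor
saturate there.

Defaults mirror the statistics of the public heart-sound corpus the
pipeline is designed for: class-conditional duration modes near 20 s
(normal) and 35 s (abnormal) with ~4 s spread, per-recording SNR centered
at 0 dB with ~5 dB spread, and the 2000 Hz native sampling rate of that
corpus.  The generator is a test fixture, not a cardiac simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io_audio import Manifest, ManifestEntry, Recording, write_wav
from .signal_stats import estimate_snr

__all__ = [
    "SynthConfig",
    "sample_durations",
    "synth_recording",
    "synth_corrupt_recording",
    "synth_corpus",
    "synth_generate",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the study conditions."""

    n_normal: int = 10
    n_abnormal: int = 10
    heart_rate_bpm: tuple[float, float] = (70.0, 10.0)  # mean, sd
    duration_normal_s: tuple[float, float] = (20.0, 4.0)  # mode, sd
    duration_abnormal_s: tuple[float, float] = (35.0, 4.0)
    snr_normal_db: tuple[float, float] = (0.0, 5.0)  # mean, sd
    snr_abnormal_db: tuple[float, float] = (0.0, 5.0)
    murmur_gain: float = 1.0  # murmur amplitude relative to S1 (prominent murmur)
    sample_rate: int = 2000
    min_duration_s: float = 5.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("counts must be nonnegative")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for pair in (
            self.heart_rate_bpm,
            self.duration_normal_s,
            self.duration_abnormal_s,
            self.snr_normal_db,
            self.snr_abnormal_db,
        ):
            if pair[1] < 0:
                raise ValueError("spreads must be nonnegative")


def _duration_params(cfg: SynthConfig, label: str) -> tuple[float, float]:
    return cfg.duration_normal_s if label == "normal" else cfg.duration_abnormal_s


def _snr_params(cfg: SynthConfig, label: str) -> tuple[float, float]:
    return cfg.snr_normal_db if label == "normal" else cfg.snr_abnormal_db


def sample_durations(cfg: SynthConfig, label: str, n: int, seed=None) -> np.ndarray:
    """Draw n recording durations (s) from the class-conditional Gaussian."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mode, sd = _duration_params(cfg, label)
    return np.maximum(rng.normal(mode, sd, size=n), cfg.min_duration_s)


def _damped_burst(sr: int, freq_hz: float, dur_s: float, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(dur_s * sr))) / sr
    envelope = np.sin(np.pi * np.minimum(t / dur_s, 1.0)) * np.exp(-t / (dur_s / 2.5))
    return envelope * np.sin(2.0 * np.pi * freq_hz * t + phase)


def _bandpass_noise(n: int, sr: int, lo_hz: float, hi_hz: float, rng) -> np.ndarray:
    hi = min(hi_hz, 0.45 * sr)
    lo = min(lo_hz, 0.5 * hi)
    sos = butter(4, [lo, hi], btype="band", fs=sr, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _clean_pcg(
    n: int,
    sr: int,
    rng: np.random.Generator,
    murmur_gain: float,
    heart_rate_bpm: tuple[float, float] = (70.0, 10.0),
) -> np.ndarray:
    """S1/S2 burst train with optional systolic murmur, peak-normalized."""
    bpm = float(np.clip(rng.normal(*heart_rate_bpm), 45.0, 140.0))
    period = 60.0 / bpm
    s1_freq = rng.uniform(40.0, 60.0)
    s2_freq = rng.uniform(60.0, 90.0)
    s1 = _damped_burst(sr, s1_freq, 0.09)
    s2 = 0.8 * _damped_burst(sr, s2_freq, 0.07)
    x = np.zeros(n)
    t0 = 0.05 * period
    while t0 * sr < n:
        jitter = 1.0 + 0.02 * rng.standard_normal()
        i1 = int(round(t0 * sr))
        i2 = int(round((t0 + 0.35 * period) * sr))
        for burst, start in ((s1, i1), (s2, i2)):
            stop = min(start + len(burst), n)
            if start < n:
                x[start:stop] += burst[: stop - start]
        if murmur_gain > 0:
            m_start = i1 + int(round(0.10 * sr))
            m_stop = min(i2 - int(round(0.02 * sr)), n)
            if m_stop - m_start > 50:  # enough samples to band-limit the noise
                noise = _bandpass_noise(m_stop - m_start, sr, 150.0, 400.0, rng)
                env = np.sin(np.pi * np.arange(m_stop - m_start) / (m_stop - m_start))
                x[m_start:m_stop] += murmur_gain * env * noise
        t0 += period * jitter
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _calibrate_noise_gain(
    clean: np.ndarray, noise: np.ndarray, sr: int, target_db: float, rec_id: str
) -> float:
    """Bisection on log-gain so the package SNR estimator hits target_db."""

    def snr_at(gain: float) -> float:
        rec = Recording(id=rec_id, samples=clean + gain * noise, sample_rate=sr)
        return estimate_snr(rec)

    lo, hi = 1e-6, 1e4  # estimator SNR is monotone decreasing in gain
    if snr_at(lo) <= target_db:
        return lo
    if snr_at(hi) >= target_db:
        return hi
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        if snr_at(mid) > target_db:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def synth_recording(
    cfg: SynthConfig,
    label: str,
    seed,
    rec_id: str | None = None,
    duration_s: float | None = None,
    snr_db: float | None = None,
) -> Recording:
    """Generate one labeled recording; fully determined by (cfg, label, seed)."""
    if label not in ("normal", "abnormal"):
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(seed)
    rec_id = rec_id or f"{label}_{seed}"
    if duration_s is None:
        mode, sd = _duration_params(cfg, label)
        duration_s = max(float(rng.normal(mode, sd)), cfg.min_duration_s)
    if snr_db is None:
        mean, sd = _snr_params(cfg, label)
        snr_db = float(rng.normal(mean, sd))
    sr = cfg.sample_rate
    n = int(round(duration_s * sr))
    gain = cfg.murmur_gain if label == "abnormal" else 0.0
    clean = _clean_pcg(n, sr, rng, gain, cfg.heart_rate_bpm)
    noise = rng.standard_normal(n)
    noise /= np.sqrt(np.mean(noise * noise))
    g = _calibrate_noise_gain(clean, noise, sr, snr_db, rec_id)
    x = clean + g * noise
    x *= 0.9 / np.max(np.abs(x))  # estimator is scale-invariant; keep WAV headroom
    return Recording(id=rec_id, samples=x, sample_rate=sr, label=label)


def synth_corrupt_recording(
    cfg: SynthConfig, label: str, seed, rec_id: str | None = None
) -> Recording:
    """A noise-buried recording: heart sounds drowned far below the noise.

    Its estimated SNR saturates at the estimator's pure-noise floor (well
    below 0 dB), so an SNR >= 0 selection provably removes it.  Used to
    model unusable corpus entries.
    """
    rng = np.random.default_rng(seed)
    rec_id = rec_id or f"corrupt_{label}_{seed}"
    mode, sd = _duration_params(cfg, label)
    duration_s = max(float(rng.normal(mode, sd)), cfg.min_duration_s)
    n = int(round(duration_s * cfg.sample_rate))
    clean = _clean_pcg(n, cfg.sample_rate, rng, 0.0, cfg.heart_rate_bpm)
    noise = rng.standard_normal(n)
    noise /= np.sqrt(np.mean(noise * noise))
    x = 0.02 * clean + noise
    x *= 0.9 / np.max(np.abs(x))
    return Recording(id=rec_id, samples=x, sample_rate=cfg.sample_rate, label=label)


def synth_corpus(cfg: SynthConfig, n_corrupt_normal: int = 0, n_corrupt_abnormal: int = 0) -> list[Recording]:
    """Generate an in-memory corpus (optionally with corrupt injections)."""
    recs: list[Recording] = []
    counter = 0
    for label, count in (("normal", cfg.n_normal), ("abnormal", cfg.n_abnormal)):
        for i in range(count):
            recs.append(
                synth_recording(cfg, label, seed=(cfg.seed, counter), rec_id=f"{label}_{i:04d}")
            )
            counter += 1
    for label, count in (("normal", n_corrupt_normal), ("abnormal", n_corrupt_abnormal)):
        for i in range(count):
            recs.append(
                synth_corrupt_recording(
                    cfg, label, seed=(cfg.seed, counter), rec_id=f"corrupt_{label}_{i:04d}"
                )
            )
            counter += 1
    return recs


def synth_generate(cfg: SynthConfig, out_dir: str | Path) -> Manifest:
    """Write a synthetic corpus (WAVs + ``manifest.csv``) under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    relative: list[ManifestEntry] = []
    for rec in synth_corpus(cfg):
        name = f"{rec.id}.wav"
        write_wav(out_dir / name, rec)
        entries.append(ManifestEntry(id=rec.id, path=str(out_dir / name), label=rec.label))
        relative.append(ManifestEntry(id=rec.id, path=name, label=rec.label))
    from .io_audio import save_manifest

    # CSV paths are relative to the manifest's own directory (portable)
    save_manifest(Manifest(entries=relative), out_dir / "manifest.csv")
    return Manifest(entries=entries)
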