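"""Log-mel spectrogram images for the CNN classifier.

Pipeline: resample to the pipeline rate (default 44,100 Hz), frame the
signal (FFT window 1024, hop 512, Hann window, left-aligned frames), take
the power spectrum, project through a triangular mel filter bank (128
bands, HTK mel scale), convert to dB relative to the global maximum with a
-80 dB floor, and render the grid as an axis-free 640x480 RGB raster (time
on x, mel band on y, low frequencies at the bottom, "magma" colormap).

An optional MFCC variant applies a DCT-II across the mel axis after the
log step.  No heart-cycle segmentation of any kind is performed — feeding
whole-recording images to the classifier is the point of the pipeline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from matplotlib import colormaps
from PIL import Image
from scipy.fft import dct, rfft

from .io_audio import Manifest, Recording, read_wav, resample

__all__ = [
    "MelSpectrogram",
    "SpectrogramImage",
    "mel_filterbank",
    "mel_spectrogram",
    "mfcc",
    "render_image",
    "batch_render",
    "PIPELINE_RATE",
]

PIPELINE_RATE = 44100
DB_FLOOR = -80.0


@dataclass(frozen=True)
class MelSpectrogram:
    """dB-scaled mel power grid, shape (n_mels, n_frames)."""

    values_db: np.ndarray
    n_fft: int
    hop: int
    n_mels: int
    sample_rate: int

    @property
    def n_frames(self) -> int:
        return self.values_db.shape[1]


@dataclass(frozen=True)
class SpectrogramImage:
    """8-bit RGB raster (height, width, 3) with no axes or margins."""

    pixels: np.ndarray
    colormap: str
    source_id: str

    @property
    def size(self) -> tuple[int, int]:  # (width, height)
        return self.pixels.shape[1], self.pixels.shape[0]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(sample_rate: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular unit-peak filters, shape (n_mels, 1 + n_fft // 2)."""
    n_bins = 1 + n_fft // 2
    freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    edges_mel = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2.0), n_mels + 2)
    edges_hz = mel_to_hz(edges_mel)
    bank = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, center, hi = edges_hz[m], edges_hz[m + 1], edges_hz[m + 2]
        rising = (freqs - lo) / max(center - lo, 1e-12)
        falling = (hi - freqs) / max(hi - center, 1e-12)
        bank[m] = np.clip(np.minimum(rising, falling), 0.0, 1.0)
    return bank


def band_center_hz(sample_rate: int, n_mels: int, band: int) -> float:
    """Center frequency of one mel band (for tests and tooling)."""
    edges = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2.0), n_mels + 2)
    return float(mel_to_hz(edges[band + 1]))


def _frame(x: np.ndarray, n_fft: int, hop: int) -> np.ndarray:
    # left-aligned frames: count is exactly 1 + (len - n_fft) // hop
    return sliding_window_view(x, n_fft)[::hop]


def mel_spectrogram(
    rec: Recording, n_fft: int = 1024, hop: int = 512, n_mels: int = 128
) -> MelSpectrogram:
    """Log-mel power spectrogram in dB relative to the grid maximum.

    Frame count is exactly ``1 + (len(samples) - n_fft) // hop``.  Digital
    silence maps to a uniform -80 dB grid; scaling the waveform by any
    positive constant leaves the grid unchanged (max-referenced dB).
    """
    x = rec.samples
    if len(x) < n_fft:
        raise ValueError(
            f"recording {rec.id!r} too short for n_fft={n_fft} ({len(x)} samples)"
        )
    frames = _frame(x, n_fft, hop) * np.hanning(n_fft)[None, :]
    spectrum = rfft(frames, axis=1)
    power = (spectrum.real**2 + spectrum.imag**2).T  # (n_bins, n_frames)
    mel_power = mel_filterbank(rec.sample_rate, n_fft, n_mels) @ power
    ref = mel_power.max()
    if ref <= 0.0:
        values_db = np.full(mel_power.shape, DB_FLOOR)
    else:
        values_db = 10.0 * np.log10(np.maximum(mel_power / ref, 10.0 ** (DB_FLOOR / 10.0)))
    return MelSpectrogram(
        values_db=values_db, n_fft=n_fft, hop=hop, n_mels=n_mels, sample_rate=rec.sample_rate
    )


def mfcc(ms: MelSpectrogram, n_mfcc: int = 20) -> np.ndarray:
    """Mel-frequency cepstral coefficients: DCT-II across the mel axis."""
    return dct(ms.values_db, type=2, axis=0, norm="ortho")[:n_mfcc]


def _interp_axis(grid: np.ndarray, n_out: int, axis: int) -> np.ndarray:
    n_in = grid.shape[axis]
    if n_in == 1:
        return np.repeat(grid, n_out, axis=axis)
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    w = pos - lo
    a = np.take(grid, lo, axis=axis)
    b = np.take(grid, hi, axis=axis)
    shape = [1, 1]
    shape[axis] = n_out
    w = w.reshape(shape)
    return a * (1.0 - w) + b * w


def _resize_bilinear(grid: np.ndarray, height: int, width: int) -> np.ndarray:
    return _interp_axis(_interp_axis(grid, width, axis=1), height, axis=0)


def render_image(
    ms: MelSpectrogram,
    width: int = 640,
    height: int = 480,
    colormap: str = "magma",
    source_id: str = "",
) -> SpectrogramImage:
    """Render the dB grid to an exact width x height RGB raster.

    The dB scale is mapped onto the colormap over the fixed [-80, 0] range
    (deterministic bytes for identical input), and the grid is flipped so
    low mel bands sit at the bottom of the image.
    """
    if ms.values_db.size == 0:
        raise ValueError("empty spectrogram grid")
    resized = _resize_bilinear(ms.values_db, height, width)
    normalized = np.clip((resized - DB_FLOOR) / (0.0 - DB_FLOOR), 0.0, 1.0)
    rgba = colormaps[colormap](normalized)
    pixels = (rgba[::-1, :, :3] * 255.0 + 0.5).astype(np.uint8)
    return SpectrogramImage(pixels=pixels, colormap=colormap, source_id=source_id)


def recording_to_image(
    rec: Recording,
    pipeline_rate: int = PIPELINE_RATE,
    n_fft: int = 1024,
    hop: int = 512,
    n_mels: int = 128,
    width: int = 640,
    height: int = 480,
    colormap: str = "magma",
) -> SpectrogramImage:
    """Full per-recording imaging step: resample -> log-mel -> raster."""
    ms = mel_spectrogram(resample(rec, pipeline_rate), n_fft=n_fft, hop=hop, n_mels=n_mels)
    return render_image(ms, width=width, height=height, colormap=colormap, source_id=rec.id)


def batch_render(
    manifest: Manifest,
    out_dir: str | Path,
    pipeline_rate: int = PIPELINE_RATE,
    **render_kwargs,
) -> list[dict]:
    """Render one PNG per manifest recording; returns the image manifest.

    Also writes ``images.csv`` (columns id, image_path, label) in out_dir.
    Per-file failures abort with the offending id in the error message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for entry in manifest.entries:
        try:
            rec = read_wav(entry.path)
            img = recording_to_image(rec, pipeline_rate=pipeline_rate, **render_kwargs)
        except Exception as exc:
            raise RuntimeError(f"failed to render recording {entry.id!r}: {exc}") from exc
        path = out_dir / f"{entry.id}.png"
        Image.fromarray(img.pixels).save(path)
        rows.append({"id": entry.id, "image_path": str(path), "label": entry.label})
    with open(out_dir / "images.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "image_path", "label"])
        writer.writeheader()
        writer.writerows(rows)
    return rows
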