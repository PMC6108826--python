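"""Audio preprocessing: cochleagrams and clip extraction.

A waveform becomes a 32-channel 'cochleagram': power spectrogram with
10 ms Hamming windows hopping by 5 ms, aggregation into 32 channels by
triangular windows (1/3-octave base width) whose centers run
geometrically from 500 Hz to 17,827 Hz, per-band division by the
training-set median, and compressive hill scaling h(x) = cx/(1+cx)
with c = 0.02, emulating auditory-nerve intensity compression. The
cochleagram is then sliced into overlapping 43-step clips.

The 32 centers are placed geometrically so both printed endpoints are
hit exactly; the implied step is log2(17827/500)/31 ~ 0.16632 octaves
(nominally 1/6 octave).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "SpectrogramConfig",
    "FilterbankConfig",
    "HillConfig",
    "Cochleagram",
    "power_spectrogram",
    "filterbank_centers",
    "triangular_filterbank",
    "hill_compress",
    "cochleagram",
    "clip_cochleagram",
]

MEDIAN_FLOOR = 1e-12


@dataclass
class SpectrogramConfig:
    """Short-time power-spectrogram framing (seconds)."""

    window: float = 0.010
    hop: float = 0.005
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if self.hop > self.window:
            raise ValueError("hop must not exceed window")
        if self.window <= 0 or self.hop <= 0:
            raise ValueError("window and hop must be positive")


@dataclass
class FilterbankConfig:
    """Triangular log-frequency filterbank geometry."""

    n_channels: int = 32
    f_low: float = 500.0
    f_high: float = 17827.0
    base_width_octaves: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError("need 0 < f_low < f_high")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")


@dataclass
class HillConfig:
    """Hill compression h(x) = c*x / (1 + c*x)."""

    c: float = 0.02

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")


@dataclass
class Cochleagram:
    values: np.ndarray  # [T x n_channels]
    hop: float  # seconds per time step
    channel_centers: np.ndarray  # Hz

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("cochleagram must be [T x channels] with T >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cochleagram values must be finite")


def power_spectrogram(
    wave: np.ndarray, cfg: SpectrogramConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-windowed power spectrogram.

    Returns (power [T x n_bins], fft_freqs). The frame count is
    floor((N - window_samples)/hop_samples) + 1.
    """
    cfg = cfg or SpectrogramConfig()
    wave = np.asarray(wave, dtype=float)
    win = int(round(cfg.window * cfg.sample_rate))
    hop = int(round(cfg.hop * cfg.sample_rate))
    if wave.size < win:
        raise ValueError("waveform shorter than one analysis window")
    frames = np.lib.stride_tricks.sliding_window_view(wave, win)[::hop]
    spectrum = np.fft.rfft(frames * np.hamming(win), axis=1)
    freqs = np.fft.rfftfreq(win, d=1.0 / cfg.sample_rate)
    return np.abs(spectrum) ** 2, freqs


def filterbank_centers(cfg: FilterbankConfig) -> np.ndarray:
    """Geometrically spaced center frequencies hitting both endpoints."""
    return np.geomspace(cfg.f_low, cfg.f_high, cfg.n_channels)


def triangular_filterbank(cfg: FilterbankConfig, fft_freqs: np.ndarray) -> np.ndarray:
    """Weight matrix [n_fft_bins x n_channels] of log-axis triangles.

    Each triangle is symmetric on the log2-frequency axis with
    half-width base_width/2 octaves each side, interpolated onto the
    FFT bins and normalized to unit column sum.
    """
    cfg = cfg or FilterbankConfig()
    fft_freqs = np.asarray(fft_freqs, dtype=float)
    half = cfg.base_width_octaves / 2.0
    if fft_freqs.max() < cfg.f_high * 2**half or fft_freqs[fft_freqs > 0].min() > cfg.f_low * 2**-half:
        raise ValueError("FFT frequency axis does not cover the filterbank range")
    centers = filterbank_centers(cfg)
    with np.errstate(divide="ignore"):
        log_f = np.log2(fft_freqs, out=np.full_like(fft_freqs, -np.inf), where=fft_freqs > 0)
    weights = np.zeros((fft_freqs.size, cfg.n_channels))
    for k, fc in enumerate(centers):
        dist = np.abs(log_f - np.log2(fc))
        tri = np.clip(1.0 - dist / half, 0.0, None)
        total = tri.sum()
        if total <= 0:
            raise ValueError("FFT resolution too coarse for a filterbank channel")
        weights[:, k] = tri / total
    return weights


def hill_compress(x: np.ndarray | float, cfg: HillConfig | None = None) -> np.ndarray | float:
    """Compressive hill function; maps [0, inf) monotonically onto [0, 1)."""
    cfg = cfg or HillConfig()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill_compress requires nonnegative input")
    out = cfg.c * x / (1.0 + cfg.c * x)
    return out if out.ndim else float(out)


def cochleagram(
    wave: np.ndarray,
    spec_cfg: SpectrogramConfig | None = None,
    bank_cfg: FilterbankConfig | None = None,
    hill_cfg: HillConfig | None = None,
    band_medians: np.ndarray | None = None,
) -> Cochleagram:
    """Full pipeline: spectrogram -> filterbank -> median norm -> hill.

    ``band_medians`` lets a training-set median be reused for held-out
    material; by default medians come from this waveform. Medians below
    1e-12 (silent bands) are clamped to avoid division by zero.
    """
    spec_cfg = spec_cfg or SpectrogramConfig()
    bank_cfg = bank_cfg or FilterbankConfig()
    hill_cfg = hill_cfg or HillConfig()
    power, freqs = power_spectrogram(wave, spec_cfg)
    weights = triangular_filterbank(bank_cfg, freqs)
    bands = power @ weights
    if band_medians is None:
        band_medians = np.median(bands, axis=0)
    band_medians = np.asarray(band_medians, dtype=float).copy()
    silent = band_medians < MEDIAN_FLOOR
    if np.any(silent):
        log.warning("%d silent band medians clamped to %g", int(silent.sum()), MEDIAN_FLOOR)
        band_medians[silent] = MEDIAN_FLOOR
    values = hill_compress(bands / band_medians, hill_cfg)
    return Cochleagram(values=values, hop=spec_cfg.hop, channel_centers=filterbank_centers(bank_cfg))


def clip_cochleagram(
    coch: Cochleagram | np.ndarray, clip_length: int = 43, stride: int = 1
) -> np.ndarray:
    """Slice into overlapping [clip_length x n_channels] clips.

    Returns [n_clips x clip_length x n_channels]; empty (with warning)
    when the cochleagram is shorter than one clip.
    """
    values = coch.values if isinstance(coch, Cochleagram) else np.asarray(coch, dtype=float)
    t, n_ch = values.shape
    if t < clip_length:
        log.warning("cochleagram of %d steps shorter than clip_length %d", t, clip_length)
        return np.empty((0, clip_length, n_ch))
    starts = range(0, t - clip_length + 1, stride)
    return np.stack([values[s : s + clip_length] for s in starts])
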