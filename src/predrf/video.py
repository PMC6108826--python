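"""Video preprocessing: crop, band-pass whitening, downsampling, patch clips.

Raw grayscale movies are square-cropped, band-pass filtered in the
frequency domain (whitening ramp with a smooth high-frequency roll-off),
bilinearly downsampled to 180 x 180, cut into non-overlapping 20 x 20
patches from the central region, and sliced into overlapping 8-frame
clips. The whole frontend is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "WhitenConfig",
    "PatchConfig",
    "square_crop",
    "bandpass_whiten",
    "downsample_movie",
    "extract_patch_clips",
    "preprocess_movie",
]


@dataclass
class WhitenConfig:
    """Band-pass whitening filter R(f) = f * exp(-(f/f0)**exponent).

    Gain is zero at DC, rises proportionally to radial spatial frequency
    (whitening the ~1/f amplitude spectrum of natural scenes), then rolls
    off smoothly above the corner frequency ``f0``.

    Parameters
    ----------
    f0
        Corner frequency in cycles/pixel; default 0.4 x Nyquist = 0.2.
    exponent
        Roll-off steepness (default quartic).
    """

    f0: float = 0.4 * 0.5
    exponent: int = 4

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")


@dataclass
class PatchConfig:
    """Spatial patching and temporal clipping geometry."""

    frame_size: int = 180
    patch_size: int = 20
    central_region: int = 100
    clip_length: int = 8
    clip_stride: int = 1

    def __post_init__(self) -> None:
        if self.central_region % self.patch_size != 0:
            raise ValueError("central_region must be divisible by patch_size")
        if self.clip_length < 2:
            raise ValueError("clip_length must be >= 2")
        if self.clip_stride < 1:
            raise ValueError("clip_stride must be >= 1")


def square_crop(movie: np.ndarray) -> np.ndarray:
    """Centered square crop along the longer spatial dimension."""
    movie = np.asarray(movie)
    t, h, w = movie.shape
    side = min(h, w)
    y0 = (h - side) // 2
    x0 = (w - side) // 2
    return movie[:, y0 : y0 + side, x0 : x0 + side]


def whitening_gain(shape: tuple[int, int], cfg: WhitenConfig) -> np.ndarray:
    """Transfer function on the FFT grid (cycles/pixel radial frequency)."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    return f * np.exp(-((f / cfg.f0) ** cfg.exponent))


def bandpass_whiten(frame: np.ndarray, cfg: WhitenConfig | None = None) -> np.ndarray:
    """Apply the whitening band-pass filter to one square frame."""
    cfg = cfg or WhitenConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] != frame.shape[1]:
        raise ValueError("bandpass_whiten expects a square 2D frame")
    gain = whitening_gain(frame.shape, cfg)
    return np.fft.ifft2(np.fft.fft2(frame) * gain).real


def downsample_movie(movie: np.ndarray, target: int) -> np.ndarray:
    """Bilinear per-frame downsampling to target x target pixels.

    Sampling is cell-centered: target pixel centers are placed at
    (i + 0.5) * side/target - 0.5 in source coordinates, which makes
    target == source an exact identity and averages evenly when
    collapsing blocks.
    """
    movie = np.asarray(movie, dtype=float)
    single = movie.ndim == 2
    if single:
        movie = movie[None]
    t, h, w = movie.shape
    if target > h or target > w:
        raise ValueError("downsample_movie cannot upsample")
    cy = (np.arange(target) + 0.5) * h / target - 0.5
    cx = (np.arange(target) + 0.5) * w / target - 0.5
    yy, xx = np.meshgrid(cy, cx, indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()])
    out = np.empty((t, target, target))
    for i in range(t):
        out[i] = ndimage.map_coordinates(
            movie[i], coords, order=1, mode="nearest"
        ).reshape(target, target)
    return out[0] if single else out


def extract_patch_clips(movie: np.ndarray, cfg: PatchConfig | None = None) -> np.ndarray:
    """Cut a movie into overlapping clips of non-overlapping central patches.

    Returns an array [n_clips x clip_length x patch x patch]; patches
    tile the central region, and temporal windows advance by
    ``clip_stride`` frames. An empty array is returned (with a warning)
    if the movie is shorter than one clip.
    """
    cfg = cfg or PatchConfig()
    movie = np.asarray(movie, dtype=float)
    t, h, w = movie.shape
    if h < cfg.central_region or w < cfg.central_region:
        raise ValueError("movie smaller than the central region")
    if t < cfg.clip_length:
        log.warning("movie of %d frames shorter than clip_length %d", t, cfg.clip_length)
        return np.empty((0, cfg.clip_length, cfg.patch_size, cfg.patch_size))
    y0 = (h - cfg.central_region) // 2
    x0 = (w - cfg.central_region) // 2
    central = movie[:, y0 : y0 + cfg.central_region, x0 : x0 + cfg.central_region]
    n_grid = cfg.central_region // cfg.patch_size
    starts = range(0, t - cfg.clip_length + 1, cfg.clip_stride)
    clips = []
    for gy in range(n_grid):
        for gx in range(n_grid):
            patch = central[
                :,
                gy * cfg.patch_size : (gy + 1) * cfg.patch_size,
                gx * cfg.patch_size : (gx + 1) * cfg.patch_size,
            ]
            for s in starts:
                clips.append(patch[s : s + cfg.clip_length])
    return np.asarray(clips)


def preprocess_movie(
    movie: np.ndarray,
    whiten_cfg: WhitenConfig | None = None,
    patch_cfg: PatchConfig | None = None,
) -> np.ndarray:
    """Full frontend: square crop, whiten each frame, downsample, patch/clip."""
    whiten_cfg = whiten_cfg or WhitenConfig()
    patch_cfg = patch_cfg or PatchConfig()
    movie = square_crop(np.asarray(movie, dtype=float))
    whitened = np.stack([bandpass_whiten(frame, whiten_cfg) for frame in movie])
    side = whitened.shape[1]
    target = min(patch_cfg.frame_size, side)
    if target < side:
        whitened = downsample_movie(whitened, target)
    return extract_patch_clips(whitened, patch_cfg)
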