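"""Clip datasets: normalization, noise augmentation, past/future splitting.

A :class:`ClipDataset` holds N clips of shape [clip_length x feature
dims] from either domain (visual: 8 x 20 x 20 frames; auditory: 43 x 32
cochleagram steps). Datasets are z-scored globally with training-set
statistics, optionally corrupted with seeded Gaussian noise at a fixed
SNR, and split into flattened past (U) / future (V) design matrices.

Flattening convention: index i runs time step slowest, then row (or
frequency channel), then column — i.e. C-order over [time, *features].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

__all__ = [
    "ClipDataset",
    "PastFuturePair",
    "NoiseConfig",
    "normalize_dataset",
    "add_gaussian_noise",
    "split_past_future",
    "train_val_split",
    "save_dataset",
    "load_dataset",
]


@dataclass
class ClipDataset:
    """N stimulus clips with normalization stats and a past/future split."""

    clips: np.ndarray  # [N x clip_length x *feature_dims]
    domain: str  # "visual" | "auditory"
    norm_stats: tuple[float, float] | None = None  # (mean, sd) from training data
    split_spec: tuple[int, int] | None = None  # (n_past, n_future)

    def __post_init__(self) -> None:
        self.clips = np.asarray(self.clips, dtype=float)
        if self.clips.ndim < 3:
            raise ValueError("clips must be [N x clip_length x features...]")
        if self.domain not in ("visual", "auditory"):
            raise ValueError("domain must be 'visual' or 'auditory'")
        if self.split_spec is None:
            length = self.clips.shape[1]
            self.split_spec = (length - 1, 1) if self.domain == "visual" else (length - 3, 3)
        n_past, n_future = self.split_spec
        if n_past + n_future != self.clips.shape[1]:
            raise ValueError("split_spec must sum to clip_length")

    @property
    def n_clips(self) -> int:
        return self.clips.shape[0]

    @property
    def clip_length(self) -> int:
        return self.clips.shape[1]


@dataclass
class PastFuturePair:
    """Flattened past inputs U [N x I] and true futures V [N x K]."""

    U: np.ndarray
    V: np.ndarray
    feature_shape: tuple[int, ...]
    n_past: int
    n_future: int

    @property
    def I(self) -> int:  # noqa: E743 - established symbol for input dimension
        return self.U.shape[1]

    @property
    def K(self) -> int:
        return self.V.shape[1]


@dataclass
class NoiseConfig:
    """Additive Gaussian input noise at a fixed signal-to-noise ratio."""

    snr_db: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must not be NaN")


def normalize_dataset(
    ds: ClipDataset, stats: tuple[float, float] | None = None
) -> ClipDataset:
    """Z-score over all pixels/bands, frames and clips.

    With ``stats`` given (the training set's mean and sd), that
    transform is applied unchanged — the way a validation set must be
    scaled. Otherwise stats are computed from ``ds`` itself.
    """
    if stats is None:
        mean = float(ds.clips.mean())
        sd = float(ds.clips.std())
        if sd == 0:
            raise ValueError("cannot normalize a constant dataset (zero variance)")
    else:
        mean, sd = stats
        if sd <= 0:
            raise ValueError("normalization sd must be positive")
    return replace(ds, clips=(ds.clips - mean) / sd, norm_stats=(mean, sd))


def add_gaussian_noise(ds: ClipDataset, cfg: NoiseConfig | None = None) -> ClipDataset:
    """Add i.i.d. Gaussian noise at ``snr_db`` relative to unit signal variance.

    The dataset is assumed z-scored (signal variance 1), so the noise
    variance is 10**(-snr_db/10). ``snr_db = inf`` is a no-op sentinel.
    """
    cfg = cfg or NoiseConfig()
    if np.isinf(cfg.snr_db) and cfg.snr_db > 0:
        return ds
    noise_sd = float(np.sqrt(10.0 ** (-cfg.snr_db / 10.0)))
    rng = np.random.default_rng(cfg.seed)
    noisy = ds.clips + rng.normal(0.0, noise_sd, size=ds.clips.shape)
    return replace(ds, clips=noisy)


def split_past_future(ds: ClipDataset) -> PastFuturePair:
    """Flatten the first n_past steps into U and the rest into V.

    At the standard geometries this gives I = 2800 / K = 400
    (visual, 7+1 frames of 20 x 20) and I = 1280 / K = 96 (auditory,
    40+3 steps of 32 channels).
    """
    n_past, n_future = ds.split_spec
    n = ds.n_clips
    past = ds.clips[:, :n_past]
    future = ds.clips[:, n_past:]
    return PastFuturePair(
        U=past.reshape(n, -1),
        V=future.reshape(n, -1),
        feature_shape=ds.clips.shape[2:],
        n_past=n_past,
        n_future=n_future,
    )


def unflatten(flat: np.ndarray, n_steps: int, feature_shape: tuple[int, ...]) -> np.ndarray:
    """Invert the past/future flattening for one or many rows."""
    flat = np.asarray(flat)
    lead = flat.shape[:-1]
    return flat.reshape(*lead, n_steps, *feature_shape)


def train_val_split(
    ds: ClipDataset, val_fraction: float = 0.2, seed: int = 0
) -> tuple[ClipDataset, ClipDataset]:
    """Random, seeded, disjoint and exhaustive train/validation partition."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ds.n_clips)
    n_val = int(round(val_fraction * ds.n_clips))
    val_idx = np.sort(order[:n_val])
    train_idx = np.sort(order[n_val:])
    return (
        replace(ds, clips=ds.clips[train_idx]),
        replace(ds, clips=ds.clips[val_idx]),
    )


def save_dataset(path: str, ds: ClipDataset) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("clips", data=ds.clips.astype(np.float32))
        dset.attrs["domain"] = ds.domain
        dset.attrs["split_spec"] = ds.split_spec
        if ds.norm_stats is not None:
            dset.attrs["norm_stats"] = ds.norm_stats


def load_dataset(path: str) -> ClipDataset:
    with h5py.File(path, "r") as f:
        dset = f["clips"]
        stats = dset.attrs.get("norm_stats")
        return ClipDataset(
            clips=dset[...].astype(float),
            domain=str(dset.attrs["domain"]),
            norm_stats=tuple(stats) if stats is not None else None,
            split_spec=tuple(int(x) for x in dset.attrs["split_spec"]),
        )
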