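"""End-to-end experiment orchestration.

An :class:`ExperimentConfig` (loadable from YAML) describes one run:
generate or load stimuli, preprocess through the domain frontend, train
a (J, lambda) grid of prediction networks, analyze receptive fields,
and compare span distributions against a reference population. All
artifacts (HDF5 datasets and parameters, CSV metric tables, a JSON
manifest, a log) land in one output directory; a master seed derives
every child seed, so reruns are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sp_stats

from . import audio, data, gabor, network, strf, synth, video

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "child_seed",
    "run_experiment",
    "prediction_similarity_correlation",
]


def child_seed(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed: crc32 of (master, stage, index)."""
    token = f"{master}:{stage}:{index}".encode()
    return zlib.crc32(token) % (2**31)


@dataclass
class ExperimentConfig:
    """One experiment: domain, generation, grid, analysis toggles."""

    domain: str = "visual"
    out_dir: str = "predrf_run"
    master_seed: int = 0
    # synthetic stimulus generation (visual)
    n_movies: int = 4
    movie_frames: int = 96
    movie_size: int = 64
    patch_size: int = 12
    clip_length: int = 8
    # synthetic stimulus generation (auditory)
    audio_duration: float = 20.0
    audio_clip_length: int = 43
    # dataset handling
    val_fraction: float = 0.2
    snr_db: float = 6.0
    max_clips: int | None = 40_000
    # training grid
    n_hidden_list: list[int] = field(default_factory=lambda: [64])
    lam_list: list[float] = field(default_factory=lambda: [1e-4])
    epochs: int = 40
    batch_size: int = 200
    nonlinearity: str = "logistic"
    # analysis
    analyze: bool = True
    reference_population: str | None = None  # path to an HDF5 [n x F x T] stack

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=False)


def _generate_visual_dataset(cfg: ExperimentConfig) -> data.ClipDataset:
    patch_cfg = video.PatchConfig(
        frame_size=cfg.movie_size,
        patch_size=cfg.patch_size,
        central_region=(cfg.movie_size // cfg.patch_size) * cfg.patch_size,
        clip_length=cfg.clip_length,
    )
    all_clips = []
    for m in range(cfg.n_movies):
        movie_cfg = synth.MovieGenConfig(
            frame_count=cfg.movie_frames,
            height=cfg.movie_size,
            width=cfg.movie_size,
            seed=child_seed(cfg.master_seed, "movie", m),
        )
        movie = synth.gen_drifting_texture_movie(movie_cfg)
        whitened = np.stack([video.bandpass_whiten(f) for f in movie])
        all_clips.append(video.extract_patch_clips(whitened, patch_cfg))
    clips = np.concatenate(all_clips)
    return data.ClipDataset(clips=clips, domain="visual")


def _generate_auditory_dataset(cfg: ExperimentConfig) -> data.ClipDataset:
    all_clips = []
    for m in range(4):
        audio_cfg = synth.AudioGenConfig(
            duration=cfg.audio_duration / 4,
            seed=child_seed(cfg.master_seed, "audio", m),
        )
        wave, sr = synth.gen_textured_audio(audio_cfg)
        coch = audio.cochleagram(wave)
        all_clips.append(audio.clip_cochleagram(coch, cfg.audio_clip_length))
    clips = np.concatenate(all_clips)
    return data.ClipDataset(clips=clips, domain="auditory")


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("predrf").addHandler(handler)
    manifest: dict = {"config": dataclasses.asdict(cfg), "artifacts": [], "status": "running"}
    try:
        # --- generate + preprocess ---
        if cfg.domain == "visual":
            ds = _generate_visual_dataset(cfg)
        else:
            ds = _generate_auditory_dataset(cfg)
        if cfg.max_clips is not None and ds.n_clips > cfg.max_clips:
            rng = np.random.default_rng(child_seed(cfg.master_seed, "subsample"))
            keep = rng.choice(ds.n_clips, size=cfg.max_clips, replace=False)
            ds = dataclasses.replace(ds, clips=ds.clips[np.sort(keep)])
        train_ds, val_ds = data.train_val_split(
            ds, cfg.val_fraction, child_seed(cfg.master_seed, "split")
        )
        train_ds = data.normalize_dataset(train_ds)
        val_ds = data.normalize_dataset(val_ds, stats=train_ds.norm_stats)
        train_ds = data.add_gaussian_noise(
            train_ds, data.NoiseConfig(cfg.snr_db, child_seed(cfg.master_seed, "noise", 0))
        )
        val_ds = data.add_gaussian_noise(
            val_ds, data.NoiseConfig(cfg.snr_db, child_seed(cfg.master_seed, "noise", 1))
        )
        data.save_dataset(str(out / "train.h5"), train_ds)
        data.save_dataset(str(out / "val.h5"), val_ds)
        manifest["artifacts"] += ["train.h5", "val.h5"]
        pair = data.split_past_future(train_ds)
        val_pair = data.split_past_future(val_ds)

        # --- train grid ---
        base = network.TrainConfig(
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            nonlinearity=cfg.nonlinearity, seed=child_seed(cfg.master_seed, "train"),
        )
        rows = network.grid_search(pair, val_pair, cfg.n_hidden_list, cfg.lam_list, base)
        geometry = (pair.n_past, *pair.feature_shape)
        table_records = []
        reference = _load_reference(cfg.reference_population)
        for ridx, row in enumerate(rows):
            pfile = f"params_J{row['n_hidden']}_lam{row['lam']:g}.h5"
            network.save_params(str(out / pfile), row["params"])
            manifest["artifacts"].append(pfile)
            record = {
                "n_hidden": row["n_hidden"],
                "lam": row["lam"],
                "val_mse": row["val_mse"],
            }
            if cfg.analyze:
                record.update(
                    _analyze_cell(row["params"], geometry, cfg.domain, reference)
                )
            table_records.append(record)
        table = pd.DataFrame.from_records(table_records)
        table.to_csv(out / "grid_results.csv", index=False)
        manifest["artifacts"].append("grid_results.csv")

        if cfg.analyze and "mean_ks" in table.columns and table["mean_ks"].notna().sum() >= 3:
            r2, p, n = prediction_similarity_correlation(table)
            manifest["prediction_similarity"] = {"signed_r2": r2, "p": p, "n": n}

        manifest["status"] = "complete"
    except Exception as exc:  # partial artifacts retained
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        log.exception("experiment failed")
        raise
    finally:
        manifest["artifacts"].append("run.log")
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
        logging.getLogger("predrf").removeHandler(handler)
    return manifest


def _load_reference(path: str | None):
    if path is None:
        return None
    import h5py

    with h5py.File(path, "r") as f:
        return f["rfs"][...]


def _analyze_cell(params, geometry, domain: str, reference=None) -> dict:
    """Per-grid-cell RF metrics; auditory adds mean KS when a reference exists."""
    out: dict = {}
    if domain == "auditory":
        params = network.normalize_sign(params.copy(), geometry)
    rfset = network.prune_inactive(network.extract_rfs(params, geometry))
    out["n_active"] = int(rfset.active_mask.sum())
    active = rfset.active
    if len(active) == 0 or not np.any(active):
        return out
    profile = strf.temporal_power_profile(active)
    out["power_most_recent_bin"] = float(profile[-1])
    if domain == "auditory" and reference is not None:
        model_spans = strf.span_distributions(list(active))
        ref_spans = strf.span_distributions(list(reference))
        out["mean_ks"] = strf.mean_ks(model_spans, ref_spans).mean
    if domain == "visual":
        kept = 0
        tdis = []
        for rf3d in active:
            t_opt = gabor.optimal_timestep(rf3d)
            fit = gabor.apply_exclusions(gabor.fit_gabor(rf3d[:, :, t_opt]), rf3d.shape[:2])
            if fit.status == "kept":
                kept += 1
                tdis.append(gabor.tdi(gabor.collapse_to_xt(rf3d, fit)).tdi)
        out["gabor_kept_fraction"] = kept / len(active)
        out["tdi_mean"] = float(np.mean(tdis)) if tdis else float("nan")
    return out


def prediction_similarity_correlation(table: pd.DataFrame) -> tuple[float, float, int]:
    """Signed r^2 between validation MSE and mean KS across grid cells.

    Pearson correlation over rows with both columns present, reported
    as sign(r) * r^2 with a two-sided p-value and the row count n. A
    negative value means better prediction co-occurs with greater
    similarity to the reference population.
    """
    sub = table.dropna(subset=["val_mse", "mean_ks"])
    if len(sub) < 3:
        raise ValueError("need at least 3 grid cells with both MSE and mean KS")
    x = sub["val_mse"].to_numpy(float)
    y = sub["mean_ks"].to_numpy(float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for a constant column")
    r, p = sp_stats.pearsonr(x, y)
    return float(np.sign(r) * r**2), float(p), int(len(sub))
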