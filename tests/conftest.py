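import numpy as np
import pytest

from predrf import data, synth, video


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_movie():
    cfg = synth.MovieGenConfig(frame_count=24, height=40, width=40, n_textures=2, seed=7)
    return synth.gen_drifting_texture_movie(cfg)


@pytest.fixture(scope="session")
def texture_clip_dataset():
    """Whitened drifting-texture clips on a 12x12 grid, ~4k clips."""
    all_clips = []
    for m in range(2):
        cfg = synth.MovieGenConfig(frame_count=60, height=36, width=36, seed=100 + m)
        movie = synth.gen_drifting_texture_movie(cfg)
        whitened = np.stack([video.bandpass_whiten(f) for f in movie])
        pc = video.PatchConfig(frame_size=36, patch_size=12, central_region=36, clip_length=8)
        all_clips.append(video.extract_patch_clips(whitened, pc))
    return data.ClipDataset(clips=np.concatenate(all_clips), domain="visual")


@pytest.fixture(scope="session")
def planted_population():
    spec = synth.PopulationSpec(n_units=40, seed=11)
    return synth.make_rf_population(spec)
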