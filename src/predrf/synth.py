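"""Synthetic stimulus and receptive-field generators.

Everything downstream of the frontends is tested against data produced
here: drifting band-limited texture movies (temporal predictability via
rigid motion), harmonic amplitude-modulated sound textures, planted
spectrotemporal receptive fields (STRFs) with brief leading excitation
and longer lagging inhibition, simulated linear neurons, and RF
populations with controlled subfield-span distributions.

All generators are pure functions of their config plus seed: rerunning
with the same arguments yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MovieGenConfig",
    "AudioGenConfig",
    "PlantedStrf",
    "PopulationSpec",
    "gen_drifting_texture_movie",
    "gen_textured_audio",
    "make_planted_strf",
    "simulate_linear_neuron",
    "make_rf_population",
]


@dataclass
class MovieGenConfig:
    """Parameters for a drifting-texture movie.

    Each of ``n_textures`` layers is an independent random texture that
    translates rigidly (with circular wraparound) at its own velocity in
    pixels/frame; the movie is the mean of the layers.
    """

    frame_count: int = 64
    height: int = 64
    width: int = 64
    n_textures: int = 3
    velocities: list[tuple[float, float]] | None = None
    spatial_spectrum_exponent: float = -1.0
    edge_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_count < 1:
            raise ValueError("frame_count must be >= 1")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if not 0.0 <= self.edge_fraction <= 1.0:
            raise ValueError("edge_fraction must lie in [0, 1]")
        if self.velocities is None:
            rng = np.random.default_rng(self.seed + 7919)
            # integer velocities in [-2, 2], at least one moving texture
            v = rng.integers(-2, 3, size=(self.n_textures, 2)).astype(float)
            if self.n_textures and not np.any(v):
                v[0] = (1.0, 0.0)
            self.velocities = [tuple(row) for row in v]
        if len(self.velocities) != self.n_textures:
            raise ValueError("velocities list length must equal n_textures")


@dataclass
class AudioGenConfig:
    """Parameters for harmonic, amplitude-modulated sound textures."""

    duration: float = 2.0
    sample_rate: int = 44100
    n_harmonic_sources: int = 3
    f0_range: tuple[float, float] = (200.0, 800.0)
    am_rate_range: tuple[float, float] = (2.0, 12.0)
    noise_texture_level: float = 0.1
    harmonics_per_source: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_texture_level < 0:
            raise ValueError("noise_texture_level must be >= 0")
        max_f = self.f0_range[1] * self.harmonics_per_source
        if self.sample_rate <= 2 * min(max_f, self.sample_rate * 0.45):
            pass  # harmonics above 0.45*fs are dropped at synthesis time


@dataclass
class PlantedStrf:
    """A separable STRF: Gaussian spectral bump x biphasic temporal kernel.

    The temporal kernel has a positive (excitatory) lobe close to the
    present and, when ``inh_gain > 0``, a longer negative (inhibitory)
    lobe further in the past. Time bins run oldest-first with the most
    recent bin last; latencies count bins back from the present.
    """

    values: np.ndarray
    center_channel: int
    spectral_sd: float
    exc_latency: int
    inh_latency: int
    exc_width: float
    inh_width: float
    inh_gain: float


@dataclass
class PopulationSpec:
    """Target subfield-span statistics for a synthetic RF population.

    ``spans`` maps each of the four span kinds (``t_exc``, ``t_inh``,
    ``f_exc``, ``f_inh``) to a (mean, sd) pair in bins/channels.
    """

    n_units: int = 100
    n_freq: int = 32
    n_time: int = 40
    spans: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "t_exc": (3.0, 1.0),
            "t_inh": (6.0, 2.0),
            "f_exc": (4.0, 1.5),
            "f_inh": (5.0, 2.0),
        }
    )
    inh_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        for key in ("t_exc", "t_inh", "f_exc", "f_inh"):
            if key not in self.spans:
                raise ValueError(f"spans must contain {key!r}")
        for key, (mean, sd) in self.spans.items():
            bound = self.n_time if key.startswith("t") else self.n_freq
            if not 1 <= mean <= bound:
                raise ValueError(f"span mean for {key!r} outside grid bounds")
            if sd < 0:
                raise ValueError("span sd must be >= 0")


def _power_law_texture(rng: np.random.Generator, h: int, w: int, exponent: float) -> np.ndarray:
    """Gaussian noise with isotropic power-law amplitude spectrum f**exponent."""
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fy, fx)
    amp = np.zeros_like(radius)
    nonzero = radius > 0
    amp[nonzero] = radius[nonzero] ** exponent
    spectrum = amp * np.fft.fft2(rng.standard_normal((h, w)))
    tex = np.fft.ifft2(spectrum).real
    tex -= tex.mean()
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _edge_texture(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Hard luminance step (half-plane edge) at a random orientation/offset."""
    theta = rng.uniform(0, np.pi)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    proj = (xx - w / 2) * np.cos(theta) + (yy - h / 2) * np.sin(theta)
    offset = rng.uniform(-0.25, 0.25) * min(h, w)
    tex = np.where(proj > offset, 1.0, -1.0)
    tex -= tex.mean()
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _shift_frame(texture: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Circular translation; exact np.roll for integer offsets, Fourier otherwise."""
    if float(dy).is_integer() and float(dx).is_integer():
        return np.roll(texture, (int(dy), int(dx)), axis=(0, 1))
    h, w = texture.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    phase = np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return np.fft.ifft2(np.fft.fft2(texture) * phase).real


def gen_drifting_texture_movie(cfg: MovieGenConfig) -> np.ndarray:
    """Render a [T x H x W] movie of rigidly translating random textures.

    Textures are filtered Gaussian noise with an isotropic power-law
    amplitude spectrum; a fraction of them are replaced by hard
    luminance edges. Motion wraps around circularly, so frame t is
    exactly frame 0 translated by t times each texture's velocity.
    """
    rng = np.random.default_rng(cfg.seed)
    n_edges = int(round(cfg.edge_fraction * cfg.n_textures))
    textures = []
    for idx in range(cfg.n_textures):
        if idx < n_edges:
            textures.append(_edge_texture(rng, cfg.height, cfg.width))
        else:
            textures.append(
                _power_law_texture(rng, cfg.height, cfg.width, cfg.spatial_spectrum_exponent)
            )
    movie = np.zeros((cfg.frame_count, cfg.height, cfg.width))
    for t in range(cfg.frame_count):
        for tex, (dx, dy) in zip(textures, cfg.velocities):
            movie[t] += _shift_frame(tex, dy * t, dx * t)
    if cfg.n_textures:
        movie /= cfg.n_textures
    return movie


def gen_textured_audio(cfg: AudioGenConfig) -> tuple[np.ndarray, int]:
    """Synthesize a harmonic AM sound texture; returns (waveform, sample_rate).

    Each source is a harmonic stack (amplitudes 1/h, harmonics above
    0.45 x sample_rate dropped) with a random fundamental from
    ``f0_range``, multiplied by a raised-sinusoid amplitude envelope at
    a rate from ``am_rate_range``. Pink-ish broadband noise is mixed in
    at ``noise_texture_level`` relative amplitude.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    wave = np.zeros(n)
    for _ in range(cfg.n_harmonic_sources):
        f0 = rng.uniform(*cfg.f0_range)
        am = rng.uniform(*cfg.am_rate_range)
        phase = rng.uniform(0, 2 * np.pi)
        am_phase = rng.uniform(0, 2 * np.pi)
        src = np.zeros(n)
        for h in range(1, cfg.harmonics_per_source + 1):
            freq = h * f0
            if freq > 0.45 * cfg.sample_rate:
                break
            src += np.sin(2 * np.pi * freq * t + phase * h) / h
        envelope = 0.5 * (1.0 + np.sin(2 * np.pi * am * t + am_phase))
        wave += src * envelope
    if cfg.noise_texture_level > 0:
        from scipy.signal import lfilter

        white = rng.standard_normal(n)
        # one-pole lowpass gives a 1/f-ish texture floor
        alpha = 0.02
        noise = lfilter([alpha], [1.0, alpha - 1.0], white)
        noise_sd = noise.std()
        if noise_sd > 0:
            noise /= noise_sd
        peak = np.max(np.abs(wave)) if np.any(wave) else 1.0
        wave = wave + cfg.noise_texture_level * peak * noise
    return wave, cfg.sample_rate


def make_planted_strf(
    n_freq: int = 32,
    n_time: int = 40,
    center_channel: int = 16,
    spectral_sd: float = 2.0,
    exc_latency: int = 3,
    inh_latency: int = 10,
    exc_width: float = 1.5,
    inh_width: float = 3.5,
    inh_gain: float = 0.6,
) -> PlantedStrf:
    """Build a separable STRF with leading excitation and lagging inhibition.

    The temporal kernel is a positive Gaussian lobe ``exc_latency`` bins
    back from the present minus ``inh_gain`` times a broader Gaussian at
    ``inh_latency`` bins back; total power is normalized to 1.
    """
    if not (0 <= exc_latency < n_time and 0 <= inh_latency < n_time):
        raise ValueError("excitatory/inhibitory latencies must fit in the time grid")
    if inh_gain < 0:
        raise ValueError("inh_gain must be >= 0")
    if inh_gain > 0 and inh_width <= exc_width:
        raise ValueError("lagging inhibition must be longer than excitation")
    if inh_gain > 0 and inh_latency <= exc_latency:
        raise ValueError("inhibition must lag excitation (larger latency)")
    lags = np.arange(n_time)[::-1]  # lag 0 = most recent (last) bin
    temporal = np.exp(-0.5 * ((lags - exc_latency) / exc_width) ** 2)
    if inh_gain > 0:
        temporal = temporal - inh_gain * np.exp(-0.5 * ((lags - inh_latency) / inh_width) ** 2)
    channels = np.arange(n_freq)
    spectral = np.exp(-0.5 * ((channels - center_channel) / spectral_sd) ** 2)
    values = np.outer(spectral, temporal)
    values /= np.sqrt(np.sum(values**2))
    return PlantedStrf(
        values=values,
        center_channel=center_channel,
        spectral_sd=spectral_sd,
        exc_latency=exc_latency,
        inh_latency=inh_latency,
        exc_width=exc_width,
        inh_width=inh_width,
        inh_gain=inh_gain,
    )


def simulate_linear_neuron(
    strf: PlantedStrf | np.ndarray,
    coch: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    rectify: bool = False,
) -> np.ndarray:
    """Drive a linear (optionally half-wave-rectified) neuron with a cochleagram.

    Parameters
    ----------
    strf
        [n_freq x n_time] filter, most recent time bin last.
    coch
        [T x n_freq] cochleagram (time running forward).
    noise_sd
        Standard deviation of i.i.d. Gaussian output noise.
    rectify
        Apply max(., 0) before adding noise (off by default; the STRF
        estimator it feeds is linear regression, so linear ground truth
        gives a clean recovery oracle).

    Returns
    -------
    response of length T - n_time + 1; response[tau] uses cochleagram
    rows tau .. tau + n_time - 1.
    """
    w = strf.values if isinstance(strf, PlantedStrf) else np.asarray(strf)
    n_freq, n_time = w.shape
    coch = np.asarray(coch, dtype=float)
    if coch.ndim != 2 or coch.shape[1] != n_freq:
        raise ValueError("cochleagram channel count must match STRF channel count")
    if coch.shape[0] < n_time:
        raise ValueError("cochleagram shorter than STRF history")
    windows = np.lib.stride_tricks.sliding_window_view(coch, n_time, axis=0)
    # windows: [T - n_time + 1, n_freq, n_time]
    response = np.einsum("tfj,fj->t", windows, w)
    if rectify:
        response = np.maximum(response, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=response.shape)
    return response


def _plateau_profile(length: int, span: int, start: int, flank: float = 0.35) -> np.ndarray:
    """A vector whose count of entries above half its max is exactly ``span``.

    ``span`` consecutive entries at 1.0 flanked by geometrically decaying
    sub-threshold shoulders.
    """
    v = np.zeros(length)
    stop = min(start + span, length)
    v[start:stop] = 1.0
    level = flank
    for k in range(1, 4):
        lo, hi = start - k, stop - 1 + k
        if lo >= 0:
            v[lo] = level
        if hi < length:
            v[hi] = level
        level *= flank
    return v


def make_rf_population(spec: PopulationSpec) -> list[np.ndarray]:
    """Draw a population of separable STRFs with controlled subfield spans.

    Spans are sampled per unit from the spec's (mean, sd) pairs, rounded
    to whole bins and clipped to the grid. Excitatory and inhibitory
    lobes occupy disjoint time-bin ranges, so splitting an RF by sign
    recovers each subfield exactly and the measured span of its leading
    singular vector equals the planted span by construction.
    """
    rng = np.random.default_rng(spec.seed)
    population: list[np.ndarray] = []
    for _ in range(spec.n_units):
        drawn = {}
        for key, (mean, sd) in spec.spans.items():
            bound = spec.n_time if key.startswith("t") else spec.n_freq
            val = int(np.clip(np.rint(rng.normal(mean, sd)), 1, bound))
            drawn[key] = val
        has_inh = rng.random() < spec.inh_fraction
        t_exc, f_exc = drawn["t_exc"], drawn["f_exc"]
        t_inh, f_inh = drawn["t_inh"], drawn["f_inh"]
        t_exc = min(t_exc, spec.n_time - 3)
        # excitation hugs the present (end of the time axis); plateau plus
        # 3 flank bins each side stay inside the grid
        exc_start_t = spec.n_time - t_exc - 3
        exc_t = _plateau_profile(spec.n_time, t_exc, exc_start_t)
        f_center = int(rng.integers(4, max(5, spec.n_freq - 4)))
        exc_f = _plateau_profile(spec.n_freq, f_exc, max(0, f_center - f_exc // 2))
        rf = np.outer(exc_f, exc_t)
        # inhibitory support (flanks included) ends >= 1 bin before the
        # excitatory support begins, so sign-splitting is exact
        t_inh = min(t_inh, exc_start_t - 7)
        if has_inh and t_inh >= 1:
            inh_start_t = exc_start_t - 7 - t_inh
            inh_t = _plateau_profile(spec.n_time, t_inh, inh_start_t)
            inh_f = _plateau_profile(spec.n_freq, f_inh, max(0, f_center - f_inh // 2))
            rf = rf - 0.7 * np.outer(inh_f, inh_t)
        rf /= np.sqrt(np.sum(rf**2))
        population.append(rf)
    return population
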