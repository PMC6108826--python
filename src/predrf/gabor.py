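"""Spatiotemporal (visual) receptive-field metrics.

Visual RFs are [20 x 20 x 7] arrays (y by x by time, most recent 40 ms
bin last). The battery: optimal time step, two-stage Gabor fitting
(spectral-domain Gaussian initialization, then spatial-domain
refinement) with exclusion rules, rotation-and-collapse to a 2D
space-time RF, SVD space-time separability, nx/ny shape indices, the
tilt direction index, and peak temporal frequency.

The Gabor is

    G(x', y') = A exp(-(x'/2 sigma_x)^2 - (y'/2 sigma_y)^2) cos(2 pi f x' + phi)

with (x', y') obtained by translating the centre (x0, y0) to the origin
and rotating by the orientation theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "GaborFit",
    "TdiResult",
    "ShapeIndices",
    "gabor_image",
    "optimal_timestep",
    "fit_gabor",
    "apply_exclusions",
    "collapse_to_xt",
    "separability",
    "shape_indices",
    "tdi",
    "peak_temporal_frequency",
    "temporal_power_profile_visual",
]

TIME_BIN_S = 0.040  # 25 fps frames
BINS_PER_SECOND = 1.0 / TIME_BIN_S


@dataclass
class GaborFit:
    """Fitted Gabor parameters plus goodness of fit and exclusion status."""

    A: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    theta: float  # [0, pi)
    f: float  # cycles/pixel
    phi: float  # [0, 2 pi)
    fit_corr: float
    status: str = "kept"


@dataclass
class TdiResult:
    Rp: float
    Rq: float
    Fspace: float  # cycles/pixel
    Ftime: float  # cycles/bin
    tdi: float
    static: bool = False


@dataclass
class ShapeIndices:
    """nx = sigma_x * f (oscillation count), ny = sigma_y * f (bar length)."""

    nx: float
    ny: float


def gabor_image(
    shape: tuple[int, int],
    A: float,
    x0: float,
    y0: float,
    sigma_x: float,
    sigma_y: float,
    theta: float,
    f: float,
    phi: float,
) -> np.ndarray:
    """Render the Gabor on a pixel grid (row = y, column = x, 0-based)."""
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    xp = (xx - x0) * np.cos(theta) + (yy - y0) * np.sin(theta)
    yp = -(xx - x0) * np.sin(theta) + (yy - y0) * np.cos(theta)
    envelope = np.exp(-((xp / (2 * sigma_x)) ** 2) - ((yp / (2 * sigma_y)) ** 2))
    return A * envelope * np.cos(2 * np.pi * f * xp + phi)


def optimal_timestep(rf3d: np.ndarray) -> int:
    """Time bin with the most power (spatial mean square); ties go recent."""
    rf3d = np.asarray(rf3d, dtype=float)
    if not np.any(rf3d):
        raise ValueError("optimal time step of an all-zero RF is undefined")
    power = np.mean(rf3d**2, axis=(0, 1))
    return int(len(power) - 1 - np.argmax(power[::-1]))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _spectral_init(rf: np.ndarray) -> tuple[float, float, float]:
    """Stage 1: Gaussian moments of the FFT magnitude lobes -> (theta, f, bw).

    The Fourier transform of a Gabor is a Gaussian pair at +/- the
    frequency vector; the magnitude-weighted centroid of the positive
    half-plane gives orientation and spatial frequency, and the spread
    about it a bandwidth estimate used to seed the envelope widths.
    """
    h, w = rf.shape
    mag = np.abs(np.fft.fft2(rf))
    mag[0, 0] = 0.0  # DC excluded
    fy = np.fft.fftfreq(h)[:, None] * np.ones((1, w))
    fx = np.fft.fftfreq(w)[None, :] * np.ones((h, 1))
    # fold onto the half-plane fx >= 0 (Hermitian symmetry)
    flip = fx < 0
    fy = np.where(flip, -fy, fy)
    fx = np.where(flip, -fx, fx)
    weights = mag.ravel() ** 2
    total = weights.sum()
    if total <= 0:
        return 0.0, 0.1, 0.1
    cx = float((fx.ravel() * weights).sum() / total)
    cy = float((fy.ravel() * weights).sum() / total)
    f_est = float(np.hypot(cx, cy))
    theta = float(np.arctan2(cy, cx)) % np.pi
    spread = float(
        np.sqrt(((fx.ravel() - cx) ** 2 + (fy.ravel() - cy) ** 2) @ weights / total)
    )
    return theta, max(f_est, 1e-3), max(spread, 1e-3)


def fit_gabor(rf: np.ndarray, phases: tuple[float, ...] = (0.0, np.pi / 2, np.pi, 1.5 * np.pi)) -> GaborFit:
    """Two-stage Gabor fit to one spatial RF frame.

    Stage 1 estimates orientation, spatial frequency and envelope scale
    from a Gaussian-moment fit to the FFT magnitude (a Gabor's spectrum
    is a Gaussian pair, which is much easier to localize). Stage 2
    refines all 8 parameters by bounded quasi-Newton minimization of
    the spatial-domain MSE, multi-started over 4 initial phases; the
    lowest-MSE fit wins and its pixelwise correlation is recorded. An
    optimizer failure is reported as status 'rejected_lowcorr' with the
    achieved correlation.
    """
    rf = np.asarray(rf, dtype=float)
    h, w = rf.shape
    theta0, f0, spread = _spectral_init(rf)
    power = rf**2
    total = power.sum()
    if total <= 0:
        return GaborFit(0, 0, 0, 1, 1, 0, 0, 0, fit_corr=0.0, status="rejected_lowcorr")
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    x0 = float((xx * power).sum() / total)
    y0 = float((yy * power).sum() / total)
    # spectral spread ~ 1/(4 pi sigma) for the exp(-(x/2sigma)^2) envelope
    sigma0 = float(np.clip(1.0 / (4 * np.pi * spread), 0.6, max(h, w)))
    a0 = float(np.abs(rf).max())

    bounds = [
        (-3 * a0, 3 * a0),
        (-w, 2 * w),
        (-h, 2 * h),
        (0.1, 3 * max(h, w)),
        (0.1, 3 * max(h, w)),
        (theta0 - np.pi, theta0 + np.pi),
        (0.0, 0.75),
        (None, None),
    ]

    def objective(p: np.ndarray) -> float:
        model = gabor_image((h, w), *p)
        return float(np.mean((model - rf) ** 2))

    best = None
    for phi0 in phases:
        p_init = np.array([a0, x0, y0, sigma0, sigma0, theta0, f0, phi0])
        try:
            res = optimize.minimize(objective, p_init, method="L-BFGS-B", bounds=bounds)
        except Exception:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        return GaborFit(a0, x0, y0, sigma0, sigma0, theta0, f0, 0.0, fit_corr=0.0,
                        status="rejected_lowcorr")
    A, bx0, by0, sx, sy, theta, f, phi = best.x
    # canonicalize: positive amplitude, theta in [0, pi), phi in [0, 2 pi)
    if A < 0:
        A, phi = -A, phi + np.pi
    theta = float(theta) % np.pi
    if theta > np.pi - 1e-4:  # orientation is defined modulo pi
        theta = 0.0
    phi = float(phi) % (2 * np.pi)
    model = gabor_image((h, w), A, bx0, by0, sx, sy, theta, f, phi)
    return GaborFit(
        A=float(A), x0=float(bx0), y0=float(by0), sigma_x=float(sx), sigma_y=float(sy),
        theta=theta, f=float(f), phi=phi, fit_corr=_corr(model, rf),
    )


def apply_exclusions(fit: GaborFit, grid: tuple[int, int] = (20, 20)) -> GaborFit:
    """Reject poor, off-grid, or degenerate-envelope fits.

    Rules: correlation < 0.7; fitted centre outside the pixel grid
    (0-based, [0, side-1] each axis); envelope SD below 0.5 pixels in
    either direction.
    """
    status = "kept"
    if fit.fit_corr < 0.7:
        status = "rejected_lowcorr"
    elif not (0 <= fit.x0 <= grid[1] - 1 and 0 <= fit.y0 <= grid[0] - 1):
        status = "rejected_center"
    elif min(fit.sigma_x, fit.sigma_y) < 0.5:
        status = "rejected_sigma"
    return GaborFit(**{**vars(fit), "status": status})


def collapse_to_xt(rf3d: np.ndarray, fit: GaborFit) -> np.ndarray:
    """Rotate each time slice to put bars parallel to y', then sum along y'.

    The rotation/translation from the unit's Gabor fit (at its optimal
    time step) is applied identically to every time slice (bilinear
    resampling, zero padding), the fitted centre moving to the grid
    centre; summing along the new y-axis yields a [n_x x n_time]
    space-time RF.
    """
    if fit.status != "kept":
        raise ValueError("refusing to collapse with a rejected Gabor fit")
    rf3d = np.asarray(rf3d, dtype=float)
    h, w, n_t = rf3d.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    xp = xx - cx
    yp = yy - cy
    src_x = fit.x0 + xp * np.cos(fit.theta) - yp * np.sin(fit.theta)
    src_y = fit.y0 + xp * np.sin(fit.theta) + yp * np.cos(fit.theta)
    coords = np.stack([src_y.ravel(), src_x.ravel()])
    out = np.empty((w, n_t))
    for t in range(n_t):
        slice_rot = ndimage.map_coordinates(
            rf3d[:, :, t], coords, order=1, mode="grid-constant", cval=0.0
        ).reshape(h, w)
        out[:, t] = slice_rot.sum(axis=0)
    return out


def separability(rf3d: np.ndarray) -> tuple[float, str]:
    """Space-time separability from the SVD of the [space x time] matrix.

    The 20 x 20 x 7 RF is reshaped to 400 x 7; the ratio of the second
    to first singular value is 0 for an exact outer product and the
    unit is labelled inseparable when it is >= 0.5.
    """
    rf3d = np.asarray(rf3d, dtype=float)
    if not np.any(rf3d):
        raise ValueError("separability of an all-zero RF is undefined")
    mat = rf3d.reshape(-1, rf3d.shape[-1])
    s = np.linalg.svd(mat, compute_uv=False)
    ratio = float(s[1] / s[0]) if s[0] > 0 else 0.0
    return ratio, ("inseparable" if ratio >= 0.5 else "separable")


def shape_indices(fit: GaborFit) -> ShapeIndices:
    """Dimensionless envelope extents in units of the oscillation period."""
    if fit.status != "kept":
        raise ValueError("shape indices require a kept Gabor fit")
    return ShapeIndices(nx=fit.sigma_x * fit.f, ny=fit.sigma_y * fit.f)


def _half_plane_peak(amp: np.ndarray, fs_ax: np.ndarray, ft_ax: np.ndarray):
    """Peak over temporal-frequency > 0 half-plane, ties toward low frequency."""
    best = None
    for si, fs in enumerate(fs_ax):
        for ti, ft in enumerate(ft_ax):
            if ft <= 0:
                continue
            val = amp[si, ti]
            key = (-val, abs(ft), abs(fs))
            if best is None or key < best[0]:
                best = (key, si, ti, fs, ft, val)
    return best


def tdi(rf_xt: np.ndarray) -> TdiResult:
    """Tilt direction index from the 2D Fourier amplitude of a space-time RF.

    Rp is the amplitude at the peak over the positive temporal-frequency
    half-plane, at (Fspace, Ftime); Rq is the amplitude at the
    time-mirrored point (Fspace, -Ftime); tdi = (Rp-Rq)/(Rp+Rq). A
    separable RF has a time-symmetric amplitude spectrum and tdi 0; if
    the global (non-DC) peak sits on the Ftime = 0 line the RF is
    static and tdi is defined as 0 with a flag. Near-equal peaks break
    toward lower frequency.
    """
    rf_xt = np.asarray(rf_xt, dtype=float)
    if not np.any(rf_xt):
        raise ValueError("TDI of an all-zero RF is undefined")
    n_s, n_t = rf_xt.shape
    amp = np.abs(np.fft.fft2(rf_xt))
    fs_ax = np.fft.fftfreq(n_s)
    ft_ax = np.fft.fftfreq(n_t)
    # static check: global non-DC peak on the zero-temporal-frequency line
    masked = amp.copy()
    masked[0, 0] = 0.0
    gi = np.unravel_index(np.argmax(masked), masked.shape)
    peak = _half_plane_peak(amp, fs_ax, ft_ax)
    if peak is None or masked[gi] > peak[5] + 1e-12 and ft_ax[gi[1]] == 0:
        si = gi[0]
        return TdiResult(Rp=float(masked[gi]), Rq=float(masked[gi]), Fspace=float(fs_ax[si]),
                         Ftime=0.0, tdi=0.0, static=True)
    _, si, ti, fs, ft, rp = peak
    tj = int(np.argmin(np.abs(ft_ax - (-ft))))
    rq = float(amp[si, tj])
    value = (rp - rq) / (rp + rq) if (rp + rq) > 0 else 0.0
    # Rp is the half-plane max, so tdi >= 0 up to rounding; clamp the epsilon
    value = max(float(value), 0.0)
    return TdiResult(Rp=float(rp), Rq=rq, Fspace=float(fs), Ftime=float(ft), tdi=value)


def peak_temporal_frequency(rf_xt: np.ndarray) -> float:
    """Temporal frequency (cycles/s) of the global Fourier amplitude peak.

    The peak is searched over the non-DC half-plane (Ftime >= 0 with
    Ftime = 0 allowed, so static patterns report 0); cycles/bin convert
    at 25 bins/s (40 ms frames).
    """
    rf_xt = np.asarray(rf_xt, dtype=float)
    if not np.any(rf_xt):
        raise ValueError("peak temporal frequency of an all-zero RF is undefined")
    n_s, n_t = rf_xt.shape
    amp = np.abs(np.fft.fft2(rf_xt))
    fs_ax = np.fft.fftfreq(n_s)
    ft_ax = np.fft.fftfreq(n_t)
    best_key, best_ft = None, 0.0
    for si, fs in enumerate(fs_ax):
        for ti, ft in enumerate(ft_ax):
            if ft < 0 or (si == 0 and ti == 0):
                continue
            key = (-amp[si, ti], abs(ft), abs(fs))
            if best_key is None or key < best_key:
                best_key, best_ft = key, abs(ft)
    return float(best_ft * BINS_PER_SECOND)


def temporal_power_profile_visual(rfs: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Proportion of power per time bin over a visual RF population.

    Same kernel as the auditory profile (mean square over units and
    space per time bin, normalized to sum to 1); accepts stacks of
    [20 x 20 x 7] or collapsed [20 x 7] RFs.
    """
    from .strf import temporal_power_profile

    return temporal_power_profile(rfs)
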