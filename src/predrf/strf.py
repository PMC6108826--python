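"""Spectrotemporal receptive-field metrics and population comparison.

STRFs are [n_freq x n_time] arrays (32 channels, 40 time bins of 5 ms
for model units, 38 after latency trimming), most recent bin last.
Analyses: sign-split into excitatory/inhibitory subfields, SVD-based
temporal and spectral span measures, population temporal power
profiles, the 4-way mean Kolmogorov-Smirnov similarity between span
distributions, classical MDS embedding of RF populations, latency
trimming, and L1-regularized STRF estimation from a response time
series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SubfieldSpans",
    "SpanDistributions",
    "MeanKsScore",
    "split_subfields",
    "subfield_span",
    "measure_spans",
    "span_distributions",
    "temporal_power_profile",
    "mean_ks",
    "mds_embed",
    "trim_latency",
    "estimate_strf",
]

INHIBITION_POWER_FLOOR = 0.05  # inhibitory subfields below 5% of exc power are absent
SPAN_THRESHOLD = 0.5  # fraction of the singular vector's max that counts toward a span
MS_PER_BIN = 5.0


@dataclass
class SubfieldSpans:
    """Temporal/spectral spans (bins) of one RF's subfields."""

    t_exc: int
    f_exc: int
    t_inh: int | None
    f_inh: int | None

    @property
    def inh_present(self) -> bool:
        return self.t_inh is not None

    @property
    def t_exc_ms(self) -> float:
        return self.t_exc * MS_PER_BIN

    @property
    def t_inh_ms(self) -> float | None:
        return None if self.t_inh is None else self.t_inh * MS_PER_BIN


@dataclass
class SpanDistributions:
    """Population span samples; inhibitory vectors only cover units with inhibition."""

    t_exc: np.ndarray
    t_inh: np.ndarray
    f_exc: np.ndarray
    f_inh: np.ndarray


@dataclass
class MeanKsScore:
    t_exc: float | None
    t_inh: float | None
    f_exc: float | None
    f_inh: float | None

    @property
    def mean(self) -> float:
        parts = [v for v in (self.t_exc, self.t_inh, self.f_exc, self.f_inh) if v is not None]
        return float(np.mean(parts)) if parts else float("nan")


def split_subfields(strf: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Split a sign-normalized STRF into excitatory and inhibitory parts.

    exc keeps the nonnegative entries, inh the nonpositive ones, so
    exc + inh reconstructs the input exactly. The inhibitory subfield is
    reported absent (None) when its power is below 5% of the excitatory
    power.
    """
    strf = np.asarray(strf, dtype=float)
    exc = np.where(strf > 0, strf, 0.0)
    inh = np.where(strf < 0, strf, 0.0)
    exc_power = float(np.sum(exc**2))
    if exc_power == 0 and not np.any(inh):
        log.warning("all-zero STRF: both subfields absent")
        return exc, None
    if float(np.sum(inh**2)) < INHIBITION_POWER_FLOOR * exc_power:
        return exc, None
    return exc, inh


def subfield_span(subfield: np.ndarray, axis: str) -> int:
    """Span of a subfield along time or frequency, in bins.

    Takes the first singular-vector pair of the subfield; the span is
    the number of entries of the requested vector whose absolute value
    exceeds 50% of the vector's maximum absolute value. The sign of the
    singular vector is fixed so its largest-magnitude entry is positive
    (spans use absolute values, so the fix only aids reproducibility).
    """
    subfield = np.asarray(subfield, dtype=float)
    if not np.any(subfield):
        raise ValueError("span of an all-zero subfield is undefined")
    u, s, vt = np.linalg.svd(subfield, full_matrices=False)
    vec = u[:, 0] if axis == "frequency" else vt[0]
    if axis not in ("time", "frequency"):
        raise ValueError("axis must be 'time' or 'frequency'")
    mag = np.abs(vec)
    return int(np.sum(mag > SPAN_THRESHOLD * mag.max()))


def measure_spans(strf: np.ndarray) -> SubfieldSpans:
    """Subfield spans of one STRF (inhibitory entries None when absent)."""
    exc, inh = split_subfields(strf)
    t_exc = subfield_span(exc, "time")
    f_exc = subfield_span(exc, "frequency")
    if inh is None:
        return SubfieldSpans(t_exc=t_exc, f_exc=f_exc, t_inh=None, f_inh=None)
    return SubfieldSpans(
        t_exc=t_exc,
        f_exc=f_exc,
        t_inh=subfield_span(inh, "time"),
        f_inh=subfield_span(inh, "frequency"),
    )


def span_distributions(rfs: list[np.ndarray] | np.ndarray) -> SpanDistributions:
    """Measure every RF and collect the four population span samples."""
    t_exc, t_inh, f_exc, f_inh = [], [], [], []
    for rf in rfs:
        if not np.any(rf):
            continue
        spans = measure_spans(rf)
        t_exc.append(spans.t_exc)
        f_exc.append(spans.f_exc)
        if spans.inh_present:
            t_inh.append(spans.t_inh)
            f_inh.append(spans.f_inh)
    return SpanDistributions(
        t_exc=np.asarray(t_exc, dtype=float),
        t_inh=np.asarray(t_inh, dtype=float),
        f_exc=np.asarray(f_exc, dtype=float),
        f_inh=np.asarray(f_inh, dtype=float),
    )


def temporal_power_profile(rfs: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Proportion of RF power per time bin, averaged over units.

    Works for any stack of RFs with time as the last axis (auditory
    [n x 32 x T] or visual [n x 20 x 20 x 7]); the mean square over
    units and all non-time axes is normalized to sum to 1.
    """
    arr = np.asarray(rfs, dtype=float)
    if arr.ndim < 2 or not np.any(arr):
        raise ValueError("temporal power profile needs a nonempty, nonzero RF set")
    if arr.ndim == 2:
        arr = arr[None]
    axes = tuple(range(arr.ndim - 1))
    profile = np.mean(arr**2, axis=axes)
    return profile / profile.sum()


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def mean_ks(model: SpanDistributions, reference: SpanDistributions) -> MeanKsScore:
    """Average the four two-sample KS distances between span distributions.

    Low values mean the model population's excitatory/inhibitory
    temporal and spectral spans are distributed like the reference's.
    Components with an empty sample on either side are skipped with a
    warning and the mean taken over the rest.
    """
    out = {}
    for key in ("t_exc", "t_inh", "f_exc", "f_inh"):
        a = getattr(model, key)
        b = getattr(reference, key)
        if len(a) == 0 or len(b) == 0:
            log.warning("empty %s span sample: component dropped from mean KS", key)
            out[key] = None
        else:
            out[key] = _ks_statistic(a, b)
    return MeanKsScore(**out)


def mds_embed(
    populations: list[np.ndarray],
    n_per_set: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) 2D MDS of RFs pooled across populations.

    Each population is an [n_i x F x T] stack on a common grid;
    ``n_per_set`` RFs are sampled (without replacement, seeded) from
    each, pairwise Euclidean distances between flattened RFs are
    double-centred, and the top-2 eigenpairs give the embedding.

    Returns (coords [m x 2], labels [m] giving the source population).
    """
    rng = np.random.default_rng(seed)
    chosen, labels = [], []
    shape = None
    for li, pop in enumerate(populations):
        pop = np.asarray(pop, dtype=float)
        if shape is None:
            shape = pop.shape[1:]
        elif pop.shape[1:] != shape:
            raise ValueError("all populations must share one RF grid before embedding")
        take = min(n_per_set, len(pop))
        idx = rng.choice(len(pop), size=take, replace=False)
        chosen.append(pop[idx].reshape(take, -1))
        labels.extend([li] * take)
    X = np.vstack(chosen)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    m = len(X)
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    top = np.argsort(eigval)[::-1][:2]
    coords = eigvec[:, top] * np.sqrt(np.maximum(eigval[top], 0.0))
    return coords, np.asarray(labels)


def trim_latency(strf: np.ndarray, end: str = "most_recent", n: int = 2) -> np.ndarray:
    """Drop n time bins from one end of the STRF (most recent bin is last).

    Neural RFs lose their most recent two bins (10 ms) to account for
    cortical response latency; model RFs lose their least recent two so
    the grids match for embedding.
    """
    strf = np.asarray(strf)
    if n >= strf.shape[-1]:
        raise ValueError("cannot trim all time bins")
    if n == 0:
        return strf.copy()
    if end == "most_recent":
        return strf[..., :-n].copy()
    if end == "least_recent":
        return strf[..., n:].copy()
    raise ValueError("end must be 'most_recent' or 'least_recent'")


def estimate_strf(
    response: np.ndarray,
    coch,
    lambda_reg: float = 1e-3,
    history: int = 40,
) -> np.ndarray:
    """L1-regularized linear STRF estimate from a response time series.

    Solves min_w sum_t (r_t - w . coch_history_t)^2 + lambda ||w||_1 by
    cyclic coordinate descent with soft-thresholding (deterministic).
    ``coch`` is a Cochleagram or [T x n_freq] array; response[tau] is
    paired with cochleagram rows tau .. tau+history-1, matching
    ``simulate_linear_neuron``. Returns a [n_freq x history] STRF with
    the most recent bin last.
    """
    from sklearn.linear_model import Lasso, LinearRegression

    values = coch.values if hasattr(coch, "values") else np.asarray(coch, dtype=float)
    n_freq = values.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(values, history, axis=0)
    X = windows.reshape(windows.shape[0], n_freq * history)
    r = np.asarray(response, dtype=float)
    if len(r) != len(X):
        raise ValueError("response length inconsistent with cochleagram and history")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate design: cochleagram is constant")
    if lambda_reg <= 0:
        fit = LinearRegression(fit_intercept=True).fit(X, r)
    else:
        # sklearn minimizes (1/2n)||r - Xw||^2 + alpha||w||_1
        alpha = lambda_reg / (2.0 * len(r))
        fit = Lasso(alpha=alpha, fit_intercept=True, max_iter=50_000, tol=1e-8).fit(X, r)
    return fit.coef_.reshape(n_freq, history)
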