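"""The temporal prediction network and its training machinery.

A single-hidden-layer feedforward network predicts the immediate future
of a stimulus clip from its recent past:

    s_j = h(b_j + sum_i w_ji u_i)          (hidden layer, nonlinearity h)
    vhat_k = b_k + sum_j w_kj s_j          (linear readout)

trained to minimize mean squared prediction error plus an L1 penalty on
all weights (biases unpenalized):

    E = (1/NK) sum_nk (vhat_kn - v_kn)^2 + lambda (sum|w_ji| + sum|w_kj|)

by minibatch Adam with analytic backprop gradients. A hidden unit's
input weights, reshaped onto the stimulus grid, are its receptive
field; utilities here prune inactive units, enforce the
leading-excitation sign convention, run hyperparameter grids, compute
white-noise response-weighted averages, and measure Vinje-Gallant
population sparsity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .data import PastFuturePair

log = logging.getLogger(__name__)

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "RfSet",
    "NONLINEARITIES",
    "init_params",
    "forward",
    "cost",
    "gradient",
    "train",
    "extract_rfs",
    "prune_inactive",
    "normalize_sign",
    "grid_search",
    "response_weighted_average",
    "population_sparsity",
]


def _logistic(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


# name -> (h, h' expressed in terms of s = h(a))
NONLINEARITIES: dict[str, tuple] = {
    "logistic": (_logistic, lambda s: s * (1.0 - s)),
    "tanh": (np.tanh, lambda s: 1.0 - s**2),
    "linear": (lambda a: a, lambda s: np.ones_like(s)),
    "relu": (lambda a: np.maximum(a, 0.0), lambda s: (s > 0).astype(float)),
}


@dataclass
class NetworkParams:
    """All learnable parameters; W_in rows are the hidden units' RFs."""

    W_in: np.ndarray  # [J x I]
    b_hidden: np.ndarray  # [J]
    W_out: np.ndarray  # [K x J]
    b_out: np.ndarray  # [K]
    nonlinearity: str = "logistic"

    def __post_init__(self) -> None:
        if self.nonlinearity not in NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        j, i = self.W_in.shape
        k = self.W_out.shape[0]
        if self.W_out.shape[1] != j or self.b_hidden.shape != (j,) or self.b_out.shape != (k,):
            raise ValueError("parameter shapes are inconsistent")
        for arr in (self.W_in, self.b_hidden, self.W_out, self.b_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.W_in.copy(), self.b_hidden.copy(), self.W_out.copy(), self.b_out.copy(),
            self.nonlinearity,
        )


@dataclass
class TrainConfig:
    """Optimization settings; the defaults are desk-scale, not corpus-scale."""

    n_hidden: int = 64
    lam: float = 1e-4  # L1 strength on both weight matrices
    batch_size: int = 200
    epochs: int = 50
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    nonlinearity: str = "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")


@dataclass
class RfSet:
    """Receptive fields of hidden units plus their connection strengths."""

    rfs: np.ndarray  # [J x *geometry]
    strengths: np.ndarray  # [J], sum of squared input weights
    active_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.active_mask is None:
            self.active_mask = np.ones(len(self.rfs), dtype=bool)

    @property
    def active(self) -> np.ndarray:
        return self.rfs[self.active_mask]

    def __len__(self) -> int:
        return len(self.rfs)


def init_params(
    n_inputs: int, n_hidden: int, n_outputs: int, nonlinearity: str = "logistic", seed: int = 0
) -> NetworkParams:
    """Gaussian fan-in-scaled weights, zero biases, seeded."""
    rng = np.random.default_rng(seed)
    return NetworkParams(
        W_in=rng.normal(0.0, 1.0 / np.sqrt(n_inputs), size=(n_hidden, n_inputs)),
        b_hidden=np.zeros(n_hidden),
        W_out=rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=(n_outputs, n_hidden)),
        b_out=np.zeros(n_outputs),
        nonlinearity=nonlinearity,
    )


def forward(params: NetworkParams, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the network; returns (hidden activities S, predictions V_hat)."""
    U = np.asarray(U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise ValueError("inputs must be finite")
    h, _ = NONLINEARITIES[params.nonlinearity]
    S = h(U @ params.W_in.T + params.b_hidden)
    V_hat = S @ params.W_out.T + params.b_out
    return S, V_hat


def cost(params: NetworkParams, U: np.ndarray, V: np.ndarray, lam: float) -> float:
    """Mean squared prediction error plus L1 weight penalty (biases free)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    _, V_hat = forward(params, U)
    n, k = V.shape
    mse = float(np.sum((V_hat - V) ** 2) / (n * k))
    return mse + lam * (float(np.abs(params.W_in).sum()) + float(np.abs(params.W_out).sum()))


def gradient(
    params: NetworkParams, U: np.ndarray, V: np.ndarray, lam: float
) -> dict[str, np.ndarray]:
    """Analytic backprop gradients of the cost.

    The L1 subgradient at exactly zero is taken as 0 (plain backprop, no
    proximal step); the relu kink likewise uses subgradient 0.
    """
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    n, k = V.shape
    h, hprime = NONLINEARITIES[params.nonlinearity]
    S = h(U @ params.W_in.T + params.b_hidden)
    V_hat = S @ params.W_out.T + params.b_out
    dV = 2.0 * (V_hat - V) / (n * k)  # [N x K]
    dW_out = dV.T @ S + lam * np.sign(params.W_out)
    db_out = dV.sum(axis=0)
    dA = (dV @ params.W_out) * hprime(S)  # [N x J]
    dW_in = dA.T @ U + lam * np.sign(params.W_in)
    db_hidden = dA.sum(axis=0)
    return {"W_in": dW_in, "b_hidden": db_hidden, "W_out": dW_out, "b_out": db_out}


def validation_mse(params: NetworkParams, U: np.ndarray, V: np.ndarray) -> float:
    """Prediction error with the regularization term excluded."""
    return cost(params, U, V, 0.0)


def train(
    pair: PastFuturePair,
    cfg: TrainConfig,
    val_pair: PastFuturePair | None = None,
) -> tuple[NetworkParams, dict[str, list[float]]]:
    """Minibatch Adam on the L1-regularized prediction cost.

    Returns the trained parameters and a history dict with per-epoch
    training cost and validation MSE (penalty excluded). Training is
    deterministic given the seed. Non-finite loss aborts with a
    diagnostic.
    """
    U, V = pair.U, pair.V
    if U.shape[0] == 0:
        raise ValueError("empty training set")
    params = init_params(pair.I, cfg.n_hidden, pair.K, cfg.nonlinearity, cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    m = {k: np.zeros_like(v) for k, v in vars(params).items() if isinstance(v, np.ndarray)}
    v_adam = {k: np.zeros_like(val) for k, val in m.items()}
    step = 0
    history: dict[str, list[float]] = {"train_cost": [], "val_mse": []}
    n = U.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_cost = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            grads = gradient(params, U[idx], V[idx], cfg.lam)
            step += 1
            for key, g in grads.items():
                m[key] = cfg.beta1 * m[key] + (1 - cfg.beta1) * g
                v_adam[key] = cfg.beta2 * v_adam[key] + (1 - cfg.beta2) * g**2
                m_hat = m[key] / (1 - cfg.beta1**step)
                v_hat = v_adam[key] / (1 - cfg.beta2**step)
                arr = getattr(params, key)
                arr -= cfg.lr * m_hat / (np.sqrt(v_hat) + cfg.eps)
            n_batches += 1
        epoch_cost = cost(params, U[order[: min(n, 2000)]], V[order[: min(n, 2000)]], cfg.lam)
        if not np.isfinite(epoch_cost):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: cost={epoch_cost!r} "
                f"(lr={cfg.lr}, lambda={cfg.lam})"
            )
        history["train_cost"].append(epoch_cost)
        if val_pair is not None:
            history["val_mse"].append(validation_mse(params, val_pair.U, val_pair.V))
    return params, history


def extract_rfs(params: NetworkParams, geometry: tuple[int, ...]) -> RfSet:
    """Reshape each hidden unit's input weights onto the stimulus grid.

    ``geometry`` follows the flattening convention (time slowest):
    auditory (40, 32) -> transposed to [32 x 40] frequency-by-time;
    visual (7, 20, 20) -> rolled to [20 x 20 x 7] with time last.
    """
    j, i = params.W_in.shape
    if int(np.prod(geometry)) != i:
        raise ValueError(f"geometry {geometry} incompatible with input dimension {i}")
    rfs = params.W_in.reshape(j, *geometry)
    # move the (leading) time axis last: the analysis convention
    rfs = np.moveaxis(rfs, 1, -1)
    strengths = np.sum(params.W_in**2, axis=1)
    return RfSet(rfs=rfs, strengths=strengths)


def prune_inactive(rfset: RfSet, threshold_fraction: float = 0.01) -> RfSet:
    """Mark units whose strength is below 1% of the population maximum."""
    if len(rfset) == 0:
        raise ValueError("empty RF set")
    cutoff = threshold_fraction * rfset.strengths.max()
    return RfSet(rfs=rfset.rfs, strengths=rfset.strengths, active_mask=rfset.strengths >= cutoff)


def _flip_unit(params: NetworkParams, j: int) -> NetworkParams:
    """The sign-flip identity: negate unit j's weights and bias, fix b_out.

    For the logistic nonlinearity h(a) = 1 - h(-a), so flipping w_ji,
    w_kj and b_j while adding w_kj to b_k leaves predictions unchanged.
    For tanh (odd), b_out is unchanged. The flip is exact for linear
    units and invalid for relu (not sign-symmetric).
    """
    out = params.copy()
    out.W_in[j] *= -1
    out.b_hidden[j] *= -1
    if params.nonlinearity == "logistic":
        out.b_out += out.W_out[:, j]
    elif params.nonlinearity == "relu":
        raise ValueError("sign flip is not an invariance for relu units")
    out.W_out[:, j] *= -1
    return out


def normalize_sign(
    params: NetworkParams, geometry: tuple[int, ...], recent_fraction: float = 0.25
) -> NetworkParams:
    """Flip units so every RF has leading excitation.

    A unit is flipped when the sum of its RF coefficients over the most
    recent quarter of time steps is negative; the flip transform leaves
    the network's predictions exactly unchanged.
    """
    out = params
    n_steps = geometry[0]
    n_recent = max(1, int(round(recent_fraction * n_steps)))
    for j in range(params.n_hidden):
        rf = out.W_in[j].reshape(geometry)  # time axis leads
        if rf[-n_recent:].sum() < 0:
            out = _flip_unit(out, j)
    return out


def grid_search(
    pair: PastFuturePair,
    val_pair: PastFuturePair,
    n_hidden_list: list[int],
    lam_list: list[float],
    base_cfg: TrainConfig | None = None,
) -> list[dict]:
    """Train one independently seeded network per (J, lambda) cell.

    Returns a list of row dicts (n_hidden, lam, val_mse, params,
    history); sort by val_mse to find the best predictor.
    """
    base_cfg = base_cfg or TrainConfig()
    if not n_hidden_list or not lam_list:
        raise ValueError("grids must be nonempty")
    rows = []
    for ci, n_hidden in enumerate(n_hidden_list):
        for cj, lam in enumerate(lam_list):
            cell_seed = (base_cfg.seed * 1_000_003 + ci * 1009 + cj) % (2**31)
            cfg = replace(base_cfg, n_hidden=n_hidden, lam=lam, seed=cell_seed)
            params, history = train(pair, cfg, val_pair)
            rows.append(
                {
                    "n_hidden": n_hidden,
                    "lam": lam,
                    "val_mse": validation_mse(params, val_pair.U, val_pair.V),
                    "params": params,
                    "history": history,
                }
            )
    return rows


def response_weighted_average(
    params: NetworkParams, n_samples: int = 10_000, seed: int = 0, batch: int = 2_000
) -> np.ndarray:
    """White-noise response-weighted average of each output unit.

    Feeds i.i.d. standard Gaussian inputs and averages input * response:
    RWA_k = (1/n) sum vhat_k(u) u, a [K x I] map. For a purely linear
    network this converges to the composed linear map's rows.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    i_dim = params.W_in.shape[1]
    k_dim = params.W_out.shape[0]
    acc = np.zeros((k_dim, i_dim))
    done = 0
    while done < n_samples:
        b = min(batch, n_samples - done)
        u = rng.standard_normal((b, i_dim))
        _, v_hat = forward(params, u)
        acc += v_hat.T @ u
        done += b
    return acc / n_samples


def population_sparsity(responses: np.ndarray) -> tuple[np.ndarray, float]:
    """Vinje-Gallant lifetime sparsity of each unit over a stimulus set.

    S = (1 - (mean r)^2 / mean(r^2)) / (1 - 1/n) for nonnegative
    responses r over n stimuli: 0 for constant responses, 1 for a
    one-hot response vector. Units that never respond get NaN.

    Parameters
    ----------
    responses : [n_stimuli x n_units] nonnegative activity matrix.

    Returns
    -------
    (per-unit sparsity, population mean over defined units)
    """
    r = np.asarray(responses, dtype=float)
    if np.any(r < 0):
        raise ValueError("Vinje-Gallant sparsity requires nonnegative responses")
    n = r.shape[0]
    if n < 2:
        raise ValueError("need at least two stimuli")
    mean_r = r.mean(axis=0)
    mean_r2 = (r**2).mean(axis=0)
    s = np.full(r.shape[1], np.nan)
    ok = mean_r2 > 0
    s[ok] = (1.0 - mean_r[ok] ** 2 / mean_r2[ok]) / (1.0 - 1.0 / n)
    if not np.any(ok):
        log.warning("all units silent: sparsity undefined")
        return s, float("nan")
    return s, float(np.nanmean(s))


def save_params(path: str, params: NetworkParams) -> None:
    with h5py.File(path, "w") as f:
        for key in ("W_in", "b_hidden", "W_out", "b_out"):
            f.create_dataset(key, data=getattr(params, key))
        f.attrs["nonlinearity"] = params.nonlinearity


def load_params(path: str) -> NetworkParams:
    with h5py.File(path, "r") as f:
        return NetworkParams(
            W_in=f["W_in"][...],
            b_hidden=f["b_hidden"][...],
            W_out=f["W_out"][...],
            b_out=f["b_out"][...],
            nonlinearity=str(f.attrs["nonlinearity"]),
        )
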