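"""Sparse coding control model: L1 activity prior, FISTA inference.

A linear generative model x ~ Phi a with unit-norm basis columns and an
L1 penalty on the code a. Inference solves

    min_a  0.5 ||x - Phi a||^2 + lambda ||a||_1

with FISTA (accelerated proximal gradient, step 1/L where L is the top
eigenvalue of Phi^T Phi). Dictionary learning alternates batched
inference with a gradient step on Phi driven by the reconstruction
residual, renormalizing columns after every update. Basis functions are
reshaped onto the stimulus grid and treated as RFs for comparison with
the prediction network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import RfSet

__all__ = ["BasisSet", "ScConfig", "fista_infer", "learn_dictionary", "basis_as_rfs"]


@dataclass
class BasisSet:
    """Unit-norm dictionary Phi [I x J_sc]."""

    Phi: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.Phi, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("basis columns must have unit norm")

    @property
    def n_units(self) -> int:
        return self.Phi.shape[1]


@dataclass
class ScConfig:
    n_units: int = 64
    lambda_act: float = 10**0.5
    learning_rate: float = 0.01
    batch_size: int = 100
    epochs: int = 1
    fista_iters: int = 100
    fista_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_act < 0:
            raise ValueError("lambda_act must be >= 0")


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def fista_infer(
    Phi: np.ndarray,
    x: np.ndarray,
    lambda_act: float,
    iters: int = 100,
    tol: float = 1e-6,
) -> np.ndarray:
    """FISTA codes for one input or a batch.

    ``x`` may be [I] or [n x I]; returns matching [J] or [n x J]. Stops
    early when the relative objective change drops below ``tol``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    Phi = np.asarray(Phi, dtype=float)
    single = np.asarray(x).ndim == 1
    X = np.atleast_2d(np.asarray(x, dtype=float))  # [n x I]
    gram = Phi.T @ Phi
    lipschitz = float(np.linalg.eigvalsh(gram)[-1])
    step = 1.0 / max(lipschitz, 1e-12)
    A = np.zeros((X.shape[0], Phi.shape[1]))
    Y = A.copy()
    t_k = 1.0
    prev_obj = np.inf
    for _ in range(iters):
        grad = (Y @ gram) - X @ Phi
        A_next = _soft(Y - step * grad, step * lambda_act)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
        Y = A_next + ((t_k - 1.0) / t_next) * (A_next - A)
        A, t_k = A_next, t_next
        resid = X - A @ Phi.T
        obj = 0.5 * float(np.sum(resid**2)) + lambda_act * float(np.abs(A).sum())
        if prev_obj < np.inf and abs(prev_obj - obj) <= tol * max(abs(prev_obj), 1.0):
            break
        prev_obj = obj
    return A[0] if single else A


def learn_dictionary(clips: np.ndarray, cfg: ScConfig) -> tuple[BasisSet, dict]:
    """Alternating FISTA inference and residual-driven dictionary updates.

    ``clips`` is [N x I] (flattened clips). Mini-batches are shuffled
    per pass; after each gradient step Phi's columns are renormalized to
    unit norm. Returns the basis and a history of per-batch objectives.
    """
    X = np.asarray(clips, dtype=float)
    if X.ndim != 2:
        raise ValueError("clips must be a flattened [N x I] matrix")
    n, i_dim = X.shape
    rng = np.random.default_rng(cfg.seed)
    Phi = rng.standard_normal((i_dim, cfg.n_units))
    Phi /= np.linalg.norm(Phi, axis=0, keepdims=True)
    history: dict[str, list[float]] = {"objective": []}
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = X[idx]
            codes = fista_infer(Phi, batch, cfg.lambda_act, cfg.fista_iters, cfg.fista_tol)
            resid = batch - codes @ Phi.T  # [b x I]
            if not np.all(np.isfinite(resid)):
                raise FloatingPointError("sparse coding update diverged (non-finite residual)")
            Phi += cfg.learning_rate * (resid.T @ codes) / len(idx)
            norms = np.linalg.norm(Phi, axis=0, keepdims=True)
            norms[norms < 1e-12] = 1.0
            Phi /= norms
            obj = 0.5 * float(np.sum(resid**2)) / len(idx) + cfg.lambda_act * float(
                np.abs(codes).sum()
            ) / len(idx)
            history["objective"].append(obj)
    return BasisSet(Phi=Phi), history


def basis_as_rfs(
    basis: BasisSet | np.ndarray, geometry: tuple[int, ...], leading_excitation: bool = True
) -> RfSet:
    """Reshape basis columns onto the stimulus grid as an RF set.

    ``geometry`` follows the flattening convention (time slowest); the
    time axis is moved last, matching the prediction model's RF layout.
    A basis function's sign is arbitrary, so with ``leading_excitation``
    each is flipped to make the most recent quarter of time steps sum
    nonnegative, as in the network's sign convention.
    """
    Phi = basis.Phi if isinstance(basis, BasisSet) else np.asarray(basis)
    i_dim, j_sc = Phi.shape
    if int(np.prod(geometry)) != i_dim:
        raise ValueError(f"geometry {geometry} incompatible with basis dimension {i_dim}")
    rfs = np.moveaxis(Phi.T.reshape(j_sc, *geometry), 1, -1)
    if leading_excitation:
        n_recent = max(1, int(round(0.25 * geometry[0])))
        flip = rfs[..., -n_recent:].sum(axis=tuple(range(1, rfs.ndim))) < 0
        rfs = rfs.copy()
        rfs[flip] *= -1
    strengths = np.sum(Phi**2, axis=0)
    return RfSet(rfs=rfs, strengths=strengths)
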