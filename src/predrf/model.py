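"""High-level modelling API: fit a model object, get a results object.

:class:`TemporalPrediction` wraps the prediction network; its ``fit``
returns a :class:`TemporalPredictionResults` carrying the trained
parameters, training history, receptive fields and diagnostics, with a
``summary()`` table. :class:`SparseCoding` does the same for the
control model. Both are built from a :class:`~predrf.data.ClipDataset`
or directly from design matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import network, sparse
from .data import ClipDataset, PastFuturePair, split_past_future

__all__ = [
    "TemporalPrediction",
    "TemporalPredictionResults",
    "SparseCoding",
    "SparseCodingResults",
]


class TemporalPrediction:
    """Temporal prediction network model.

    Parameters
    ----------
    past, future
        Design matrices U [N x I] and targets V [N x K]; the past and
        immediate future of each clip, flattened time-slowest.
    feature_shape
        Spatial/spectral shape of one time step, e.g. (20, 20) or (32,).
    n_past
        Number of past time steps per clip.
    nonlinearity
        Hidden-unit nonlinearity: logistic (default), tanh, linear, relu.
    """

    def __init__(
        self,
        past: np.ndarray,
        future: np.ndarray,
        feature_shape: tuple[int, ...],
        n_past: int,
        nonlinearity: str = "logistic",
    ) -> None:
        self.U = np.asarray(past, dtype=float)
        self.V = np.asarray(future, dtype=float)
        self.feature_shape = tuple(feature_shape)
        self.n_past = n_past
        self.nonlinearity = nonlinearity
        self._pair = PastFuturePair(
            U=self.U, V=self.V, feature_shape=self.feature_shape,
            n_past=n_past, n_future=0,
        )

    @classmethod
    def from_dataset(cls, ds: ClipDataset, nonlinearity: str = "logistic") -> "TemporalPrediction":
        pair = split_past_future(ds)
        model = cls(pair.U, pair.V, pair.feature_shape, pair.n_past, nonlinearity)
        model._pair = pair
        return model

    def fit(
        self,
        n_hidden: int = 64,
        lam: float = 1e-4,
        epochs: int = 50,
        batch_size: int = 200,
        lr: float = 1e-3,
        seed: int = 0,
        val_pair: PastFuturePair | None = None,
    ) -> "TemporalPredictionResults":
        cfg = network.TrainConfig(
            n_hidden=n_hidden, lam=lam, epochs=epochs, batch_size=batch_size,
            lr=lr, seed=seed, nonlinearity=self.nonlinearity,
        )
        params, history = network.train(self._pair, cfg, val_pair)
        return TemporalPredictionResults(self, params, history, cfg, val_pair)


class TemporalPredictionResults:
    """Trained network plus diagnostics."""

    def __init__(self, model, params, history, cfg, val_pair=None) -> None:
        self.model = model
        self.params = params
        self.history = history
        self.cfg = cfg
        self.val_pair = val_pair

    @property
    def geometry(self) -> tuple[int, ...]:
        return (self.model.n_past, *self.model.feature_shape)

    @property
    def train_mse(self) -> float:
        return network.validation_mse(self.params, self.model.U, self.model.V)

    @property
    def val_mse(self) -> float | None:
        if self.val_pair is None:
            return None
        return network.validation_mse(self.params, self.val_pair.U, self.val_pair.V)

    def predict(self, U: np.ndarray) -> np.ndarray:
        _, v_hat = network.forward(self.params, U)
        return v_hat

    def rfs(self, pruned: bool = True, sign_normalized: bool = True) -> network.RfSet:
        """Hidden-unit receptive fields on the stimulus grid, time last."""
        params = self.params
        if sign_normalized and self.model.nonlinearity in ("logistic", "tanh", "linear"):
            params = network.normalize_sign(params.copy(), self.geometry)
        rfset = network.extract_rfs(params, self.geometry)
        return network.prune_inactive(rfset) if pruned else rfset

    def sparsity(self, U: np.ndarray | None = None) -> float:
        """Mean Vinje-Gallant sparsity of hidden activities over stimuli."""
        if U is None:
            U = self.val_pair.U if self.val_pair is not None else self.model.U
        s, _ = network.forward(self.params, U)
        if self.model.nonlinearity == "tanh":
            s = np.abs(s)
        elif self.model.nonlinearity == "linear":
            s = np.maximum(s, 0.0)
        _, mean_s = network.population_sparsity(s)
        return mean_s

    def summary(self) -> str:
        rfset = self.rfs()
        lines = [
            "Temporal Prediction Network Results",
            "=" * 42,
            f"hidden units (J):        {self.params.n_hidden}",
            f"input dim (I):           {self.params.W_in.shape[1]}",
            f"output dim (K):          {self.params.W_out.shape[0]}",
            f"nonlinearity:            {self.params.nonlinearity}",
            f"L1 strength (lambda):    {self.cfg.lam:g}",
            f"epochs:                  {self.cfg.epochs}",
            f"training MSE:            {self.train_mse:.5f}",
        ]
        if self.val_mse is not None:
            lines.append(f"validation MSE:          {self.val_mse:.5f}")
        lines.append(f"active units (>=1% max): {int(rfset.active_mask.sum())}/{len(rfset)}")
        return "\n".join(lines)

    def plot_rfs(self, n: int = 16, ax_grid=None):
        """Tile the strongest active RFs (time-collapsed for 3D fields)."""
        import matplotlib.pyplot as plt

        rfset = self.rfs()
        order = np.argsort(rfset.strengths[rfset.active_mask])[::-1][:n]
        fields = rfset.active[order]
        cols = int(np.ceil(np.sqrt(len(fields))))
        rows = int(np.ceil(len(fields) / cols))
        fig, axes = plt.subplots(rows, cols, figsize=(2 * cols, 2 * rows), squeeze=False)
        for k, axx in enumerate(axes.ravel()):
            axx.axis("off")
            if k < len(fields):
                rf = fields[k]
                img = rf if rf.ndim == 2 else rf[..., -1]
                vmax = np.abs(img).max() or 1.0
                axx.imshow(img, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        fig.tight_layout()
        return fig


class SparseCoding:
    """Sparse coding model over flattened clips (the control model)."""

    def __init__(self, X: np.ndarray, feature_shape: tuple[int, ...], n_steps: int) -> None:
        self.X = np.asarray(X, dtype=float)
        self.feature_shape = tuple(feature_shape)
        self.n_steps = n_steps

    @classmethod
    def from_dataset(cls, ds: ClipDataset, use_past_only: bool = True) -> "SparseCoding":
        pair = split_past_future(ds)
        if use_past_only:
            return cls(pair.U, pair.feature_shape, pair.n_past)
        n = ds.n_clips
        return cls(ds.clips.reshape(n, -1), pair.feature_shape, ds.clip_length)

    def fit(
        self,
        n_units: int = 64,
        lambda_act: float = 10**0.5,
        learning_rate: float = 0.01,
        epochs: int = 1,
        batch_size: int = 100,
        seed: int = 0,
    ) -> "SparseCodingResults":
        cfg = sparse.ScConfig(
            n_units=n_units, lambda_act=lambda_act, learning_rate=learning_rate,
            epochs=epochs, batch_size=batch_size, seed=seed,
        )
        basis, history = sparse.learn_dictionary(self.X, cfg)
        return SparseCodingResults(self, basis, history, cfg)


class SparseCodingResults:
    def __init__(self, model, basis, history, cfg) -> None:
        self.model = model
        self.basis = basis
        self.history = history
        self.cfg = cfg

    def rfs(self) -> network.RfSet:
        geometry = (self.model.n_steps, *self.model.feature_shape)
        return sparse.basis_as_rfs(self.basis, geometry)

    def encode(self, X: np.ndarray) -> np.ndarray:
        return sparse.fista_infer(self.basis.Phi, X, self.cfg.lambda_act, self.cfg.fista_iters)

    def reconstruction_mse(self, X: np.ndarray) -> float:
        codes = self.encode(X)
        return float(np.mean((X - codes @ self.basis.Phi.T) ** 2))

    def summary(self) -> str:
        return "\n".join(
            [
                "Sparse Coding Results",
                "=" * 42,
                f"basis functions:      {self.basis.n_units}",
                f"input dim (I):        {self.basis.Phi.shape[0]}",
                f"activity L1 strength: {self.cfg.lambda_act:g}",
                f"final objective:      {self.history['objective'][-1]:.5f}",
            ]
        )


def grid_result_table(rows: list[dict]) -> pd.DataFrame:
    """Tabulate grid-search rows as (n_hidden, lam, val_mse, n_active)."""
    records = []
    for row in rows:
        rfset = network.prune_inactive(
            network.extract_rfs(row["params"], (1, row["params"].W_in.shape[1]))
        )
        records.append(
            {
                "n_hidden": row["n_hidden"],
                "lam": row["lam"],
                "val_mse": row["val_mse"],
                "n_active": int(rfset.active_mask.sum()),
            }
        )
    return pd.DataFrame.from_records(records)
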