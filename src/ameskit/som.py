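"""Kohonen self-organizing maps of fingerprint space.

A planar hexagonal grid of codebook vectors is trained by the online
best-matching-unit rule with linearly decaying learning rate and Gaussian
neighborhood.  Cells then summarize membership fractions (set origin,
Ames outcome, substructure presence) and model error (mean absolute
difference between predicted probability and the 0/1 experimental
class).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


def _hex_cell_distances(rows: int, cols: int) -> np.ndarray:
    """Pairwise hex-grid distances between cells in odd-r offset layout."""
    r, c = np.divmod(np.arange(rows * cols), cols)
    # offset -> axial -> cube coordinates
    q = c - (r - (r & 1)) // 2
    x, z = q, r
    y = -x - z
    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    dz = np.abs(z[:, None] - z[None, :])
    return np.maximum(np.maximum(dx, dy), dz).astype(float)


class SelfOrganizingMap(BaseEstimator):
    """Planar hexagonal SOM trained online (Euclidean distance).

    Parameters
    ----------
    rows, cols : int
        Grid shape; the study layout is 30 x 30.
    epochs : int
        Passes over the shuffled data; learning rate decays linearly from
        ``lr_start`` to ``lr_end`` and the Gaussian neighborhood radius
        from ``max(rows, cols)/2`` to ``sigma_end`` across epochs.
    seed : int
        Drives codebook initialization (random sample of input rows) and
        presentation order; identical seeds give identical codebooks.
    """

    def __init__(self, rows: int = 30, cols: int = 30, epochs: int = 100,
                 lr_start: float = 0.05, lr_end: float = 0.01,
                 sigma_start: float | None = None, sigma_end: float = 1.0,
                 seed: int = 0):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.sigma_start = sigma_start
        self.sigma_end = sigma_end
        self.seed = seed

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def _bmu(self, codebook: np.ndarray, x: np.ndarray) -> int:
        d = np.einsum("ij,ij->i", codebook, codebook) - 2.0 * codebook @ x + x @ x
        return int(np.argmin(d))  # ties break to the lowest cell index

    def fit(self, X, y=None):
        X = np.asarray(pd.DataFrame(X).to_numpy(dtype=float))
        if len(X) == 0:
            raise ValueError("empty input")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in input")
        rng = np.random.default_rng(self.seed)
        cells = self.n_cells
        # Random-uniform init within the per-feature data range: training
        # then monotonically improves quantization in expectation (a
        # data-sample init already quantizes well, and the topological
        # smoothing would only degrade it).
        lo, hi = X.min(axis=0), X.max(axis=0)
        codebook = rng.uniform(size=(cells, X.shape[1])) * (hi - lo) + lo
        cell_dist = _hex_cell_distances(self.rows, self.cols)
        self.initial_quantization_error_ = self._qe(codebook, X)
        sigma0 = self.sigma_start if self.sigma_start is not None else max(self.rows, self.cols) / 2.0
        for epoch in range(self.epochs):
            frac = epoch / max(1, self.epochs - 1)
            lr = self.lr_start + (self.lr_end - self.lr_start) * frac
            sigma = sigma0 + (self.sigma_end - sigma0) * frac
            for i in rng.permutation(len(X)):
                x = X[i]
                bmu = self._bmu(codebook, x)
                h = np.exp(-(cell_dist[bmu] ** 2) / (2.0 * sigma**2))
                codebook += (lr * h)[:, None] * (x - codebook)
        self.codebook_ = codebook
        self.cell_distances_ = cell_dist
        self.quantization_error_ = self._qe(codebook, X)
        return self

    @staticmethod
    def _assign(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
        d = (
            np.einsum("ij,ij->i", codebook, codebook)[None, :]
            - 2.0 * X @ codebook.T
            + np.einsum("ij,ij->i", X, X)[:, None]
        )
        return np.argmin(d, axis=1)

    def _qe(self, codebook: np.ndarray, X: np.ndarray) -> float:
        assign = self._assign(codebook, X)
        return float(np.mean(np.linalg.norm(X - codebook[assign], axis=1)))

    def predict(self, X) -> np.ndarray:
        """Best-matching cell index per row (argmin Euclidean distance,
        ties to the lowest cell index)."""
        X = np.asarray(pd.DataFrame(X).to_numpy(dtype=float))
        if X.shape[1] != self.codebook_.shape[1]:
            raise ValueError("dimension mismatch with trained codebook")
        return self._assign(self.codebook_, X)

    def to_json(self, path) -> None:
        payload = {
            "rows": self.rows, "cols": self.cols, "epochs": self.epochs,
            "lr_start": self.lr_start, "lr_end": self.lr_end,
            "sigma_start": self.sigma_start, "sigma_end": self.sigma_end,
            "seed": self.seed,
            "codebook": self.codebook_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SelfOrganizingMap":
        with open(path) as fh:
            payload = json.load(fh)
        codebook = np.asarray(payload.pop("codebook"))
        som = cls(**payload)
        som.codebook_ = codebook
        som.cell_distances_ = _hex_cell_distances(som.rows, som.cols)
        return som


def map_to_cells(som: SelfOrganizingMap, X) -> np.ndarray:
    return som.predict(X)


def cell_summary(
    n_cells: int,
    assignments,
    labels=None,
    predictions=None,
    flags: dict | None = None,
) -> pd.DataFrame:
    """Per-cell counts, property fractions and model MAE.

    MAE per cell is the mean of |predicted probability - experimental
    class| over members; empty cells are kept with ``n = 0`` and NaN
    statistics.
    """
    assignments = np.asarray(assignments)
    aligned = {"labels": labels, "predictions": predictions, **(flags or {})}
    for name, arr in aligned.items():
        if arr is not None and len(np.asarray(arr)) != len(assignments):
            raise ValueError(f"{name} length does not match assignments")
    out = {"cell": np.arange(n_cells), "n": np.bincount(assignments, minlength=n_cells)}
    df = pd.DataFrame(out).set_index("cell")

    def per_cell(values, reducer):
        values = np.asarray(values, dtype=float)
        col = np.full(n_cells, np.nan)
        for cell in np.unique(assignments):
            col[cell] = reducer(values[assignments == cell])
        return col

    if labels is not None:
        df["frac_positive"] = per_cell(labels, np.mean)
    for name, arr in (flags or {}).items():
        df[f"frac_{name}"] = per_cell(arr, np.mean)
    if predictions is not None:
        if labels is None:
            raise ValueError("predictions require labels for the error map")
        err = np.abs(np.asarray(predictions, dtype=float) - np.asarray(labels, dtype=float))
        df["mae"] = per_cell(err, np.mean)
    return df.reset_index()
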