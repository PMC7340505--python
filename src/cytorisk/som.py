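"""Batch-trained self-organizing map.

A small rectangular SOM (default 10 x 10 = 100 nodes) is trained on the
embedding coordinates; downstream metaclustering merges the node codebook
into the requested number of cell populations.  The batch update rule is
used because it is deterministic given the initialisation and fast in
vectorised form:

    w_j  <-  sum_i h(bmu(x_i), j) * x_i  /  sum_i h(bmu(x_i), j)

with a Gaussian neighborhood h of width sigma shrinking each epoch.
"""

from __future__ import annotations

import numpy as np

from .io import ValidationError

__all__ = ["SelfOrganizingMap"]


class SelfOrganizingMap:
    """Rectangular-grid batch SOM.

    Parameters
    ----------
    shape : (rows, cols)
        Grid dimensions; ``rows * cols`` codebook vectors.
    n_epochs : int
        Full passes of the batch update.
    sigma0 : float, optional
        Initial Gaussian neighborhood radius in grid units; defaults to
        half the larger grid dimension.  Decays linearly to 0.5.
    """

    def __init__(
        self,
        shape: tuple[int, int] = (10, 10),
        n_epochs: int = 10,
        sigma0: float | None = None,
    ) -> None:
        if shape[0] < 1 or shape[1] < 1:
            raise ValidationError("SOM grid must be at least 1x1")
        self.shape = shape
        self.n_nodes = shape[0] * shape[1]
        self.n_epochs = n_epochs
        self.sigma0 = sigma0 if sigma0 is not None else max(shape) / 2.0
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        # pairwise squared grid distance between nodes
        self._grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1)
        self.codebook: np.ndarray | None = None

    def fit(self, X: np.ndarray, seed: int = 0) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValidationError("X must be a nonempty 2-D array")
        rng = np.random.default_rng(seed)
        init_idx = rng.choice(X.shape[0], size=self.n_nodes, replace=X.shape[0] < self.n_nodes)
        W = X[init_idx].astype(float).copy()
        W += rng.normal(scale=1e-6, size=W.shape)  # break exact duplicates

        for epoch in range(self.n_epochs):
            frac = epoch / max(self.n_epochs - 1, 1)
            sigma = self.sigma0 + (0.5 - self.sigma0) * frac
            bmu = self._bmu(X, W)
            counts = np.bincount(bmu, minlength=self.n_nodes).astype(float)
            sums = np.empty_like(W)
            for f in range(X.shape[1]):
                sums[:, f] = np.bincount(bmu, weights=X[:, f], minlength=self.n_nodes)
            H = np.exp(-self._grid_d2 / (2.0 * sigma**2))
            num = H @ sums
            den = (H @ counts)[:, None]
            nonzero = den[:, 0] > 0
            W[nonzero] = num[nonzero] / den[nonzero]
        self.codebook = W
        return self

    @staticmethod
    def _bmu(X: np.ndarray, W: np.ndarray, block: int = 20000) -> np.ndarray:
        """Best-matching unit per sample, computed in blocks to bound memory."""
        out = np.empty(X.shape[0], dtype=np.int64)
        w_sq = (W**2).sum(1)
        for start in range(0, X.shape[0], block):
            chunk = X[start : start + block]
            d2 = w_sq[None, :] - 2.0 * chunk @ W.T
            out[start : start + block] = np.argmin(d2, axis=1)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Node assignment (0..n_nodes-1) per sample."""
        if self.codebook is None:
            raise ValidationError("SOM not fitted")
        return self._bmu(np.asarray(X, dtype=float), self.codebook)
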