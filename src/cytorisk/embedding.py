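"""Pluggable 2-D embedding of the pooled cell table.

The clustering stage can run on t-SNE coordinates (the reference choice),
UMAP coordinates, or directly on the selected marker channels
(``method='none'``), which is the fast path and demonstrates that the
pipeline is not tied to any particular dimensionality-reduction tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import CellTable, ValidationError

__all__ = ["Embedding", "embed"]


@dataclass
class Embedding:
    """Per-cell coordinates, row-aligned with the pooled CellTable."""

    coords: np.ndarray
    method: str
    seed: int
    params: dict = field(default_factory=dict)
    markers: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def embed(
    pooled: CellTable,
    markers: Sequence[str] | None = None,
    method: str = "tsne",
    params: dict | None = None,
    seed: int = 0,
) -> Embedding:
    """Embed the pooled cells with t-SNE, UMAP, or the identity.

    ``method='none'`` returns the selected marker submatrix unchanged
    (dimension = number of clustering markers); t-SNE and UMAP return two
    columns.  Deterministic under a fixed seed and parameter set.
    """
    params = dict(params or {})
    markers = list(markers) if markers is not None else list(pooled.marker_names)
    if not markers:
        raise ValidationError("markers must not be empty")
    X = pooled.marker_matrix(markers)

    if method == "none":
        coords = X.copy()
    elif method in ("tsne", "umap"):
        if X.shape[0] < 3:
            raise ValidationError("need at least 3 cells to embed")
        if method == "tsne":
            from sklearn.manifold import TSNE

            defaults = dict(perplexity=30.0, init="pca", max_iter=750)
            defaults.update(params)
            defaults["perplexity"] = min(
                defaults["perplexity"], max(2.0, (X.shape[0] - 1) / 3.0)
            )
            coords = TSNE(
                n_components=2, random_state=seed, **defaults
            ).fit_transform(X)
        else:
            import warnings

            from umap import UMAP

            defaults = dict(n_neighbors=15, min_dist=0.1)
            defaults.update(params)
            defaults["n_neighbors"] = min(defaults["n_neighbors"], X.shape[0] - 1)
            with warnings.catch_warnings():
                # UMAP warns that a fixed random_state disables parallelism;
                # determinism is the contract here
                warnings.simplefilter("ignore")
                coords = UMAP(
                    n_components=2, random_state=seed, **defaults
                ).fit_transform(X)
        coords = np.asarray(coords, dtype=float)
    else:
        raise ValidationError(f"unsupported embedding method {method!r}")

    return Embedding(coords=coords, method=method, seed=seed, params=params, markers=markers)
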