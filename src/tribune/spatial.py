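"""Neighborhood composition and recurrent cellular neighborhoods (RCNs).

For every cell, the fraction of neighboring cell types within a fixed radius
(closed ball, Euclidean, self excluded) forms a composition vector; k-means
on those vectors yields RCNs — recurring local tissue contexts such as a
tumor-stromal interface.  A cell with no neighbors inside the radius falls
back to a one-hot on its own type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

#: Radius (in coordinate units) conventionally used for imaging data.
DEFAULT_RADIUS = 100.0
#: Conventional RCN count; empty clusters may leave fewer distinct ids.
DEFAULT_K = 10


@dataclass
class NeighborhoodMatrix:
    """Rows = cells, columns = cell types; rows sum to 1."""

    cell_types: list[str]
    fractions: np.ndarray  # (n_cells, n_types)
    radius: float

    @property
    def n_cells(self) -> int:
        return self.fractions.shape[0]


def neighbor_fractions(coords, labels, radius: float) -> NeighborhoodMatrix:
    """Per-cell fractions of neighboring cell types within ``radius``.

    Neighbors are the other cells at Euclidean distance <= radius.  Uses a
    k-d tree; output is identical to the brute-force pairwise rule.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if len(coords) != len(labels):
        raise ValueError("coords and labels must be aligned")
    if radius <= 0:
        raise ValueError("radius must be positive")

    types = sorted(set(labels))
    type_index = {t: j for j, t in enumerate(types)}
    lab_idx = np.array([type_index[t] for t in labels])

    tree = cKDTree(coords)
    counts = np.zeros((len(coords), len(types)))
    for i, j in tree.query_pairs(r=radius):  # closed ball: distance <= radius
        counts[i, lab_idx[j]] += 1
        counts[j, lab_idx[i]] += 1
    totals = counts.sum(axis=1)
    fractions = np.zeros_like(counts)
    has = totals > 0
    fractions[has] = counts[has] / totals[has, None]
    lonely = np.flatnonzero(~has)
    fractions[lonely, lab_idx[lonely]] = 1.0  # self one-hot fallback
    return NeighborhoodMatrix(cell_types=types, fractions=fractions, radius=radius)


def rcn_cluster(nm: NeighborhoodMatrix, k: int = DEFAULT_K, seed: int = 0) -> np.ndarray:
    """k-means RCN ids (0..k-1) for each cell's neighborhood composition.

    Euclidean k-means with k-means++ initialization and 10 restarts,
    deterministic for a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > nm.n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({nm.n_cells})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(nm.fractions)
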