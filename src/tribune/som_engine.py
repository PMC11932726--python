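"""Self-organizing map training, quantization error and hyperparameter tuning.

A SOM quantizes the cells x markers matrix onto a small rectangular grid of
prototype ("node") vectors trained by online competitive learning: each step
draws one cell, finds its best-matching unit (BMU, nearest node by Euclidean
distance) and pulls nodes toward the cell with a Gaussian neighborhood kernel
whose spread (sigma) and learning rate decay asymptotically over iterations.

Map quality is the quantization error Q, the average Euclidean distance from
each cell to its BMU codebook vector; sigma and the learning rate can be
tuned by seeded random search minimizing Q over [0.001, 5]^2 (log-uniform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

#: Hyperparameter search space shared by sigma and the learning rate.
TUNE_BOUNDS = (0.001, 5.0)
#: Defaults evaluated as the first tuning trial.
DEFAULT_SIGMA = 1.0
DEFAULT_LEARNING_RATE = 0.5
#: Grid-side clamp for the Vesanto-style size heuristic.
MIN_SIDE, MAX_SIDE = 2, 50
#: Hard cap on online training steps.
MAX_ITERATIONS = 200_000
#: Sigma and learning rate decay exponentially to this fraction of their
#: initial values by the final training step.
END_FRACTION = 0.01


@dataclass
class SOMModel:
    """Trained map: grid geometry, codebook and the hyperparameters used."""

    rows: int
    cols: int
    codebook: np.ndarray  # (rows, cols, n_markers)
    sigma: float
    learning_rate: float
    n_iterations: int
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def weights(self) -> np.ndarray:
        """Codebook flattened to (n_nodes, n_markers), row-major node order."""
        return self.codebook.reshape(self.n_nodes, -1)


@dataclass
class NodeAssignment:
    """Per-cell BMU index plus per-node occupancy counts."""

    node_index: np.ndarray  # (n_cells,) ints in [0, n_nodes)
    occupancy: np.ndarray   # (n_nodes,) ints summing to n_cells

    def __post_init__(self) -> None:
        assert self.occupancy.sum() == len(self.node_index)


def grid_dims(n_cells: int) -> tuple[int, int]:
    """Square grid size for ``n_cells`` via the G = 5 * sqrt(N) node-count
    heuristic; side = ceil(sqrt(G)), clamped to [2, 50]."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    target_nodes = round(5.0 * math.sqrt(n_cells))
    side = math.ceil(math.sqrt(target_nodes))
    side = min(max(side, MIN_SIDE), MAX_SIDE)
    return side, side


def default_iterations(rows: int, cols: int, n_cells: int) -> int:
    """Default online step count: ~100 updates per node, at least one pass."""
    return min(max(100 * rows * cols, n_cells), MAX_ITERATIONS)


def _grid_sq_distances(rows: int, cols: int) -> np.ndarray:
    """(n_nodes, n_nodes) squared grid distances between node positions."""
    r, c = np.unravel_index(np.arange(rows * cols), (rows, cols))
    pos = np.column_stack([r, c]).astype(float)
    diff = pos[:, None, :] - pos[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _init_codebook(X: np.ndarray, n_nodes: int, rng: np.random.Generator,
                   init: str) -> np.ndarray:
    if init == "pca":
        # span the first two principal axes with a regular grid
        Xc = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        side = math.isqrt(n_nodes)
        side = max(side, 1)
        g1 = np.linspace(-1, 1, max(side, 2))[: max(side, 1)]
        coef = np.array([[a, b] for a in g1 for b in g1])[:n_nodes]
        while len(coef) < n_nodes:  # non-square node counts
            coef = np.vstack([coef, coef[: n_nodes - len(coef)]])
        scale = s[:2] / math.sqrt(max(len(X) - 1, 1))
        book = X.mean(axis=0) + coef * scale @ vt[:2]
        return book
    if init != "sample":
        raise ValueError(f"unknown codebook init {init!r}")
    replace = len(X) < n_nodes
    idx = rng.choice(len(X), size=n_nodes, replace=replace)
    return X[idx].astype(float).copy()


def train_som(
    X: np.ndarray,
    dims: tuple[int, int],
    sigma: float = DEFAULT_SIGMA,
    learning_rate: float = DEFAULT_LEARNING_RATE,
    n_iterations: int | None = None,
    seed: int = 0,
    init: str = "sample",
    return_initial: bool = False,
) -> SOMModel | tuple[SOMModel, np.ndarray]:
    """Train a SOM by online (random-sample) updates.

    Gaussian neighborhood on a rectangular grid, Euclidean BMU rule, and
    exponential decay of both sigma and the learning rate to 1% of their
    initial values over the run, so late updates are local and small and the
    codebook settles near per-node data centroids.  Deterministic for a
    given seed.  ``return_initial`` additionally returns a copy of the
    initial codebook (useful for checking that training reduces Q).
    """
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("X must be a non-empty 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    rows, cols = dims
    if rows < 1 or cols < 1:
        raise ValueError("grid dims must be positive")
    if sigma <= 0 or learning_rate <= 0:
        raise ValueError("sigma and learning_rate must be positive")
    n_nodes = rows * cols
    if n_iterations is None:
        n_iterations = default_iterations(rows, cols, len(X))

    rng = np.random.default_rng(seed)
    book = _init_codebook(X, n_nodes, rng, init)
    initial = book.copy() if return_initial else None
    grid_d2 = _grid_sq_distances(rows, cols)

    sample_idx = rng.integers(0, len(X), size=n_iterations)
    # decay factor reaching END_FRACTION at the final step
    rate = END_FRACTION ** (1.0 / max(n_iterations - 1, 1))
    decay = 1.0
    for t in range(n_iterations):
        sig_t = sigma * decay
        lr_t = learning_rate * decay
        decay *= rate
        x = X[sample_idx[t]]
        diff = book - x
        bmu = int(np.einsum("ij,ij->i", diff, diff).argmin())
        h = lr_t * np.exp(-grid_d2[bmu] / (2.0 * sig_t * sig_t))
        book -= h[:, None] * diff

    model = SOMModel(
        rows=rows,
        cols=cols,
        codebook=book.reshape(rows, cols, X.shape[1]),
        sigma=sigma,
        learning_rate=learning_rate,
        n_iterations=n_iterations,
        seed=seed,
    )
    if return_initial:
        return model, initial
    return model


def _bmu_indices(weights: np.ndarray, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Per-row nearest codebook vector; ties go to the lowest node index."""
    if X.shape[1] != weights.shape[1]:
        raise ValueError(
            f"dimension mismatch: data has {X.shape[1]} markers, "
            f"codebook has {weights.shape[1]}"
        )
    out = np.empty(len(X), dtype=int)
    for start in range(0, len(X), chunk):
        block = X[start:start + chunk]
        d = cdist(block, weights, metric="sqeuclidean")
        out[start:start + chunk] = d.argmin(axis=1)  # argmin keeps first = lowest index
    return out


def quantization_error(model_or_weights: SOMModel | np.ndarray, X: np.ndarray) -> float:
    """Q = mean Euclidean distance from each sample to its BMU codebook vector."""
    weights = (
        model_or_weights.weights
        if isinstance(model_or_weights, SOMModel)
        else np.asarray(model_or_weights, dtype=float)
    )
    X = np.asarray(X, dtype=float)
    bmu = _bmu_indices(weights, X)
    return float(np.linalg.norm(X - weights[bmu], axis=1).mean())


def map_to_nodes(model: SOMModel, X: np.ndarray) -> NodeAssignment:
    """Assign every cell to its best-matching node."""
    X = np.asarray(X, dtype=float)
    bmu = _bmu_indices(model.weights, X)
    occupancy = np.bincount(bmu, minlength=model.n_nodes)
    return NodeAssignment(node_index=bmu, occupancy=occupancy)


@dataclass
class TuningResult:
    """Outcome of the quantization-error search over (sigma, learning rate)."""

    sigma: float
    learning_rate: float
    best_q: float
    trials: list[tuple[float, float, float]] = field(default_factory=list)

    def __iter__(self):  # allows (sigma, lr, q) unpacking
        return iter((self.sigma, self.learning_rate, self.best_q))


def tune_hyperparameters(
    X: np.ndarray,
    dims: tuple[int, int],
    n_trials: int = 20,
    seed: int = 0,
    n_iterations: int | None = None,
) -> TuningResult:
    """Random search for (sigma, learning rate) minimizing quantization error.

    Trial 1 always evaluates the package defaults (sigma=1.0, lr=0.5), so
    tuning can never return a worse Q than the defaults; remaining trials
    sample log-uniformly from [0.001, 5]^2.  All trials train with the same
    seed so candidates are compared on equal footing.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = np.log(TUNE_BOUNDS[0]), np.log(TUNE_BOUNDS[1])
    candidates = [(DEFAULT_SIGMA, DEFAULT_LEARNING_RATE)]
    for _ in range(n_trials - 1):
        sig, lr = np.exp(rng.uniform(lo, hi, size=2))
        candidates.append((float(sig), float(lr)))

    trials: list[tuple[float, float, float]] = []
    for sig, lr in candidates:
        model = train_som(X, dims, sigma=sig, learning_rate=lr,
                          n_iterations=n_iterations, seed=seed)
        trials.append((sig, lr, quantization_error(model, X)))
    best = min(trials, key=lambda t: t[2])
    return TuningResult(sigma=best[0], learning_rate=best[1], best_q=best[2],
                        trials=trials)
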