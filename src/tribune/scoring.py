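"""Knowledge-based scoring of SOM nodes (or single cells) against cell types.

Each SOM cluster is summarized by its per-marker median into a node matrix,
min-max scaled per marker across nodes so values lie in [0, 1].  For a cell
type i the expected value of marker j is the 99th percentile of the scaled
column when the logic entry is +1 (robust stand-in for the maximum) and the
column minimum when it is -1; neutral markers (0) are excluded.  The score

    s_i(n_k) = (1 / |M_i|) * sum_{j in M_i} [1 - (v_kj - vhat_ij)^2]

averages the complement of the squared deviation over the |M_i| non-neutral
markers, so it is bounded in [0, 1].  A row is labeled with the argmax cell
type unless its best score falls below ``other_threshold`` ("other": low
signal across all candidates) or the best-vs-runner-up gap falls below
``undefined_threshold`` ("undefined": ambiguous identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import OTHER_LABEL, UNDEFINED_LABEL, LogicTable

#: Percentile used for the positive-marker reference value.
REFERENCE_PERCENTILE = 99.0


@dataclass
class Thresholds:
    """Ambiguity cutoffs on the [0, 1] score scale."""

    other_threshold: float = 0.04
    undefined_threshold: float = 0.001

    def __post_init__(self) -> None:
        for name in ("other_threshold", "undefined_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class NodeMatrix:
    """Per-node median marker expression with node occupancy."""

    node_ids: np.ndarray      # original node indices of non-empty nodes
    marker_names: list[str]
    values: np.ndarray        # (n_nodes, n_markers)
    occupancy: np.ndarray     # cells per retained node

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def marker_values(self, markers: list[str]) -> np.ndarray:
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise ValueError(f"markers missing from node matrix: {missing}")
        idx = [self.marker_names.index(m) for m in markers]
        return self.values[:, idx]


@dataclass
class ScoreTable:
    """Rows = nodes (or cells), columns = one logic table's cell types."""

    row_ids: np.ndarray
    cell_types: list[str]
    scores: np.ndarray  # (n_rows, n_types) in [0, 1]

    def __post_init__(self) -> None:
        eps = 1e-9
        if self.scores.size and (
            self.scores.min() < -eps or self.scores.max() > 1 + eps
        ):
            raise AssertionError("scores escaped [0, 1]")
        self.scores = np.clip(self.scores, 0.0, 1.0)

    def best(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(best label, best score, best-minus-second gap) per row.

        Ties take the earliest logic-table row.  With a single cell-type
        column the gap is defined as the best score minus zero.
        """
        order = np.argsort(-self.scores, axis=1, kind="stable")
        best_idx = order[:, 0]
        rows = np.arange(len(self.scores))
        best_score = self.scores[rows, best_idx]
        if self.scores.shape[1] > 1:
            second = self.scores[rows, order[:, 1]]
        else:
            second = np.zeros(len(self.scores))
        labels = np.array(self.cell_types, dtype=object)[best_idx]
        return labels, best_score, best_score - second


def build_node_matrix(X: np.ndarray, assignment, marker_names: list[str]) -> NodeMatrix:
    """Per-marker median over each non-empty node's member cells."""
    node_index = assignment.node_index
    occ = assignment.occupancy
    keep = np.flatnonzero(occ > 0)
    values = np.empty((len(keep), X.shape[1]))
    order = np.argsort(node_index, kind="stable")
    sorted_nodes = node_index[order]
    bounds = np.searchsorted(sorted_nodes, keep)
    bounds = np.append(bounds, len(order))
    for i, node in enumerate(keep):
        members = order[bounds[i]:bounds[i + 1]]
        values[i] = np.median(X[members], axis=0)
    return NodeMatrix(
        node_ids=keep,
        marker_names=list(marker_names),
        values=values,
        occupancy=occ[keep],
    )


def scale_node_matrix(nm: NodeMatrix) -> NodeMatrix:
    """Min-max scale each marker across nodes into [0, 1]; constant -> 0."""
    lo = nm.values.min(axis=0)
    hi = nm.values.max(axis=0)
    span = hi - lo
    scaled = np.zeros_like(nm.values)
    ok = span > 0
    scaled[:, ok] = (nm.values[:, ok] - lo[ok]) / span[ok]
    return NodeMatrix(nm.node_ids.copy(), list(nm.marker_names), scaled,
                      nm.occupancy.copy())


def reference_vector(nm_scaled: NodeMatrix, logic_row: np.ndarray) -> np.ndarray:
    """Expected scaled value per marker for one cell type.

    +1 -> 99th percentile of the column (linear interpolation); -1 -> column
    minimum; 0 -> NaN (excluded from scoring).
    """
    values = nm_scaled.values
    vhat = np.full(values.shape[1], np.nan)
    pos = logic_row == 1
    neg = logic_row == -1
    if pos.any():
        vhat[pos] = np.percentile(values[:, pos], REFERENCE_PERCENTILE, axis=0)
    if neg.any():
        vhat[neg] = values[:, neg].min(axis=0)
    return vhat


def score_nodes(nm_scaled: NodeMatrix, logic: LogicTable) -> ScoreTable:
    """Score every node against every cell type of one logic table."""
    values = nm_scaled.marker_values(logic.markers)
    scores = np.empty((nm_scaled.n_nodes, logic.n_types))
    for i, row in enumerate(logic.entries):
        used = row != 0
        vhat = reference_vector(
            NodeMatrix(nm_scaled.node_ids, logic.markers, values, nm_scaled.occupancy),
            row,
        )
        dev = values[:, used] - vhat[used]
        scores[:, i] = 1.0 - (dev * dev).mean(axis=1)
    return ScoreTable(row_ids=nm_scaled.node_ids, cell_types=list(logic.cell_types),
                      scores=scores)


def score_cells(X: np.ndarray, logic: LogicTable, marker_names: list[str],
                row_ids: np.ndarray | None = None) -> ScoreTable:
    """Per-cell fallback: the identical pipeline with cells standing in for
    nodes (min-max scale per marker across the subset, P99/min references,
    same score formula)."""
    if len(X) == 0:
        raise ValueError("cell subset is empty")
    if row_ids is None:
        row_ids = np.arange(len(X))
    nm = NodeMatrix(
        node_ids=np.asarray(row_ids),
        marker_names=list(marker_names),
        values=np.asarray(X, dtype=float),
        occupancy=np.ones(len(X), dtype=int),
    )
    return score_nodes(scale_node_matrix(nm), logic)


def assign_labels(scores: ScoreTable, thresholds: Thresholds) -> np.ndarray:
    """Label each row: "other" if the best score is below ``other_threshold``,
    else "undefined" if the gap is below ``undefined_threshold``, else the
    argmax cell type."""
    labels, best, gap = scores.best()
    out = labels.copy()
    out[gap < thresholds.undefined_threshold] = UNDEFINED_LABEL
    out[best < thresholds.other_threshold] = OTHER_LABEL
    return out
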