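"""Hierarchical phenotyping pipeline: cluster, score and label per level.

The root logic table is applied to all cells; each deeper table is applied
only to the cells currently carrying its parent label.  Large subsets are
SOM-clustered first and every cell inherits its node's label and scores;
subsets at or below ``min_cluster_size`` are scored per cell, which keeps
rare populations from being absorbed into coarse clusters.  Cells labeled
"other" or "undefined" never cascade to deeper levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import som_engine
from .data_model import (
    NOT_EVALUATED,
    ExpressionMatrix,
    LabelResult,
    LogicHierarchy,
    LogicTable,
)
from .preprocess import Recipe, apply_recipe, make_recipe
from .scoring import (
    NodeMatrix,
    ScoreTable,
    Thresholds,
    assign_labels,
    build_node_matrix,
    scale_node_matrix,
    score_cells,
    score_nodes,
)

logger = logging.getLogger("tribune")


@dataclass
class SomConfig:
    """SOM settings for the pipeline; ``dims=None`` uses the size heuristic."""

    sigma: float = som_engine.DEFAULT_SIGMA
    learning_rate: float = som_engine.DEFAULT_LEARNING_RATE
    n_iterations: int | None = None
    dims: tuple[int, int] | None = None
    tune: bool = False
    n_trials: int = 20


@dataclass
class RunConfig:
    """Everything a phenotyping run needs besides the data and logic."""

    recipe: Recipe = ()
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_cluster_size: int = 1000
    som: SomConfig = field(default_factory=SomConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a parsed YAML/JSON mapping."""
    som_raw = dict(raw.get("som", {}))
    if "dims" in som_raw and som_raw["dims"] is not None:
        som_raw["dims"] = tuple(int(v) for v in som_raw["dims"])
    scoring_raw = dict(raw.get("scoring", {}))
    return RunConfig(
        recipe=make_recipe(raw.get("recipe", [])),
        thresholds=Thresholds(
            other_threshold=float(scoring_raw.get("other_threshold", 0.04)),
            undefined_threshold=float(scoring_raw.get("undefined_threshold", 0.001)),
        ),
        min_cluster_size=int(raw.get("min_cluster_size", 1000)),
        som=SomConfig(**som_raw),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class LevelOutput:
    """Per-level artifacts: per-cell labels/scores plus the score table and
    (on the SOM path) the node matrix."""

    labels: np.ndarray
    best_scores: np.ndarray
    score_gaps: np.ndarray
    score_table: ScoreTable
    node_matrix: NodeMatrix | None


def run_level(
    X_subset: ExpressionMatrix,
    logic: LogicTable,
    cfg: RunConfig,
    level_index: int = 0,
) -> LevelOutput:
    """Cluster-and-score one logic table on one cell subset.

    Subsets larger than ``cfg.min_cluster_size`` take the SOM path
    (grid size heuristic, train, map, node-median matrix, scale, score,
    label; cells inherit node labels).  Smaller subsets are scored per cell.
    The level's SOM seed is ``cfg.seed + level_index`` so levels differ but
    the whole run is reproducible.
    """
    if X_subset.n_cells == 0:
        raise ValueError("cell subset is empty")
    values = X_subset.marker_values(logic.markers)
    seed = cfg.seed + level_index

    if X_subset.n_cells > cfg.min_cluster_size:
        dims = cfg.som.dims or som_engine.grid_dims(X_subset.n_cells)
        sigma, lr = cfg.som.sigma, cfg.som.learning_rate
        if cfg.som.tune:
            tuned = som_engine.tune_hyperparameters(
                values, dims, n_trials=cfg.som.n_trials, seed=seed,
                n_iterations=cfg.som.n_iterations,
            )
            sigma, lr = tuned.sigma, tuned.learning_rate
            logger.info("level %d: tuned sigma=%.4g lr=%.4g (Q=%.4g)",
                        level_index, sigma, lr, tuned.best_q)
        model = som_engine.train_som(
            values, dims, sigma=sigma, learning_rate=lr,
            n_iterations=cfg.som.n_iterations, seed=seed,
        )
        assignment = som_engine.map_to_nodes(model, values)
        nm = build_node_matrix(values, assignment, logic.markers)
        nm_scaled = scale_node_matrix(nm)
        table = score_nodes(nm_scaled, logic)
        node_labels = assign_labels(table, cfg.thresholds)
        _, node_best, node_gap = table.best()
        # cells inherit their node's label and scores
        node_pos = np.full(model.n_nodes, -1, dtype=int)
        node_pos[nm.node_ids] = np.arange(nm.n_nodes)
        pos = node_pos[assignment.node_index]
        return LevelOutput(
            labels=node_labels[pos],
            best_scores=node_best[pos],
            score_gaps=node_gap[pos],
            score_table=table,
            node_matrix=nm,
        )

    table = score_cells(values, logic, logic.markers)
    labels = assign_labels(table, cfg.thresholds)
    _, best, gap = table.best()
    return LevelOutput(labels=labels, best_scores=best, score_gaps=gap,
                       score_table=table, node_matrix=None)


def run(
    X: ExpressionMatrix,
    hierarchy: LogicHierarchy,
    cfg: RunConfig,
) -> LabelResult:
    """Run the full hierarchy and return per-cell labels for every level.

    The root level sees all cells; a deeper table sees the cells whose
    current deepest label equals its parent label ("other"/"undefined"
    cells therefore never cascade).  An empty parent population skips the
    level with a warning.  The preprocessing recipe is applied once, up
    front, to the full matrix.
    """
    X.marker_values(hierarchy.all_markers())  # fail fast on missing markers
    Xp = apply_recipe(X, cfg.recipe) if cfg.recipe else X

    n, L = X.n_cells, len(hierarchy.levels)
    labels = np.full((n, L), NOT_EVALUATED, dtype=object)
    best = np.full((n, L), np.nan)
    gaps = np.full((n, L), np.nan)
    current = np.full(n, NOT_EVALUATED, dtype=object)  # deepest label so far

    for j, logic in enumerate(hierarchy.levels):
        if j == 0:
            mask = np.ones(n, dtype=bool)
        else:
            mask = current == logic.parent_label
        if not mask.any():
            logger.warning("level %r: no cells carry parent label %r; skipped",
                           logic.level_name, logic.parent_label)
            continue
        out = run_level(Xp.subset(mask), logic, cfg, level_index=j)
        idx = np.flatnonzero(mask)
        labels[idx, j] = out.labels
        best[idx, j] = out.best_scores
        gaps[idx, j] = out.score_gaps
        current[idx] = out.labels

    return LabelResult(
        cell_ids=list(X.cell_ids),
        level_names=hierarchy.level_names,
        labels=labels,
        best_scores=best,
        score_gaps=gaps,
    )
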