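"""Ground-truthed synthetic single-cell tables with matched logic hierarchies.

Emulates the structure a knowledge-based phenotyper assumes: a mixture of
cell populations, each defined by positive / negative / neutral marker roles.
Marker intensities are truncated Gaussians — positive markers high, negative
and neutral markers low — plus additive measurement noise, on a roughly
[0, 1] scale.  Intensity realism (lognormal tails, spillover, batch
artifacts) is deliberately out of scope; the point is a benchmark whose
ground truth and separability are controlled exactly.

The spatial variant places cells inside circular domains with per-domain
composition, producing the spatially clustered neighborhoods the spatial
module is meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    ROOT_PARENT,
    ExpressionMatrix,
    LogicHierarchy,
    LogicTable,
    ValidationError,
)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic mixture.

    ``roles`` is a (types x markers) matrix over {-1, 0, 1}: the marker is
    drawn around ``positive_mean`` for +1 and ``negative_mean`` otherwise
    (neutral markers are uninformative low background).  ``parents`` maps
    each cell type to its coarse class when ``hierarchy_depth`` is 2; a
    parent with a single child must share that child's name.
    """

    n_cells: int
    cell_types: list[str]
    proportions: list[float]
    markers: list[str]
    roles: np.ndarray
    positive_mean: float = 0.8
    negative_mean: float = 0.2
    sd: float = 0.1
    noise_sd: float = 0.05
    hierarchy_depth: int = 1
    parents: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.roles = np.asarray(self.roles, dtype=int)
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        if len(self.cell_types) != len(self.proportions):
            raise ValidationError("one proportion per cell type required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError(f"proportions sum to {sum(self.proportions)}, not 1")
        if any(p < 0 for p in self.proportions):
            raise ValidationError("proportions must be non-negative")
        if self.roles.shape != (len(self.cell_types), len(self.markers)):
            raise ValidationError("roles must be (n_types, n_markers)")
        if not np.isin(self.roles, (-1, 0, 1)).all():
            raise ValidationError("roles must be in {-1, 0, 1}")
        if not (self.roles == 1).any(axis=1).all():
            bad = [t for t, r in zip(self.cell_types, self.roles) if not (r == 1).any()]
            raise ValidationError(f"cell types without a positive marker: {bad}")
        if not self.positive_mean > self.negative_mean:
            raise ValidationError("positive_mean must exceed negative_mean")
        if self.sd <= 0 or self.noise_sd < 0:
            raise ValidationError("sd must be > 0 and noise_sd >= 0")
        if self.hierarchy_depth not in (1, 2):
            raise ValidationError("hierarchy_depth must be 1 or 2")
        if self.hierarchy_depth == 2:
            if self.parents is None or set(self.parents) != set(self.cell_types):
                raise ValidationError("depth-2 specs need a parent for every cell type")


@dataclass
class SimulationResult:
    expression: ExpressionMatrix
    truth: pd.DataFrame            # cell_id + one column per hierarchy level + final
    hierarchy: LogicHierarchy
    domain_ids: np.ndarray | None = None


def largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Integer class counts summing to n, by the largest-remainder rule.

    Ties in the fractional remainders go to earlier classes.
    """
    exact = np.asarray(proportions, dtype=float) * n
    base = np.floor(exact).astype(int)
    leftover = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:leftover]] += 1
    return base


def _parent_order(spec: SyntheticSpec) -> list[str]:
    seen: dict[str, None] = {}
    for t in spec.cell_types:
        seen.setdefault(spec.parents[t])
    return list(seen)


def build_hierarchy(spec: SyntheticSpec) -> LogicHierarchy:
    """Logic hierarchy encoding exactly the spec's marker roles.

    Depth 1: a single root table equal to ``roles``.  Depth 2: a root table
    over parent classes (entry +1/-1 where all children agree, else 0) plus
    one sub-table per parent with two or more children.
    """
    if spec.hierarchy_depth == 1:
        return LogicHierarchy([
            LogicTable("global", ROOT_PARENT, list(spec.cell_types),
                       list(spec.markers), spec.roles)
        ])
    parents = _parent_order(spec)
    root_entries = np.zeros((len(parents), len(spec.markers)), dtype=int)
    for i, p in enumerate(parents):
        child_rows = spec.roles[[spec.cell_types.index(t)
                                 for t in spec.cell_types if spec.parents[t] == p]]
        root_entries[i, (child_rows == 1).all(axis=0)] = 1
        root_entries[i, (child_rows == -1).all(axis=0)] = -1
    levels = [LogicTable("global", ROOT_PARENT, parents, list(spec.markers),
                         root_entries)]
    for p in parents:
        children = [t for t in spec.cell_types if spec.parents[t] == p]
        if len(children) == 1:
            if children[0] != p:
                raise ValidationError(
                    f"singleton parent {p!r} must share its child's name"
                )
            continue
        rows = spec.roles[[spec.cell_types.index(t) for t in children]]
        levels.append(LogicTable(f"{p}_subtypes", p, children,
                                 list(spec.markers), rows))
    return LogicHierarchy(levels)


def _draw_values(spec: SyntheticSpec, type_index: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    means = np.where(spec.roles == 1, spec.positive_mean, spec.negative_mean)
    values = rng.normal(means[type_index], spec.sd)
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=values.shape)
    return np.clip(values, 0.0, None)


def _truth_frame(spec: SyntheticSpec, cell_ids: list[str],
                 type_index: np.ndarray, hierarchy: LogicHierarchy) -> pd.DataFrame:
    types = np.array(spec.cell_types, dtype=object)[type_index]
    truth = pd.DataFrame({"cell_id": cell_ids})
    if spec.hierarchy_depth == 1:
        truth[hierarchy.level_names[0]] = types
    else:
        truth[hierarchy.level_names[0]] = [spec.parents[t] for t in types]
        for name in hierarchy.level_names[1:]:
            truth[name] = types
    truth["final"] = types
    return truth


def simulate(spec: SyntheticSpec) -> SimulationResult:
    """Draw a ground-truthed expression table for ``spec``.

    Class counts follow the proportions exactly (largest remainder); cell
    order is shuffled; deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    counts = largest_remainder_counts(spec.n_cells, spec.proportions)
    type_index = np.repeat(np.arange(len(spec.cell_types)), counts)
    rng.shuffle(type_index)
    values = _draw_values(spec, type_index, rng)
    cell_ids = [f"cell_{i:06d}" for i in range(spec.n_cells)]
    hierarchy = build_hierarchy(spec)
    expression = ExpressionMatrix(cell_ids, list(spec.markers), values)
    return SimulationResult(expression, _truth_frame(spec, cell_ids, type_index, hierarchy),
                            hierarchy)


# ---------------------------------------------------------------------------
# Spatial variant
# ---------------------------------------------------------------------------


@dataclass
class DomainLayout:
    """Circular tissue domains on a rectangular field.

    ``proportions`` optionally overrides the cell-type mix per domain
    (one vector per domain); by default every domain uses the spec's mix.
    """

    k_domains: int = 2
    domain_radius: float = 100.0
    field_size: tuple[float, float] = (1000.0, 1000.0)
    proportions: list[list[float]] | None = None
    centers: list[tuple[float, float]] | None = None  # random placement if None

    def __post_init__(self) -> None:
        if self.k_domains < 1:
            raise ValidationError("k_domains must be >= 1")
        if self.domain_radius <= 0:
            raise ValidationError("domain_radius must be positive")
        if min(self.field_size) < 2 * self.domain_radius:
            raise ValidationError(
                f"field {self.field_size} cannot contain a domain of "
                f"diameter {2 * self.domain_radius}"
            )
        if self.proportions is not None and len(self.proportions) != self.k_domains:
            raise ValidationError("need one proportion vector per domain")
        if self.centers is not None:
            if len(self.centers) != self.k_domains:
                raise ValidationError("need one center per domain")
            w, h = self.field_size
            r = self.domain_radius
            for cx, cy in self.centers:
                if not (r <= cx <= w - r and r <= cy <= h - r):
                    raise ValidationError(
                        f"domain at ({cx}, {cy}) does not fit inside the field"
                    )


def simulate_spatial(spec: SyntheticSpec, layout: DomainLayout) -> SimulationResult:
    """Spatially clustered mixture: cells uniform inside circular domains,
    each domain with its own cell-type composition."""
    rng = np.random.default_rng(spec.seed)
    w, h = layout.field_size
    r = layout.domain_radius
    if layout.centers is not None:
        centers = np.asarray(layout.centers, dtype=float)
    else:
        centers = np.column_stack([
            rng.uniform(r, w - r, size=layout.k_domains),
            rng.uniform(r, h - r, size=layout.k_domains),
        ])
    per_domain = largest_remainder_counts(
        spec.n_cells, [1.0 / layout.k_domains] * layout.k_domains
    )
    type_chunks, coord_chunks, domain_chunks = [], [], []
    for d in range(layout.k_domains):
        props = (layout.proportions[d] if layout.proportions is not None
                 else spec.proportions)
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValidationError(f"domain {d} proportions sum to {sum(props)}")
        counts = largest_remainder_counts(per_domain[d], props)
        ti = np.repeat(np.arange(len(spec.cell_types)), counts)
        rng.shuffle(ti)
        rad = r * np.sqrt(rng.uniform(size=per_domain[d]))
        ang = rng.uniform(0, 2 * np.pi, size=per_domain[d])
        coord_chunks.append(centers[d] + np.column_stack([rad * np.cos(ang),
                                                          rad * np.sin(ang)]))
        type_chunks.append(ti)
        domain_chunks.append(np.full(per_domain[d], d))
    type_index = np.concatenate(type_chunks)
    coords = np.vstack(coord_chunks)
    domain_ids = np.concatenate(domain_chunks)
    values = _draw_values(spec, type_index, rng)
    cell_ids = [f"cell_{i:06d}" for i in range(spec.n_cells)]
    hierarchy = build_hierarchy(spec)
    expression = ExpressionMatrix(cell_ids, list(spec.markers), values, coords=coords)
    return SimulationResult(expression,
                            _truth_frame(spec, cell_ids, type_index, hierarchy),
                            hierarchy, domain_ids=domain_ids)


# ---------------------------------------------------------------------------
# Built-in presets
# ---------------------------------------------------------------------------

_PANEL = ["PanCK", "Ecad", "aSMA", "Vimentin", "CD3", "CD8",
          "CD20", "CD79a", "CD68", "CD163", "CD31", "CD34"]
_TYPES = ["Tumor", "Stroma", "Tcell", "Bcell", "Macrophage", "Endothelial"]
_PROPORTIONS = [0.30, 0.25, 0.15, 0.12, 0.10, 0.08]


def _block_roles(n_types: int, n_markers: int, per_type: int = 2) -> np.ndarray:
    roles = -np.ones((n_types, n_markers), dtype=int)
    for i in range(n_types):
        roles[i, per_type * i: per_type * (i + 1)] = 1
    return roles


def default_spec(n_cells: int = 20_000, seed: int = 0) -> SyntheticSpec:
    """Standard benchmark: 6 populations, 12 markers (two dedicated positive
    markers per type), well-separated means 0.8/0.2 at sd 0.1 with noise 0.05."""
    return SyntheticSpec(
        n_cells=n_cells,
        cell_types=list(_TYPES),
        proportions=list(_PROPORTIONS),
        markers=list(_PANEL),
        roles=_block_roles(6, 12),
        seed=seed,
    )


def hard_spec(n_cells: int = 5_000, seed: int = 0) -> SyntheticSpec:
    """Deliberately ambiguous mixture: overlapping means (0.6 vs 0.4) and one
    positive marker shared between two types, exercising the "undefined" path."""
    markers = ["M_shared", "M_a", "M_b", "M_c", "M_d"]
    types = ["TypeA", "TypeB", "TypeC"]
    roles = np.array([
        [1, 1, 0, -1, -1],   # TypeA
        [1, 0, 1, -1, -1],   # TypeB shares M_shared with TypeA
        [-1, -1, -1, 1, 1],  # TypeC
    ])
    return SyntheticSpec(
        n_cells=n_cells,
        cell_types=types,
        proportions=[0.4, 0.4, 0.2],
        markers=markers,
        roles=roles,
        positive_mean=0.6,
        negative_mean=0.4,
        sd=0.1,
        noise_sd=0.05,
        seed=seed,
    )


def hierarchical_spec(n_cells: int = 20_000, seed: int = 0) -> SyntheticSpec:
    """Two-level benchmark: root classes Tumor / Stromal / Immune, with
    immune subtypes (T, B, macrophage) split under a shared CD45 signal."""
    markers = _PANEL + ["CD45"]
    roles = _block_roles(6, 13)
    immune = [_TYPES.index(t) for t in ("Tcell", "Bcell", "Macrophage")]
    roles[:, 12] = -1
    roles[immune, 12] = 1
    # Vimentin is positive for endothelium too, giving the Stromal root class
    # a shared positive marker alongside immune CD45.
    roles[_TYPES.index("Endothelial"), _PANEL.index("Vimentin")] = 1
    parents = {
        "Tumor": "Tumor",
        "Stroma": "Stromal",
        "Endothelial": "Stromal",
        "Tcell": "Immune",
        "Bcell": "Immune",
        "Macrophage": "Immune",
    }
    return SyntheticSpec(
        n_cells=n_cells,
        cell_types=list(_TYPES),
        proportions=list(_PROPORTIONS),
        markers=markers,
        roles=roles,
        hierarchy_depth=2,
        parents=parents,
        seed=seed,
    )


def spatial_spec(n_cells: int = 4_000, seed: int = 0) -> tuple[SyntheticSpec, DomainLayout]:
    """Two circular domains with complementary compositions (tumor-rich vs
    stroma-rich), sized for neighborhood analysis at a 100-unit radius."""
    spec = default_spec(n_cells=n_cells, seed=seed)
    layout = DomainLayout(
        k_domains=2,
        domain_radius=150.0,
        field_size=(1000.0, 1000.0),
        proportions=[
            [0.70, 0.05, 0.10, 0.05, 0.05, 0.05],
            [0.05, 0.55, 0.10, 0.05, 0.10, 0.15],
        ],
        # separated by more than the conventional 100-unit neighbor radius
        centers=[(250.0, 500.0), (750.0, 500.0)],
    )
    return spec, layout
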