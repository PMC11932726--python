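"""Core data structures and table I/O for knowledge-based cell phenotyping.

The two user-facing inputs are a single-cell marker-expression table
(rows = cells, columns = markers, plus optional identifier / sample /
centroid columns) and a hierarchy of *logic tables*: per-level matrices
over {-1, 0, 1} stating, for each candidate cell type, which markers are
expected present (+1), absent (-1) or uninformative (0).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("tribune")

#: Parent sentinel naming the root of a logic hierarchy.
ROOT_PARENT = "root"
#: Label given to rows whose best score falls below ``other_threshold``.
OTHER_LABEL = "other"
#: Label given to rows whose top two scores are closer than ``undefined_threshold``.
UNDEFINED_LABEL = "undefined"
#: Sentinel for a (cell, level) pair that was never evaluated.
NOT_EVALUATED = ""

RESERVED_LABELS = frozenset({OTHER_LABEL, UNDEFINED_LABEL, NOT_EVALUATED})


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Cells x markers measurement table.

    Parameters
    ----------
    cell_ids
        Unique string identifier per cell (unique within a sample).
    marker_names
        Unique marker (column) names.
    values
        Float matrix of shape ``(n_cells, n_markers)``; no missing values.
    sample_id
        Optional per-cell sample identifier.
    coords
        Optional ``(n_cells, 2)`` array of x/y centroids in image units.
    """

    cell_ids: list[str]
    marker_names: list[str]
    values: np.ndarray
    sample_id: list[str] | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.cell_ids) != n:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n} value rows"
            )
        if len(self.marker_names) != m:
            raise ValidationError(
                f"{len(self.marker_names)} marker names for {m} value columns"
            )
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at row {bad[0]}, marker "
                f"{self.marker_names[bad[1]]!r}"
            )
        if len(set(self.marker_names)) != m:
            dupes = sorted({x for x in self.marker_names if self.marker_names.count(x) > 1})
            raise ValidationError(f"duplicate marker names: {dupes}")
        self._check_unique_cell_ids()
        if self.sample_id is not None and len(self.sample_id) != n:
            raise ValidationError("sample_id length does not match cell count")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValidationError("coords must be an (n_cells, 2) array")

    def _check_unique_cell_ids(self) -> None:
        samples = self.sample_id if self.sample_id is not None else ["" for _ in self.cell_ids]
        seen: set[tuple[str, str]] = set()
        for sid, cid in zip(samples, self.cell_ids):
            key = (sid, cid)
            if key in seen:
                raise ValidationError(f"duplicate cell id {cid!r} within sample {sid!r}")
            seen.add(key)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_values(self, markers: Sequence[str]) -> np.ndarray:
        """Return the value columns for ``markers``, reindexed by name.

        A requested marker absent from the table is a hard error: silently
        dropping it would silently change downstream scores.
        """
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise ValidationError(
                f"markers missing from expression table: {missing}"
            )
        idx = [self.marker_names.index(m) for m in markers]
        return self.values[:, idx]

    def subset(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            cell_ids=[self.cell_ids[i] for i in idx],
            marker_names=list(self.marker_names),
            values=self.values[idx],
            sample_id=None if self.sample_id is None else [self.sample_id[i] for i in idx],
            coords=None if self.coords is None else self.coords[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.marker_names)
        df.insert(0, "cell_id", self.cell_ids)
        if self.sample_id is not None:
            df["sample_id"] = self.sample_id
        if self.coords is not None:
            df["x"] = self.coords[:, 0]
            df["y"] = self.coords[:, 1]
        return df


# ---------------------------------------------------------------------------
# LogicTable / LogicHierarchy
# ---------------------------------------------------------------------------


@dataclass
class LogicTable:
    """One hierarchy level: cell types x markers over {-1, 0, 1}."""

    level_name: str
    parent_label: str
    cell_types: list[str]
    markers: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.shape != (len(self.cell_types), len(self.markers)):
            raise ValidationError(
                f"logic table {self.level_name!r}: entries shape "
                f"{self.entries.shape} does not match "
                f"{len(self.cell_types)} cell types x {len(self.markers)} markers"
            )
        if not np.isin(self.entries, (-1, 0, 1)).all():
            r, c = np.argwhere(~np.isin(self.entries, (-1, 0, 1)))[0]
            raise ValidationError(
                f"logic table {self.level_name!r}: entry for cell type "
                f"{self.cell_types[r]!r}, marker {self.markers[c]!r} is "
                f"{self.entries[r, c]!r}, not in {{-1, 0, 1}}"
            )
        self.entries = self.entries.astype(int)
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValidationError(
                f"logic table {self.level_name!r}: duplicate cell types"
            )
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError(
                f"logic table {self.level_name!r}: duplicate markers"
            )
        for ct in self.cell_types:
            if ct in RESERVED_LABELS:
                raise ValidationError(
                    f"logic table {self.level_name!r}: {ct!r} is a reserved "
                    "label and cannot be a cell type"
                )
        no_pos = [
            ct for ct, row in zip(self.cell_types, self.entries) if not (row == 1).any()
        ]
        if no_pos:
            raise ValidationError(
                f"logic table {self.level_name!r}: cell types with no positive "
                f"marker: {no_pos} (each cell type needs at least one +1 entry)"
            )

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.cell_types, columns=self.markers)


@dataclass
class LogicHierarchy:
    """Ordered levels of logic tables; the first level is the root."""

    levels: list[LogicTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValidationError("a logic hierarchy needs at least one level")
        names = [lv.level_name for lv in self.levels]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate level names: {names}")
        if self.levels[0].parent_label != ROOT_PARENT:
            raise ValidationError(
                f"first level {names[0]!r} must have parent {ROOT_PARENT!r}, "
                f"got {self.levels[0].parent_label!r}"
            )
        declared: set[str] = set(self.levels[0].cell_types)
        for lv in self.levels[1:]:
            if lv.parent_label not in declared:
                raise ValidationError(
                    f"level {lv.level_name!r}: parent label "
                    f"{lv.parent_label!r} is not a cell type declared at an "
                    "earlier level"
                )
            declared |= set(lv.cell_types)

    @property
    def level_names(self) -> list[str]:
        return [lv.level_name for lv in self.levels]

    def all_markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for lv in self.levels:
            for m in lv.markers:
                seen.setdefault(m)
        return list(seen)


# ---------------------------------------------------------------------------
# LabelResult
# ---------------------------------------------------------------------------


@dataclass
class LabelResult:
    """Per-cell labels across hierarchy levels.

    ``labels``, ``best_scores`` and ``score_gaps`` are ``(n_cells, n_levels)``
    arrays; a cell not evaluated at a level carries :data:`NOT_EVALUATED` and
    NaN scores there.
    """

    cell_ids: list[str]
    level_names: list[str]
    labels: np.ndarray          # dtype object, strings
    best_scores: np.ndarray     # float, NaN where not evaluated
    score_gaps: np.ndarray      # float, NaN where not evaluated

    def __post_init__(self) -> None:
        n, L = len(self.cell_ids), len(self.level_names)
        self.labels = np.asarray(self.labels, dtype=object)
        self.best_scores = np.asarray(self.best_scores, dtype=float)
        self.score_gaps = np.asarray(self.score_gaps, dtype=float)
        for arr, name in ((self.labels, "labels"), (self.best_scores, "best_scores"),
                          (self.score_gaps, "score_gaps")):
            if arr.shape != (n, L):
                raise ValidationError(f"{name} must have shape ({n}, {L})")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def final_level_index(self) -> np.ndarray:
        """Index of the deepest evaluated level per cell (-1 if none)."""
        evaluated = self.labels != NOT_EVALUATED
        idx = np.full(self.n_cells, -1, dtype=int)
        for j in range(len(self.level_names)):
            idx[evaluated[:, j]] = j
        return idx

    def final_labels(self) -> np.ndarray:
        """Deepest non-sentinel label per cell."""
        idx = self.final_level_index()
        out = np.empty(self.n_cells, dtype=object)
        for i, j in enumerate(idx):
            out[i] = NOT_EVALUATED if j < 0 else self.labels[i, j]
        return out

    def path(self, i: int) -> list[str]:
        """Chain of labels from root to the deepest evaluated level for cell i."""
        out = []
        for j in range(len(self.level_names)):
            if self.labels[i, j] == NOT_EVALUATED:
                break
            out.append(self.labels[i, j])
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids})
        for j, name in enumerate(self.level_names):
            df[name] = self.labels[:, j].astype(str)
        idx = self.final_level_index()
        df["final_label"] = self.final_labels().astype(str)
        rows = np.arange(self.n_cells)
        safe = np.maximum(idx, 0)
        df["best_score"] = np.where(idx >= 0, self.best_scores[rows, safe], np.nan)
        df["score_gap"] = np.where(idx >= 0, self.score_gaps[rows, safe], np.nan)
        return df


# ---------------------------------------------------------------------------
# Expression table I/O
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path,
    marker_columns: Sequence[str] | None = None,
    id_column: str | None = None,
    sample_column: str | None = None,
    x_column: str | None = None,
    y_column: str | None = None,
    sep: str = ",",
) -> ExpressionMatrix:
    """Read a delimited-text (or Parquet, by extension) expression table.

    Columns not named as markers, identifiers or coordinates are dropped
    with a logged warning.  Without ``marker_columns``, every column not
    claimed by one of the named roles is treated as a marker.
    """
    path = Path(path)
    if path.suffix.lower() == ".parquet":
        df = pd.read_parquet(path)
    else:
        import csv

        with open(path, newline="", encoding="utf-8") as fh:
            try:
                header = next(csv.reader(fh, delimiter=sep))
            except StopIteration:
                raise ValidationError(f"{path.name} is empty (missing header)") from None
        if len(set(header)) != len(header):  # pandas silently mangles duplicates
            dupes = sorted({c for c in header if header.count(c) > 1})
            raise ValidationError(f"duplicate column names in {path.name}: {dupes}")
        df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValidationError(f"duplicate column names in {path.name}: {dupes}")

    special = [c for c in (id_column, sample_column, x_column, y_column) if c is not None]
    for col in special:
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not found in {path.name}")

    if marker_columns is None:
        markers = [c for c in df.columns if c not in special]
    else:
        markers = list(marker_columns)
        missing = [m for m in markers if m not in df.columns]
        if missing:
            raise ValidationError(f"marker columns not found: {missing}")
        dropped = [c for c in df.columns if c not in markers and c not in special]
        if dropped:
            logger.warning("dropping unrecognized columns: %s", dropped)

    values = np.empty((len(df), len(markers)), dtype=float)
    for j, m in enumerate(markers):
        col = pd.to_numeric(df[m], errors="coerce")
        bad = col.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric or empty value in marker column {m!r} at row {row}"
            )
        values[:, j] = col.to_numpy(dtype=float)

    cell_ids = (
        df[id_column].astype(str).tolist()
        if id_column is not None
        else [str(i) for i in range(len(df))]
    )
    sample_id = df[sample_column].astype(str).tolist() if sample_column else None
    coords = None
    if (x_column is None) != (y_column is None):
        raise ValidationError("x_column and y_column must be given together")
    if x_column is not None:
        coords = df[[x_column, y_column]].to_numpy(dtype=float)
    return ExpressionMatrix(cell_ids, markers, values, sample_id, coords)


def write_expression_table(X: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    """Write an expression table as CSV (cell_id, markers, sample_id, x, y).

    Floats are printed with 17 significant digits so a write/read round trip
    reproduces the values bit for bit.
    """
    X.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Logic hierarchy I/O
# ---------------------------------------------------------------------------

_LOGIC_FILE_RE = re.compile(r"^(\d+)_(.+?)__(.+?)\.csv$")


def _logic_from_frame(df: pd.DataFrame, level_name: str, parent_label: str) -> LogicTable:
    cell_types = df.iloc[:, 0].astype(str).tolist()
    markers = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:].to_numpy()
    entries = np.empty(raw.shape)
    for (r, c), v in np.ndenumerate(raw):
        try:
            entries[r, c] = float(v)
        except (TypeError, ValueError):
            raise ValidationError(
                f"logic table {level_name!r}: non-numeric entry {v!r} for cell "
                f"type {cell_types[r]!r}, marker {markers[c]!r}"
            ) from None
    if not np.isin(entries, (-1.0, 0.0, 1.0)).all():
        r, c = np.argwhere(~np.isin(entries, (-1.0, 0.0, 1.0)))[0]
        raise ValidationError(
            f"logic table {level_name!r}: entry {entries[r, c]} for cell type "
            f"{cell_types[r]!r}, marker {markers[c]!r} is outside {{-1, 0, 1}}"
        )
    return LogicTable(level_name, parent_label, cell_types, markers, entries.astype(int))


def read_logic_hierarchy(path: str | Path) -> LogicHierarchy:
    """Read a logic hierarchy from a CSV directory or an XLSX workbook.

    Directory layout: one ``<order>_<level_name>__<parent_label>.csv`` per
    level, root parent named ``root``; first column = cell types, remaining
    columns = markers.  Workbook layout: sheet order = level order, cell A1
    holds ``parent=<label>``, the table itself starts at row 2 with a header
    of cell types + markers.  Both are read into identical hierarchies.
    """
    path = Path(path)
    if path.is_dir():
        parsed = []
        for f in sorted(path.glob("*.csv")):
            m = _LOGIC_FILE_RE.match(f.name)
            if m is None:
                raise ValidationError(
                    f"logic file {f.name!r} does not match "
                    "<order>_<level_name>__<parent_label>.csv"
                )
            parsed.append((int(m.group(1)), m.group(2), m.group(3), f))
        if not parsed:
            raise ValidationError(f"no logic tables found in {path}")
        parsed.sort(key=lambda t: t[0])
        levels = [
            _logic_from_frame(pd.read_csv(f, header=0), name, parent)
            for _, name, parent, f in parsed
        ]
        return LogicHierarchy(levels)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return _read_logic_workbook(path)
    raise ValidationError(
        f"{path} is neither a directory of logic CSVs nor an XLSX workbook"
    )


def _read_logic_workbook(path: Path) -> LogicHierarchy:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    levels = []
    for ws in wb.worksheets:
        rows = list(ws.values)
        if not rows or rows[0][0] is None or not str(rows[0][0]).startswith("parent="):
            raise ValidationError(
                f"sheet {ws.title!r}: cell A1 must hold 'parent=<label>'"
            )
        parent = str(rows[0][0]).split("=", 1)[1]
        if len(rows) < 2:
            raise ValidationError(f"sheet {ws.title!r}: missing header row")
        header = [c for c in rows[1] if c is not None]
        body = [list(r[: len(header)]) for r in rows[2:] if any(v is not None for v in r)]
        df = pd.DataFrame(body, columns=[str(h) for h in header])
        levels.append(_logic_from_frame(df, ws.title, parent))
    wb.close()
    return LogicHierarchy(levels)


def write_logic_hierarchy(hierarchy: LogicHierarchy, directory: str | Path) -> None:
    """Write one ``<order>_<level>__<parent>.csv`` per level."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, lv in enumerate(hierarchy.levels, start=1):
        df = lv.to_frame().reset_index(names="cell_type")
        df.to_csv(directory / f"{i}_{lv.level_name}__{lv.parent_label}.csv", index=False)


# ---------------------------------------------------------------------------
# Label I/O
# ---------------------------------------------------------------------------


def write_labels(result: LabelResult, path: str | Path, sep: str = ",") -> None:
    """Write one row per cell: cell_id, per-level labels, final label + scores."""
    result.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_labels(path: str | Path, sep: str = ",") -> LabelResult:
    """Read a label table written by :func:`write_labels`."""
    df = pd.read_csv(path, sep=sep, keep_default_na=False)
    fixed = {"cell_id", "final_label", "best_score", "score_gap"}
    level_names = [c for c in df.columns if c not in fixed]
    labels = df[level_names].to_numpy(dtype=object)
    n, L = labels.shape
    best = np.full((n, L), np.nan)
    gaps = np.full((n, L), np.nan)
    # Per-level scores are not serialized; restore the final level's pair.
    res = LabelResult(df["cell_id"].astype(str).tolist(), level_names, labels, best, gaps)
    idx = res.final_level_index()
    score = pd.to_numeric(df["best_score"], errors="coerce").to_numpy()
    gap = pd.to_numeric(df["score_gap"], errors="coerce").to_numpy()
    for i, j in enumerate(idx):
        if j >= 0:
            best[i, j] = score[i]
            gaps[i, j] = gap[i]
    return res
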