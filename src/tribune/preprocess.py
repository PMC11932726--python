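"""Composable per-marker normalization recipes.

Multiplexed-imaging intensity tables are routinely clipped at a high
percentile, log-transformed, z-scored and/or arcsinh-compressed before
phenotyping; suspension cytometry tables are usually rescaled to their
99.5th-percentile maximum.  A :class:`Recipe` is an ordered list of such
steps, each applied column-wise (marker scales are incommensurable, so no
step is ever global).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np

from .data_model import ExpressionMatrix, ValidationError


class ConfigError(ValueError):
    """Raised for malformed recipes or unknown step names."""


@dataclass(frozen=True)
class Step:
    """One normalization step; ``param`` is the percentile or cofactor."""

    name: str
    param: float | None = None

    def __post_init__(self) -> None:
        if self.name in ("log1p", "zscore", "minmax"):
            if self.param is not None:
                raise ConfigError(f"step {self.name!r} takes no parameter")
        elif self.name == "clip_percentile":
            if self.param is None or not 50 < self.param <= 100:
                raise ConfigError(
                    f"clip_percentile needs a percentile in (50, 100], got {self.param}"
                )
        elif self.name == "arcsinh":
            if self.param is None or self.param <= 0:
                raise ConfigError(f"arcsinh needs a positive cofactor, got {self.param}")
        else:
            raise ConfigError(f"unknown preprocessing step {self.name!r}")


Recipe = tuple[Step, ...]


def make_recipe(steps: Iterable[Union[str, dict, Step]]) -> Recipe:
    """Build a recipe from config-style entries.

    Accepts plain names (``"log1p"``) and one-key mappings
    (``{"clip_percentile": 99.9}``, ``{"arcsinh": 5}``), as they appear in a
    YAML/JSON config list.
    """
    out: list[Step] = []
    for s in steps:
        if isinstance(s, Step):
            out.append(s)
        elif isinstance(s, str):
            out.append(Step(s))
        elif isinstance(s, dict) and len(s) == 1:
            (name, param), = s.items()
            out.append(Step(name, float(param)))
        else:
            raise ConfigError(f"malformed recipe entry {s!r}")
    return tuple(out)


def default_recipe(kind: str) -> Recipe:
    """Standard recipe for ``"imaging"`` or ``"suspension"`` data.

    Imaging: 99.9th-percentile clipping, log1p, z-score, arcsinh(5).
    Suspension: 99.5th-percentile clipping then min-max to [0, 1]
    (rescaling by a percentile-defined maximum).
    """
    if kind == "imaging":
        return make_recipe([{"clip_percentile": 99.9}, "log1p", "zscore", {"arcsinh": 5}])
    if kind == "suspension":
        return make_recipe([{"clip_percentile": 99.5}, "minmax"])
    raise ConfigError(f"unknown recipe kind {kind!r}; expected 'imaging' or 'suspension'")


def _apply_step(values: np.ndarray, step: Step, marker_names: list[str]) -> np.ndarray:
    if step.name == "log1p":
        if (values < 0).any():
            j = int(np.argwhere((values < 0).any(axis=0)).ravel()[0])
            raise ValidationError(
                f"log1p requires non-negative values; marker {marker_names[j]!r} "
                "has negatives"
            )
        return np.log1p(values)
    if step.name == "zscore":
        mean = values.mean(axis=0)
        sd = values.std(axis=0)
        out = np.zeros_like(values)
        ok = sd > 0
        out[:, ok] = (values[:, ok] - mean[ok]) / sd[ok]
        return out
    if step.name == "clip_percentile":
        # linear interpolation between order statistics
        cap = np.percentile(values, step.param, axis=0)
        return np.minimum(values, cap)
    if step.name == "arcsinh":
        return np.arcsinh(values / step.param)
    if step.name == "minmax":
        lo = values.min(axis=0)
        hi = values.max(axis=0)
        span = hi - lo
        out = np.zeros_like(values)
        ok = span > 0
        out[:, ok] = (values[:, ok] - lo[ok]) / span[ok]
        return out
    raise ConfigError(f"unknown preprocessing step {step.name!r}")


def apply_recipe(X: ExpressionMatrix, recipe: Recipe) -> ExpressionMatrix:
    """Apply each step in order, column-wise, returning a new matrix."""
    values = X.values.copy()
    for step in recipe:
        values = _apply_step(values, step, X.marker_names)
    return ExpressionMatrix(
        cell_ids=list(X.cell_ids),
        marker_names=list(X.marker_names),
        values=values,
        sample_id=None if X.sample_id is None else list(X.sample_id),
        coords=None if X.coords is None else X.coords.copy(),
    )
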