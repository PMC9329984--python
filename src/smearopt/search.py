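"""Hyperparameter search-space description and unit-cube coordinates.

The optimizer works internally on the unit cube ``[0, 1]^d``.  Each search
variable maps its natural range onto ``[0, 1]`` either linearly or on a
``log10`` scale, and may be continuous or integer-valued.  Integer variables
are represented on the cube by the images of their admissible integer values
(a finite grid); denormalization rounds back to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "SearchVariable",
    "SearchSpace",
    "paper_search_space",
]


@dataclass(frozen=True)
class SearchVariable:
    """One dimension of the hyperparameter domain.

    Parameters
    ----------
    name:
        Unique identifier of the variable.
    lower, upper:
        Inclusive bounds in natural units; ``lower < upper``.
    scale:
        ``"linear"`` or ``"log10"``.  A log10 scale requires ``lower > 0``.
    kind:
        ``"continuous"`` or ``"integer"``.  Integer variables require
        integral bounds.
    """

    name: str
    lower: float
    upper: float
    scale: str = "linear"
    kind: str = "continuous"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"unknown scale {self.scale!r} for {self.name!r}")
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if not self.lower < self.upper:
            raise ValueError(
                f"variable {self.name!r}: lower ({self.lower}) must be "
                f"strictly below upper ({self.upper})"
            )
        if self.scale == "log10" and self.lower <= 0:
            raise ValueError(
                f"variable {self.name!r}: log10 scale requires lower > 0"
            )
        if self.kind == "integer" and (
            self.lower != int(self.lower) or self.upper != int(self.upper)
        ):
            raise ValueError(
                f"variable {self.name!r}: integer kind requires integral bounds"
            )

    def to_unit(self, value: float) -> float:
        """Map a natural-units value onto [0, 1]."""
        if not (self.lower <= value <= self.upper):
            raise ValueError(
                f"variable {self.name!r}: value {value} outside bounds "
                f"[{self.lower}, {self.upper}]"
            )
        if self.scale == "log10":
            lo, hi = math.log10(self.lower), math.log10(self.upper)
            return (math.log10(value) - lo) / (hi - lo)
        return (value - self.lower) / (self.upper - self.lower)

    def from_unit(self, u: float) -> float:
        """Map a unit-cube coordinate back to natural units."""
        u = min(max(float(u), 0.0), 1.0)
        if self.scale == "log10":
            lo, hi = math.log10(self.lower), math.log10(self.upper)
            value = 10.0 ** (lo + u * (hi - lo))
        else:
            value = self.lower + u * (self.upper - self.lower)
        if self.kind == "integer":
            return float(int(round(value)))
        return value

    def unit_grid(self) -> np.ndarray | None:
        """Unit-cube images of the admissible values (integer kind only)."""
        if self.kind != "integer":
            return None
        values = np.arange(int(self.lower), int(self.upper) + 1)
        return np.array([self.to_unit(v) for v in values])


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of :class:`SearchVariable` with unique names."""

    variables: tuple[SearchVariable, ...]

    def __init__(self, variables: Iterable[SearchVariable]) -> None:
        variables = tuple(variables)
        names = [v.name for v in variables]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")
        object.__setattr__(self, "variables", variables)

    @property
    def dimension(self) -> int:
        return len(self.variables)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> SearchVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def normalize(self, raw: Mapping[str, float]) -> np.ndarray:
        """Map a point in natural units to the unit cube."""
        missing = set(self.names) - set(raw)
        if missing:
            raise ValueError(f"missing variables: {sorted(missing)}")
        return np.array([v.to_unit(raw[v.name]) for v in self.variables])

    def denormalize(self, unit: np.ndarray) -> dict[str, float]:
        """Map a unit-cube vector back to natural units (integers rounded)."""
        unit = np.asarray(unit, dtype=float)
        if unit.shape != (self.dimension,):
            raise ValueError(
                f"expected vector of length {self.dimension}, got {unit.shape}"
            )
        return {v.name: v.from_unit(u) for v, u in zip(self.variables, unit)}

    def snap(self, unit: np.ndarray) -> np.ndarray:
        """Project unit-cube points onto the representable grid.

        Integer-kind coordinates are moved to the image of the nearest
        admissible integer; continuous coordinates are clipped to [0, 1].
        Accepts a single vector or an ``(m, d)`` array.
        """
        pts = np.atleast_2d(np.asarray(unit, dtype=float)).copy()
        pts = np.clip(pts, 0.0, 1.0)
        for j, v in enumerate(self.variables):
            grid = v.unit_grid()
            if grid is not None:
                idx = np.abs(pts[:, [j]] - grid[None, :]).argmin(axis=1)
                pts[:, j] = grid[idx]
        return pts[0] if np.asarray(unit).ndim == 1 else pts

    def to_config(self) -> list[dict]:
        """YAML/JSON-friendly description of every variable."""
        return [
            {
                "name": v.name,
                "lower": v.lower,
                "upper": v.upper,
                "scale": v.scale,
                "kind": v.kind,
            }
            for v in self.variables
        ]

    @classmethod
    def from_config(cls, entries: Iterable[Mapping]) -> "SearchSpace":
        return cls(SearchVariable(**dict(e)) for e in entries)


def paper_search_space() -> SearchSpace:
    """The four-variable CNN hyperparameter domain used throughout.

    Initial learning rate (1e-2 .. 1, log10), convolutional block depth
    (integers 1..6), SGDM momentum (0.75 .. 0.99, linear) and L2
    regularization coefficient (1e-11 .. 1e-2, log10).
    """
    return SearchSpace(
        [
            SearchVariable("initial_learning_rate", 1e-2, 1.0, "log10"),
            SearchVariable("cbd", 1, 6, "linear", "integer"),
            SearchVariable("momentum", 0.75, 0.99, "linear"),
            SearchVariable("regularization", 1e-11, 1e-2, "log10"),
        ]
    )
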