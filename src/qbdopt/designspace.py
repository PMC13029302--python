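"""Design-space overlay maps: per-response feasibility and their intersection.

The overlay is a sensitivity map of the design space over a 2-D slice of
the factor domain: each quality constraint (e.g. recovery >= 90 %)
produces a boolean mask on the slice lattice, and the intersection of
all masks is the multi-response design space.  Optimizer solutions can
be marked on the map with an in/out-of-region flag.  Discrete factors
that are not on the slice axes must sit at anchor levels — the map shows
admissible operating points, never relaxed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .factors import FactorSpace
from .model import PolynomialModel


@dataclass(frozen=True)
class OverlayConstraint:
    """A threshold on one response: direction '<=' or '>='."""

    response: str
    direction: str
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("<=", ">="):
            raise ValueError("direction must be '<=' or '>='")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")

    def satisfied(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return z <= self.threshold if self.direction == "<=" else z >= self.threshold

    @property
    def label(self) -> str:
        return f"{self.response}{self.direction}{self.threshold:g}"


@dataclass(frozen=True)
class MarkedPoint:
    label: str
    x: float
    y: float
    in_region: bool


@dataclass(frozen=True)
class OverlayGrid:
    """Feasibility masks over a 2-D slice of the coded factor domain."""

    free: tuple
    fixed: dict
    axis_x: np.ndarray
    axis_y: np.ndarray
    masks: dict  # constraint label -> bool array, shape (len(axis_x), len(axis_y))
    points: tuple = field(default_factory=tuple)

    @property
    def intersection(self) -> np.ndarray:
        out = np.ones(next(iter(self.masks.values())).shape, dtype=bool)
        for m in self.masks.values():
            out &= m
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per lattice cell."""
        X, Y = np.meshgrid(self.axis_x, self.axis_y, indexing="ij")
        data = {self.free[0]: X.ravel(), self.free[1]: Y.ravel()}
        for label, mask in self.masks.items():
            data[label] = mask.ravel()
        data["intersection"] = self.intersection.ravel()
        return pd.DataFrame(data)


def overlay_masks(models: dict, constraints, free: tuple, fixed: dict,
                  resolution: int = 101, space: FactorSpace | None = None) -> OverlayGrid:
    """Evaluate each constraint on a [-1, 1]^2 lattice over the slice.

    `fixed` holds coded levels for the non-free factors; with a factor
    space supplied, free factors must be continuous and fixed discrete
    factors must sit at anchors.
    """
    if len(free) != 2:
        raise ValueError("exactly two free factors required")
    constraints = list(constraints)
    labels = [c.label for c in constraints]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate constraint labels")
    for c in constraints:
        if c.response not in models:
            raise KeyError(f"constraint on unmodelled response {c.response!r}")
    some_model = models[constraints[0].response] if constraints else next(iter(models.values()))
    names = list(some_model.terms.factor_names)
    missing = [n for n in names if n not in free and n not in fixed]
    if missing:
        raise ValueError(f"fixed levels missing for factors {missing}")
    if space is not None:
        disc_free = [f for f in free if f in space.discrete_names]
        if disc_free:
            raise ValueError(
                f"free overlay factors {disc_free} are discrete; the design-space "
                "map does not relax discrete constraints"
            )
        for n in space.discrete_names:
            if n in fixed and fixed[n] not in (-1.0, 0.0, 1.0):
                raise ValueError(f"discrete factor {n} must be fixed at an anchor level")

    ax = np.linspace(-1.0, 1.0, resolution)
    A, B = np.meshgrid(ax, ax, indexing="ij")
    pts = np.zeros((resolution * resolution, len(names)))
    for i, n in enumerate(names):
        if n == free[0]:
            pts[:, i] = A.ravel()
        elif n == free[1]:
            pts[:, i] = B.ravel()
        else:
            pts[:, i] = fixed[n]
    masks = {}
    for c in constraints:
        z = models[c.response].predict(pts)
        masks[c.label] = c.satisfied(z).reshape(resolution, resolution)
    return OverlayGrid(free=tuple(free), fixed=dict(fixed),
                       axis_x=ax, axis_y=ax.copy(), masks=masks)


def region_fraction(grid: OverlayGrid, which: str = "intersection") -> float:
    """Fraction of lattice cells satisfying one constraint or the intersection."""
    mask = grid.intersection if which == "intersection" else grid.masks[which]
    return float(mask.mean())


def mark_points(grid: OverlayGrid, points: dict) -> OverlayGrid:
    """Attach labelled slice coordinates with an in/out-of-region flag.

    `points` maps label -> (x, y) in the coded square of the free factors.
    """
    existing = {p.label for p in grid.points}
    marked = list(grid.points)
    inter = grid.intersection
    for label, (x, y) in points.items():
        if label in existing:
            raise ValueError(f"duplicate point label {label!r}")
        if not (-1.0 <= x <= 1.0 and -1.0 <= y <= 1.0):
            raise ValueError(f"point {label!r} outside the coded slice square")
        i = int(np.argmin(np.abs(grid.axis_x - x)))
        j = int(np.argmin(np.abs(grid.axis_y - y)))
        marked.append(MarkedPoint(label, float(x), float(y), bool(inter[i, j])))
        existing.add(label)
    return replace(grid, points=tuple(marked))


def clz_sedds_overlay_constraints() -> list:
    """Default study overlay: AR <= 40 deg (flowability QTPP), BE <= 0.12, CR >= 90 %."""
    return [
        OverlayConstraint("z1", "<=", 40.0),
        OverlayConstraint("z2", "<=", 0.12),
        OverlayConstraint("z3", ">=", 90.0),
    ]
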