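"""Deterministic global optimization over the mixed factor domain.

The factor domain mixes continuous coordinates on [-1, 1] with discrete
three-level coordinates in {-1, 0, +1}.  Discrete combinations are
enumerated exactly (never relaxed); per combination, a uniform seed grid
over the continuous square is evaluated and the best seeds are polished
with derivative-free Nelder-Mead.  Everything is deterministic given the
parameters; a dense exhaustive :func:`grid_oracle` provides an
independent brute-force check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as sp_opt

from .factors import FactorSpace

DISCRETE_LEVELS = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class MixedDomain:
    """Factor names partitioned into continuous ([-1,1]) and discrete ({-1,0,1})."""

    names: tuple
    continuous: tuple
    discrete: tuple

    def __post_init__(self) -> None:
        if set(self.continuous) | set(self.discrete) != set(self.names):
            raise ValueError("continuous/discrete partition must cover all factors")
        if set(self.continuous) & set(self.discrete):
            raise ValueError("a factor cannot be both continuous and discrete")

    @classmethod
    def from_space(cls, space: FactorSpace) -> "MixedDomain":
        return cls(tuple(space.names), tuple(space.continuous_names),
                   tuple(space.discrete_names))

    @property
    def cont_idx(self) -> list:
        return [self.names.index(n) for n in self.continuous]

    @property
    def disc_idx(self) -> list:
        return [self.names.index(n) for n in self.discrete]

    def contains(self, point) -> bool:
        point = np.asarray(point, dtype=float)
        if point.shape != (len(self.names),):
            return False
        if np.any(np.abs(point[self.cont_idx]) > 1 + 1e-12):
            return False
        return all(point[i] in DISCRETE_LEVELS for i in self.disc_idx)


@dataclass
class Optimum:
    """Optimizer output: coded coordinates, objective value and audit trace."""

    coordinates: np.ndarray
    value: float
    status: str = "converged"
    trace: dict = field(default_factory=dict)

    def as_dict(self, names) -> dict:
        return dict(zip(names, (float(c) for c in self.coordinates)))


def _discrete_combos(domain: MixedDomain):
    return itertools.product(DISCRETE_LEVELS, repeat=len(domain.discrete))


def _assemble(domain: MixedDomain, cont: np.ndarray, disc) -> np.ndarray:
    pt = np.empty(len(domain.names))
    pt[domain.cont_idx] = cont
    for i, v in zip(domain.disc_idx, disc):
        pt[i] = v
    return pt


def _is_better(value, coords, best_value, best_coords) -> bool:
    if value < best_value:
        return True
    if value == best_value and best_coords is not None:
        return tuple(coords) < tuple(best_coords)
    return False


def minimize_mixed(objective, domain: MixedDomain, seed_resolution: float = 0.05,
                   n_polish: int = 5, polish_tolerance: float = 1e-8,
                   maximize: bool = False) -> Optimum:
    """Global optimum of `objective` over the mixed domain.

    `objective` maps an (n, k) array of coded points to n values (scalar
    on a single point).  Per discrete combination a uniform seed grid of
    step ``seed_resolution`` over the continuous cube is evaluated, the
    best ``n_polish`` seeds are refined with bounded Nelder-Mead, and the
    overall best point wins; ties break to the lexicographically smallest
    coordinates.  Raises if the objective is non-finite on more than half
    of the seeds.
    """
    sign = -1.0 if maximize else 1.0

    def f(points):
        return sign * np.asarray(objective(np.asarray(points, dtype=float)), dtype=float)

    n_cont = len(domain.continuous)
    n_grid = max(2, int(round(2.0 / seed_resolution)) + 1)
    axis = np.linspace(-1.0, 1.0, n_grid)
    if n_cont:
        mesh = np.meshgrid(*([axis] * n_cont), indexing="ij")
        cont_seeds = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        cont_seeds = np.zeros((1, 0))

    best_val, best_coords = np.inf, None
    seed_best_val = np.inf
    n_bad = n_total = 0
    for disc in _discrete_combos(domain):
        pts = np.empty((len(cont_seeds), len(domain.names)))
        pts[:, domain.cont_idx] = cont_seeds
        for i, v in zip(domain.disc_idx, disc):
            pts[:, i] = v
        vals = f(pts)
        finite = np.isfinite(vals)
        n_bad += int((~finite).sum())
        n_total += len(vals)
        if not finite.any():
            continue
        order = np.argsort(np.where(finite, vals, np.inf), kind="stable")
        seed_best_val = min(seed_best_val, vals[order[0]])
        # grid winners count even if polish cannot run (no continuous dims)
        top = order[: max(1, n_polish)] if n_cont else order[:1]
        for k in top:
            if not finite[k]:
                continue
            if n_cont == 0:
                cand_val, cand_cont = vals[k], cont_seeds[k]
            else:
                res = sp_opt.minimize(
                    lambda c: float(f(_assemble(domain, c, disc)[None, :])[0]),
                    cont_seeds[k],
                    method="Nelder-Mead",
                    bounds=[(-1.0, 1.0)] * n_cont,
                    options={"xatol": polish_tolerance, "fatol": polish_tolerance,
                             "maxiter": 2000},
                )
                if np.isfinite(res.fun) and res.fun <= vals[k]:
                    cand_val, cand_cont = float(res.fun), res.x
                else:  # polish never worsens the seed
                    cand_val, cand_cont = float(vals[k]), cont_seeds[k]
            coords = _assemble(domain, cand_cont, disc)
            if _is_better(cand_val, coords, best_val, best_coords):
                best_val, best_coords = cand_val, coords
    if n_bad > 0.5 * n_total:
        raise ValueError("objective non-finite on more than half of the seed grid")
    if best_coords is None:
        raise ValueError("objective non-finite everywhere on the seed grid")
    return Optimum(
        coordinates=np.asarray(best_coords),
        value=sign * best_val,
        status="converged",
        trace={"seed_grid_best": sign * float(seed_best_val),
               "seed_resolution": seed_resolution, "n_polish": n_polish},
    )


def maximize_mixed(objective, domain: MixedDomain, **kwargs) -> Optimum:
    return minimize_mixed(objective, domain, maximize=True, **kwargs)


def grid_oracle(objective, domain: MixedDomain, resolution: float = 0.005,
                maximize: bool = False, max_points: int = 20_000_000) -> Optimum:
    """Exhaustive lattice evaluation — the brute-force reference optimum.

    Continuous dimensions are discretized at `resolution`; all discrete
    combinations are enumerated.  Returns the exact arg-optimum of the
    evaluated set, first-in-lexicographic-order on ties.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    sign = -1.0 if maximize else 1.0
    n_cont = len(domain.continuous)
    n_grid = int(round(2.0 / resolution)) + 1
    n_disc_combo = 3 ** len(domain.discrete)
    if n_grid ** n_cont * n_disc_combo > max_points:
        raise ValueError("lattice size exceeds max_points cap")
    axis = np.linspace(-1.0, 1.0, n_grid)
    if n_cont:
        mesh = np.meshgrid(*([axis] * n_cont), indexing="ij")
        cont_pts = np.stack([m.ravel() for m in mesh], axis=1)
    else:
        cont_pts = np.zeros((1, 0))

    best_val, best_coords = np.inf, None
    for disc in _discrete_combos(domain):
        pts = np.empty((len(cont_pts), len(domain.names)))
        pts[:, domain.cont_idx] = cont_pts
        for i, v in zip(domain.disc_idx, disc):
            pts[:, i] = v
        vals = sign * np.asarray(objective(pts), dtype=float)
        vals = np.where(np.isfinite(vals), vals, np.inf)
        k = int(np.argmin(vals))  # argmin takes the first (lexicographic) tie
        if _is_better(float(vals[k]), pts[k], best_val, best_coords):
            best_val, best_coords = float(vals[k]), pts[k]
    return Optimum(coordinates=np.asarray(best_coords), value=sign * best_val,
                   status="grid_only", trace={"resolution": resolution})
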