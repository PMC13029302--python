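"""Weighted goal programming over fitted response surfaces.

The procedure follows four phases: (a) a payoff (trade-off) matrix of
single-response optima yielding the ideal and anti-ideal (nadir) points;
(b) aspiration levels T_i per response; (c) weights from priorities by
the reciprocal rule; (d) minimization of the achievement function

    G = sum_i (w_i / T_i) * unwanted_deviation_i

where the unwanted deviation is the over-achievement p_i for
smaller-the-better goals and the under-achievement n_i for
larger-the-better goals.  Deviations are derived from the predicted
response, n = max(T - z, 0), p = max(z - T, 0), so the goal constraint
z + n - p = T and the complementarity n * p = 0 hold identically and G
becomes a deterministic objective over the factor domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import published
from .optimize import MixedDomain, Optimum, maximize_mixed, minimize_mixed


class DeviationPair(NamedTuple):
    """Under- (n) and over- (p) achievement relative to an aspiration level."""

    n: float
    p: float


def weights_from_priorities(priorities) -> np.ndarray:
    """Reciprocal-priority weights: w_i = (1/r_i) / sum_j (1/r_j).

    Priority 1 is the most important, so lower r gives higher weight;
    the weights sum to 1.
    """
    r = np.asarray(priorities, dtype=float)
    if (r <= 0).any():
        raise ValueError("priorities must be positive")
    inv = 1.0 / r
    return inv / inv.sum()


def deviations(z: float, aspiration: float) -> DeviationPair:
    """Split z - T into the non-negative deviation pair (n, p)."""
    n = max(aspiration - z, 0.0)
    p = max(z - aspiration, 0.0)
    return DeviationPair(n=n, p=p)


def normalize_response(z, ideal: float, nadir: float):
    """Map z onto [0, 1] with 0 at the ideal and 1 at the nadir point.

    Values outside the payoff range are clipped (with a warning): the
    payoff matrix brackets what single-response optimization can reach,
    so excursions indicate an inconsistent model set.
    """
    if ideal == nadir:
        raise ValueError("degenerate payoff range: ideal equals nadir")
    z = np.asarray(z, dtype=float)
    raw = (z - ideal) / (nadir - ideal)
    if ((raw < 0) | (raw > 1)).any():
        warnings.warn("response outside the ideal/nadir payoff range; clipping",
                      stacklevel=2)
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GoalSpec:
    """One goal: direction, aspiration level and weight (or priority)."""

    response: str
    direction: str  # "stb" (z <= T) | "ltb" (z >= T)
    aspiration: float
    weight: float = 1.0
    priority: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("stb", "ltb"):
            raise ValueError("direction must be 'stb' or 'ltb'")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    @property
    def unwanted(self) -> str:
        """Which deviation the achievement function penalizes."""
        return "p" if self.direction == "stb" else "n"


@dataclass(frozen=True)
class GoalConfig:
    goals: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [g.response for g in self.goals]
        if len(set(names)) != len(names):
            raise ValueError("goal response names must be unique")

    @property
    def response_names(self) -> list:
        return [g.response for g in self.goals]

    @classmethod
    def from_priorities(cls, specs) -> "GoalConfig":
        """Build goals from (response, direction, aspiration, priority) tuples."""
        w = weights_from_priorities([s[3] for s in specs])
        return cls(tuple(
            GoalSpec(resp, direction, asp, weight=float(wi), priority=int(r))
            for (resp, direction, asp, r), wi in zip(specs, w)
        ))

    @classmethod
    def from_file(cls, path) -> "GoalConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        goals = raw["goals"]
        if all("priority" in g for g in goals) and not any("weight" in g for g in goals):
            return cls.from_priorities([
                (g["response"], g["direction"], float(g["aspiration"]), int(g["priority"]))
                for g in goals
            ])
        return cls(tuple(
            GoalSpec(g["response"], g["direction"], float(g["aspiration"]),
                     weight=float(g.get("weight", 1.0)),
                     priority=g.get("priority"))
            for g in goals
        ))


def clz_sedds_goals() -> GoalConfig:
    """Canonical study goals: AR <= 35 (w 0.2), BE <= 0.12 (w 0.4), CR >= 90 (w 0.4)."""
    return GoalConfig.from_priorities([
        ("z1", "stb", published.ASPIRATIONS["z1"], published.PRIORITIES["z1"]),
        ("z2", "stb", published.ASPIRATIONS["z2"], published.PRIORITIES["z2"]),
        ("z3", "ltb", published.ASPIRATIONS["z3"], published.PRIORITIES["z3"]),
    ])


def achievement(z, config: GoalConfig) -> float:
    """Achievement function G = sum_i (w_i/T_i) * unwanted deviation.

    `z` is the response vector in the order of `config.goals` (or an
    array of vectors, goals on the last axis).  G >= 0, and G = 0 exactly
    when every goal is met.
    """
    z = np.asarray(z, dtype=float)
    total = 0.0
    for i, g in enumerate(config.goals):
        if g.aspiration == 0:
            raise ValueError(
                f"goal {g.response}: zero aspiration cannot normalize the deviation"
            )
        zi = z[..., i]
        dev = np.maximum(zi - g.aspiration, 0.0) if g.direction == "stb" \
            else np.maximum(g.aspiration - zi, 0.0)
        total = total + (g.weight / abs(g.aspiration)) * dev
    return float(total) if np.ndim(total) == 0 else total


@dataclass(frozen=True)
class PayoffMatrix:
    """Single-response optima and the derived ideal / anti-ideal points.

    ``table`` has one row per response (the optimum of that response
    alone) and one column per response (all models evaluated there);
    ``coordinates`` holds the optimizing coded points.
    """

    table: pd.DataFrame
    coordinates: pd.DataFrame
    directions: dict

    @property
    def ideal(self) -> pd.Series:
        best = {}
        for resp, d in self.directions.items():
            col = self.table[resp]
            best[resp] = float(col.min() if d == "stb" else col.max())
        return pd.Series(best, name="ideal")

    @property
    def anti_ideal(self) -> pd.Series:
        worst = {}
        for resp, d in self.directions.items():
            col = self.table[resp]
            worst[resp] = float(col.max() if d == "stb" else col.min())
        return pd.Series(worst, name="anti_ideal")


def payoff_matrix(models: dict, directions: dict, domain: MixedDomain,
                  **opt_kwargs) -> PayoffMatrix:
    """Phase (a): optimize each response alone and cross-evaluate all models.

    `directions` maps response name to "stb" (minimized) or "ltb"
    (maximized).  The componentwise best across rows is the ideal point,
    the componentwise worst the anti-ideal (nadir estimate).
    """
    missing = [r for r in directions if r not in models]
    if missing:
        raise KeyError(f"no model for responses {missing}")
    rows, coords = {}, {}
    for resp, d in directions.items():
        obj = models[resp].predict
        try:
            opt = (minimize_mixed if d == "stb" else maximize_mixed)(obj, domain, **opt_kwargs)
        except Exception as exc:
            raise RuntimeError(f"single-response optimization failed for {resp!r}") from exc
        rows[resp] = {r: float(models[r].predict(opt.coordinates)) for r in directions}
        coords[resp] = opt.as_dict(domain.names)
    index = [f"opt[{r}]" for r in directions]
    table = pd.DataFrame([rows[r] for r in directions], index=index)
    coordinates = pd.DataFrame([coords[r] for r in directions], index=index)
    return PayoffMatrix(table=table, coordinates=coordinates, directions=dict(directions))


@dataclass
class WgpResult:
    """Goal-programming solution: coordinates, responses, deviations and G."""

    coordinates: np.ndarray
    coded: dict
    actual: dict | None
    responses: dict
    deviation_pairs: dict
    achievement: float
    optimum: Optimum

    def report(self) -> pd.DataFrame:
        """Deviation report: optimal value, aspiration and (n, p) per goal."""
        rows = []
        for resp, (n, p) in self.deviation_pairs.items():
            rows.append({"response": resp, "optimal_value": self.responses[resp],
                         "n": n, "p": p})
        return pd.DataFrame(rows).set_index("response")


def optimize_wgp(models: dict, config: GoalConfig, domain: MixedDomain,
                 space=None, normalization: PayoffMatrix | None = None,
                 **opt_kwargs) -> WgpResult:
    """Phase (d): minimize the achievement function over the factor domain.

    With `normalization` supplied, responses and aspirations are first
    mapped onto the [0, 1] ideal/nadir scale and G becomes the plain
    weighted sum of normalized unwanted deviations (the T_i normalizer
    would be ill-posed near a zero normalized aspiration).
    """
    missing = [g.response for g in config.goals if g.response not in models]
    if missing:
        raise KeyError(f"no model supplied for goals {missing}")
    preds = [models[g.response] for g in config.goals]

    if normalization is None:
        def objective(points):
            pts = np.asarray(points, dtype=float)
            z = np.stack([np.atleast_1d(m.predict(pts)) for m in preds], axis=-1)
            out = achievement(z, config)
            return out if pts.ndim > 1 else float(np.asarray(out).reshape(()))
    else:
        ideal, nadir = normalization.ideal, normalization.anti_ideal
        scaled_T = {}
        for g in config.goals:
            lo, hi = ideal[g.response], nadir[g.response]
            scaled_T[g.response] = (g.aspiration - lo) / (hi - lo)

        def objective(points):
            pts = np.asarray(points, dtype=float)
            total = 0.0
            for g, m in zip(config.goals, preds):
                lo, hi = ideal[g.response], nadir[g.response]
                u = (np.atleast_1d(m.predict(pts)) - lo) / (hi - lo)
                # on the 0=ideal scale both directions penalize u above the target
                dev = np.maximum(u - scaled_T[g.response], 0.0)
                total = total + g.weight * dev
            return total if pts.ndim > 1 else float(np.asarray(total).reshape(()))

    try:
        opt = minimize_mixed(objective, domain, **opt_kwargs)
    except ValueError as exc:
        raise RuntimeError(f"goal-programming optimization failed: {exc}") from exc

    responses = {g.response: float(m.predict(opt.coordinates))
                 for g, m in zip(config.goals, preds)}
    pairs = {g.response: deviations(responses[g.response], g.aspiration)
             for g in config.goals}
    z_vec = np.array([responses[g.response] for g in config.goals])
    coded = dict(zip(domain.names, (float(c) for c in opt.coordinates)))
    actual = space.decode_point(opt.coordinates) if space is not None else None
    return WgpResult(
        coordinates=opt.coordinates, coded=coded, actual=actual,
        responses=responses, deviation_pairs=pairs,
        achievement=achievement(z_vec, config), optimum=opt,
    )
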