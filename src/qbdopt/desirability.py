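"""Derringer-type desirability functions and the stringency sweep.

Each response is mapped to a [0, 1] satisfaction score: smaller-the-better
(STB) responses score 1 at or below the target T and 0 at or above the
upper cut-off U; larger-the-better (LTB) responses score 0 at or below
the lower cut-off L and 1 at or above T.  Between the anchors the score
is a power ``s`` of the linear ramp — the stringency exponent.  The
global desirability D is the weighted geometric mean of the individual
scores, so any fully unacceptable response annihilates D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import published
from .optimize import MixedDomain, maximize_mixed


def d_stb(z, target: float, upper: float, s: float = 1.0):
    """Smaller-the-better desirability: 1 below `target`, 0 above `upper`."""
    if target >= upper:
        raise ValueError("STB desirability requires target < upper")
    if s <= 0:
        raise ValueError("stringency exponent s must be positive")
    z = np.asarray(z, dtype=float)
    ramp = np.clip((upper - z) / (upper - target), 0.0, 1.0)
    out = ramp ** s
    return float(out) if out.ndim == 0 else out


def d_ltb(z, lower: float, target: float, s: float = 1.0):
    """Larger-the-better desirability: 0 below `lower`, 1 above `target`."""
    if lower >= target:
        raise ValueError("LTB desirability requires lower < target")
    if s <= 0:
        raise ValueError("stringency exponent s must be positive")
    z = np.asarray(z, dtype=float)
    ramp = np.clip((z - lower) / (target - lower), 0.0, 1.0)
    out = ramp ** s
    return float(out) if out.ndim == 0 else out


def global_desirability(d, w):
    """Weighted geometric mean (prod d_i^w_i)^(1/sum w).

    Along the last axis for array input.  D is 0 whenever any d_i with
    positive weight is 0, and 1 only when all positively weighted d_i are 1.
    """
    d = np.asarray(d, dtype=float)
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("at least one weight must be positive")
    if ((d < 0) | (d > 1)).any():
        raise ValueError("individual desirabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        logs = np.where((d == 0) & (w > 0), -np.inf, np.log(np.where(d > 0, d, 1.0)))
    score = np.exp((logs * w).sum(axis=-1) / w.sum())
    return float(score) if score.ndim == 0 else score


@dataclass(frozen=True)
class DesirabilityGoal:
    """Per-response desirability specification.

    STB goals use (target, upper); LTB goals use (lower, target).
    """

    response: str
    direction: str  # "stb" | "ltb"
    target: float
    upper: float | None = None
    lower: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("stb", "ltb"):
            raise ValueError("direction must be 'stb' or 'ltb'")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")
        if self.direction == "stb":
            if self.upper is None or self.target >= self.upper:
                raise ValueError(f"goal {self.response}: STB needs target < upper")
        else:
            if self.lower is None or self.lower >= self.target:
                raise ValueError(f"goal {self.response}: LTB needs lower < target")

    def d(self, z, s: float = 1.0):
        if self.direction == "stb":
            return d_stb(z, self.target, self.upper, s)
        return d_ltb(z, self.lower, self.target, s)


@dataclass(frozen=True)
class DesirabilityConfig:
    goals: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [g.response for g in self.goals]
        if len(set(names)) != len(names):
            raise ValueError("goal response names must be unique")
        if sum(g.weight for g in self.goals) <= 0:
            raise ValueError("total weight must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([g.weight for g in self.goals])

    @property
    def response_names(self) -> list:
        return [g.response for g in self.goals]

    def score(self, z, s: float = 1.0):
        """Global D for a response vector (or array of vectors, last axis)."""
        z = np.asarray(z, dtype=float)
        d = np.stack([g.d(z[..., i], s) for i, g in enumerate(self.goals)], axis=-1)
        return global_desirability(d, self.weights)

    @classmethod
    def from_file(cls, path) -> "DesirabilityConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        goals = tuple(
            DesirabilityGoal(
                response=g["response"], direction=g["direction"],
                target=float(g["target"]),
                upper=float(g["upper"]) if "upper" in g else None,
                lower=float(g["lower"]) if "lower" in g else None,
                weight=float(g.get("weight", 1.0)),
            )
            for g in raw["goals"]
        )
        return cls(goals)


def clz_sedds_desirability() -> DesirabilityConfig:
    """Canonical study configuration.

    Targets are the aspiration levels (35 deg, 0.12, 90 %); the STB upper
    and LTB lower cut-offs are the anti-ideal points from the trade-off
    matrix; weights follow the reciprocal-priority rule (0.2, 0.4, 0.4).
    This assignment reproduces the published five-point D(s) column.
    """
    return DesirabilityConfig((
        DesirabilityGoal("z1", "stb", target=published.ASPIRATIONS["z1"],
                         upper=published.ANTI_IDEAL["z1"], weight=published.WEIGHTS["z1"]),
        DesirabilityGoal("z2", "stb", target=published.ASPIRATIONS["z2"],
                         upper=published.ANTI_IDEAL["z2"], weight=published.WEIGHTS["z2"]),
        DesirabilityGoal("z3", "ltb", target=published.ASPIRATIONS["z3"],
                         lower=published.ANTI_IDEAL["z3"], weight=published.WEIGHTS["z3"]),
    ))


def desirability_objective(models: dict, config: DesirabilityConfig, s: float = 1.0):
    """Compose response predictors with the desirability chain.

    Returns a vectorised callable: coded points -> global D in [0, 1].
    """
    missing = [g.response for g in config.goals if g.response not in models]
    if missing:
        raise KeyError(f"no model supplied for goals {missing}")
    preds = [models[g.response] for g in config.goals]

    def objective(points):
        pts = np.asarray(points, dtype=float)
        z = np.stack([np.atleast_1d(m.predict(pts)) for m in preds], axis=-1)
        out = config.score(z, s)
        return out if pts.ndim > 1 else float(np.asarray(out).reshape(()))

    return objective


def maximize_desirability(models: dict, config: DesirabilityConfig,
                          domain: MixedDomain, s: float = 1.0, **opt_kwargs):
    """Maximize global desirability over the mixed factor domain.

    Returns ``(optimum, predicted)`` where `predicted` maps response
    names to model predictions at the optimum.
    """
    opt = maximize_mixed(desirability_objective(models, config, s), domain, **opt_kwargs)
    predicted = {name: float(models[name].predict(opt.coordinates))
                 for name in config.response_names}
    return opt, predicted


def sensitivity_sweep(models: dict, config: DesirabilityConfig, s_values,
                      domain: MixedDomain, **opt_kwargs) -> pd.DataFrame:
    """Re-optimize D for each stringency exponent s.

    One row per s with the arg-max coordinates, the predicted responses
    there and the achieved D.  When the optimum pins every goal but one
    at d = 1, D is a monotone transform of the remaining ramp for every
    s, so the coordinates are s-invariant and D decays geometrically.
    """
    s_values = list(s_values)
    if not s_values:
        raise ValueError("s_values must be non-empty")
    if any(s <= 0 for s in s_values):
        raise ValueError("stringency exponents must be positive")
    rows = []
    for s in s_values:
        opt, predicted = maximize_desirability(models, config, domain, s, **opt_kwargs)
        row = {"s": s}
        row.update(predicted)
        row["D"] = opt.value
        row.update(opt.as_dict(domain.names))
        rows.append(row)
    return pd.DataFrame(rows)
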