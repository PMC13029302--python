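"""Factor definitions and coded/actual conversion for three-level designs.

Factors live on the coded scale [-1, +1] with three anchor levels
(-1, 0, +1) mapped to physical values.  Continuous factors decode by
piecewise-linear interpolation between adjacent anchors — the levels need
not be evenly spaced (e.g. a drug load of 0.1 / 0.21 / 0.31 %) — so the
map is exact at all three anchors.  Discrete factors (categorical process
choices such as a blending method) only ever take the anchor values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

CODED_LEVELS = (-1.0, 0.0, 1.0)


@dataclass(frozen=True)
class FactorSpec:
    """One design factor: three coded anchors and their physical levels.

    Parameters
    ----------
    name : str
        Factor label, e.g. ``"F1"``.
    kind : {"continuous", "discrete"}
        Continuous factors may take any coded value in [-1, 1];
        discrete factors only the anchors {-1, 0, +1}.
    actual_levels : tuple
        Physical values (numbers, strictly increasing) or categorical
        labels at coded -1, 0, +1.
    unit : str
        Optional physical unit for reporting.
    """

    name: str
    kind: str
    actual_levels: tuple
    unit: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"factor {self.name}: kind must be 'continuous' or 'discrete'")
        if len(self.actual_levels) != 3:
            raise ValueError(f"factor {self.name}: exactly three levels required")
        if self.is_numeric:
            lo, mid, hi = self.actual_levels
            if not (lo < mid < hi):
                raise ValueError(f"factor {self.name}: numeric levels must be strictly increasing")
        if self.kind == "continuous" and not self.is_numeric:
            raise ValueError(f"factor {self.name}: continuous factors need numeric levels")

    @property
    def is_numeric(self) -> bool:
        return all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in self.actual_levels)

    def decode(self, coded: float):
        """Coded value -> physical value.

        Numeric factors interpolate piecewise-linearly between adjacent
        anchors; categorical factors decode only at -1/0/+1.
        """
        if not -1.0 <= coded <= 1.0:
            raise ValueError(f"factor {self.name}: coded value {coded} outside [-1, 1]")
        lo, mid, hi = self.actual_levels
        if not self.is_numeric:
            for anchor, level in zip(CODED_LEVELS, self.actual_levels):
                if coded == anchor:
                    return level
            raise ValueError(
                f"factor {self.name}: categorical factor decodes only at -1/0/+1, got {coded}"
            )
        if self.kind == "discrete" and coded not in CODED_LEVELS:
            raise ValueError(
                f"factor {self.name}: discrete factor decodes only at -1/0/+1, got {coded}"
            )
        if coded <= 0:
            return mid + coded * (mid - lo)
        return mid + coded * (hi - mid)

    def encode(self, actual) -> float:
        """Physical value -> coded value (inverse of :meth:`decode`)."""
        lo, mid, hi = self.actual_levels
        if not self.is_numeric:
            try:
                idx = self.actual_levels.index(actual)
            except ValueError:
                raise ValueError(f"factor {self.name}: unknown level {actual!r}") from None
            return CODED_LEVELS[idx]
        if not lo <= actual <= hi:
            raise ValueError(
                f"factor {self.name}: value {actual} outside [{lo}, {hi}]"
            )
        if actual <= mid:
            coded = (actual - mid) / (mid - lo)
        else:
            coded = (actual - mid) / (hi - mid)
        if self.kind == "discrete" and coded not in CODED_LEVELS:
            raise ValueError(f"factor {self.name}: {actual} is not an anchor level of a discrete factor")
        return coded

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "actual_levels": list(self.actual_levels),
            "unit": self.unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpec":
        return cls(d["name"], d["kind"], tuple(d["actual_levels"]), d.get("unit", ""))


@dataclass(frozen=True)
class FactorSpace:
    """Ordered collection of factors spanning the coded design domain."""

    factors: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)

    def __getitem__(self, name: str) -> FactorSpec:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r}")

    @property
    def names(self) -> list:
        return [f.name for f in self.factors]

    @property
    def continuous_names(self) -> list:
        return [f.name for f in self.factors if f.kind == "continuous"]

    @property
    def discrete_names(self) -> list:
        return [f.name for f in self.factors if f.kind == "discrete"]

    def decode_point(self, coded: Sequence[float]) -> dict:
        """Decode a full coded coordinate vector to physical values."""
        if len(coded) != len(self.factors):
            raise ValueError("coordinate dimension does not match factor count")
        return {f.name: f.decode(c) for f, c in zip(self.factors, coded)}

    def to_dict(self) -> dict:
        return {"factors": [f.to_dict() for f in self.factors]}

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpace":
        return cls(tuple(FactorSpec.from_dict(x) for x in d["factors"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "FactorSpace":
        """Load a factor space from a JSON or YAML definition file."""
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)


def clz_sedds_space() -> FactorSpace:
    """The canonical four-factor space of the clonazepam S-SEDDS study.

    F1 drug concentration (%) and F3 SEDDS percentage (%) are continuous;
    F2 lactose/Aerosil adsorbent ratio and F4 blending method are
    discrete three-level choices.
    """
    return FactorSpace((
        FactorSpec("F1", "continuous", (0.1, 0.21, 0.31), unit="% CLZ"),
        FactorSpec("F2", "discrete", ("A", "B", "C"), unit="lactose/Aerosil ratio"),
        FactorSpec("F3", "continuous", (8.0, 18.0, 28.0), unit="% SEDDS"),
        FactorSpec("F4", "discrete", ("Bman", "Bcon", "Bint"), unit="blending method"),
    ))
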