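"""Box-Behnken design construction and design-table I/O.

A :class:`DesignTable` holds the coded run matrix together with response
summaries (mean, sd, n per run) and, optionally, the raw replicates.
The bundled 27-run clonazepam S-SEDDS study ships as a CSV fixture and
loads through the same reader as user tables.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import FactorSpace, clz_sedds_space

# Pair-block order reproducing the canonical 27-run layout: edge blocks
# (F1,F2), (F3,F4), centre, (F1,F4), (F2,F3), centre, (F1,F3), (F2,F4), centre.
_BBD_PAIR_ORDER = ((0, 1), (2, 3), (0, 3), (1, 2), (0, 2), (1, 3))
_SIGN_ORDER = ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass
class DesignTable:
    """Runs x coded levels with per-run response summaries.

    Attributes
    ----------
    coded : pandas.DataFrame
        Runs x factors, entries in [-1, 1]; indexed by run id.
    responses : dict[str, pandas.DataFrame]
        Per response name, a frame with columns ``mean``, ``sd``, ``n``
        indexed like ``coded``.
    replicates : dict[str, numpy.ndarray]
        Optional raw replicate matrix (runs x n) per response.
    space : FactorSpace
        Factor definitions matching the coded columns.
    """

    coded: pd.DataFrame
    responses: dict = field(default_factory=dict)
    replicates: dict = field(default_factory=dict)
    space: FactorSpace | None = None

    def __post_init__(self) -> None:
        vals = self.coded.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError("coded matrix contains missing entries")
        if (np.abs(vals) > 1 + 1e-12).any():
            raise ValueError("coded values must lie in [-1, 1]")
        if self.space is not None:
            if list(self.coded.columns) != self.space.names:
                raise ValueError("coded columns do not match the factor space")
            for name in self.space.discrete_names:
                col = self.coded[name].to_numpy(dtype=float)
                if not np.isin(col, (-1.0, 0.0, 1.0)).all():
                    raise ValueError(
                        f"discrete factor {name} has non-anchor coded values"
                    )
        for name, frame in self.responses.items():
            if not frame.index.equals(self.coded.index):
                raise ValueError(f"response {name!r} not aligned with runs")

    @property
    def run_ids(self) -> list:
        return list(self.coded.index)

    @property
    def n_runs(self) -> int:
        return len(self.coded)

    @property
    def response_names(self) -> list:
        return list(self.responses)

    def means(self, response: str) -> pd.Series:
        return self.responses[response]["mean"]

    def to_dataframe(self) -> pd.DataFrame:
        """Flat frame: run id index, coded columns, then <resp>_mean/_sd and n."""
        out = self.coded.copy()
        n_col = None
        for name, frame in self.responses.items():
            out[f"{name}_mean"] = frame["mean"]
            out[f"{name}_sd"] = frame["sd"]
            n_col = frame["n"]
        if n_col is not None:
            out["n"] = n_col
        return out


def build_bbd(space: FactorSpace, center_replicates: int = 3) -> DesignTable:
    """Construct the coded 4-factor Box-Behnken design.

    For each of the six factor pairs the four (+/-1, +/-1) combinations are
    run with the remaining factors at 0 (24 edge runs); centre replicates
    are interleaved after every second pair block (matching the canonical
    27-run layout when ``center_replicates`` is 3) with any surplus
    appended at the end.
    """
    if len(space) != 4:
        raise ValueError(
            "only 4-factor Box-Behnken designs are supported "
            "(extend _BBD_PAIR_ORDER for other sizes)"
        )
    if center_replicates < 1:
        raise ValueError("center_replicates must be >= 1")
    rows: list[list[float]] = []
    centers_left = center_replicates
    for block, (i, j) in enumerate(_BBD_PAIR_ORDER, start=1):
        for si, sj in _SIGN_ORDER:
            row = [0.0, 0.0, 0.0, 0.0]
            row[i], row[j] = float(si), float(sj)
            rows.append(row)
        if block % 2 == 0 and centers_left > 0:
            rows.append([0.0, 0.0, 0.0, 0.0])
            centers_left -= 1
    rows.extend([[0.0, 0.0, 0.0, 0.0]] * centers_left)
    idx = pd.Index([f"R{k}" for k in range(1, len(rows) + 1)], name="run")
    coded = pd.DataFrame(rows, index=idx, columns=space.names)
    return DesignTable(coded=coded, space=space)


def write_design_table(table: DesignTable, path) -> None:
    """Write a design table as CSV (run, coded columns, summaries, replicates)."""
    out = table.to_dataframe()
    for name, reps in table.replicates.items():
        for k in range(reps.shape[1]):
            out[f"{name}_rep{k + 1}"] = reps[:, k]
    out.index.name = "run"
    out.to_csv(path)


def load_design_table(path, space: FactorSpace | None = None) -> DesignTable:
    """Read a design-table CSV.

    Expects a ``run`` column, one coded column per factor, and per response
    either ``<name>_mean`` / ``<name>_sd`` (with an optional shared ``n``
    column) or replicate columns ``<name>_rep1``, ``<name>_rep2``, ...
    """
    df = pd.read_csv(path)
    if "run" not in df.columns:
        raise ValueError("design CSV must have a 'run' column")
    df = df.set_index("run")
    space = space or clz_sedds_space()
    missing = [n for n in space.names if n not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing factor columns {missing}")
    extra = [
        c for c in df.columns
        if c not in space.names and c != "n"
        and not c.endswith(("_mean", "_sd")) and "_rep" not in c
    ]
    if extra:
        raise ValueError(f"unknown columns in design CSV: {extra}")
    coded = df[space.names].astype(float)

    responses: dict[str, pd.DataFrame] = {}
    replicates: dict[str, np.ndarray] = {}
    n_default = df["n"] if "n" in df.columns else None
    resp_names = sorted({c[: -len("_mean")] for c in df.columns if c.endswith("_mean")})
    for name in resp_names:
        frame = pd.DataFrame(index=df.index)
        frame["mean"] = df[f"{name}_mean"].astype(float)
        frame["sd"] = df[f"{name}_sd"].astype(float) if f"{name}_sd" in df.columns else np.nan
        frame["n"] = n_default.astype(int) if n_default is not None else 1
        responses[name] = frame
    rep_names = sorted({c.split("_rep")[0] for c in df.columns if "_rep" in c})
    for name in rep_names:
        cols = sorted(
            (c for c in df.columns if c.startswith(f"{name}_rep")),
            key=lambda c: int(c.split("_rep")[1]),
        )
        reps = df[cols].to_numpy(dtype=float)
        replicates[name] = reps
        if name not in responses:
            responses[name] = pd.DataFrame(
                {
                    "mean": reps.mean(axis=1),
                    "sd": reps.std(axis=1, ddof=1),
                    "n": reps.shape[1],
                },
                index=df.index,
            )
    return DesignTable(coded=coded, responses=responses, replicates=replicates, space=space)


def clz_sedds_study() -> DesignTable:
    """The bundled 27-run clonazepam S-SEDDS Box-Behnken study.

    Responses: z1 angle of repose (deg), z2 blending efficiency (CV),
    z3 drug recovery (%), each as mean +/- sd of triplicates.
    """
    ref = importlib.resources.files("qbdopt.data") / "clz_sedds_bbd.csv"
    with importlib.resources.as_file(ref) as p:
        return load_design_table(p, clz_sedds_space())
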