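"""Formulation quality metrics: flow, blend homogeneity, recovery, uniformity.

Scalar formulas used to score powder formulations: the angle of repose
from cone geometry, blending efficiency as the coefficient of variation
of drug content, percent drug recovery, and the Ph.Eur. 2.9.6 content-
uniformity acceptance value AV = |M - X| + k*s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Acceptability constant for a first-stage sample of 10 units.
K_N10 = 2.4
#: Compliance limit for the acceptance value.
AV_LIMIT = 15.0


def angle_of_repose(height: float, diameter: float) -> float:
    """Angle of repose alpha = arctan(h / (d/2)), in degrees.

    `height` is the powder-cone height and `diameter` the flat base
    diameter, in the same length units.  Lower angles mean better flow.
    """
    if diameter <= 0:
        raise ValueError("base diameter must be positive")
    if height < 0:
        raise ValueError("cone height cannot be negative")
    return float(np.degrees(np.arctan(height / (0.5 * diameter))))


def coefficient_of_variation(values) -> float:
    """Sample CV: sd (n-1 denominator) / mean. Lower = more homogeneous blend."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least two replicates")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def drug_recovery(measured_total: float, theoretical_total: float) -> float:
    """Percent of drug recovered relative to the theoretical load.

    Values above 100 % are legitimate (assay and sampling variability)
    and are never clipped.
    """
    if theoretical_total <= 0:
        raise ValueError("theoretical amount must be positive")
    return 100.0 * measured_total / theoretical_total


@dataclass(frozen=True)
class ContentSample:
    """Replicate content-uniformity assays (% of label claim).

    `k` is the pharmacopoeial acceptability constant; 2.4 applies to the
    first-stage sample of n = 10 units, other sample sizes need a
    user-supplied k.
    """

    values: tuple
    k: float = K_N10

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("content uniformity needs at least two units")
        if any(v <= 0 for v in vals):
            raise ValueError("assay values must be positive")


def acceptance_value(sample: ContentSample) -> float:
    """Ph.Eur. 2.9.6 acceptance value AV = |M - X| + k*s.

    X is the mean content, s the sample standard deviation, and the
    reference value M clamps X to the [98.5, 101.5] band (M = X inside
    the band; the two clamp branches follow the pharmacopoeial rule).
    """
    x = np.asarray(sample.values, dtype=float)
    X = float(x.mean())
    s = float(x.std(ddof=1))
    M = min(max(X, 98.5), 101.5)
    return abs(M - X) + sample.k * s


def complies(sample: ContentSample, limit: float = AV_LIMIT) -> bool:
    """True when the acceptance value does not exceed the stage limit."""
    return acceptance_value(sample) <= limit


def qc_report(assays: dict, k: float = K_N10) -> pd.DataFrame:
    """Batch QC summary: X, s, M, AV and compliance per batch of replicates."""
    rows = []
    for batch, values in assays.items():
        sample = ContentSample(tuple(values), k=k)
        x = np.asarray(sample.values)
        X = float(x.mean())
        rows.append({
            "batch": batch, "mean": X, "sd": float(x.std(ddof=1)),
            "M": min(max(X, 98.5), 101.5),
            "AV": acceptance_value(sample),
            "complies": complies(sample),
        })
    return pd.DataFrame(rows).set_index("batch")
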