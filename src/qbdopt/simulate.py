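"""Synthetic Box-Behnken studies from known polynomial ground truths.

Every pipeline stage is testable without laboratory data: a
:class:`TruthSpec` fixes per-response ground-truth polynomials, replicate
counts and Gaussian noise levels, and :func:`generate_bbd_study` emits a
design table with the same triplicate mean +/- sd structure as a real
study.  Per-(response, run) random substreams are derived from one
master seed, so adding a response or run never perturbs the draws of the
others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignTable, build_bbd
from .factors import FactorSpace, clz_sedds_space
from .model import PolynomialModel
from .terms import make_term_set
import pandas as pd


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for a simulated study.

    ``noise_sd`` maps each response to a scalar standard deviation or a
    per-run vector (heteroscedastic noise mimics real triplicate tables
    whose sd varies run to run).
    """

    models: dict
    noise_sd: dict = field(default_factory=dict)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name, sd in self.noise_sd.items():
            if np.any(np.asarray(sd) < 0):
                raise ValueError(f"noise sd for {name!r} must be >= 0")


def generate_bbd_study(truth: TruthSpec, space: FactorSpace | None = None,
                       center_replicates: int = 3) -> DesignTable:
    """Simulate a Box-Behnken study from the ground truth.

    Each run's replicates are the truth prediction plus i.i.d. Gaussian
    noise; the table stores both the raw replicates and the mean/sd/n
    summaries.  Fully reproducible from ``truth.seed``.
    """
    space = space or clz_sedds_space()
    table = build_bbd(space, center_replicates=center_replicates)
    coded = table.coded.to_numpy(dtype=float)
    n_runs = len(coded)
    responses, replicates = {}, {}
    for ridx, (name, model) in enumerate(truth.models.items()):
        mu = np.atleast_1d(model.predict(coded))
        sd = np.broadcast_to(np.asarray(truth.noise_sd.get(name, 0.0), dtype=float),
                             (n_runs,))
        reps = np.empty((n_runs, truth.replicates))
        for run in range(n_runs):
            rng = np.random.default_rng(
                np.random.SeedSequence(truth.seed, spawn_key=(ridx, run)))
            reps[run] = mu[run] + sd[run] * rng.standard_normal(truth.replicates)
        replicates[name] = reps
        if truth.replicates > 1:
            sd_col = reps.std(axis=1, ddof=1)
        else:
            sd_col = np.zeros(n_runs)
        responses[name] = pd.DataFrame(
            {"mean": reps.mean(axis=1), "sd": sd_col, "n": truth.replicates},
            index=table.coded.index,
        )
    return DesignTable(coded=table.coded, responses=responses,
                       replicates=replicates, space=space)


def preset_conflicting_truth(seed: int = 0) -> TruthSpec:
    """Three-response truth with a built-in objective conflict.

    The third factor (the F3 analogue) raises the larger-the-better
    recovery response while degrading both smaller-the-better responses,
    so no single setting satisfies every goal and both optimizers must
    trade off.  Closed-form single-response optima (coded):

    - z1 = 42 + 2*F3 + 1.5*F1^2        -> min 40 at F1 = 0, F3 = -1
    - z2 = 0.12 + 0.06*F3 + 0.02*F2    -> min 0.04 at F2 = F3 = -1
    - z3 = 75 + 30*F3 + 5*F1 - 2*F1^2  -> max 108 at F1 = +1, F3 = +1

    Noise levels mirror the scale of real triplicate studies (sd of a few
    degrees / a few percent; CV noise an order of magnitude below its mean).
    """
    t_z1 = make_term_set([(0, 0, 0, 0), (0, 0, 1, 0), (2, 0, 0, 0)])
    t_z2 = make_term_set([(0, 0, 0, 0), (0, 0, 1, 0), (0, 1, 0, 0)])
    t_z3 = make_term_set([(0, 0, 0, 0), (0, 0, 1, 0), (1, 0, 0, 0), (2, 0, 0, 0)])
    models = {
        "z1": PolynomialModel(t_z1, np.array([42.0, 2.0, 1.5]), "z1"),
        "z2": PolynomialModel(t_z2, np.array([0.12, 0.06, 0.02]), "z2"),
        "z3": PolynomialModel(t_z3, np.array([75.0, 30.0, 5.0, -2.0]), "z3"),
    }
    noise = {"z1": 1.5, "z2": 0.02, "z3": 8.0}
    return TruthSpec(models=models, noise_sd=noise, replicates=3, seed=seed)
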