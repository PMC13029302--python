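"""As-published regression models and canonical optimization settings.

The study reports rounded regression coefficients for the three quality
attributes; downstream results (desirability sweep, goal-programming
deviations) were produced with the authors' internal full-precision
models, so the refit and as-published predictors are kept as distinct
first-class objects and can disagree in the second decimal.
"""

from __future__ import annotations

import numpy as np

from .model import PolynomialModel
from .terms import ar_terms, be_terms, cr_terms

#: Aspiration levels T_i for (z1, z2, z3): AR <= 35 deg, BE <= 0.12, CR >= 90 %.
ASPIRATIONS = {"z1": 35.0, "z2": 0.12, "z3": 90.0}

#: Anti-ideal (nadir) points used as desirability cut-offs.
ANTI_IDEAL = {"z1": 45.29, "z2": 0.4811, "z3": 23.829}

#: Ideal points from the single-response trade-off matrix.
IDEAL = {"z1": 35.48, "z2": 0.0, "z3": 121.454}

#: Response priorities (1 = most important) and the reciprocal-rule weights.
PRIORITIES = {"z1": 2, "z2": 1, "z3": 1}
WEIGHTS = {"z1": 0.2, "z2": 0.4, "z3": 0.4}


def published_ar_model() -> PolynomialModel:
    """Angle of repose (deg) as published: 13-term cubic-interaction surface."""
    return PolynomialModel(ar_terms(), np.array([
        42.9, 1.9, -2.3, 1.7, 0.1, -0.3, -0.6, 2.1,
        -1.0, 2.8, -1.1, 1.2, -1.4,
    ]), "z1")


def published_be_model() -> PolynomialModel:
    """Blending efficiency (CV) as published: 14-term surface."""
    return PolynomialModel(be_terms(), np.array([
        0.150, 0.003, -0.007, -0.020, 0.072,
        -0.082, 0.049, -0.013, -0.030,
        0.033, -0.030, -0.070, -0.135, -0.049,
    ]), "z2")


def published_cr_model() -> PolynomialModel:
    """Drug recovery (%) as published: 6-term quadratic surface."""
    return PolynomialModel(cr_terms(), np.array([
        76.4, 7.0, 34.6, -3.4, -1.7, -1.7,
    ]), "z3")


def published_models() -> dict:
    """All three as-published response surfaces keyed by response name."""
    return {
        "z1": published_ar_model(),
        "z2": published_be_model(),
        "z3": published_cr_model(),
    }
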