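"""Response-surface models: OLS fitting, prediction and diagnostics.

The modelling interface follows the Model/Results convention:
:class:`ResponseSurfaceModel` is built from a design table, its
:meth:`~ResponseSurfaceModel.fit` returns a
:class:`ResponseSurfaceResults` carrying coefficient estimates, standard
errors, t/p values and fit statistics, and exposing the fitted
:class:`PolynomialModel` predictor used by the optimizers.  Published
coefficient sets can be wrapped directly in a :class:`PolynomialModel`
without refitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import DesignTable
from .terms import TermSet, make_term_set


@dataclass(frozen=True)
class PolynomialModel:
    """A response surface: monomial term set plus coefficients.

    Evaluation is vectorised: ``predict`` accepts a single coded point
    (length-4 sequence) or an (n, 4) array of points.
    """

    terms: TermSet
    coefficients: np.ndarray
    response_name: str = ""

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.shape != (len(self.terms),) :
            raise ValueError("coefficient count must equal term count")

    def predict(self, points) -> np.ndarray | float:
        pts = np.asarray(points, dtype=float)
        scalar = pts.ndim == 1
        X = self.terms.design_matrix(pts)
        out = X @ self.coefficients
        return float(out[0]) if scalar else out

    __call__ = predict

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.terms.names)

    def to_json(self, path=None) -> str:
        payload = {
            "response_name": self.response_name,
            "factor_names": list(self.terms.factor_names),
            "terms": [list(t) for t in self.terms.exponents],
            "coefficients": [float(c) for c in self.coefficients],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PolynomialModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        terms = make_term_set(payload["terms"], payload["factor_names"])
        return cls(terms, np.asarray(payload["coefficients"]), payload["response_name"])


class ResponseSurfaceModel:
    """OLS response-surface model for one response of a design table.

    Parameters
    ----------
    table : DesignTable
        Coded design with response summaries (and optionally replicates).
    response : str
        Which response to model, e.g. ``"z3"``.
    terms : TermSet
        Monomials to include; must be full rank on the design.
    level : {"means", "replicates"}
        Fit to per-run means (default, one observation per run) or to the
        raw replicates (changes residual df and MSE).
    """

    def __init__(self, table: DesignTable, response: str, terms: TermSet,
                 level: str = "means") -> None:
        if response not in table.responses:
            raise KeyError(f"response {response!r} not in design table")
        if level not in ("means", "replicates"):
            raise ValueError("level must be 'means' or 'replicates'")
        if level == "replicates" and response not in table.replicates:
            raise ValueError(f"no replicate data stored for {response!r}")
        self.table = table
        self.response = response
        self.terms = terms
        self.level = level

        coded = table.coded.to_numpy(dtype=float)
        if level == "means":
            self.endog = table.means(response).to_numpy(dtype=float)
            self.exog = terms.design_matrix(coded)
        else:
            reps = table.replicates[response]
            self.endog = reps.ravel()
            self.exog = np.repeat(terms.design_matrix(coded), reps.shape[1], axis=0)
        self._check_rank()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, terms: TermSet,
                       factor_names=("F1", "F2", "F3", "F4")) -> "ResponseSurfaceModel":
        """Build from a flat frame with coded factor columns and a response column."""
        coded = df[list(factor_names)]
        responses = {response: pd.DataFrame({
            "mean": df[response].astype(float), "sd": np.nan, "n": 1}, index=df.index)}
        table = DesignTable(coded=coded.astype(float), responses=responses)
        return cls(table, response, terms)

    def _check_rank(self) -> None:
        X = self.exog
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify collinear terms via QR pivoting on the correlation structure
            _, R = np.linalg.qr(X)
            diag = np.abs(np.diag(R))
            bad = [self.terms.names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
                f"collinear terms: {bad or 'undetermined'}"
            )

    def fit(self) -> "ResponseSurfaceResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return ResponseSurfaceResults(self, res)


class ResponseSurfaceResults:
    """Fitted response surface with coefficient inference and fit statistics."""

    def __init__(self, model: ResponseSurfaceModel, sm_results) -> None:
        self.model = model
        self._sm = sm_results
        names = model.terms.names
        self.params = pd.Series(sm_results.params, index=names)
        self.df_resid = int(sm_results.df_resid)
        if self.df_resid >= 1:
            self.bse = pd.Series(sm_results.bse, index=names)
            self.tvalues = pd.Series(sm_results.tvalues, index=names)
            self.pvalues = pd.Series(sm_results.pvalues, index=names)
            self.mse_resid = float(sm_results.mse_resid)
        else:
            # saturated fit: inference undefined
            nan = pd.Series(np.nan, index=names)
            self.bse, self.tvalues, self.pvalues = nan, nan.copy(), nan.copy()
            self.mse_resid = np.nan
        self.rsquared = float(sm_results.rsquared)
        self.rsquared_adj = float(sm_results.rsquared_adj)
        self.nobs = int(sm_results.nobs)

    @property
    def polynomial(self) -> PolynomialModel:
        return PolynomialModel(self.model.terms, self.params.to_numpy(),
                               self.model.response)

    def predict(self, points):
        return self.polynomial.predict(points)

    def diagnostics_frame(self) -> pd.DataFrame:
        """Per-term coefficient table plus fit statistics as attrs."""
        df = pd.DataFrame({
            "coef": self.params, "se": self.bse,
            "t": self.tvalues, "p": self.pvalues,
        })
        df.attrs.update(mse=self.mse_resid, r2=self.rsquared,
                        r2_adj=self.rsquared_adj, df_resid=self.df_resid)
        return df

    def summary(self) -> str:
        head = (
            f"Response surface OLS  response={self.model.response}  "
            f"n={self.nobs}  terms={len(self.params)}\n"
            f"R2={self.rsquared:.4f}  R2_adj={self.rsquared_adj:.4f}  "
            f"MSE={self.mse_resid:.6g}  df_resid={self.df_resid}\n"
        )
        return head + self.diagnostics_frame().to_string(float_format=lambda v: f"{v:10.4f}")


def fit_ols(table: DesignTable, response: str, terms: TermSet,
            level: str = "means") -> ResponseSurfaceResults:
    """Convenience wrapper: build and fit in one call."""
    return ResponseSurfaceModel(table, response, terms, level=level).fit()


def marginal_means(table: DesignTable, response: str, factor: str) -> pd.Series:
    """Mean of the run-level response means at each coded level of `factor`."""
    if factor not in table.coded.columns:
        raise KeyError(f"no factor {factor!r} in design")
    means = table.means(response)
    levels = table.coded[factor]
    out = {}
    for lvl in (-1.0, 0.0, 1.0):
        mask = levels == lvl
        if not mask.any():
            raise ValueError(f"factor {factor} has no runs at level {lvl}")
        out[lvl] = float(means[mask].mean())
    return pd.Series(out, name=f"{response}|{factor}")


def evaluate_grid(model: PolynomialModel, free: tuple, fixed: dict,
                  resolution: int = 41, space=None, relax_discrete: bool = False):
    """Predictions of `model` on a [-1,1]^2 grid over two free factors.

    Remaining factors sit at the coded levels in `fixed`.  If a factor
    space is given and a free factor is discrete, the grid relaxes its
    discrete constraint — this is a visualisation device and must be
    requested explicitly with ``relax_discrete=True``.

    Returns ``(axis1, axis2, Z)`` with ``Z[i, j]`` the prediction at
    ``(axis1[i], axis2[j])``.
    """
    if len(free) != 2:
        raise ValueError("exactly two free factors required")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    names = list(model.terms.factor_names)
    for f in free:
        if f not in names:
            raise KeyError(f"unknown factor {f!r}")
    others = [n for n in names if n not in free]
    missing = [n for n in others if n not in fixed]
    if missing:
        raise ValueError(f"fixed levels missing for factors {missing}")
    if space is not None and not relax_discrete:
        disc = [f for f in free if f in space.discrete_names]
        if disc:
            raise ValueError(
                f"free factors {disc} are discrete; pass relax_discrete=True "
                "to evaluate them on a continuous grid (visualisation only)"
            )
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
    Z = model.predict(pts).reshape(resolution, resolution)
    return ax, ax.copy(), Z
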