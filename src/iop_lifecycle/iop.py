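"""Ex-ante parametric inequality of opportunity for one analysis cell.

The estimator works in three steps, applied to the individuals of a single
country × cohort × age cell:

1. a reduced-form logit of the binary health outcome on the vector of
   childhood circumstances,
2. the counterfactual distribution: every individual's outcome is replaced by
   the fitted probability, which is constant within a circumstance type,
3. the dissimilarity index of that predicted distribution,

       D = (1 / (2 ybar)) * sum_i  l_i * |yhat_i - ybar|,

   with uniform weights l_i = 1/n and ybar the weighted mean of yhat.

D is the minimum fraction of favourable outcomes that would have to be
reallocated across circumstance types to equalise opportunity; it is 0 when
all types face the same prospects and bounded above by 1.  Because only
observed circumstances enter the model, D is a lower bound on total
inequality of opportunity.

The module exposes both a statsmodels-style object pair
(:class:`CellIOpModel` / :class:`CellIOpResults`) and flat functions
(:func:`fit_logit`, :func:`predict_counterfactual`,
:func:`dissimilarity_index`, :func:`estimate_cell`) for pipeline use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.special import expit

from .exceptions import CellDegenerate, RankDeficientDesign

__all__ = [
    "LogitFit",
    "CellChecks",
    "CellIOpModel",
    "CellIOpResults",
    "fit_logit",
    "predict_counterfactual",
    "dissimilarity_index",
    "estimate_cell",
    "empirical_type_means",
]


# ---------------------------------------------------------------------------
# logit fit
# ---------------------------------------------------------------------------

@dataclass
class LogitFit:
    """Maximum-likelihood fit of the reduced-form circumstance logit.

    Attributes
    ----------
    alpha : float
        Intercept, log-odds of the outcome for the all-zero circumstance
        vector.
    beta : pandas.Series
        Coefficients (log-odds per unit), indexed by circumstance name.
        Constant columns dropped before fitting do not appear here.
    bse : pandas.Series
        Standard errors aligned with ``beta`` (NaN when the information
        matrix could not be inverted).
    n : int
        Number of observations used.
    converged : bool
    separation_flag : bool
        True when fitted probabilities pile up within 1e-8 of 0 or 1 together
        with a diverging coefficient — quasi-complete separation.
    dropped_columns : list[str]
        Circumstance columns that were constant in this cell and therefore
        excluded from the design.
    """

    alpha: float
    beta: pd.Series
    bse: pd.Series
    n: int
    converged: bool
    separation_flag: bool
    dropped_columns: list = field(default_factory=list)
    llf: float = np.nan

    @property
    def circumstance_names(self):
        return list(self.beta.index)


_SEP_PROB_TOL = 1e-8
_SEP_COEF = 10.0


def _collinear_columns(X: np.ndarray, names) -> list:
    # QR with column pivoting: tiny diagonal entries of R identify the
    # columns that are linear combinations of earlier pivots.
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    bad += [names[j] for j in piv[len(diag):]]
    return bad


def fit_logit(
    records: pd.DataFrame,
    outcome: str,
    circumstances,
    maxiter: int = 100,
    tol: float = 1e-8,
    ridge: float = 0.0,
) -> LogitFit:
    """Fit the reduced-form logit of ``outcome`` on ``circumstances``.

    Parameters
    ----------
    records : DataFrame with the outcome column (0/1) and one column per
        circumstance (numeric; booleans are cast).
    outcome : name of the outcome column.
    circumstances : ordered collection of circumstance column names.
    ridge : optional L2 penalty weight; 0 (default) is the plain MLE.

    Raises
    ------
    CellDegenerate
        If the outcome is all-case or all-non-case.
    RankDeficientDesign
        If, after dropping constant columns, the design is rank deficient;
        the exception names the collinear columns.
    """
    circumstances = list(circumstances)
    y = np.asarray(records[outcome], dtype=float)
    n = len(y)
    n_cases = int(y.sum())
    if n == 0:
        raise CellDegenerate("empty cell")
    if n_cases == 0:
        raise CellDegenerate("no cases: outcome all zero")
    if n_cases == n:
        raise CellDegenerate("no non-cases: outcome all one")

    X = records.loc[:, circumstances].astype(float)
    dropped = [c for c in circumstances if X[c].nunique() <= 1]
    kept = [c for c in circumstances if c not in dropped]

    design = sm.add_constant(X[kept], has_constant="add")
    mat = design.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # never blame the intercept; report circumstance columns only
        bad = [c for c in _collinear_columns(mat, list(design.columns)) if c != "const"]
        raise RankDeficientDesign(bad)

    model = sm.Logit(y, design)
    separation_hint = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if ridge > 0:
            res = model.fit_regularized(
                alpha=ridge, L1_wt=0.0, maxiter=maxiter, disp=0
            )
            converged = True
        else:
            try:
                res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception as err:
                # Newton fails outright under (quasi-)separation or a
                # singular Hessian; BFGS walks to a finite point on the
                # flat likelihood ridge instead.
                is_sep = ("separation" in str(err).lower()
                          or isinstance(err, np.linalg.LinAlgError))
                if not is_sep:
                    raise
                separation_hint = True
                res = model.fit(method="bfgs", maxiter=500, disp=0)
                converged = bool(res.mle_retvals.get("converged", False))

    params = pd.Series(res.params, index=design.columns, dtype=float)
    try:
        bse = pd.Series(np.asarray(res.bse, dtype=float), index=design.columns)
    except Exception:  # singular information matrix
        bse = pd.Series(np.nan, index=design.columns)

    probs = np.asarray(res.predict(design))
    at_boundary = np.any((probs < _SEP_PROB_TOL) | (probs > 1 - _SEP_PROB_TOL))
    diverging = np.max(np.abs(params.to_numpy())) > _SEP_COEF
    separation = separation_hint or (at_boundary and diverging)

    beta = params.drop("const")
    return LogitFit(
        alpha=float(params["const"]),
        beta=beta,
        bse=bse.drop("const"),
        n=n,
        converged=converged,
        separation_flag=bool(separation),
        dropped_columns=dropped,
        llf=float(getattr(res, "llf", np.nan)),
    )


def predict_counterfactual(fit: LogitFit, records: pd.DataFrame) -> np.ndarray:
    """Predicted probabilities yhat_i = logistic(alpha + beta·CI_i).

    Individuals with identical circumstance vectors receive identical
    predictions, so the output is constant within circumstance types.
    """
    missing = [c for c in fit.circumstance_names if c not in records.columns]
    if missing:
        raise KeyError(f"records lack circumstance columns {missing}")
    X = records.loc[:, fit.circumstance_names].astype(float).to_numpy()
    linpred = fit.alpha + X @ fit.beta.to_numpy()
    return expit(linpred)


# ---------------------------------------------------------------------------
# dissimilarity index
# ---------------------------------------------------------------------------

def dissimilarity_index(yhat, weights=None) -> float:
    """Dissimilarity index of a predicted-probability vector.

    ``D = (1 / (2 ybar)) * sum_i w_i |yhat_i - ybar|`` with ``ybar`` the
    weighted mean.  Weights default to uniform 1/n and must sum to 1.

    Equals 0 iff all predictions coincide, is invariant to permutation and to
    replicating every observation, and lies in [0, 1] for predictions in
    [0, 1].

    Raises
    ------
    CellDegenerate
        If the weighted mean is zero — there is no favourable-outcome mass to
        redistribute, so the index is undefined.
    """
    yhat = np.asarray(yhat, dtype=float)
    if yhat.ndim != 1 or yhat.size == 0:
        raise ValueError("yhat must be a non-empty 1-d array")
    if np.any((yhat < -1e-12) | (yhat > 1 + 1e-12)):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if weights is None:
        w = np.full(yhat.size, 1.0 / yhat.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != yhat.shape:
            raise ValueError("weights must match yhat in length")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
    ybar = float(w @ yhat)
    if ybar <= 0.0:
        raise CellDegenerate("mean predicted probability is zero; D undefined")
    if np.all(yhat == yhat[0]):
        return 0.0  # evenly spread opportunities: exact zero, no roundoff
    return float(w @ np.abs(yhat - ybar) / (2.0 * ybar))


def empirical_type_means(
    records: pd.DataFrame, columns, outcome: str
) -> np.ndarray:
    """Predicted probabilities from within-type empirical outcome means.

    Groups individuals by their exact pattern on ``columns`` and assigns each
    the mean observed outcome of the group — the saturated, nonparametric
    counterpart of the logit prediction.  With no columns the grand mean is
    used.  Serves as the fallback predictor when a subset logit cannot be
    fitted.
    """
    y = records[outcome].astype(float)
    if not list(columns):
        return np.full(len(records), y.mean())
    return y.groupby([records[c] for c in columns]).transform("mean").to_numpy()


# ---------------------------------------------------------------------------
# cell-level model / results objects
# ---------------------------------------------------------------------------

@dataclass
class CellChecks:
    """Reliability thresholds for a single analysis cell.

    Cells below these thresholds are still estimated when mathematically
    possible but flagged unreliable, mirroring the practice of dropping
    small or low-prevalence cells from reported results.
    """

    min_n: int = 50
    min_cases: int = 10
    min_noncases: int = 10


class CellIOpModel:
    """Inequality-of-opportunity model for one analysis cell.

    Parameters
    ----------
    data : DataFrame holding the outcome and circumstance columns for the
        individuals of a single (country, cohort, age) cell.
    outcome : name of the binary outcome column.
    circumstances : ordered circumstance column names (the CI vector).
    cell : optional identifier tuple carried through to the results.
    checks : reliability thresholds, see :class:`CellChecks`.

    Examples
    --------
    >>> model = CellIOpModel(df, "outcome_any", ["harm", "financial_hardship"])
    >>> res = model.fit()
    >>> res.d_index, res.reliable
    """

    def __init__(self, data, outcome, circumstances, cell=None,
                 checks: CellChecks | None = None):
        self.data = data
        self.outcome = outcome
        self.circumstances = list(circumstances)
        self.cell = cell
        self.checks = checks or CellChecks()

    @classmethod
    def from_dataframe(cls, data, outcome, circumstances, **kwargs):
        return cls(data, outcome, circumstances, **kwargs)

    def fit(self, ridge: float = 0.0, maxiter: int = 100,
            tol: float = 1e-8) -> "CellIOpResults":
        """Fit the logit, build the counterfactual distribution, compute D."""
        df = self.data
        y = np.asarray(df[self.outcome], dtype=float)
        n = len(y)
        n_cases = int(y.sum())

        reasons = []
        if n < self.checks.min_n:
            reasons.append(f"n={n}<{self.checks.min_n}")
        if n_cases < self.checks.min_cases:
            reasons.append(f"cases={n_cases}<{self.checks.min_cases}")
        if n - n_cases < self.checks.min_noncases:
            reasons.append(f"noncases={n - n_cases}<{self.checks.min_noncases}")

        fit = fit_logit(df, self.outcome, self.circumstances,
                        maxiter=maxiter, tol=tol, ridge=ridge)
        if not fit.converged:
            reasons.append("logit did not converge")
        if fit.separation_flag:
            reasons.append("separation")

        yhat = predict_counterfactual(fit, df)
        weights = np.full(n, 1.0 / n)
        d = dissimilarity_index(yhat, weights)
        return CellIOpResults(
            model=self, fit=fit, yhat=yhat, weights=weights,
            ybar=float(weights @ yhat), d_index=d,
            cell=self.cell, reliable=not reasons, reasons=reasons,
        )


@dataclass
class CellIOpResults:
    """Results of :meth:`CellIOpModel.fit` for one cell.

    Carries the per-individual predicted probabilities, the uniform weights,
    their weighted mean ``ybar``, the dissimilarity index ``d_index``, and a
    reliability flag with reason codes.
    """

    model: CellIOpModel
    fit: LogitFit
    yhat: np.ndarray
    weights: np.ndarray
    ybar: float
    d_index: float
    cell: object
    reliable: bool
    reasons: list

    @property
    def n(self) -> int:
        return self.fit.n

    def shapley(self, grouping, method="exact", n_permutations=None, seed=None):
        """Shapley decomposition of this cell's D by circumstance group."""
        from .shapley import ShapleySpec, shapley_decompose

        spec = ShapleySpec(players=grouping, method=method,
                           n_permutations=n_permutations, seed=seed)
        return shapley_decompose(
            self.model.data, spec, self.model.outcome, cell=self.cell
        )

    def summary(self) -> str:
        """Plain-text summary table of the fit and the index."""
        lines = [
            "Inequality of opportunity — cell estimate",
            "=" * 45,
            f"cell:        {self.cell}",
            f"n:           {self.n}",
            f"mean yhat:   {self.ybar:.4f}",
            f"D index:     {self.d_index:.4f}",
            f"reliable:    {self.reliable}"
            + (f"  ({'; '.join(self.reasons)})" if self.reasons else ""),
            f"converged:   {self.fit.converged}"
            f"   separation: {self.fit.separation_flag}",
            "-" * 45,
            f"{'term':<22}{'coef':>10}{'se':>10}",
            f"{'intercept':<22}{self.fit.alpha:>10.4f}{'':>10}",
        ]
        for name in self.fit.circumstance_names:
            se = self.fit.bse[name]
            se_s = f"{se:>10.4f}" if np.isfinite(se) else f"{'--':>10}"
            lines.append(f"{name:<22}{self.fit.beta[name]:>10.4f}{se_s}")
        if self.fit.dropped_columns:
            lines.append(f"dropped (constant): {self.fit.dropped_columns}")
        return "\n".join(lines)


def estimate_cell(
    records: pd.DataFrame,
    outcome: str,
    circumstances,
    cell=None,
    checks: CellChecks | None = None,
    ridge: float = 0.0,
) -> CellIOpResults:
    """One-shot cell estimate: logit → counterfactual distribution → D."""
    return CellIOpModel(
        records, outcome, circumstances, cell=cell, checks=checks
    ).fit(ridge=ridge)
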