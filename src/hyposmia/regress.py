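"""Association models linking olfaction to age, gender and disease duration.

Six outcomes are analysed on one cohort: the four binary hyposmia calls
(logistic regression, each adjusted only for the covariates its definition
does not already correct for), the five-level ordinal grade (proportional-
odds logistic regression, with the Brant test of the parallel-regression
assumption), and the continuous SS-scale score (ordinary least squares).

Method-specific covariate sets for the binary models:

==========  =============================  ==================================
Method      adjusts for                    because the rule already corrects
==========  =============================  ==================================
1           duration, gender               age
2 (binary)  duration, age                  gender
3           duration                       age and gender
4           duration, age, gender          nothing
==========  =============================  ==================================

All models are complete-case on the covariates used and report the n fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .classify import HyposmiaGrade
from .cohort import Cohort

METHOD_COVARIATES = {
    1: ["disease_duration", "gender_male"],
    2: ["disease_duration", "age_at_test"],
    3: ["disease_duration"],
    4: ["age_at_test", "gender_male", "disease_duration"],
}

ORDERED_COVARIATES = ["disease_duration", "age_at_test"]
LINEAR_COVARIATES = ["age_at_test", "gender_male", "disease_duration"]


class ModelFitError(RuntimeError):
    pass


@dataclass
class RegressionResult:
    """Per-term estimates for one fitted model.

    ``terms`` has columns term, estimate, ci_low, ci_high, p; estimates are
    odds ratios for the logistic family and betas for the linear model.
    """

    kind: str      # "logistic" | "ordered_logistic" | "linear"
    outcome: str
    terms: pd.DataFrame
    n: int
    diagnostics: dict = field(default_factory=dict)
    # retained fit context for follow-up tests (e.g. Brant)
    _endog: np.ndarray | None = None
    _exog: pd.DataFrame | None = None

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"term {name!r} not in model ({list(self.terms['term'])})")
        return row.iloc[0]


def _design(cohort: Cohort, covariates: list[str], extra: pd.Series | None = None):
    df = cohort.df.copy()
    df["gender_male"] = (df["gender"] == "male").astype(float)
    cols = df[covariates].astype(float)
    if extra is not None:
        keep = cols.notna().all(axis=1) & extra.notna()
        return cols[keep], extra[keep]
    keep = cols.notna().all(axis=1)
    return cols[keep], None


def fit_binary_model(cohort: Cohort, matrix: pd.DataFrame, method: int) -> RegressionResult:
    """Logistic fit of one method's binary call on its covariate set (ORs)."""
    if method not in METHOD_COVARIATES:
        raise ValueError(f"method must be 1..4, got {method}")
    outcome_col = "method2_binary" if method == 2 else f"method{method}"
    y_all = matrix[outcome_col].astype(float)
    X, y = _design(cohort, METHOD_COVARIATES[method], extra=y_all)
    if y.nunique() < 2:
        raise ModelFitError(f"outcome {outcome_col} has a single class; logistic fit undefined")
    if len(y) < 10 * (X.shape[1] + 1):
        raise ModelFitError(f"too few complete cases ({len(y)}) for {X.shape[1]} terms")
    try:
        fit = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy())).fit(disp=0)
    except Exception as exc:  # separation, non-convergence
        raise ModelFitError(f"logistic fit failed for {outcome_col}: {exc}") from exc
    names = ["const"] + list(X.columns)
    ci = fit.conf_int()
    terms = pd.DataFrame(
        {
            "term": names,
            "estimate": np.exp(fit.params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p": fit.pvalues,
        }
    )
    terms = terms[terms["term"] != "const"].reset_index(drop=True)
    return RegressionResult(
        kind="logistic",
        outcome=outcome_col,
        terms=terms,
        n=int(len(y)),
        diagnostics={"log_likelihood": float(fit.llf)},
    )


def fit_ordered_model(cohort: Cohort, matrix: pd.DataFrame) -> RegressionResult:
    """Proportional-odds fit of the 5-level grade on duration and age (ORs)."""
    grades_all = matrix["method2_grade"].astype(float)
    X, grades = _design(cohort, ORDERED_COVARIATES, extra=grades_all)
    levels = np.sort(grades.unique())
    if len(levels) < 3:
        raise ModelFitError(f"need >= 3 grade levels, found {len(levels)}")
    endog = pd.Series(
        pd.Categorical(grades, categories=levels, ordered=True), name="grade"
    )
    model = OrderedModel(endog, X.to_numpy(), distr="logit")
    fit = model.fit(method="bfgs", disp=0)
    k = X.shape[1]
    params = np.asarray(fit.params)[:k]
    ci = np.asarray(fit.conf_int())[:k]
    pvals = np.asarray(fit.pvalues)[:k]
    terms = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": np.exp(params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p": pvals,
        }
    )
    res = RegressionResult(
        kind="ordered_logistic",
        outcome="method2_grade",
        terms=terms,
        n=int(len(grades)),
        diagnostics={"levels": [int(l) for l in levels]},
        _endog=grades.to_numpy(float),
        _exog=X.reset_index(drop=True),
    )
    chi2, df, p = brant_test(res)
    res.diagnostics.update({"brant_chi2": chi2, "brant_df": df, "brant_p": p})
    return res


def brant_test(ordered_fit: RegressionResult) -> tuple[float, int, float]:
    """Brant's Wald test of the parallel-regression assumption.

    For a J-level ordinal outcome, fits the J-1 cumulative binary logistic
    models P(Y > c_j) on the same covariates, stacks their slope vectors,
    builds the joint covariance from the score cross-products of the
    cumulative indicators, and tests equality of the slope vectors across
    splits.  Returns (chi-square, df, p) with df = (J-2) * n_covariates.
    """
    if ordered_fit._endog is None or ordered_fit._exog is None:
        raise ValueError("brant_test needs a RegressionResult from fit_ordered_model")
    y = np.asarray(ordered_fit._endog, dtype=float)
    Xdf = ordered_fit._exog
    X = sm.add_constant(Xdf.to_numpy(float))
    n, p1 = X.shape
    p = p1 - 1  # slopes only
    levels = np.sort(np.unique(y))
    J = len(levels)
    if J < 3:
        raise ValueError("Brant test needs >= 3 outcome levels")
    m = J - 1
    betas = np.empty((m, p))
    pis = np.empty((m, n))
    for j in range(m):
        z = (y > levels[j]).astype(float)
        if z.min() == z.max():
            raise ModelFitError(f"cumulative split Y > {levels[j]} has a single class")
        fit = sm.Logit(z, X).fit(disp=0)
        betas[j] = fit.params[1:]
        pis[j] = fit.predict(X)
    # joint covariance of the stacked (intercept+slope) estimates;
    # for splits j <= l (pi_l <= pi_j): W_jl = diag(pi_l - pi_j*pi_l)
    V = np.zeros((m * p1, m * p1))
    XtWX_inv = []
    for j in range(m):
        w = pis[j] * (1 - pis[j])
        XtWX_inv.append(np.linalg.inv(X.T @ (X * w[:, None])))
    for j in range(m):
        for l in range(j, m):
            w = pis[l] - pis[j] * pis[l]
            mid = X.T @ (X * w[:, None])
            block = XtWX_inv[j] @ mid @ XtWX_inv[l]
            V[j * p1:(j + 1) * p1, l * p1:(l + 1) * p1] = block
            V[l * p1:(l + 1) * p1, j * p1:(j + 1) * p1] = block.T
    # drop intercept rows/cols
    keep = np.concatenate([np.arange(1, p1) + j * p1 for j in range(m)])
    Vb = V[np.ix_(keep, keep)]
    beta_vec = betas.ravel()
    # contrasts: beta_j - beta_{j+1} = 0 for j = 1..m-1, each of length p
    D = np.zeros(((m - 1) * p, m * p))
    for j in range(m - 1):
        for k in range(p):
            D[j * p + k, j * p + k] = 1.0
            D[j * p + k, (j + 1) * p + k] = -1.0
    diff = D @ beta_vec
    chi2 = float(diff @ np.linalg.solve(D @ Vb @ D.T, diff))
    df = (J - 2) * p
    pval = float(stats.chi2.sf(chi2, df))
    return chi2, df, pval


def fit_linear_model(cohort: Cohort, score_col: str = "score_ss") -> RegressionResult:
    """OLS of the continuous SS-scale score on age, male gender and duration."""
    if score_col not in cohort.df.columns:
        raise ValueError(f"cohort lacks {score_col!r}; run convert_scores first")
    y_all = cohort.df[score_col].astype(float)
    X, y = _design(cohort, LINEAR_COVARIATES, extra=y_all)
    if len(y) < 30:
        raise ModelFitError(f"too few complete cases ({len(y)}) for the linear model")
    Xc = sm.add_constant(X.to_numpy())
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ModelFitError("collinear design matrix")
    fit = sm.OLS(y.to_numpy(), Xc).fit()
    names = ["const"] + list(X.columns)
    ci = fit.conf_int()
    terms = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": fit.pvalues,
        }
    )
    return RegressionResult(
        kind="linear",
        outcome=score_col,
        terms=terms,
        n=int(len(y)),
        diagnostics={
            "residual_skewness": float(stats.skew(fit.resid)),
            "r_squared": float(fit.rsquared),
        },
    )
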