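"""Risk-factor cascade: univariate screen -> LASSO selection -> logistic fit.

The screen keeps drugs whose disproportionality panel passes a report-count
floor, an ROR 95% lower bound above 1, and an adjusted-p ceiling. Survivors
enter an L1-penalized logistic regression (10-fold cross-validated lambda,
mean-squared-error criterion on predicted probabilities) together with
demographic covariates (age in years, sex, weight in kg) and a polypharmacy
count. Variables with non-zero coefficients at the selected lambda go into
an unpenalized multivariable logistic model whose Wald odds ratios, 95% CIs
and Bonferroni-adjusted p-values form the final forest table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .faers_ingest import CaseSet, ReportStore

DEFAULT_COVARIATES = ("age_years", "sex_male", "weight_kg", "n_drugs")


@dataclass
class ScreenThresholds:
    """Univariate entry thresholds. ``strict_count`` switches the report
    floor from n >= min_reports to n > min_reports (the stricter variant
    used at the selection-entry stage)."""

    min_reports: int = 3
    strict_count: bool = False
    ror_lcl_min: float = 1.0
    p_adj_max: float = 0.05


@dataclass
class ModelMatrix:
    """Design for the regression stages: one row per deduplicated report."""

    X: pd.DataFrame
    y: pd.Series
    n_dropped_missing: int
    candidate_drugs: tuple

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class LassoResult:
    lambdas: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_selected: float
    coef_path: pd.DataFrame  # one row per lambda, one column per variable
    selected: tuple
    cv_folds: int
    seed: int


@dataclass
class LogisticTerm:
    variable: str
    coef: float
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    p_adj: float
    separated: bool = False


# ---------------------------------------------------------------------------
# stage 1: univariate screen


def univariate_screen(
    metrics: pd.DataFrame, thr: ScreenThresholds = ScreenThresholds(), p_col: str = "p_adj"
) -> tuple[list[str], pd.DataFrame]:
    """Filter the per-drug signal panel; returns the candidate list and a
    per-drug pass/fail table with the failing reasons."""
    count_ok = (
        metrics["n_reports"] > thr.min_reports
        if thr.strict_count
        else metrics["n_reports"] >= thr.min_reports
    )
    lcl_ok = metrics["ror_lcl"].fillna(-np.inf) > thr.ror_lcl_min
    p_ok = metrics[p_col].fillna(np.inf) < thr.p_adj_max

    reasons = pd.DataFrame(
        {
            "drug": metrics["drug"],
            "count_ok": count_ok.to_numpy(),
            "ror_lcl_ok": lcl_ok.to_numpy(),
            "p_adj_ok": p_ok.to_numpy(),
        }
    )
    reasons["passed"] = reasons[["count_ok", "ror_lcl_ok", "p_adj_ok"]].all(axis=1)
    candidates = reasons.loc[reasons["passed"], "drug"].tolist()
    return candidates, reasons


# ---------------------------------------------------------------------------
# stage 2: design matrix


def build_matrix(
    store: ReportStore,
    cases: CaseSet,
    candidates: list[str],
    covariates: tuple = DEFAULT_COVARIATES,
    missing: str = "complete-case",
) -> ModelMatrix:
    """One row per report: candidate-drug indicators (1 iff the drug is in
    the report's primary-suspect set), demographic covariates, and the
    polypharmacy count (distinct drug names, any role).

    ``missing="complete-case"`` drops rows missing any modelled covariate;
    ``missing="indicator"`` imputes continuous covariates to their mean and
    adds a per-covariate missing indicator (spontaneous reports are mostly
    missing weight, so complete-case can be very lossy).
    """
    if not candidates:
        raise ValueError("candidate drug list is empty")

    rep = store.reports
    pairs = store.drugs.loc[
        (store.drugs["role"] == "primary-suspect") & store.drugs["drug_name"].isin(candidates),
        ["report_id", "drug_name"],
    ].drop_duplicates()
    X = pd.DataFrame(index=rep.index)
    ind = pd.crosstab(pairs["report_id"], pairs["drug_name"]).clip(upper=1)
    for drug in candidates:
        X[drug] = ind[drug].reindex(rep.index, fill_value=0).astype(float) if drug in ind else 0.0

    cov = pd.DataFrame(index=rep.index)
    if "age_years" in covariates:
        cov["age_years"] = rep["age_years"]
    if "sex_male" in covariates:
        cov["sex_male"] = rep["sex"].map({"male": 1.0, "female": 0.0})
    if "weight_kg" in covariates:
        cov["weight_kg"] = rep["weight_kg"]
    if "n_drugs" in covariates:
        cov["n_drugs"] = store.n_distinct_drugs().astype(float)

    if missing == "complete-case":
        keep = ~cov.isna().any(axis=1)
    elif missing == "indicator":
        keep = pd.Series(True, index=rep.index)
        for col in list(cov.columns):
            na = cov[col].isna()
            if na.any():
                cov[f"{col}_missing"] = na.astype(float)
                cov[col] = cov[col].fillna(cov[col].mean())
    else:
        raise ValueError("missing must be 'complete-case' or 'indicator'")

    X = pd.concat([X, cov], axis=1)[keep.values if hasattr(keep, "values") else keep]
    y = pd.Series(rep.index.isin(cases.case_ids).astype(int), index=rep.index)[X.index]
    n_dropped = len(rep) - len(X)

    # screened candidates should vary; a constant column cannot be fit
    nunique = X.nunique()
    constant = nunique[nunique <= 1].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}")
        X = X.drop(columns=constant)
    if len(X) == 0:
        raise ValueError("zero usable rows after missing-data policy")
    return ModelMatrix(X=X, y=y, n_dropped_missing=n_dropped, candidate_drugs=tuple(candidates))


# ---------------------------------------------------------------------------
# stage 3: LASSO selection


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def lasso_select(
    mm: ModelMatrix,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 20,
    lambda_min_ratio: float = 1e-3,
    criterion: str = "mse",
    lambdas: np.ndarray | None = None,
) -> LassoResult:
    """L1-penalized logistic path with k-fold cross-validated lambda.

    Columns are standardized internally; reported coefficients are on the
    original scale. The CV criterion is the mean squared error of
    predicted probabilities (``criterion="deviance"`` uses the mean
    binomial deviance instead). Fold assignment is stratified by outcome
    and deterministic given ``seed``.
    """
    y = mm.y.to_numpy(dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class; cannot fit")
    Xs, _, sd = _standardize(mm.X.to_numpy(dtype=float))
    n = len(y)

    if lambdas is None:
        # lambda_max: smallest penalty with an all-zero solution (KKT bound)
        lam_max = np.max(np.abs(Xs.T @ (y - y.mean()))) / n
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.asarray(lambdas, dtype=float)
        n_lambda = lambdas.size

    def l1_fit(X_, y_, lam):
        if lam <= 0:  # exact unpenalized limit
            clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10, max_iter=2000)
        else:
            # liblinear penalizes the intercept; a large intercept_scaling
            # makes that penalty negligible
            clf = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (len(y_) * lam), solver="liblinear",
                tol=1e-4, max_iter=500, intercept_scaling=50.0, random_state=0,
            )
        clf.fit(X_, y_)
        return clf

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    Xcsr = sparse.csr_matrix(Xs)
    fold_data = [
        (Xcsr[tr], y[tr], Xcsr[va], y[va]) for tr, va in skf.split(Xs, y)
    ]
    cv_err = np.zeros((folds, n_lambda))
    for k, (Xtr, ytr, Xva, yva) in enumerate(fold_data):
        for j, lam in enumerate(lambdas):
            clf = l1_fit(Xtr, ytr, lam)
            p = clf.predict_proba(Xva)[:, 1]
            if criterion == "mse":
                cv_err[k, j] = float(np.mean((p - yva) ** 2))
            elif criterion == "deviance":
                eps = 1e-12
                cv_err[k, j] = float(
                    -2.0 * np.mean(yva * np.log(p + eps) + (1 - yva) * np.log(1 - p + eps))
                )
            else:
                raise ValueError("criterion must be 'mse' or 'deviance'")
    cv_mean = cv_err.mean(axis=0)
    cv_se = cv_err.std(axis=0, ddof=1) / math.sqrt(folds)
    j_star = int(np.argmin(cv_mean))
    lam_star = float(lambdas[j_star])

    # full-data path (original-scale coefficients)
    path = np.zeros((n_lambda, Xs.shape[1]))
    for j, lam in enumerate(lambdas):
        path[j] = l1_fit(Xcsr if lam > 0 else Xs, y, lam).coef_[0] / sd

    coef_path = pd.DataFrame(path, index=lambdas, columns=mm.X.columns)
    coef_path.index.name = "lambda"
    selected = tuple(mm.X.columns[np.abs(path[j_star]) > 0])
    return LassoResult(
        lambdas=lambdas, cv_mean=cv_mean, cv_se=cv_se, lambda_selected=lam_star,
        coef_path=coef_path, selected=selected, cv_folds=folds, seed=seed,
    )


# ---------------------------------------------------------------------------
# stage 4: multivariable logistic regression


def logistic_fit(
    mm: ModelMatrix, selected: tuple | list | None = None, bonferroni_over: int | None = None
) -> list[LogisticTerm]:
    """Unpenalized maximum-likelihood logistic fit of the selected
    variables with Wald 95% CIs. Per-term p-values are Bonferroni-adjusted
    over the number of reported terms (the intercept is fit but not
    reported). Collinear columns are dropped with a warning; terms showing
    separation are flagged and reported with an infinite-CI marker."""
    cols = list(selected) if selected is not None else list(mm.X.columns)
    if not cols:
        raise ValueError("no variables selected for the logistic model")
    X = mm.X[cols].copy()

    # drop collinear columns (QR rank check)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        keep: list[str] = []
        for col in X.columns:
            trial = keep + [col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
                keep.append(col)
        dropped = sorted(set(X.columns) - set(keep))
        warnings.warn(f"dropping collinear columns: {dropped}")
        X = X[keep]
        cols = keep

    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(mm.y.to_numpy(), design.to_numpy())
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:  # singular Hessian under (quasi-)separation
            res = model.fit(method="bfgs", disp=0, maxiter=1000)

    params = pd.Series(res.params, index=design.columns)
    with np.errstate(all="ignore"):
        bse = pd.Series(np.asarray(res.bse, dtype=float), index=design.columns)
        pvals = pd.Series(np.asarray(res.pvalues, dtype=float), index=design.columns)

    fitted = res.predict()
    separated_any = bool(np.any((fitted < 1e-8) | (fitted > 1 - 1e-8)))

    m = bonferroni_over if bonferroni_over is not None else len(cols)
    terms = []
    for var in cols:
        beta, se, p = float(params[var]), float(bse[var]), float(pvals[var])
        flagged = separated_any and (abs(beta) > 15 or se > 50 or not math.isfinite(se))
        if flagged:
            ci = (0.0, math.inf)
        else:
            ci = (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se))
        terms.append(
            LogisticTerm(
                variable=var, coef=beta, odds_ratio=math.exp(beta), ci95=ci,
                p=p, p_adj=min(1.0, p * m), separated=flagged,
            )
        )
    terms.sort(key=lambda t: -t.odds_ratio)
    return terms


def forest_table(terms: list[LogisticTerm], sig_level: float = 0.01) -> pd.DataFrame:
    """Forest-plot export rows, sorted descending by OR, with a
    significance marker at adjusted p below ``sig_level``."""
    rows = [
        {
            "variable": t.variable,
            "odds_ratio": t.odds_ratio,
            "or_lcl": t.ci95[0],
            "or_ucl": t.ci95[1],
            "p_adj": t.p_adj,
            "significant": t.p_adj < sig_level,
            "separated": t.separated,
        }
        for t in sorted(terms, key=lambda t: -t.odds_ratio)
    ]
    return pd.DataFrame(
        rows, columns=["variable", "odds_ratio", "or_lcl", "or_ucl", "p_adj", "significant", "separated"]
    )
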