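"""Time-to-onset (TTO) analysis: exclusion audit, Weibull failure typing,
Kaplan-Meier cumulative incidence and Kruskal-Wallis subgroup tests.

TTO is ``event_date - start_date`` in whole days for each (case report,
primary-suspect drug). Records with missing/partial dates or non-positive
TTO are excluded and accounted for exactly in an :class:`ExclusionAudit`.
Onset distributions are fit by uncensored Weibull maximum likelihood; the
shape parameter types the hazard: beta < 1 "early failure" (decreasing
hazard, events cluster soon after exposure), beta > 1 "wear-out failure"
(increasing hazard), beta = 1 "random" (constant, exponential).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize, stats

from .faers_ingest import BinningSpec, CaseSet, ReportStore, _band_labels, round_half_up


@dataclass
class ExclusionAudit:
    """Bookkeeping of the TTO screen; counts are conserved exactly."""

    n_total: int
    n_excluded_missing: int
    n_excluded_invalid: int

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_excluded_missing - self.n_excluded_invalid

    @property
    def exclusion_fraction(self) -> float:
        if self.n_total == 0:
            return 0.0
        return (self.n_excluded_missing + self.n_excluded_invalid) / self.n_total

    @property
    def exclusion_percent(self) -> float:
        """Exclusion fraction as a printed percentage (half-up, 1 dp)."""
        return round_half_up(100.0 * self.exclusion_fraction, 1)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded_missing": self.n_excluded_missing,
            "n_excluded_invalid": self.n_excluded_invalid,
            "n_retained": self.n_retained,
            "exclusion_percent": self.exclusion_percent,
        }


@dataclass
class WeibullFit:
    """Uncensored Weibull MLE with delta-method CIs on the log parameters.

    ``median_days``/``iqr_days`` are empirical sample quantiles (linear
    interpolation); ``median_model`` is the parametric alpha*(ln 2)^(1/beta).
    """

    alpha: float
    beta: float
    ci95_alpha: tuple[float, float]
    ci95_beta: tuple[float, float]
    n: int
    median_days: float
    iqr_days: tuple[float, float]

    @property
    def median_model(self) -> float:
        return self.alpha * math.log(2.0) ** (1.0 / self.beta)

    @property
    def failure_type(self) -> str:
        return classify_failure(self)


# ---------------------------------------------------------------------------
# TTO records


def compute_tto(
    cases: CaseSet,
    store: ReportStore,
    per: str = "drug",
    binning: BinningSpec = BinningSpec(),
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """TTO records for the case subset with the exclusion audit.

    ``per="drug"`` yields one candidate record per (case, primary-suspect
    drug) for drug-level fits; ``per="case"`` collapses to one record per
    case using the earliest available start date (subgroup analyses, so
    patients are not double-counted).
    """
    if per not in ("drug", "case"):
        raise ValueError("per must be 'drug' or 'case'")
    case_ids = pd.Index(list(cases.case_ids))
    drugs = store.drugs
    ps = drugs[
        (drugs["role"] == "primary-suspect") & drugs["report_id"].isin(case_ids)
    ][["report_id", "drug_name", "start_date"]].drop_duplicates(["report_id", "drug_name"])

    rep = store.reports.loc[store.reports.index.isin(case_ids)]
    merged = ps.merge(
        rep[["event_date", "sex", "age_years", "weight_kg"]],
        left_on="report_id", right_index=True, how="left",
    )
    if per == "case":
        merged = merged.sort_values(
            ["report_id", "start_date"], na_position="last"
        ).groupby("report_id", as_index=False).first()

    n_total = len(merged)
    missing = merged["start_date"].isna() | merged["event_date"].isna()
    tto = (merged["event_date"] - merged["start_date"]).dt.days
    invalid = ~missing & (tto <= 0)
    keep = ~missing & ~invalid

    records = merged.loc[keep, ["report_id", "drug_name"]].copy()
    records["tto_days"] = tto[keep].astype(int)
    records["sex"] = merged.loc[keep, "sex"].values
    records["age_band"] = _band_labels(merged.loc[keep, "age_years"], binning.age_bands).values
    records["weight_band"] = _band_labels(merged.loc[keep, "weight_kg"], binning.weight_bands).values
    records = records.rename(columns={"drug_name": "drug"}).reset_index(drop=True)

    audit = ExclusionAudit(
        n_total=n_total,
        n_excluded_missing=int(missing.sum()),
        n_excluded_invalid=int(invalid.sum()),
    )
    return records, audit


# ---------------------------------------------------------------------------
# Weibull MLE


def _weibull_loglik(logparams: np.ndarray, x: np.ndarray) -> float:
    la, lb = logparams
    alpha, beta = math.exp(la), math.exp(lb)
    z = x / alpha
    return float(
        len(x) * (math.log(beta) - beta * math.log(alpha))
        + (beta - 1.0) * np.sum(np.log(x))
        - np.sum(z**beta)
    )


def fit_weibull(samples: np.ndarray | pd.Series | list) -> WeibullFit:
    """Maximum-likelihood Weibull fit for uncensored positive durations.

    The shape equation d logL/d beta = 0 is solved by bracketed root
    finding (profile likelihood); the scale then has the closed form
    alpha = (mean x^beta)^(1/beta). 95% CIs come from the delta method on
    (log alpha, log beta) using a finite-difference observed information.
    Degenerate inputs (n < 3, non-positive or constant samples) are
    refused.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 durations to fit a Weibull (got {x.size})")
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("durations must be positive and finite")
    if np.ptp(x) == 0:
        raise ValueError("constant durations: shape diverges, fit is degenerate")

    logx = np.log(x)
    mean_logx = logx.mean()
    z = x / x.max()  # rescaling cancels in the ratio; avoids overflow at large beta

    def score(beta: float) -> float:
        zb = z**beta
        return float(np.sum(zb * logx) / np.sum(zb) - 1.0 / beta - mean_logx)

    lo, hi = 1e-3, 1e3
    # score is increasing in beta; bracket then solve
    beta = optimize.brentq(score, lo, hi, xtol=1e-12, rtol=1e-12)
    alpha = float(np.mean(x**beta) ** (1.0 / beta))

    # observed information in log-parameter space (finite differences)
    theta = np.array([math.log(alpha), math.log(beta)])
    h = 1e-5
    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            tpp = theta.copy(); tpp[i] += h; tpp[j] += h
            tpm = theta.copy(); tpm[i] += h; tpm[j] -= h
            tmp = theta.copy(); tmp[i] -= h; tmp[j] += h
            tmm = theta.copy(); tmm[i] -= h; tmm[j] -= h
            hess[i, j] = (
                _weibull_loglik(tpp, x) - _weibull_loglik(tpm, x)
                - _weibull_loglik(tmp, x) + _weibull_loglik(tmm, x)
            ) / (4 * h * h)
    cov = np.linalg.inv(-hess)
    se_la, se_lb = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))

    ci_alpha = (alpha * math.exp(-1.96 * se_la), alpha * math.exp(1.96 * se_la))
    ci_beta = (beta * math.exp(-1.96 * se_lb), beta * math.exp(1.96 * se_lb))

    q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return WeibullFit(
        alpha=alpha, beta=beta, ci95_alpha=ci_alpha, ci95_beta=ci_beta,
        n=int(x.size), median_days=float(q50), iqr_days=(float(q25), float(q75)),
    )


def classify_failure(fit: WeibullFit, rule: str = "point") -> str:
    """Hazard typing from the Weibull shape.

    ``point`` (default): beta < 1 early, beta > 1 wear-out, beta == 1
    random. ``ci``: classify only when the 95% CI excludes 1, else random.
    """
    if rule == "point":
        if fit.beta < 1.0:
            return "early"
        if fit.beta > 1.0:
            return "wear-out"
        return "random"
    if rule == "ci":
        lo, hi = fit.ci95_beta
        if hi < 1.0:
            return "early"
        if lo > 1.0:
            return "wear-out"
        return "random"
    raise ValueError("rule must be 'point' or 'ci'")


def weibull_fit_table(records: pd.DataFrame, min_n: int = 3, rule: str = "point") -> pd.DataFrame:
    """Per-drug Weibull fits over TTO records (drugs under ``min_n`` or
    with degenerate samples are skipped)."""
    rows = []
    for drug, grp in records.groupby("drug"):
        x = grp["tto_days"].to_numpy(dtype=float)
        if x.size < min_n:
            continue
        try:
            fit = fit_weibull(x)
        except ValueError:
            continue
        rows.append(
            {
                "drug": drug,
                "n": fit.n,
                "median_days": fit.median_days,
                "iqr_low": fit.iqr_days[0],
                "iqr_high": fit.iqr_days[1],
                "min_days": float(x.min()),
                "max_days": float(x.max()),
                "alpha": fit.alpha,
                "alpha_lcl": fit.ci95_alpha[0],
                "alpha_ucl": fit.ci95_alpha[1],
                "beta": fit.beta,
                "beta_lcl": fit.ci95_beta[0],
                "beta_ucl": fit.ci95_beta[1],
                "failure_type": classify_failure(fit, rule),
            }
        )
    cols = ["drug", "n", "median_days", "iqr_low", "iqr_high", "min_days", "max_days",
            "alpha", "alpha_lcl", "alpha_ucl", "beta", "beta_lcl", "beta_ucl", "failure_type"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("n", ascending=False).reset_index(drop=True) if len(out) else out


# ---------------------------------------------------------------------------
# nonparametric comparisons


def km_curve(durations, groups) -> tuple[pd.DataFrame, dict[str, float]]:
    """Kaplan-Meier cumulative incidence per group (no censoring, so each
    curve equals the group's empirical CDF). Returns the stepwise curves
    as tidy rows (group, time, cum_incidence) and per-group median TTO.
    Empty groups are dropped with a warning."""
    s = pd.DataFrame({"t": np.asarray(durations, dtype=float), "g": np.asarray(groups, dtype=object)})
    curves = []
    medians: dict[str, float] = {}
    for g, grp in s.groupby("g", sort=True):
        t = grp["t"].to_numpy()
        if t.size == 0:
            warnings.warn(f"km_curve: group {g!r} is empty; omitted")
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t, event_observed=np.ones_like(t))
        sf = kmf.survival_function_
        curves.append(
            pd.DataFrame(
                {"group": g, "time": sf.index.to_numpy(), "cum_incidence": 1.0 - sf.iloc[:, 0].to_numpy()}
            )
        )
        medians[str(g)] = float(np.median(t))
    if not curves:
        return pd.DataFrame(columns=["group", "time", "cum_incidence"]), medians
    return pd.concat(curves, ignore_index=True), medians


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).
    If every value is identical across all groups, returns (0.0, 1.0)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)
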