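"""Disproportionality signal detection on report-level 2x2 tables.

For each suspect drug a contingency table is built over unique
deduplicated reports:

====================  ==============  ==============
\                      target event    other events
target drug            a               b
all other drugs        c               d
====================  ==============  ==============

and a four-metric panel is computed:

* ``ROR = ad/bc`` with Wald 95% CI on the log scale;
* ``PRR = [a/(a+b)] / [c/(c+d)]`` with the (uncorrected) chi-square;
* ``RRR = aN/((a+b)(a+c))`` — the observed/expected relative reporting
  ratio; ``IC = log2 RRR`` with a delta-method IC025; and
* ``EBGM = RRR`` with a one-sided lognormal-style 5th percentile EBGM05.

The IC/EBGM forms are the simplified observed/expected variants (no
gamma-Poisson hyperparameter estimation); the full-shrinkage versions can
be slotted in behind :func:`compute_signal_metrics` if ever needed.
Positivity follows the usual any-of rule: PRR-positive (n >= 3, PRR >= 2,
chi2 >= 4), ROR-positive (95% lower bound > 1), IC-positive (IC025 > 0).
"""

from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .faers_ingest import CaseSet, ReportStore

Z95 = 1.96          # two-sided 95% normal quantile, as printed in the CIs
Z90_ONESIDED = 1.64  # one-sided 95% factor used for EBGM05


@dataclass
class ContingencyTable:
    """Report-level 2x2 counts; ``a`` is drug-and-event."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe +0.5 on every cell (for zero-cell tables)."""
        return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5


@dataclass
class SignalMetrics:
    drug: str
    n_reports: int
    ror: float
    ror_lcl: float
    ror_ucl: float
    prr: float
    chi2: float
    rrr: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    fisher_p: float
    p_adj: float = math.nan
    source: str = ""
    undefined: frozenset = frozenset()

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "undefined"}
        d["undefined"] = ";".join(sorted(self.undefined))
        return d


@dataclass
class SignalCriteria:
    """Positivity thresholds; the defaults are the standard ones."""

    prr_min: float = 2.0
    chi2_min: float = 4.0
    n_min: int = 3
    ror_lcl_min: float = 1.0
    ic025_min: float = 0.0
    rule: str = "any-of"


@dataclass
class SignalStatus:
    prr_positive: bool
    ror_positive: bool
    ic_positive: bool
    rule: str = "any-of"

    @property
    def overall(self) -> bool:
        flags = (self.prr_positive, self.ror_positive, self.ic_positive)
        return any(flags) if self.rule == "any-of" else all(flags)


# ---------------------------------------------------------------------------
# tables


def contingency(cases: CaseSet, store: ReportStore, drug: str) -> ContingencyTable:
    """2x2 table for one drug, counting unique deduplicated reports."""
    ps = store.primary_suspect_sets()
    exposed = ps.map(lambda s: drug in s).to_numpy()
    is_case = store.report_ids.isin(cases.case_ids)
    a = int((exposed & is_case).sum())
    b = int((exposed & ~is_case).sum())
    c = int((~exposed & is_case).sum())
    d = int((~exposed & ~is_case).sum())
    return ContingencyTable(a, b, c, d)


def contingency_panel(
    cases: CaseSet, store: ReportStore, drugs: Sequence[str] | None = None
) -> pd.DataFrame:
    """Vectorized per-drug 2x2 counts for every (or the given) primary-suspect
    drug. Returns a DataFrame indexed by drug with columns a, b, c, d."""
    pairs = store.drugs.loc[store.drugs["role"] == "primary-suspect", ["report_id", "drug_name"]]
    pairs = pairs.drop_duplicates()
    case_ids = pd.Index(list(cases.case_ids))
    n_cases = len(case_ids)
    n_total = len(store)
    pairs = pairs.assign(is_case=pairs["report_id"].isin(case_ids))
    g = pairs.groupby("drug_name")["is_case"]
    a = g.sum().astype(int)
    exposed = g.size().astype(int)
    panel = pd.DataFrame({"a": a, "b": exposed - a})
    panel["c"] = n_cases - panel["a"]
    panel["d"] = n_total - n_cases - panel["b"]
    if drugs is not None:
        panel = panel.reindex(drugs)
        absent = panel["a"].isna()
        if absent.any():  # drug absent from store: a = b = 0, flagged
            panel.loc[absent, ["a", "b"]] = 0
            panel.loc[absent, "c"] = n_cases
            panel.loc[absent, "d"] = n_total - n_cases
        panel = panel.astype(int)
        panel["absent"] = absent.to_numpy()
    else:
        panel["absent"] = False
    panel.index.name = "drug"
    return panel


# ---------------------------------------------------------------------------
# metrics


def compute_signal_metrics(
    t: ContingencyTable,
    drug: str = "",
    zero_correction: bool = False,
    yates: bool = False,
    source: str = "",
) -> SignalMetrics:
    """Compute the four-metric panel for one 2x2 table.

    With a zero cell and ``zero_correction`` off, ratio metrics are
    returned NaN and named in ``undefined``; the Fisher exact p is always
    defined. ``zero_correction`` applies Haldane-Anscombe +0.5 to all
    cells (ratio metrics only) when any cell is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    fisher_p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])

    has_zero = (a == 0) or (b == 0) or (c == 0) or (d == 0)
    undefined: set[str] = set()
    if has_zero and not zero_correction:
        nanpack = dict(
            ror=math.nan, ror_lcl=math.nan, ror_ucl=math.nan, prr=math.nan,
            rrr=math.nan, ic=math.nan, ic025=math.nan, ebgm=math.nan, ebgm05=math.nan,
        )
        undefined = {"ror", "prr", "rrr", "ic", "ebgm"}
        chi2 = _chi2(a, b, c, d, n, yates)
        return SignalMetrics(
            drug=drug, n_reports=a, chi2=chi2, fisher_p=fisher_p,
            source=source, undefined=frozenset(undefined), **nanpack,
        )

    fa, fb, fc, fd = (t.corrected() if (has_zero and zero_correction) else (a, b, c, d))
    fn = fa + fb + fc + fd
    se_log = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    ror = (fa * fd) / (fb * fc)
    ror_lcl = math.exp(math.log(ror) - Z95 * se_log)
    ror_ucl = math.exp(math.log(ror) + Z95 * se_log)
    prr = (fa / (fa + fb)) / (fc / (fc + fd))
    rrr = fa * fn / ((fa + fb) * (fa + fc))
    ic = math.log2(rrr)
    ic025 = ic - Z95 * se_log / math.log(2)
    ebgm = rrr
    ebgm05 = math.exp(math.log(ebgm) - Z90_ONESIDED * se_log)
    chi2 = _chi2(a, b, c, d, n, yates)

    return SignalMetrics(
        drug=drug, n_reports=a, ror=ror, ror_lcl=ror_lcl, ror_ucl=ror_ucl,
        prr=prr, chi2=chi2, rrr=rrr, ic=ic, ic025=ic025, ebgm=ebgm,
        ebgm05=ebgm05, fisher_p=fisher_p, source=source, undefined=frozenset(undefined),
    )


def _chi2(a: int, b: int, c: int, d: int, n: int, yates: bool) -> float:
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return math.nan
    num = abs(a * d - b * c)
    if yates:
        num = max(0.0, num - n / 2)
    return float(n * num * num / (r1 * r2 * c1 * c2))


def evaluate_signal(m: SignalMetrics, crit: SignalCriteria = SignalCriteria()) -> SignalStatus:
    prr_pos = (
        (m.n_reports >= crit.n_min)
        and not math.isnan(m.prr)
        and (m.prr >= crit.prr_min)
        and (m.chi2 >= crit.chi2_min)
    )
    ror_pos = (not math.isnan(m.ror_lcl)) and (m.ror_lcl > crit.ror_lcl_min)
    ic_pos = (not math.isnan(m.ic025)) and (m.ic025 > crit.ic025_min)
    return SignalStatus(prr_pos, ror_pos, ic_pos, rule=crit.rule)


def adjust_pvalues(pvals: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiplicity adjustment, order-preserving. ``bonferroni`` is
    min(1, m*p); ``BH`` is the Benjamini-Hochberg step-up."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = method.lower()
    if key == "bonferroni":
        return np.minimum(1.0, p * p.size)
    if key in ("bh", "fdr_bh", "fdr"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method: {method}")


# ---------------------------------------------------------------------------
# panel-level driver


def signal_panel(
    cases: CaseSet,
    store: ReportStore,
    drugs: Sequence[str] | None = None,
    criteria: SignalCriteria = SignalCriteria(),
    zero_correction: bool = False,
    source: str = "",
) -> pd.DataFrame:
    """Per-drug metric panel with Bonferroni and BH adjusted Fisher
    p-values and per-method positivity flags. One row per drug."""
    panel = contingency_panel(cases, store, drugs)
    rows = []
    for drug, row in panel.iterrows():
        t = ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
        m = compute_signal_metrics(t, drug=drug, zero_correction=zero_correction, source=source)
        status = evaluate_signal(m, criteria)
        rec = m.to_dict()
        rec.update(
            absent=bool(row["absent"]),
            prr_positive=status.prr_positive,
            ror_positive=status.ror_positive,
            ic_positive=status.ic_positive,
            overall_positive=status.overall,
        )
        rows.append(rec)
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = adjust_pvalues(df["fisher_p"].to_numpy(), "bonferroni")
        df["p_adj_bh"] = adjust_pvalues(df["fisher_p"].to_numpy(), "BH")
    else:
        df = pd.DataFrame(columns=[*SignalMetrics("", 0, *[math.nan] * 11).to_dict(), "p_adj_bh"])
    return df


def volcano_table(metrics: pd.DataFrame, p_col: str = "p_adj_bh") -> pd.DataFrame:
    """Volcano-plot export: (drug, log2 ROR, -log10 adjusted p, n).
    Zero p-values are floored at the smallest positive float before the
    log. Both axis layouts of the figure are just a transpose of these
    two columns."""
    if metrics.empty:
        return pd.DataFrame(columns=["drug", "log2_ror", "neg_log10_p_adj", "n_reports"])
    p = metrics[p_col].to_numpy(dtype=float)
    p = np.where(p <= 0.0, np.nextafter(0.0, 1.0), p)
    return pd.DataFrame(
        {
            "drug": metrics["drug"].to_numpy(),
            "log2_ror": np.log2(metrics["ror"].to_numpy(dtype=float)),
            "neg_log10_p_adj": -np.log10(p),
            "n_reports": metrics["n_reports"].to_numpy(dtype=int),
        }
    )


def compare_sources(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side two-source comparison of signal panels computed under
    identical criteria. A drug is corroborated when overall-positive in
    both sources; discordant drugs carry ``discordant=True``."""
    cols = [
        "drug", "n_reports", "ror", "ror_lcl", "ror_ucl", "prr", "chi2",
        "ic", "ic025", "ebgm", "ebgm05", "p_adj", "overall_positive",
    ]
    left = a[cols].add_suffix("_a").rename(columns={"drug_a": "drug"})
    right = b[cols].add_suffix("_b").rename(columns={"drug_b": "drug"})
    merged = left.merge(right, on="drug", how="outer")
    pos_a = merged["overall_positive_a"].fillna(False).astype(bool)
    pos_b = merged["overall_positive_b"].fillna(False).astype(bool)
    merged["corroborated"] = pos_a & pos_b
    merged["discordant"] = pos_a ^ pos_b
    return merged


def pt_composition(cases: CaseSet, class_map: Mapping[str, str]) -> pd.DataFrame:
    """Share of each matched preferred term among all matched-term
    occurrences within each drug class. Drugs missing from ``class_map``
    fall into class ``"other"``; shares sum to 1 per class."""
    records = []
    for rid in cases.case_ids:
        classes = {class_map.get(d, "other") for d in cases.suspect_drugs[rid]}
        for klass in classes:
            for term in cases.matched_terms[rid]:
                records.append({"drug_class": klass, "pt": str(term)})
    if not records:
        return pd.DataFrame(columns=["drug_class", "pt", "count", "share"])
    df = pd.DataFrame(records)
    counts = df.groupby(["drug_class", "pt"]).size().rename("count").reset_index()
    totals = counts.groupby("drug_class")["count"].transform("sum")
    counts["share"] = counts["count"] / totals
    return counts
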