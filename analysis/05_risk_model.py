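"""Risk-factor cascade: univariate screen -> LASSO -> logistic forest.

Filters the disproportionality panel (n >= 3 reports, ROR 95% lower bound
> 1, Bonferroni-adjusted p < 0.01), selects variables by 10-fold
cross-validated L1 logistic regression, and fits the final multivariable
logistic model whose odds-ratio forest is the study's risk-factor table.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pvep import faers_ingest as fi  # noqa: E402
from pvep import risk_regression as rr  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    store = fi.ReportStore.read_csv(RESULTS / "store")
    cases = fi.extract_cases(store)
    panel = pd.read_csv(RESULTS / "signal_metrics.csv")

    candidates, reasons = rr.univariate_screen(panel, rr.ScreenThresholds(p_adj_max=0.01))
    reasons.to_csv(RESULTS / "candidates.csv", index=False)
    print(f"univariate screen: {len(candidates)} of {len(panel)} drugs retained: {candidates}")
    if not candidates:
        print("nothing to model; stopping")
        return

    mm = rr.build_matrix(store, cases, candidates, missing="indicator")
    lasso = rr.lasso_select(mm, folds=10, seed=42)
    lasso.coef_path.reset_index().to_csv(RESULTS / "lasso_path.csv", index=False)
    pd.DataFrame(
        {"lambda": lasso.lambdas, "cv_mse": lasso.cv_mean, "cv_se": lasso.cv_se}
    ).to_csv(RESULTS / "cv_curve.csv", index=False)
    print(f"LASSO at lambda={lasso.lambda_selected:.2e} keeps {len(lasso.selected)} variables")

    terms = rr.logistic_fit(mm, list(lasso.selected))
    forest = rr.forest_table(terms)
    forest.to_csv(RESULTS / "forest.csv", index=False)
    print("final multivariable logistic model (OR, 95% CI, Bonferroni p):")
    for _, row in forest.iterrows():
        mark = " *" if row["significant"] else ""
        print(f"  {row['variable']}: OR {row['odds_ratio']:.2f} "
              f"({row['or_lcl']:.2f}-{row['or_ucl']:.2f}), p_adj {row['p_adj']:.2g}{mark}")


if __name__ == "__main__":
    main()
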