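"""Per-drug disproportionality panel, volcano export, two-source check.

Computes ROR/PRR/IC/EBGM with positivity flags and adjusted p-values for
every primary-suspect drug, exports the volcano coordinates, and runs the
two-source corroboration comparison against an independently seeded second
cohort (standing in for a second pharmacovigilance database).
"""

from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pvep import disproportionality as dp  # noqa: E402
from pvep import faers_ingest as fi  # noqa: E402
from pvep import synthetic_faers as sf  # noqa: E402

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    store = fi.ReportStore.read_csv(RESULTS / "store")
    import pandas as pd

    cases_df = pd.read_csv(RESULTS / "cases.csv")
    case_ids = frozenset(cases_df["report_id"])
    cases = fi.extract_cases(store)  # rebuild matched terms/suspects
    assert cases.case_ids == case_ids

    panel = dp.signal_panel(cases, store, source="primary")
    panel.to_csv(RESULTS / "signal_metrics.csv", index=False)
    dp.volcano_table(panel).to_csv(RESULTS / "volcano.csv", index=False)
    pos = panel[panel["overall_positive"]].sort_values("ror", ascending=False)
    print(f"{len(panel)} drugs tabulated; {len(pos)} signal-positive:")
    for _, row in pos.head(8).iterrows():
        print(f"  {row['drug']}: n={row['n_reports']} ROR={row['ror']:.2f} "
              f"({row['ror_lcl']:.2f}-{row['ror_ucl']:.2f}) IC025={row['ic025']:.2f}")

    # second source: same planted world, independent seed
    sim_mod = import_module("01_simulate_cohort")
    cfg2 = sim_mod.study_world(n_reports=100_000, seed=20_002)
    store2, _, _ = sf.generate_store(cfg2)
    store2, _ = fi.deduplicate(store2)
    cases2 = fi.extract_cases(store2)
    panel2 = dp.signal_panel(cases2, store2, source="second-source")
    comp = dp.compare_sources(panel, panel2)
    comp.to_csv(RESULTS / "comparison.csv", index=False)
    print(f"corroborated signals: {int(comp['corroborated'].sum())}; "
          f"discordant: {int(comp['discordant'].sum())}")

    # PT composition by drug class
    class_map = {
        "DAPTO_LIKE": "antibacterial",
        "ICI_LIKE_A": "checkpoint inhibitor", "ICI_LIKE_B": "checkpoint inhibitor",
        "WEAROUT_LIKE": "targeted agent",
    }
    comp_pt = dp.pt_composition(cases, class_map)
    comp_pt.to_csv(RESULTS / "pt_composition.csv", index=False)
    print(f"PT-composition rows: {len(comp_pt)} across {comp_pt['drug_class'].nunique()} classes")


if __name__ == "__main__":
    main()
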