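"""Ingest the cohort, deduplicate, extract SMQ cases, summarize demographics.

Reads the $-delimited tables written by 01_simulate_cohort.py, applies the
two-stage deduplication (case-id rule, then the complete-key demographic
rule), identifies eosinophilic-pneumonia cases (SMQ term hit + primary
suspect drug), and writes the normalized store, case list, audits and the
Table-1-style demographic summary under results/.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pvep import faers_ingest as fi  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim_dir = RESULTS / "sim"
    paths = {t: sim_dir / f"{t}.txt" for t in ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")}
    store, parse_audit = fi.parse_tables(paths)
    print(f"parsed {len(store)} reports "
          f"({sum(parse_audit.rows_read.values())} raw rows across {len(parse_audit.rows_read)} tables)")

    store, dedup_audit = fi.deduplicate(store)
    print(f"dedup: {dedup_audit.n_in} -> {dedup_audit.n_out} "
          f"(case-id rule removed {dedup_audit.removed_case_id_rule}, "
          f"demographic rule removed {dedup_audit.removed_demographic_rule})")

    cases = fi.extract_cases(store)
    print(f"{len(cases)} cases match the eosinophilic-pneumonia term set with a primary suspect")

    store.write_csv(RESULTS / "store")
    cases.write_csv(RESULTS / "cases.csv")
    (RESULTS / "audit.json").write_text(
        json.dumps({"parse": parse_audit.__dict__, "dedup": dedup_audit.__dict__}, indent=2)
    )
    summary = fi.demographic_summary(cases, store)
    summary.to_csv(RESULTS / "demographics.csv", index=False)
    sex = summary[summary["characteristic"] == "sex"].set_index("category")
    print("case sex split: " + ", ".join(f"{k} {sex.loc[k, 'case_pct']}%" for k in sex.index))


if __name__ == "__main__":
    main()
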