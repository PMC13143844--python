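"""Generate the study cohort: a synthetic spontaneous-report quarter set.

Plants a study-like world — a rare antibacterial with a very strong
reporting signal and fast onset, two common checkpoint-inhibitor-like
drugs with moderate signals and slow onset, one wear-out-profile drug,
and null comparators — then writes the seven $-delimited tables plus the
ground-truth table under results/sim/.

Run:  python analysis/01_simulate_cohort.py [--seed 1] [--n 100000]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pvep import synthetic_faers as sf  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def study_world(n_reports: int, seed: int) -> sf.SimConfig:
    drugs = [
        sf.DrugSpec("DAPTO_LIKE", 0.004, 15.0, tto_shape=0.9, tto_scale=25.0),
        sf.DrugSpec("ICI_LIKE_A", 0.02, 2.1, tto_shape=0.77, tto_scale=130.0),
        sf.DrugSpec("ICI_LIKE_B", 0.015, 2.2, tto_shape=0.76, tto_scale=125.0),
        sf.DrugSpec("WEAROUT_LIKE", 0.01, 5.2, tto_shape=1.14, tto_scale=82.0),
        sf.DrugSpec("NULL_A", 0.02, 1.0),
        sf.DrugSpec("NULL_B", 0.02, 1.0),
    ]
    return sf.SimConfig(
        n_reports=n_reports,
        drugs=drugs,
        background_event_rate=0.01,
        missingness=sf.Missingness(age=0.2, weight=0.3, start_date=0.4, event_date=0.4),
        duplicate_rate=0.10,
        seed=seed,
    )


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=100_000)
    args = parser.parse_args()

    cfg = study_world(args.n, args.seed)
    tables, truth = sf.generate(cfg)
    out = RESULTS / "sim"
    paths = sf.write_dialect(tables, out)
    truth.to_csv(out / "truth.csv", index=False)
    n_rows = {k: len(v) for k, v in tables.items()}
    print(f"wrote {len(paths)} tables to {out}")
    print(f"rows per table: {n_rows}")
    print(f"planted drugs: {list(truth['drug'])}")


if __name__ == "__main__":
    main()
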