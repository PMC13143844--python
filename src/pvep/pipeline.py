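"""End-to-end orchestration: ingest (or simulate) -> dedup -> case
extraction -> disproportionality panel -> TTO/Weibull -> risk cascade,
with one global seed, per-stage derived seeds, structured JSON logging and
a manifest of emitted artifacts with checksums and cascade counts."""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import disproportionality as dp
from . import faers_ingest as fi
from . import risk_regression as rr
from . import synthetic_faers as sf
from . import tto_survival as tto


@dataclass
class RunConfig:
    """One pipeline run. Exactly one input mode: a synthetic SimConfig or a
    directory of FAERS-dialect tables."""

    out_dir: str
    sim: sf.SimConfig | None = None
    table_paths: dict | None = None
    smq: fi.SmqTermSet = field(default_factory=fi.SmqTermSet)
    criteria: dp.SignalCriteria = field(default_factory=dp.SignalCriteria)
    screen: rr.ScreenThresholds = field(default_factory=lambda: rr.ScreenThresholds(p_adj_max=0.01))
    adjust: str = "bonferroni"
    folds: int = 10
    min_tto_n: int = 3
    failure_rule: str = "point"
    covariate_missing: str = "complete-case"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.table_paths is None):
            raise ValueError("exactly one input mode: sim or table_paths")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stage-name hashed) so
    stages are individually reproducible."""
    return (seed + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(fh, stage: str, **kv) -> None:
    fh.write(json.dumps({"stage": stage, "t": round(time.time(), 3), **kv}) + "\n")
    fh.flush()


def run(config: RunConfig) -> dict:
    """Execute all stages in order and return the manifest. Any stage
    failure aborts with the stage name attached; identical config + seed
    gives identical artifact checksums."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "counts": {}, "artifacts": {}}
    log_fh = (out / "run_log.jsonl").open("w")

    def save(name: str, df: pd.DataFrame) -> Path:
        p = out / name
        df.to_csv(p, index=False)
        (out / f"{name}.dtypes.json").write_text(
            json.dumps({c: str(t) for c, t in df.dtypes.items()}, indent=2)
        )
        manifest["artifacts"][name] = _sha256(p)
        return p

    stage = "init"
    try:
        # ---- ingest -----------------------------------------------------
        stage = "ingest"
        if config.sim is not None:
            sim = sf.SimConfig(**{**config.sim.__dict__, "seed": stage_seed(config.seed, "simulate")})
            tables, truth = sf.generate(sim)
            sf.write_dialect(tables, out / "tables")
            store, parse_audit = fi.store_from_frames(tables)
            if len(truth):
                save("truth.csv", truth)
        else:
            store, parse_audit = fi.parse_tables(config.table_paths)
        manifest["counts"]["reports_in"] = len(store)
        _log(log_fh, stage, reports=len(store))

        # ---- dedup ------------------------------------------------------
        stage = "deduplicate"
        store, dedup_audit = fi.deduplicate(store)
        manifest["counts"]["reports_after_dedup"] = len(store)
        (out / "audit.json").write_text(
            json.dumps({"parse": parse_audit.__dict__, "dedup": dedup_audit.__dict__}, indent=2)
        )
        _log(log_fh, stage, **dedup_audit.__dict__)

        # ---- cases ------------------------------------------------------
        stage = "extract_cases"
        cases = fi.extract_cases(store, config.smq)
        manifest["counts"]["n_cases"] = len(cases)
        cases.write_csv(out / "cases.csv")
        manifest["artifacts"]["cases.csv"] = _sha256(out / "cases.csv")
        save("demographics.csv", fi.demographic_summary(cases, store))
        _log(log_fh, stage, n_cases=len(cases))

        # ---- signals ----------------------------------------------------
        stage = "signals"
        panel = dp.signal_panel(cases, store, criteria=config.criteria)
        manifest["counts"]["n_suspect_drugs"] = len(panel)
        manifest["counts"]["n_signal_positive"] = int(panel["overall_positive"].sum()) if len(panel) else 0
        save("signal_metrics.csv", panel)
        save("volcano.csv", dp.volcano_table(panel))
        _log(log_fh, stage, n_drugs=len(panel))

        # ---- tto --------------------------------------------------------
        stage = "tto"
        records, audit = tto.compute_tto(cases, store, per="drug")
        save("tto_records.csv", records)
        (out / "exclusion_audit.json").write_text(json.dumps(audit.to_dict(), indent=2))
        fits = tto.weibull_fit_table(records, min_n=config.min_tto_n, rule=config.failure_rule)
        save("weibull_fits.csv", fits)
        by_case, _ = tto.compute_tto(cases, store, per="case")
        if len(by_case):
            curves, _ = tto.km_curve(by_case["tto_days"], by_case["sex"])
            save("km_curves.csv", curves)
            kw_rows = []
            for label in ("sex", "age_band", "weight_band"):
                groups = [g["tto_days"].to_numpy() for _, g in by_case.groupby(label) if len(g)]
                if len(groups) >= 2:
                    h, p = tto.kruskal_wallis(*groups)
                    kw_rows.append({"grouping": label, "H": h, "p": p})
            save("kw_tests.csv", pd.DataFrame(kw_rows, columns=["grouping", "H", "p"]))
        _log(log_fh, stage, n_records=len(records), excluded_pct=audit.exclusion_percent)

        # ---- risk cascade ------------------------------------------------
        stage = "riskmodel"
        candidates, reasons = rr.univariate_screen(panel, config.screen, p_col="p_adj")
        save("candidates.csv", reasons)
        manifest["counts"]["n_candidates_univariate"] = len(candidates)
        mm = None
        if candidates:
            mm = rr.build_matrix(store, cases, candidates, missing=config.covariate_missing)
            if mm.y.nunique() < 2:
                # every retained row is one class (e.g. complete-case wiped
                # out the cases): a degenerate outcome, not a failure
                manifest["riskmodel_skipped"] = "outcome single-class after missing-data policy"
                mm = None
        if mm is not None:
            lasso = rr.lasso_select(mm, folds=config.folds, seed=stage_seed(config.seed, "lasso"))
            save("lasso_path.csv", lasso.coef_path.reset_index())
            save("cv_curve.csv", pd.DataFrame(
                {"lambda": lasso.lambdas, "cv_mse": lasso.cv_mean, "cv_se": lasso.cv_se}
            ))
            selected_drugs = [v for v in lasso.selected if v in candidates]
            manifest["counts"]["n_selected_lasso"] = len(selected_drugs)
            final_vars = list(lasso.selected)
            if final_vars:
                terms = rr.logistic_fit(mm, final_vars)
                save("forest.csv", rr.forest_table(terms))
                manifest["counts"]["n_terms_final"] = len(terms)
        else:
            manifest["counts"]["n_selected_lasso"] = 0
        _log(log_fh, stage, n_candidates=len(candidates))

    except Exception as exc:  # attach the failing stage, keep partial manifest
        log_fh.close()
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log_fh.close()
    manifest["config_hash"] = hashlib.sha256(
        repr((config.seed, sorted(manifest["counts"].items()))).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (synthetic mode uses a nested
    ``sim`` mapping; ingest mode a ``tables`` mapping of table -> path)."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = None
    if "sim" in raw:
        s = dict(raw["sim"])
        drugs = [sf.DrugSpec(**d) for d in s.pop("drugs", [])]
        sim = sf.SimConfig(drugs=drugs, **s)
    return RunConfig(
        out_dir=raw["out_dir"],
        sim=sim,
        table_paths=raw.get("tables"),
        seed=int(raw.get("seed", 0)),
        adjust=raw.get("adjust", "bonferroni"),
        folds=int(raw.get("folds", 10)),
    )
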