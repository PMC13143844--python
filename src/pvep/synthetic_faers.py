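"""Synthetic FAERS-dialect spontaneous reports with planted ground truth.

Emulates the seven quarterly ASCII tables (DEMO, DRUG, REAC, OUTC, THER,
INDI, RPSR) with a known generative model so every downstream stage —
deduplication, SMQ case extraction, disproportionality, time-to-onset,
and the regression cascade — can be validated against planted truth.

The generative model, per report:

* demographics from configurable sex/age/weight/country mixtures;
* one primary-suspect drug drawn from the configured :class:`DrugSpec`
  list (marginal prevalences) or from a background pool;
* the target (SMQ) event assigned Bernoulli with probability ``p`` such
  that odds(event | drug) / odds(event | background) equals the drug's
  planted reporting-odds multiplier;
* if the target event fires, time-to-onset drawn from the drug's planted
  Weibull(shape, scale) and ``event_date = start_date + TTO``;
* MCAR missingness per field, and a configurable fraction of reports
  cloned as same-case duplicates with a later receipt date.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations


from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .faers_ingest import DEFAULT_EP_TERMS, ParseAudit, ReportStore, store_from_frames

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

#: non-target preferred terms assigned to background reports
BACKGROUND_PTS: tuple[tuple[int, str], ...] = (
    (10028813, "Nausea"),
    (10019211, "Headache"),
    (10012735, "Diarrhoea"),
    (10016256, "Fatigue"),
    (10037660, "Pyrexia"),
    (10047700, "Vomiting"),
    (10013968, "Dyspnoea"),
    (10037844, "Rash"),
    (10003239, "Arthralgia"),
    (10061428, "Drug ineffective"),
)

#: how target-event PTs are apportioned when the event fires
TARGET_PT_WEIGHTS: tuple[tuple[int, str, float], ...] = (
    (10035742, "Pneumonitis", 0.60),
    (10014962, "Eosinophilic pneumonia", 0.25),
    (10037382, "Pulmonary eosinophilia", 0.15),
)


@dataclass
class DrugSpec:
    """One simulated drug: marginal prevalence as the report's primary
    suspect, planted reporting-odds multiplier for the target event, and a
    planted Weibull onset law (shape beta, scale alpha in days)."""

    name: str
    prevalence: float
    ep_odds_multiplier: float = 1.0
    tto_shape: float = 1.0
    tto_scale: float = 60.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"{self.name}: prevalence must be in (0,1)")
        if self.ep_odds_multiplier <= 0:
            raise ValueError(f"{self.name}: ep_odds_multiplier must be > 0")
        if self.tto_shape <= 0 or self.tto_scale <= 0:
            raise ValueError(f"{self.name}: Weibull parameters must be > 0")


@dataclass
class Demographics:
    """Marginal demographic mixtures; defaults follow the all-report
    column of a large spontaneous-report cohort (slightly more female than
    male, ~15% unknown sex, age mass concentrated in 45-74)."""

    sex_probs: dict = field(default_factory=lambda: {"M": 0.355, "F": 0.493, "UNK": 0.152})
    age_band_probs: dict = field(
        default_factory=lambda: {
            "(0,18)": 0.04, "(18,45)": 0.14, "(45,65)": 0.37, "(65,75)": 0.26, "(75,95)": 0.19,
        }
    )
    weight_mean: float = 75.0
    weight_sd: float = 16.0
    country_probs: dict = field(
        default_factory=lambda: {
            "US": 0.41, "JP": 0.08, "CA": 0.08, "DE": 0.05, "GB": 0.05,
            "FR": 0.06, "ES": 0.02, "IT": 0.04, "CN": 0.03, "OTHER": 0.18,
        }
    )


@dataclass
class Missingness:
    """Per-field MCAR missing probabilities. Defaults emulate heavy
    real-world incompleteness: ~72% missing weight, ~35% missing age, and
    date missingness that excludes roughly 84% of cases from day-level
    onset arithmetic. ``mar_dates`` switches start/event-date missingness
    to a MAR mode where older reports are more likely to lack dates."""

    age: float = 0.35
    weight: float = 0.72
    start_date: float = 0.60
    event_date: float = 0.60
    rept_dt: float = 0.50
    mar_dates: bool = False

    def __post_init__(self) -> None:
        for f, v in asdict(self).items():
            if f != "mar_dates" and not (0.0 <= v <= 1.0):
                raise ValueError(f"missingness.{f} must be in [0,1]")


@dataclass
class SimConfig:
    n_reports: int = 20_000
    drugs: list = field(default_factory=list)
    background_event_rate: float = 0.01
    n_background_drugs: int = 20
    background_tto_shape: float = 1.0
    background_tto_scale: float = 60.0
    demographics: Demographics = field(default_factory=Demographics)
    missingness: Missingness = field(default_factory=Missingness)
    duplicate_rate: float = 0.10
    window_start: str = "2014-01-01"
    window_end: str = "2025-03-31"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not (0.0 < self.background_event_rate < 1.0):
            raise ValueError("background_event_rate must be in (0,1)")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError("duplicate_rate must be in [0,1)")
        total_prev = sum(d.prevalence for d in self.drugs)
        if total_prev > 1.0 + 1e-12:
            raise ValueError("drug marginal prevalences must sum to <= 1")


def _event_probability(multiplier: float, background_rate: float, name: str) -> float:
    """Per-report event probability giving the planted odds ratio vs the
    background stratum: p = m*odds0 / (1 + m*odds0)."""
    odds = multiplier * background_rate / (1.0 - background_rate)
    p = odds / (1.0 + odds)
    if not (p < 1.0):
        raise ValueError(f"infeasible event probability for drug {name!r} (p >= 1)")
    return p


def _sample_bands(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    return np.asarray(labels, dtype=object)[idx]


def _fmt_dates(days: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Days-since-epoch (float, may be nan) -> YYYYMMDD strings with ''
    for missing."""
    base = np.datetime64("1970-01-01")
    out = np.full(days.shape, "", dtype=object)
    ok = ~missing & ~np.isnan(days)
    if ok.any():
        dates = base + days[ok].astype("int64").astype("timedelta64[D]")
        out[ok] = np.char.replace(np.datetime_as_string(dates, unit="D"), "-", "")
    return out


def generate(config: SimConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate the seven FAERS-dialect tables and a planted truth table.

    Returns ``(tables, truth)`` where ``tables`` maps table name to a
    string-typed DataFrame ready for :func:`write_dialect`, and ``truth``
    holds one row per configured drug (prevalence, planted odds
    multiplier, planted Weibull shape/scale).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    demo_cfg = config.demographics
    miss = config.missingness

    # --- drug assignment -------------------------------------------------
    spec_names = [d.name for d in config.drugs]
    bg_names = [f"BACKGROUND_{i:02d}" for i in range(1, config.n_background_drugs + 1)]
    all_names = spec_names + bg_names
    prev = np.asarray([d.prevalence for d in config.drugs], dtype=float)
    remainder = 1.0 - prev.sum()
    bg_p = np.full(len(bg_names), remainder / max(len(bg_names), 1))
    probs = np.concatenate([prev, bg_p]) if len(bg_names) else prev
    drug_idx = rng.choice(len(all_names), size=n, p=probs / probs.sum())
    drug_names = np.asarray(all_names, dtype=object)[drug_idx]

    # --- event assignment -------------------------------------------------
    q0 = config.background_event_rate
    p_by_drug = np.full(len(all_names), q0)
    for j, d in enumerate(config.drugs):
        p_by_drug[j] = _event_probability(d.ep_odds_multiplier, q0, d.name)
    is_case = rng.random(n) < p_by_drug[drug_idx]

    # --- time to onset ----------------------------------------------------
    shape = np.full(len(all_names), config.background_tto_shape)
    scale = np.full(len(all_names), config.background_tto_scale)
    for j, d in enumerate(config.drugs):
        shape[j] = d.tto_shape
        scale[j] = d.tto_scale
    tto = scale[drug_idx] * rng.weibull(shape[drug_idx], size=n)
    tto = np.maximum(1, np.ceil(tto)).astype(np.int64)  # whole days >= 1

    # --- dates ------------------------------------------------------------
    w0 = np.datetime64(config.window_start).astype("datetime64[D]").astype(np.int64)
    w1 = np.datetime64(config.window_end).astype("datetime64[D]").astype(np.int64)
    start = rng.integers(w0, w1 + 1, size=n)
    event = start + tto
    lag = rng.integers(0, 91, size=n)
    receipt = event + lag

    # --- demographics -----------------------------------------------------
    sex = _sample_bands(rng, demo_cfg.sex_probs, n)
    age_band = _sample_bands(rng, demo_cfg.age_band_probs, n)
    lo = np.asarray([float(b.strip("()").split(",")[0]) for b in age_band])
    hi = np.asarray([float(b.strip("()").split(",")[1]) for b in age_band])
    age = np.round(lo + rng.random(n) * (hi - lo), 0)
    weight = np.round(np.clip(rng.normal(demo_cfg.weight_mean, demo_cfg.weight_sd, n), 30, None), 1)
    country = _sample_bands(rng, demo_cfg.country_probs, n)

    # --- missingness masks -------------------------------------------------
    age_miss = rng.random(n) < miss.age
    wt_miss = rng.random(n) < miss.weight
    if miss.mar_dates:
        # older reports lack dates more often: scale missingness linearly
        # from 2x at window start to 0.5x at window end (clipped to [0,1])
        frac = (start - w0) / max(w1 - w0, 1)
        pm_start = np.clip(miss.start_date * (2.0 - 1.5 * frac), 0, 1)
        pm_event = np.clip(miss.event_date * (2.0 - 1.5 * frac), 0, 1)
        start_miss = rng.random(n) < pm_start
        event_miss = rng.random(n) < pm_event
    else:
        start_miss = rng.random(n) < miss.start_date
        event_miss = rng.random(n) < miss.event_date
    rept_miss = rng.random(n) < miss.rept_dt

    # --- identifiers and duplicates ----------------------------------------
    base_id = 100_000_001
    report_id = np.arange(base_id, base_id + n, dtype=np.int64)
    case_id = report_id.copy()

    n_dup = int(round(config.duplicate_rate * n))
    dup_src = rng.choice(n, size=n_dup, replace=False) if n_dup else np.empty(0, dtype=int)
    dup_report_id = np.arange(900_000_001, 900_000_001 + n_dup, dtype=np.int64)
    dup_receipt = receipt[dup_src] + rng.integers(30, 181, size=n_dup)

    # --- DEMO ---------------------------------------------------------------
    def demo_frame(rid, cid, rcpt, idx, rcpt_missing) -> pd.DataFrame:
        m = len(rid)
        return pd.DataFrame(
            {
                "primaryid": rid.astype(str),
                "caseid": cid.astype(str),
                "fda_dt": _fmt_dates(rcpt.astype(float), np.zeros(m, bool)),
                "event_dt": _fmt_dates(event[idx].astype(float), event_miss[idx]),
                "rept_dt": _fmt_dates(receipt[idx].astype(float), rcpt_missing),
                "sex": np.where(sex[idx] == "UNK", "", sex[idx]),
                "age": np.where(age_miss[idx], "", age[idx].astype(np.int64).astype(str)),
                "age_cod": np.where(age_miss[idx], "", "YR"),
                "wt": np.where(wt_miss[idx], "", weight[idx].astype(str)),
                "wt_cod": np.where(wt_miss[idx], "", "KG"),
                "occr_country": country[idx],
            }
        )

    idx_all = np.arange(n)
    demo = demo_frame(report_id, case_id, receipt, idx_all, rept_miss)
    demo_dup = demo_frame(dup_report_id, case_id[dup_src], dup_receipt, dup_src, rept_miss[dup_src])
    demo_out = pd.concat([demo, demo_dup], ignore_index=True)

    # --- child tables --------------------------------------------------------
    def ids_for(idx: np.ndarray, rid: np.ndarray) -> np.ndarray:
        return rid.astype(str)

    all_rid = np.concatenate([report_id, dup_report_id])
    all_idx = np.concatenate([idx_all, dup_src])

    drug_out = pd.DataFrame(
        {
            "primaryid": ids_for(all_idx, all_rid),
            "drug_seq": "1",
            "role_cod": "PS",
            "drugname": drug_names[all_idx],
        }
    )

    # REAC: one target PT for cases, one background PT otherwise
    t_codes = np.asarray([c for c, _, _ in TARGET_PT_WEIGHTS])
    t_names = np.asarray([s for _, s, _ in TARGET_PT_WEIGHTS], dtype=object)
    t_w = np.asarray([w for _, _, w in TARGET_PT_WEIGHTS])
    b_codes = np.asarray([c for c, _ in BACKGROUND_PTS])
    b_names = np.asarray([s for _, s in BACKGROUND_PTS], dtype=object)
    pt_code = np.empty(n, dtype=np.int64)
    pt_name = np.empty(n, dtype=object)
    n_case = int(is_case.sum())
    ci = rng.choice(len(t_codes), size=n_case, p=t_w / t_w.sum())
    bi = rng.choice(len(b_codes), size=n - n_case)
    pt_code[is_case], pt_name[is_case] = t_codes[ci], t_names[ci]
    pt_code[~is_case], pt_name[~is_case] = b_codes[bi], b_names[bi]

    reac_out = pd.DataFrame(
        {
            "primaryid": ids_for(all_idx, all_rid),
            "pt": pt_name[all_idx],
            "pt_code": pt_code[all_idx].astype(str),
        }
    )

    # OUTC: categorical outcome, some reports have none
    outc_labels = np.asarray(["HO", "OT", "DE", "LT", "DS", "DC", "RI", ""], dtype=object)
    outc_probs = np.asarray([0.25, 0.30, 0.10, 0.04, 0.04, 0.01, 0.005, 0.255])
    outc = outc_labels[rng.choice(len(outc_labels), size=n, p=outc_probs / outc_probs.sum())]
    outc_all = outc[all_idx]
    keep_outc = outc_all != ""
    outc_out = pd.DataFrame(
        {"primaryid": ids_for(all_idx, all_rid)[keep_outc], "outc_cod": outc_all[keep_outc]}
    )

    ther_out = pd.DataFrame(
        {
            "primaryid": ids_for(all_idx, all_rid),
            "dsg_drug_seq": "1",
            "start_dt": _fmt_dates(start[all_idx].astype(float), start_miss[all_idx]),
        }
    )

    indi_out = pd.DataFrame(
        {
            "primaryid": ids_for(all_idx, all_rid),
            "indi_drug_seq": "1",
            "indi_pt": "Product used for unknown indication",
        }
    )
    rpsr_codes = np.asarray(["FGN", "HP", "CSM", "OTH"], dtype=object)
    rpsr = rpsr_codes[rng.choice(4, size=n, p=[0.2, 0.5, 0.2, 0.1])]
    rpsr_out = pd.DataFrame({"primaryid": ids_for(all_idx, all_rid), "rpsr_cod": rpsr[all_idx]})

    tables = {
        "DEMO": demo_out,
        "DRUG": drug_out,
        "REAC": reac_out,
        "OUTC": outc_out,
        "THER": ther_out,
        "INDI": indi_out,
        "RPSR": rpsr_out,
    }
    truth = pd.DataFrame(
        [
            {
                "drug": d.name,
                "prevalence": d.prevalence,
                "ep_odds_multiplier": d.ep_odds_multiplier,
                "tto_shape": d.tto_shape,
                "tto_scale": d.tto_scale,
            }
            for d in config.drugs
        ],
        columns=["drug", "prevalence", "ep_odds_multiplier", "tto_shape", "tto_scale"],
    )
    return tables, truth


def sample_onsets(spec: DrugSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n planted whole-day onset times for one drug (the same law
    `generate` uses)."""
    t = spec.tto_scale * rng.weibull(spec.tto_shape, size=n)
    return np.maximum(1, np.ceil(t)).astype(np.int64)


def write_dialect(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path, sep: str = "$"
) -> dict[str, Path]:
    """Write the generated tables as ``$``-delimited ASCII files that
    :func:`pvep.faers_ingest.parse_tables` reads back with zero losses."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / f"{name}.txt"
        df.to_csv(p, sep=sep, index=False)
        paths[name] = p
    return paths


def generate_store(config: SimConfig) -> tuple[ReportStore, pd.DataFrame, ParseAudit]:
    """Generate and parse in memory (no disk round trip): returns the
    normalized store, the truth table, and the parse audit."""
    tables, truth = generate(config)
    store, audit = store_from_frames(tables)
    return store, truth, audit
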