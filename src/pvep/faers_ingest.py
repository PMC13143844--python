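"""Ingestion of FAERS-dialect spontaneous-report tables.

FAERS quarters ship as seven ``$``-delimited ASCII tables (DEMO, DRUG, REAC,
OUTC, THER, INDI, RPSR). This module parses them into a normalized
:class:`ReportStore`, applies the FDA deduplication rules (latest receipt
date per case, largest report id on ties, then a demographic secondary key),
extracts outcome-event cases through a Standardized MedDRA Query (SMQ) term
set, and produces Table-1-style demographic summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# constants / vocabularies

ROLE_CODES = {
    "PS": "primary-suspect",
    "SS": "secondary-suspect",
    "C": "concomitant",
    "I": "interacting",
}

OUTCOME_CODES = {
    "HO": "hospitalization",
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
    "DC": "discontinued",
    "RI": "required-intervention",
    "OT": "other",
}

SEX_CODES = {"M": "male", "F": "female"}

#: default eosinophilic-pneumonia SMQ term table (SMQ 20000159). The SMQ
#: nominally spans 15 preferred terms; the nine below are the publicly
#: printed ones and the shipped default — the table is user-extendable.
DEFAULT_EP_SMQ_ID = "20000159"
DEFAULT_EP_TERMS: tuple[tuple[int, str], ...] = (
    (10014962, "Eosinophilic pneumonia"),
    (10052832, "Eosinophilic pneumonia acute"),
    (10052833, "Eosinophilic pneumonia chronic"),
    (10024794, "Loeffler's syndrome"),
    (10035742, "Pneumonitis"),
    (10037382, "Pulmonary eosinophilia"),
    (10048643, "Hypereosinophilic syndrome"),
    (10078117, "Eosinophilic granulomatosis with polyangiitis"),
    (10080148, "Eosinophilic pleural effusion"),
)

#: salt/ester suffixes stripped during drug-name normalization (editable).
DEFAULT_SALT_SUFFIXES: tuple[str, ...] = (
    " SODIUM", " HYDROCHLORIDE", " HCL", " SULFATE", " SULPHATE",
    " MESYLATE", " MESILATE", " TARTRATE", " BITARTRATE", " CITRATE",
    " MALEATE", " FUMARATE", " PHOSPHATE", " ACETATE", " BESYLATE",
    " CALCIUM", " POTASSIUM", " DIHYDRATE", " MONOHYDRATE",
)

LB_TO_KG = 0.45359237

MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")
OPTIONAL_TABLES = ("OUTC", "THER", "INDI", "RPSR")

_CANONICAL_COLUMNS: dict[str, dict[str, tuple[str, ...]]] = {
    # canonical name -> accepted aliases (matched case-insensitively)
    "DEMO": {
        "primaryid": ("primaryid", "primary_id", "isr"),
        "caseid": ("caseid", "case_id", "case"),
        "fda_dt": ("fda_dt",),
        "event_dt": ("event_dt",),
        "rept_dt": ("rept_dt",),
        "sex": ("sex", "gndr_cod"),
        "age": ("age",),
        "age_cod": ("age_cod",),
        "wt": ("wt",),
        "wt_cod": ("wt_cod",),
        "occr_country": ("occr_country", "reporter_country"),
    },
    "DRUG": {
        "primaryid": ("primaryid", "primary_id", "isr"),
        "drug_seq": ("drug_seq", "dsg_drug_seq"),
        "role_cod": ("role_cod",),
        "drugname": ("drugname", "drug_name"),
    },
    "REAC": {
        "primaryid": ("primaryid", "primary_id", "isr"),
        "pt": ("pt", "pt_name"),
        "pt_code": ("pt_code", "pt_cod"),
    },
    "OUTC": {
        "primaryid": ("primaryid", "primary_id", "isr"),
        "outc_cod": ("outc_cod", "outc_code"),
    },
    "THER": {
        "primaryid": ("primaryid", "primary_id", "isr"),
        "dsg_drug_seq": ("dsg_drug_seq", "drug_seq"),
        "start_dt": ("start_dt",),
    },
    "INDI": {
        "primaryid": ("primaryid", "primary_id", "isr"),
        "indi_drug_seq": ("indi_drug_seq", "drug_seq"),
        "indi_pt": ("indi_pt",),
    },
    "RPSR": {
        "primaryid": ("primaryid", "primary_id", "isr"),
        "rpsr_cod": ("rpsr_cod",),
    },
}

_OPTIONAL_COLUMNS = {
    "DEMO": {"event_dt", "rept_dt", "sex", "age", "age_cod", "wt", "wt_cod", "occr_country", "caseid"},
    "DRUG": {"drug_seq"},
    "REAC": {"pt_code"},
    "OUTC": set(),
    "THER": {"dsg_drug_seq"},
    "INDI": {"indi_drug_seq", "indi_pt"},
    "RPSR": {"rpsr_cod"},
}


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class Dialect:
    """Delimiter/quoting convention of the ASCII tables."""

    sep: str = "$"
    encoding: str = "utf-8"


@dataclass
class SmqTermSet:
    """A Standardized MedDRA Query: a flat set of preferred terms.

    ``terms`` maps PT code -> PT name. Name matching downstream is
    case-insensitive exact; code matching is used whenever event rows
    carry codes.
    """

    smq_id: str = DEFAULT_EP_SMQ_ID
    terms: tuple[tuple[int, str], ...] = DEFAULT_EP_TERMS

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.terms]
        if len(set(codes)) != len(codes):
            raise ValueError("SMQ term codes must be unique")

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(c for c, _ in self.terms)

    @property
    def names_lower(self) -> frozenset[str]:
        return frozenset(n.strip().lower() for _, n in self.terms)

    @classmethod
    def from_csv(cls, path: str | Path, smq_id: str = DEFAULT_EP_SMQ_ID) -> "SmqTermSet":
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        code_col = cols.get("pt_code", list(df.columns)[0])
        name_col = cols.get("pt_name", list(df.columns)[1])
        terms = tuple((int(c), str(n)) for c, n in zip(df[code_col], df[name_col]))
        return cls(smq_id=smq_id, terms=terms)

    def restrict(self, codes: Iterable[int]) -> "SmqTermSet":
        keep = set(codes)
        return SmqTermSet(self.smq_id, tuple(t for t in self.terms if t[0] in keep))


@dataclass
class ReportStore:
    """Normalized relational view of one or more FAERS-dialect quarters.

    ``reports`` is indexed by ``report_id`` (FAERS primaryid) and holds one
    row per report; ``drugs``/``events``/``outcomes`` are child tables keyed
    by ``report_id``.
    """

    reports: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    outcomes: pd.DataFrame
    indications: pd.DataFrame | None = None
    sources: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def report_ids(self) -> pd.Index:
        return self.reports.index

    def primary_suspect_sets(self) -> pd.Series:
        """Per-report frozenset of primary-suspect drug names (may be empty)."""
        ps = self.drugs[self.drugs["role"] == "primary-suspect"]
        grouped = ps.groupby("report_id")["drug_name"].agg(frozenset)
        return grouped.reindex(self.report_ids, fill_value=frozenset())

    def event_name_sets(self) -> pd.Series:
        grouped = self.events.groupby("report_id")["pt_name"].agg(
            lambda s: frozenset(x.strip().lower() for x in s.dropna())
        )
        return grouped.reindex(self.report_ids, fill_value=frozenset())

    def event_code_sets(self) -> pd.Series:
        ev = self.events.dropna(subset=["pt_code"])
        grouped = ev.groupby("report_id")["pt_code"].agg(lambda s: frozenset(int(x) for x in s))
        return grouped.reindex(self.report_ids, fill_value=frozenset())

    def n_distinct_drugs(self) -> pd.Series:
        """Polypharmacy count: distinct drug names per report, any role."""
        grouped = self.drugs.groupby("report_id")["drug_name"].nunique()
        return grouped.reindex(self.report_ids, fill_value=0).astype(int)

    def subset(self, report_ids: Iterable) -> "ReportStore":
        ids = pd.Index(report_ids)
        keep = self.reports.index.isin(ids)
        sel = self.reports.index[keep]

        def _child(df: pd.DataFrame | None) -> pd.DataFrame | None:
            if df is None:
                return None
            return df[df["report_id"].isin(sel)].reset_index(drop=True)

        return ReportStore(
            reports=self.reports.loc[sel],
            drugs=_child(self.drugs),
            events=_child(self.events),
            outcomes=_child(self.outcomes),
            indications=_child(self.indications),
            sources=_child(self.sources),
        )

    # -- serialization ------------------------------------------------------

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        rep = self.reports.reset_index()
        for name, df in (
            ("reports", rep),
            ("drugs", self.drugs),
            ("events", self.events),
            ("outcomes", self.outcomes),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def read_csv(cls, in_dir: str | Path) -> "ReportStore":
        d = Path(in_dir)
        rep = pd.read_csv(d / "reports.csv", dtype={"case_id": str})
        rep["report_id"] = rep["report_id"].astype(np.int64)
        for c in ("receipt_date", "event_date"):
            rep[c] = pd.to_datetime(rep[c], errors="coerce")
        rep = rep.set_index("report_id")
        drugs = pd.read_csv(d / "drugs.csv")
        drugs["start_date"] = pd.to_datetime(drugs["start_date"], errors="coerce")
        events = pd.read_csv(d / "events.csv")
        events["pt_code"] = events["pt_code"].astype("Int64")
        outcomes = pd.read_csv(d / "outcomes.csv")
        return cls(rep, drugs, events, outcomes)


@dataclass
class CaseSet:
    """Reports meeting the event definition (SMQ hit + primary-suspect drug)."""

    case_ids: frozenset
    matched_terms: dict
    suspect_drugs: dict
    smq_id: str = DEFAULT_EP_SMQ_ID

    def __len__(self) -> int:
        return len(self.case_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "report_id": rid,
                "matched_pts": ";".join(sorted(str(t) for t in self.matched_terms[rid])),
                "suspect_drugs": ";".join(sorted(self.suspect_drugs[rid])),
            }
            for rid in sorted(self.case_ids)
        ]
        return pd.DataFrame(rows, columns=["report_id", "matched_pts", "suspect_drugs"])

    def write_csv(self, path: str | Path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(p, index=False)
        return p


@dataclass
class ParseAudit:
    rows_read: dict[str, int] = field(default_factory=dict)
    rows_dropped: dict[str, int] = field(default_factory=dict)
    fields_nulled: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass
class DedupAudit:
    n_in: int
    removed_case_id_rule: int
    removed_demographic_rule: int
    n_out: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# parsing helpers


def parse_faers_date(value) -> pd.Timestamp:
    """Parse a FAERS date string; YYYYMMDD is a full date, YYYYMM/YYYY are
    partial and returned as NaT (day-level arithmetic cannot use them)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return pd.NaT
    s = str(value).strip()
    if not s.isdigit() or len(s) != 8:
        return pd.NaT
    try:
        return pd.Timestamp(f"{s[:4]}-{s[4:6]}-{s[6:8]}")
    except ValueError:
        return pd.NaT


def _parse_date_col(col: pd.Series) -> pd.Series:
    s = col.astype("string").str.strip()
    full = s.str.fullmatch(r"\d{8}", na=False)
    out = pd.to_datetime(s.where(full), format="%Y%m%d", errors="coerce")
    return out


def normalize_drug_name(name: str, salt_suffixes: Sequence[str] = DEFAULT_SALT_SUFFIXES) -> str:
    """Uppercase, trim, and strip a trailing salt/ester suffix."""
    s = str(name).strip().upper()
    for suf in salt_suffixes:
        if s.endswith(suf):
            s = s[: -len(suf)].strip()
            break
    return s


def _resolve_columns(df: pd.DataFrame, table: str) -> pd.DataFrame:
    spec = _CANONICAL_COLUMNS[table]
    lower = {c.lower().strip(): c for c in df.columns}
    rename = {}
    used = set()
    for canon, aliases in spec.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canon
                used.add(lower[alias])
                break
    unknown = [c for c in df.columns if c not in used]
    if unknown:
        warnings.warn(f"{table}: ignoring unknown columns {unknown}", stacklevel=3)
    missing = [
        canon for canon in spec
        if canon not in rename.values() and canon not in _OPTIONAL_COLUMNS[table]
    ]
    if missing:
        raise ValueError(f"{table}: required columns missing: {missing}")
    return df.rename(columns=rename)[[c for c in spec if c in rename.values()]]


def _age_to_years(age: pd.Series, code: pd.Series) -> pd.Series:
    a = pd.to_numeric(age, errors="coerce")
    c = code.astype("string").str.upper().str.strip().fillna("YR")
    factor = pd.Series(1.0, index=a.index)
    factor[c == "DEC"] = 10.0
    factor[c == "MON"] = 1.0 / 12.0
    factor[c == "WK"] = 7.0 / 365.25
    factor[c == "DY"] = 1.0 / 365.25
    factor[c == "HR"] = 1.0 / (24 * 365.25)
    years = a * factor
    years[years < 0] = np.nan
    return years


def _weight_to_kg(wt: pd.Series, code: pd.Series) -> pd.Series:
    w = pd.to_numeric(wt, errors="coerce")
    c = code.astype("string").str.upper().str.strip().fillna("KG")
    kg = w.where(~c.isin(["LBS", "LB"]), w * LB_TO_KG)
    kg[kg <= 0] = np.nan
    return kg


def parse_tables(
    paths: Mapping[str, str | Path],
    dialect: Dialect = Dialect(),
    salt_suffixes: Sequence[str] = DEFAULT_SALT_SUFFIXES,
) -> tuple[ReportStore, ParseAudit]:
    """Parse FAERS-dialect ASCII tables into a normalized :class:`ReportStore`.

    ``paths`` maps table names (DEMO, DRUG, REAC, optionally OUTC/THER/INDI/
    RPSR) to files. Unparseable dates/ages/weights become missing and are
    counted in the audit; they never fail a row. A missing mandatory table
    is a hard error naming the table.
    """
    upper = {k.upper(): Path(v) for k, v in paths.items()}
    for t in MANDATORY_TABLES:
        if t not in upper:
            raise ValueError(f"missing mandatory table: {t}")
        if not upper[t].exists():
            raise ValueError(f"missing mandatory table file: {t} ({upper[t]})")

    frames: dict[str, pd.DataFrame] = {}
    for t, p in upper.items():
        if t not in _CANONICAL_COLUMNS:
            warnings.warn(f"ignoring unrecognized table {t}")
            continue
        if not p.exists():
            warnings.warn(f"optional table {t} not found at {p}; skipped")
            continue
        raw = pd.read_csv(p, sep=dialect.sep, dtype=str, encoding=dialect.encoding,
                          keep_default_na=False, na_values=[""], engine="python")
        frames[t] = raw
    return store_from_frames(frames, salt_suffixes=salt_suffixes)


def store_from_frames(
    frames: Mapping[str, pd.DataFrame],
    salt_suffixes: Sequence[str] = DEFAULT_SALT_SUFFIXES,
) -> tuple[ReportStore, ParseAudit]:
    """Build a store from raw (string-typed) per-table DataFrames.

    Shared backend of :func:`parse_tables`; also the fast path for
    synthetic tables that never touch disk.
    """
    audit = ParseAudit()
    for t in MANDATORY_TABLES:
        if t not in frames:
            raise ValueError(f"missing mandatory table: {t}")

    resolved = {t: _resolve_columns(df, t) for t, df in frames.items() if t in _CANONICAL_COLUMNS}
    for t, df in resolved.items():
        audit.rows_read[t] = len(df)

    demo = resolved["DEMO"].copy()
    demo["report_id"] = pd.to_numeric(demo["primaryid"], errors="coerce")
    n_bad_id = int(demo["report_id"].isna().sum())
    if n_bad_id:
        audit.rows_dropped["DEMO"] = n_bad_id
        demo = demo.dropna(subset=["report_id"])
    demo["report_id"] = demo["report_id"].astype(np.int64)
    demo = demo.drop_duplicates(subset="report_id", keep="first")
    dup_ids = audit.rows_read["DEMO"] - n_bad_id - len(demo)
    if dup_ids:
        audit.rows_dropped["DEMO"] = audit.rows_dropped.get("DEMO", 0) + dup_ids

    def opt(col: str) -> pd.Series:
        if col in demo.columns:
            return demo[col]
        return pd.Series(pd.NA, index=demo.index, dtype="string")

    receipt = _parse_date_col(opt("fda_dt"))
    event = _parse_date_col(opt("event_dt"))
    rept = opt("rept_dt").astype("string").str.strip()
    report_year = pd.to_numeric(rept.str[:4], errors="coerce").astype("Int64")
    sex_raw = opt("sex").astype("string").str.upper().str.strip()
    sex = sex_raw.map(SEX_CODES).fillna("unknown")
    age_years = _age_to_years(opt("age"), opt("age_cod"))
    weight_kg = _weight_to_kg(opt("wt"), opt("wt_cod"))
    country = opt("occr_country").astype("string").str.strip()

    audit.fields_nulled["receipt_date"] = int((receipt.isna() & opt("fda_dt").notna()).sum())
    audit.fields_nulled["event_date"] = int((event.isna() & opt("event_dt").notna()).sum())
    audit.fields_nulled["age_years"] = int((age_years.isna() & opt("age").notna()).sum())
    audit.fields_nulled["weight_kg"] = int((weight_kg.isna() & opt("wt").notna()).sum())

    reports = pd.DataFrame(
        {
            "report_id": demo["report_id"].values,
            "case_id": opt("caseid").astype("string").str.strip().values,
            "receipt_date": receipt.values,
            "sex": sex.values,
            "age_years": age_years.values,
            "weight_kg": weight_kg.values,
            "country": country.values,
            "report_year": report_year.values,
            "event_date": event.values,
        }
    ).set_index("report_id")
    known_ids = reports.index

    def child(table: str, cols: dict[str, str]) -> pd.DataFrame:
        if table not in resolved:
            return pd.DataFrame(columns=["report_id", *cols.values()])
        df = resolved[table].copy()
        df["report_id"] = pd.to_numeric(df["primaryid"], errors="coerce")
        df = df.dropna(subset=["report_id"])
        df["report_id"] = df["report_id"].astype(np.int64)
        orphan = ~df["report_id"].isin(known_ids)
        if orphan.any():
            audit.rows_dropped[table] = int(orphan.sum())
            df = df[~orphan]
        out = df[["report_id"]].copy()
        for src, dst in cols.items():
            out[dst] = df[src] if src in df.columns else pd.NA
        return out.reset_index(drop=True)

    drugs = child("DRUG", {"drug_seq": "drug_seq", "role_cod": "role", "drugname": "drug_name"})
    if len(drugs):
        n_no_role = int(drugs["role"].isna().sum())
        if n_no_role:
            audit.rows_dropped["DRUG"] = audit.rows_dropped.get("DRUG", 0) + n_no_role
            drugs = drugs.dropna(subset=["role"])
        drugs["role"] = (
            drugs["role"].astype("string").str.upper().str.strip().map(ROLE_CODES).fillna("concomitant")
        )
        drugs["drug_name"] = drugs["drug_name"].map(lambda s: normalize_drug_name(s, salt_suffixes))
        drugs = drugs[drugs["drug_name"] != ""]
        drugs["drug_seq"] = pd.to_numeric(drugs["drug_seq"], errors="coerce").astype("Int64")

    # therapy start dates join onto drug rows via (report_id, drug_seq)
    ther = child("THER", {"dsg_drug_seq": "drug_seq", "start_dt": "start_dt"})
    if len(ther):
        ther["drug_seq"] = pd.to_numeric(ther["drug_seq"], errors="coerce").astype("Int64")
        ther["start_date"] = _parse_date_col(ther["start_dt"])
        audit.fields_nulled["start_date"] = int((ther["start_date"].isna() & ther["start_dt"].notna()).sum())
        ther = ther.drop(columns=["start_dt"]).dropna(subset=["drug_seq"])
        ther = ther.drop_duplicates(subset=["report_id", "drug_seq"], keep="first")
        drugs = drugs.merge(ther, on=["report_id", "drug_seq"], how="left")
    else:
        drugs["start_date"] = pd.NaT
    drugs["start_date"] = pd.to_datetime(drugs["start_date"])

    events = child("REAC", {"pt": "pt_name", "pt_code": "pt_code"})
    if len(events):
        events["pt_name"] = events["pt_name"].astype("string").str.strip()
        events = events.dropna(subset=["pt_name"])
        events["pt_code"] = pd.to_numeric(events["pt_code"], errors="coerce").astype("Int64")
    else:
        events["pt_code"] = pd.Series(dtype="Int64")

    outcomes = child("OUTC", {"outc_cod": "outcome"})
    if len(outcomes):
        outcomes["outcome"] = (
            outcomes["outcome"].astype("string").str.upper().str.strip().map(OUTCOME_CODES).fillna("other")
        )

    indications = child("INDI", {"indi_drug_seq": "drug_seq", "indi_pt": "indi_pt"}) if "INDI" in resolved else None
    sources = child("RPSR", {"rpsr_cod": "source_code"}) if "RPSR" in resolved else None

    store = ReportStore(reports, drugs, events, outcomes, indications, sources)
    return store, audit


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(store: ReportStore) -> tuple[ReportStore, DedupAudit]:
    """Apply the two-stage FDA-style deduplication.

    Stage 1 (case-id rule): at most one report per ``case_id`` — keep the
    latest ``receipt_date``; ties broken by largest ``report_id``. Reports
    with a missing receipt date sort as older than any dated report.
    Stage 2 (demographic rule): among survivors, reports identical on
    (age_years, sex, event_date, sorted PT set, sorted primary-suspect drug
    set) collapse to the largest ``report_id``. The rule only considers
    reports whose key fields are all present (age known, sex male/female,
    event date present): absent data cannot establish that two reports
    describe the same patient. Idempotent.
    """
    n_in = len(store)
    if n_in == 0:
        return store, DedupAudit(0, 0, 0, 0)

    rep = store.reports
    # stage 1: missing receipt dates lose against any dated record
    sort_key = rep["receipt_date"].fillna(pd.Timestamp.min)
    order = pd.DataFrame({"d": sort_key, "rid": rep.index}, index=rep.index)
    # case_id missing -> each report is its own case
    case = rep["case_id"].astype("string")
    case = case.fillna("\x00rid:" + pd.Series(rep.index.astype(str), index=rep.index))
    order["case"] = case
    keep1 = order.sort_values(["case", "d", "rid"]).groupby("case", sort=False).tail(1)["rid"]
    removed1 = n_in - len(keep1)
    stage1 = store.subset(keep1)

    # stage 2: demographic secondary key, complete key fields only
    rep1 = stage1.reports
    complete = (
        rep1["age_years"].notna()
        & rep1["sex"].isin(["male", "female"])
        & rep1["event_date"].notna()
    )
    sub = rep1.index[complete]
    ev = stage1.events[stage1.events["report_id"].isin(sub)]
    pts = (
        ev.sort_values(["report_id", "pt_name"])
        .groupby("report_id")["pt_name"].agg("|".join)
        .reindex(sub, fill_value="")
    )
    psd = stage1.drugs[
        (stage1.drugs["role"] == "primary-suspect") & stage1.drugs["report_id"].isin(sub)
    ]
    ps = (
        psd.sort_values(["report_id", "drug_name"])
        .groupby("report_id")["drug_name"].agg(lambda s: "|".join(dict.fromkeys(s)))
        .reindex(sub, fill_value="")
    )
    key = pd.DataFrame(
        {
            "age": rep1.loc[sub, "age_years"],
            "sex": rep1.loc[sub, "sex"],
            "event": rep1.loc[sub, "event_date"],
            "pts": pts,
            "ps": ps,
            "rid": sub,
        },
        index=sub,
    )
    keep_complete = key.sort_values(["age", "sex", "event", "pts", "ps", "rid"]).groupby(
        ["age", "sex", "event", "pts", "ps"], sort=False
    ).tail(1)["rid"]
    keep2 = pd.Index(keep_complete.to_numpy()).union(rep1.index[~complete])
    removed2 = len(rep1) - len(keep2)
    final = stage1.subset(keep2)
    audit = DedupAudit(n_in, int(removed1), int(removed2), len(final))
    return final, audit


# ---------------------------------------------------------------------------
# case extraction


def extract_cases(store: ReportStore, smq: SmqTermSet = SmqTermSet()) -> CaseSet:
    """Identify outcome cases: >=1 event in the SMQ term set AND >=1 drug
    with role primary-suspect. PT matching is by code where event rows carry
    codes, else case-insensitive exact name match."""
    if not smq.terms:
        raise ValueError("empty SMQ term set: degenerate event definition")

    ev = store.events
    codes = smq.codes
    names = smq.names_lower
    has_code = ev["pt_code"].notna()
    code_hit = pd.Series(False, index=ev.index)
    if has_code.any():
        code_hit[has_code] = ev.loc[has_code, "pt_code"].astype("int64").isin(codes)
    name_hit = ev["pt_name"].astype("string").str.strip().str.lower().isin(names)
    hit = code_hit | (~has_code & name_hit)

    hits = ev[hit].copy()
    hits["term"] = [
        int(code) if pd.notna(code) else str(name)
        for code, name in zip(hits["pt_code"], hits["pt_name"])
    ]
    matched: dict = hits.groupby("report_id")["term"].agg(set).to_dict()

    # primary-suspect sets only for reports with a term hit
    hit_ids = pd.Index(list(matched))
    psd = store.drugs[
        (store.drugs["role"] == "primary-suspect") & store.drugs["report_id"].isin(hit_ids)
    ]
    suspects = psd.groupby("report_id")["drug_name"].agg(set).to_dict()
    case_ids = frozenset(suspects)
    matched = {rid: matched[rid] for rid in case_ids}
    return CaseSet(case_ids=case_ids, matched_terms=matched, suspect_drugs=suspects, smq_id=smq.smq_id)


# ---------------------------------------------------------------------------
# demographic summary


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (matches printed-table percentage formatting)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(n: int, d: int, ndigits: int = 1) -> float:
    if d == 0:
        return 0.0
    return round_half_up(100.0 * n / d, ndigits)


@dataclass
class BinningSpec:
    """Category bins for the demographic summary. Numeric bands are
    (label, low, high] half-open intervals and must not overlap."""

    age_bands: tuple = (("<18", 0, 18), ("18-44", 18, 45), ("45-64", 45, 65),
                        ("65-74", 65, 75), (">75", 75, np.inf))
    weight_bands: tuple = (("<50", 0, 50), ("50-70", 50, 70), ("70-90", 70, 90),
                           ("90-110", 90, 110), (">110", 110, np.inf))
    year_bands: tuple = (("2014-2020", 2014, 2021), ("2021", 2021, 2022), ("2022", 2022, 2023),
                         ("2023", 2023, 2024), ("2024", 2024, 2025), ("2025", 2025, 2026))

    def __post_init__(self) -> None:
        for name in ("age_bands", "weight_bands", "year_bands"):
            bands = sorted(getattr(self, name), key=lambda b: b[1])
            for (l1, _, hi), (l2, lo, _) in zip(bands, bands[1:]):
                if lo < hi:
                    raise ValueError(f"overlapping bins in {name}: {l1!r} and {l2!r}")


def _band_labels(values: pd.Series, bands: tuple) -> pd.Series:
    out = pd.Series("unknown", index=values.index, dtype=object)
    for label, lo, hi in bands:
        mask = values.notna() & (values >= lo) & (values < hi)
        out[mask] = label
    return out


def demographic_summary(
    cases: CaseSet, store: ReportStore, binning: BinningSpec = BinningSpec()
) -> pd.DataFrame:
    """Counts and round-half-up percentages per category, for the case
    subset and the full store (denominators = subset sizes). Outcome
    percentages use the report denominator, so a report with several
    serious outcomes contributes to several rows."""
    rep = store.reports
    is_case = rep.index.isin(cases.case_ids)
    n_cases, n_all = int(is_case.sum()), len(rep)

    cat = pd.DataFrame(index=rep.index)
    cat["sex"] = rep["sex"]
    cat["age_band"] = _band_labels(rep["age_years"], binning.age_bands)
    cat["weight_band"] = _band_labels(rep["weight_kg"], binning.weight_bands)
    cat["report_year"] = _band_labels(rep["report_year"].astype("float"), binning.year_bands)
    cat["country"] = rep["country"].fillna("unknown").replace("", "unknown")

    rows = []

    def emit(characteristic: str, labels: pd.Series, ordered: list[str]) -> None:
        for label in ordered:
            in_cat = labels == label
            cn = int((in_cat & is_case).sum())
            an = int(in_cat.sum())
            rows.append(
                {
                    "characteristic": characteristic,
                    "category": label,
                    "case_n": cn,
                    "case_pct": percent(cn, n_cases),
                    "all_n": an,
                    "all_pct": percent(an, n_all),
                }
            )

    emit("sex", cat["sex"], ["male", "female", "unknown"])
    emit("age_band", cat["age_band"], [b[0] for b in binning.age_bands] + ["unknown"])
    emit("weight_band", cat["weight_band"], [b[0] for b in binning.weight_bands] + ["unknown"])
    emit("report_year", cat["report_year"], [b[0] for b in binning.year_bands] + ["unknown"])
    # cases are a subset of the store, so the store covers every category
    emit("country", cat["country"], cat["country"].value_counts().index.tolist())

    # outcomes: one row per category, counted over distinct reports
    oc = store.outcomes.drop_duplicates(["report_id", "outcome"])
    case_idx = rep.index[is_case]
    for outcome in OUTCOME_CODES.values():
        sub = oc[oc["outcome"] == outcome]
        cn = int(sub["report_id"].isin(case_idx).sum())
        an = len(sub)
        rows.append(
            {
                "characteristic": "outcome",
                "category": outcome,
                "case_n": cn,
                "case_pct": percent(cn, n_cases),
                "all_n": an,
                "all_pct": percent(an, n_all),
            }
        )
    return pd.DataFrame(rows)
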