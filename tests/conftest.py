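"""Shared fixtures: a hand-written toy quarter and small synthetic stores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pvep import faers_ingest as fi
from pvep import synthetic_faers as sf

TOY_TABLES = {
    # three reports: 1 = EP case w/ primary suspect, 2 = EP term but only
    # concomitant drug, 3 = non-case with "UNK" age
    "DEMO": pd.DataFrame(
        {
            "primaryid": ["101", "102", "103"],
            "caseid": ["9001", "9002", "9003"],
            "fda_dt": ["20240105", "20240110", "20240131"],
            "event_dt": ["20240102", "20240103", ""],
            "rept_dt": ["20240104", "20240108", "20240130"],
            "sex": ["M", "F", ""],
            "age": ["63", "47", "UNK"],
            "age_cod": ["YR", "YR", ""],
            "wt": ["80", "132", ""],
            "wt_cod": ["KG", "LBS", ""],
            "occr_country": ["US", "JP", "DE"],
        }
    ),
    "DRUG": pd.DataFrame(
        {
            "primaryid": ["101", "102", "103"],
            "drug_seq": ["1", "1", "1"],
            "role_cod": ["PS", "C", "PS"],
            "drugname": ["Daptomycin Sodium", "amiodarone", "IBUPROFEN"],
        }
    ),
    "REAC": pd.DataFrame(
        {
            "primaryid": ["101", "102", "103"],
            "pt": ["Eosinophilic pneumonia", "Pneumonitis", "Nausea"],
            "pt_code": ["10014962", "10035742", "10028813"],
        }
    ),
    "OUTC": pd.DataFrame({"primaryid": ["101", "102"], "outc_cod": ["HO", "DE"]}),
    "THER": pd.DataFrame(
        {"primaryid": ["101", "103"], "dsg_drug_seq": ["1", "1"], "start_dt": ["20231214", "20240120"]}
    ),
}


@pytest.fixture()
def toy_paths(tmp_path):
    return {name: sf.write_dialect({name: df}, tmp_path)[name] for name, df in TOY_TABLES.items()}


@pytest.fixture()
def toy_store(toy_paths):
    store, audit = fi.parse_tables(toy_paths)
    return store


@pytest.fixture(scope="session")
def small_sim_config():
    """A 5,000-report synthetic quarter with one strong planted signal and
    full covariate observation (used by several modules)."""
    return sf.SimConfig(
        n_reports=5_000,
        drugs=[
            sf.DrugSpec("SIGNALDRUG", prevalence=0.02, ep_odds_multiplier=15.0,
                        tto_shape=0.9, tto_scale=25.0),
            sf.DrugSpec("NULLDRUG", prevalence=0.02, ep_odds_multiplier=1.0),
        ],
        background_event_rate=0.02,
        missingness=sf.Missingness(age=0.1, weight=0.2, start_date=0.3, event_date=0.3),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_store(small_sim_config):
    store, truth, _ = sf.generate_store(small_sim_config)
    store, _ = fi.deduplicate(store)
    return store


@pytest.fixture(scope="session")
def small_cases(small_store):
    return fi.extract_cases(small_store)
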