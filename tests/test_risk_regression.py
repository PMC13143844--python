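"""Screen thresholds, design matrix, LASSO selection, logistic forest."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pvep import disproportionality as dp
from pvep import faers_ingest as fi
from pvep import risk_regression as rr
from pvep import synthetic_faers as sf


def _metrics_frame(rows):
    return pd.DataFrame(rows, columns=["drug", "n_reports", "ror_lcl", "p_adj"])


class TestUnivariateScreen:
    def test_count_rule_excludes(self):
        m = _metrics_frame([("A", 2, 5.0, 1e-6)])
        candidates, reasons = rr.univariate_screen(m)
        assert candidates == []
        assert not reasons["count_ok"].iloc[0]

    def test_strong_drug_retained(self):
        m = _metrics_frame([("DAPTO", 758, 13.90, 1e-30)])
        candidates, _ = rr.univariate_screen(m)
        assert candidates == ["DAPTO"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(4)
        m = _metrics_frame(
            [(f"D{i}", int(rng.integers(1, 50)), float(rng.uniform(0.5, 4)),
              float(rng.uniform(0, 0.2))) for i in range(40)]
        )
        base, _ = rr.univariate_screen(m, rr.ScreenThresholds())
        tighter = [
            rr.ScreenThresholds(min_reports=10),
            rr.ScreenThresholds(strict_count=True),
            rr.ScreenThresholds(ror_lcl_min=2.0),
            rr.ScreenThresholds(p_adj_max=0.01),
        ]
        for thr in tighter:
            cand, _ = rr.univariate_screen(m, thr)
            assert set(cand) <= set(base)

    def test_null_data_near_empty(self, small_store, small_cases):
        panel = dp.signal_panel(small_cases, small_store)
        nulls = panel[panel["drug"] != "SIGNALDRUG"]
        cand, _ = rr.univariate_screen(nulls, rr.ScreenThresholds(p_adj_max=0.01))
        assert len(cand) <= 1


class TestBuildMatrix:
    def test_indicators_and_polypharmacy(self):
        demo = pd.DataFrame(
            [{"primaryid": "1", "caseid": "1", "fda_dt": "20240101", "sex": "M",
              "age": "60", "age_cod": "YR", "wt": "70", "wt_cod": "KG"},
             {"primaryid": "2", "caseid": "2", "fda_dt": "20240101", "sex": "F",
              "age": "40", "age_cod": "YR", "wt": "60", "wt_cod": "KG"}]
        )
        drug = pd.DataFrame(
            [
                {"primaryid": "1", "drug_seq": "1", "role_cod": "PS", "drugname": "A"},
                {"primaryid": "1", "drug_seq": "2", "role_cod": "PS", "drugname": "B"},
                {"primaryid": "1", "drug_seq": "3", "role_cod": "C", "drugname": "Z"},
                {"primaryid": "2", "drug_seq": "1", "role_cod": "PS", "drugname": "C"},
            ]
        )
        reac = pd.DataFrame(
            [{"primaryid": "1", "pt": "Pneumonitis", "pt_code": "10035742"},
             {"primaryid": "2", "pt": "Nausea", "pt_code": "10028813"}]
        )
        store, _ = fi.store_from_frames({"DEMO": demo, "DRUG": drug, "REAC": reac})
        cases = fi.extract_cases(store)
        mm = rr.build_matrix(store, cases, ["A", "B"], missing="indicator")
        row = mm.X.loc[1]
        assert row["A"] == 1.0 and row["B"] == 1.0
        assert row["n_drugs"] == 3.0  # distinct names, any role
        assert mm.X.loc[2, "A"] == 0.0

    def test_complete_case_drops_exactly_missing_rows(self, small_store, small_cases):
        mm = rr.build_matrix(small_store, small_cases, ["SIGNALDRUG"])
        rep = small_store.reports
        expected_kept = (
            rep["age_years"].notna()
            & rep["weight_kg"].notna()
            & rep["sex"].isin(["male", "female"])
        ).sum()
        assert mm.n == expected_kept
        assert mm.n_dropped_missing == len(rep) - expected_kept

    def test_column_means_match_brute_force(self, small_store, small_cases):
        mm = rr.build_matrix(small_store, small_cases, ["SIGNALDRUG", "NULLDRUG"])
        ps = small_store.primary_suspect_sets()
        exposed = {rid for rid, s in ps.items() if "SIGNALDRUG" in s}
        brute = np.mean([rid in exposed for rid in mm.X.index])
        assert mm.X["SIGNALDRUG"].mean() == pytest.approx(brute)

    def test_empty_candidates_rejected(self, small_store, small_cases):
        with pytest.raises(ValueError):
            rr.build_matrix(small_store, small_cases, [])


class TestLassoSelect:
    @pytest.fixture(scope="class")
    def planted_matrix(self):
        """n=50,000 with 3 true drug effects (OR 12/5/3) among 30 nulls.

        Prevalence 0.02 keeps the expected drug-by-event cell at ~30, the
        generator's stated recovery regime.
        """
        drugs = [sf.DrugSpec(f"NULL_{i:02d}", 0.02) for i in range(30)]
        drugs += [sf.DrugSpec("TRUE12", 0.02, 12.0), sf.DrugSpec("TRUE5", 0.02, 5.0),
                  sf.DrugSpec("TRUE3", 0.02, 3.0)]
        cfg = sf.SimConfig(
            n_reports=50_000, drugs=drugs, background_event_rate=0.01,
            missingness=sf.Missingness(age=0.0, weight=0.0), duplicate_rate=0.0, seed=2,
        )
        store, _, _ = sf.generate_store(cfg)
        cases = fi.extract_cases(store)
        all_drugs = [d.name for d in drugs]
        return rr.build_matrix(store, cases, all_drugs), store, cases

    def test_penalty_limit_all_zero(self, planted_matrix):
        mm, _, _ = planted_matrix
        res = rr.lasso_select(mm, folds=3, seed=0, n_lambda=5, lambda_min_ratio=0.9)
        # at lambda_max every penalized coefficient is zero
        assert np.allclose(res.coef_path.iloc[0].to_numpy(), 0.0, atol=1e-8)

    def test_planted_effects_selected(self, planted_matrix):
        mm, _, _ = planted_matrix
        res = rr.lasso_select(mm, folds=10, seed=2)
        selected_drugs = {v for v in res.selected if v.startswith(("TRUE", "NULL"))}
        assert {"TRUE12", "TRUE5", "TRUE3"} <= selected_drugs
        false_hits = {v for v in selected_drugs if v.startswith("NULL")}
        assert len(false_hits) <= 5

    def test_nonzero_count_monotone_along_path(self, planted_matrix):
        mm, _, _ = planted_matrix
        res = rr.lasso_select(mm, folds=3, seed=1, n_lambda=12)
        nnz = (np.abs(res.coef_path.to_numpy()) > 0).sum(axis=1)
        assert np.all(np.diff(nnz) >= -1)  # non-strict growth as penalty shrinks

    def test_unpenalized_limit_matches_mle(self):
        rng = np.random.default_rng(6)
        n = 2000
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.binomial(1, 0.3, n).astype(float)})
        eta = -2.0 + 0.8 * X["x1"] + 1.2 * X["x2"]
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))), index=X.index)
        mm = rr.ModelMatrix(X=X, y=y, n_dropped_missing=0, candidate_drugs=())
        res = rr.lasso_select(mm, folds=3, seed=0, lambdas=np.array([0.1, 0.01, 0.0]))
        mle = sm.Logit(y.to_numpy(), sm.add_constant(X.to_numpy())).fit(disp=0)
        assert np.allclose(res.coef_path.iloc[-1].to_numpy(), mle.params[1:], atol=1e-4)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        y = pd.Series([0, 0, 0])
        with pytest.raises(ValueError, match="single class"):
            rr.lasso_select(rr.ModelMatrix(X, y, 0, ()), folds=2, seed=0)


class TestLogisticFit:
    def test_single_binary_predictor_equals_sample_or(self):
        rng = np.random.default_rng(9)
        x = rng.binomial(1, 0.3, 4000).astype(float)
        p = np.where(x == 1, 0.15, 0.05)
        y = rng.binomial(1, p)
        a = np.sum((x == 1) & (y == 1)); b = np.sum((x == 1) & (y == 0))
        c = np.sum((x == 0) & (y == 1)); d = np.sum((x == 0) & (y == 0))
        mm = rr.ModelMatrix(pd.DataFrame({"drug": x}), pd.Series(y), 0, ("drug",))
        terms = rr.logistic_fit(mm)
        assert terms[0].odds_ratio == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_age_per_year_effect_recovered(self):
        """Planted log-OR 0.01 per year of age comes back as OR ~ 1.01."""
        rng = np.random.default_rng(14)
        n = 60_000
        age = rng.uniform(18, 90, n)
        eta = -4.5 + 0.01 * age
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        mm = rr.ModelMatrix(pd.DataFrame({"age_years": age}), pd.Series(y), 0, ())
        terms = rr.logistic_fit(mm)
        assert terms[0].odds_ratio == pytest.approx(1.01, abs=0.004)

    def test_separation_flagged(self):
        X = pd.DataFrame({"x": [0.0] * 20 + [1.0] * 20})
        y = pd.Series([0] * 20 + [1] * 20)
        mm = rr.ModelMatrix(X, y, 0, ())
        terms = rr.logistic_fit(mm)
        assert terms[0].separated
        assert terms[0].ci95[1] == math.inf

    def test_collinear_column_dropped(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-x))))
        mm = rr.ModelMatrix(X, y, 0, ())
        with pytest.warns(UserWarning, match="collinear"):
            terms = rr.logistic_fit(mm)
        assert len(terms) == 1


class TestForestTable:
    def _term(self, var, or_, p_adj):
        return rr.LogisticTerm(var, math.log(or_), or_, (or_ * 0.8, or_ * 1.3), p_adj, p_adj)

    def test_significance_marker(self):
        out = rr.forest_table([self._term("dapto-like", 12.50, 1e-12)])
        assert bool(out["significant"].iloc[0])
        assert out["odds_ratio"].iloc[0] == pytest.approx(12.50)

    def test_sorted_descending(self):
        out = rr.forest_table(
            [self._term("a", 2.0, 0.5), self._term("b", 8.0, 0.5), self._term("c", 4.0, 0.5)]
        )
        assert list(out["variable"]) == ["b", "c", "a"]

    def test_empty(self):
        assert rr.forest_table([]).empty


class TestCascadeConcordance:
    def test_final_or_rank_concordant_with_truth(self):
        """Planted ORs {12.5, 5, 3} stay rank-ordered in the final model
        across 10 seeds (Spearman rho >= 0.9)."""
        from scipy.stats import spearmanr

        truth = {"TRUE12": 12.5, "TRUE5": 5.0, "TRUE3": 3.0}
        rhos = []
        # strongest effects on the rarer drugs, as in real reporting data;
        # prevalences keep every planted drug's expected case cell >= 30
        prevalence = {"TRUE12": 0.008, "TRUE5": 0.015, "TRUE3": 0.03}
        for seed in range(10):
            drugs = [sf.DrugSpec(f"NULL_{i:02d}", 0.03) for i in range(10)]
            drugs += [sf.DrugSpec(k, prevalence[k], v) for k, v in truth.items()]
            cfg = sf.SimConfig(
                n_reports=50_000, drugs=drugs, background_event_rate=0.01,
                missingness=sf.Missingness(age=0.0, weight=0.0),
                duplicate_rate=0.0, seed=100 + seed,
            )
            store, _, _ = sf.generate_store(cfg)
            cases = fi.extract_cases(store)
            panel = dp.signal_panel(cases, store)
            cand, _ = rr.univariate_screen(panel, rr.ScreenThresholds(p_adj_max=0.01))
            mm = rr.build_matrix(store, cases, cand)
            lasso = rr.lasso_select(mm, folds=10, seed=seed)
            terms = rr.logistic_fit(mm, list(lasso.selected))
            # concordance over the drugs reaching the final model; null
            # survivors enter with planted OR 1
            est = {t.variable: t.odds_ratio for t in terms if t.variable in mm.candidate_drugs}
            assert len(set(est) & set(truth)) >= 2
            order = sorted(est)
            planted = [truth.get(k, 1.0) for k in order]
            rho = spearmanr(planted, [est[k] for k in order]).statistic
            rhos.append(rho)
        assert np.mean(rhos) >= 0.9
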