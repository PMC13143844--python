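"""Metric formulas against arbitrary-precision oracles, positivity rules,
multiplicity adjustment, volcano/comparison/composition exports."""

from __future__ import annotations

import math
from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pvep import disproportionality as dp
from pvep import faers_ingest as fi
from pvep import synthetic_faers as sf

getcontext().prec = 50


def decimal_oracle(a: int, b: int, c: int, d: int) -> dict:
    """Closed-form metric panel evaluated in 50-digit decimal arithmetic."""
    A, B, C, D = (Decimal(v) for v in (a, b, c, d))
    N = A + B + C + D
    se = (1 / A + 1 / B + 1 / C + 1 / D).sqrt()
    ror = (A * D) / (B * C)
    prr = (A / (A + B)) / (C / (C + D))
    chi2 = N * (A * D - B * C) ** 2 / ((A + B) * (C + D) * (A + C) * (B + D))
    rrr = A * N / ((A + B) * (A + C))
    ln2 = Decimal(2).ln()
    return {
        "ror": ror,
        "ror_lcl": (ror.ln() - Decimal("1.96") * se).exp(),
        "ror_ucl": (ror.ln() + Decimal("1.96") * se).exp(),
        "prr": prr,
        "chi2": chi2,
        "rrr": rrr,
        "ic": rrr.ln() / ln2,
        "ic025": rrr.ln() / ln2 - Decimal("1.96") * se / ln2,
        "ebgm": rrr,
        "ebgm05": (rrr.ln() - Decimal("1.64") * se).exp(),
    }


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exact-rational hypergeometric
    enumeration (tie tolerance 1e-7 as in the conditional test's standard
    floating-point convention)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom) for k in support}
    obs = pmf[a]
    cutoff = obs * Fraction(10**7 + 1, 10**7)
    return float(sum(p for p in pmf.values() if p <= cutoff))


class TestContingency:
    def test_enumeration_example(self):
        # 10 reports: 2 exposed cases, 3 exposed non-cases, 5 unexposed non-cases
        rows = []
        for i in range(10):
            rows.append({"primaryid": str(i + 1), "caseid": str(i + 1), "fda_dt": "20240101"})
        drug = pd.DataFrame(
            {"primaryid": [str(i + 1) for i in range(5)], "drug_seq": "1",
             "role_cod": "PS", "drugname": "X"}
        )
        other = pd.DataFrame(
            {"primaryid": [str(i + 6) for i in range(5)], "drug_seq": "1",
             "role_cod": "PS", "drugname": "Y"}
        )
        reac = pd.DataFrame(
            {
                "primaryid": [str(i + 1) for i in range(10)],
                "pt": ["Pneumonitis"] * 2 + ["Nausea"] * 8,
                "pt_code": ["10035742"] * 2 + ["10028813"] * 8,
            }
        )
        store, _ = fi.store_from_frames(
            {"DEMO": pd.DataFrame(rows), "DRUG": pd.concat([drug, other]), "REAC": reac}
        )
        cases = fi.extract_cases(store)
        t = dp.contingency(cases, store, "X")
        assert (t.a, t.b, t.c, t.d) == (2, 3, 0, 5)

    def test_cells_sum_to_store_size(self, small_store, small_cases):
        for drug in ("SIGNALDRUG", "NULLDRUG", "BACKGROUND_01"):
            t = dp.contingency(small_cases, small_store, drug)
            assert t.n == len(small_store)

    def test_panel_matches_set_algebra(self, small_store, small_cases):
        """Vectorized panel counts equal brute-force set intersections."""
        panel = dp.contingency_panel(small_cases, small_store)
        ps = small_store.primary_suspect_sets()
        for drug in ("SIGNALDRUG", "NULLDRUG"):
            exposed = {rid for rid, s in ps.items() if drug in s}
            a_brute = len(exposed & set(small_cases.case_ids))
            assert panel.loc[drug, "a"] == a_brute
            assert panel.loc[drug, "b"] == len(exposed) - a_brute

    def test_absent_drug_flagged_zero(self, small_store, small_cases):
        panel = dp.contingency_panel(small_cases, small_store, drugs=["NO_SUCH_DRUG"])
        row = panel.loc["NO_SUCH_DRUG"]
        assert row["a"] == 0 and row["b"] == 0 and bool(row["absent"])

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            dp.ContingencyTable(-1, 2, 3, 4)


class TestComputeSignalMetrics:
    def test_null_table_symmetry(self):
        m = dp.compute_signal_metrics(dp.ContingencyTable(10, 10, 10, 10))
        assert m.ror == pytest.approx(1.0)
        assert m.prr == pytest.approx(1.0)
        assert m.ic == pytest.approx(0.0)
        assert m.chi2 == pytest.approx(0.0)

    def test_worked_example_against_decimal_oracle(self):
        t = dp.ContingencyTable(5, 95, 50, 9850)
        m = dp.compute_signal_metrics(t)
        o = decimal_oracle(5, 95, 50, 9850)
        for field in ("ror", "ror_lcl", "ror_ucl", "prr", "chi2", "rrr", "ic", "ic025", "ebgm", "ebgm05"):
            assert getattr(m, field) == pytest.approx(float(o[field]), rel=1e-10), field
        # frozen round values for the record
        assert round(m.ror, 2) == 10.37
        assert round(m.prr, 1) == 9.9
        assert round(m.chi2, 1) == 36.6
        assert round(m.ic, 2) == 3.18
        assert round(m.ebgm05, 2) == 4.14

    def test_zero_cell_flags_but_fisher_defined(self):
        m = dp.compute_signal_metrics(dp.ContingencyTable(0, 10, 5, 100))
        assert math.isnan(m.ror) and math.isnan(m.ic)
        assert "ror" in m.undefined
        assert 0.0 <= m.fisher_p <= 1.0

    def test_haldane_correction_defines_metrics(self):
        m = dp.compute_signal_metrics(dp.ContingencyTable(0, 10, 5, 100), zero_correction=True)
        assert not math.isnan(m.ror)
        # +0.5 on every cell: ROR = (0.5 * 100.5) / (10.5 * 5.5)
        assert m.ror == pytest.approx((0.5 * 100.5) / (10.5 * 5.5), rel=1e-12)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = dp.ContingencyTable(int(a), int(b), int(c), int(d))
            m, mt = dp.compute_signal_metrics(t), dp.compute_signal_metrics(t.transpose())
            assert m.ror == pytest.approx(mt.ror, rel=1e-12)
            assert m.chi2 == pytest.approx(mt.chi2, rel=1e-12)

    def test_yates_correction_reduces_chi2(self):
        plain = dp.compute_signal_metrics(dp.ContingencyTable(5, 95, 50, 9850))
        yates = dp.compute_signal_metrics(dp.ContingencyTable(5, 95, 50, 9850), yates=True)
        assert yates.chi2 < plain.chi2


class TestEvaluateSignal:
    def test_strong_panel_all_positive(self):
        """A panel like the strongest antibacterial signal (n=758,
        PRR 13.17, chi2 8187.5, ROR LCL 13.90, IC025 3.38) trips all rules."""
        m = dp.SignalMetrics(
            drug="x", n_reports=758, ror=15.03, ror_lcl=13.90, ror_ucl=16.25,
            prr=13.17, chi2=8187.51, rrr=12.82, ic=3.65, ic025=3.38,
            ebgm=12.82, ebgm05=11.86, fisher_p=0.0,
        )
        s = dp.evaluate_signal(m)
        assert s.prr_positive and s.ror_positive and s.ic_positive and s.overall

    def test_count_rule_blocks_prr_only(self):
        m = dp.compute_signal_metrics(dp.ContingencyTable(2, 3, 10, 10000))
        s = dp.evaluate_signal(m)
        assert not s.prr_positive          # n = 2 < 3
        assert s.ror_positive and s.overall  # huge ROR still flags

    def test_null_table_all_negative(self):
        m = dp.compute_signal_metrics(dp.ContingencyTable(10, 10, 10, 10))
        s = dp.evaluate_signal(m)
        assert not (s.prr_positive or s.ror_positive or s.ic_positive or s.overall)


class TestAdjustPvalues:
    def test_bonferroni_closed_form(self):
        out = dp.adjust_pvalues([0.01, 0.02, 0.03], "bonferroni")
        assert np.allclose(out, [0.03, 0.06, 0.09])

    def test_bh_hand_stepup(self):
        # hand-executed step-up: 0.03*3/3=0.03; min(0.03, 0.02*3/2)=0.03; min(.., 0.01*3)=0.03
        out = dp.adjust_pvalues([0.01, 0.02, 0.03], "BH")
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "BH"):
            assert dp.adjust_pvalues([0.2], method)[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dp.adjust_pvalues([0.5, 1.5], "bonferroni")

    def test_order_preserving_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.random(40)
        for method in ("bonferroni", "BH"):
            q = dp.adjust_pvalues(p, method)
            assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
            assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)


class TestVolcano:
    def test_null_point_at_origin(self):
        df = pd.DataFrame({"drug": ["x"], "ror": [1.0], "p_adj_bh": [1.0], "n_reports": [5]})
        v = dp.volcano_table(df)
        assert v["log2_ror"].iloc[0] == 0.0 and v["neg_log10_p_adj"].iloc[0] == 0.0

    def test_direct_evaluation(self):
        df = pd.DataFrame({"drug": ["x"], "ror": [15.03], "p_adj_bh": [1e-10], "n_reports": [758]})
        v = dp.volcano_table(df)
        assert v["log2_ror"].iloc[0] == pytest.approx(math.log2(15.03))
        assert v["neg_log10_p_adj"].iloc[0] == pytest.approx(10.0)

    def test_zero_p_floored(self):
        df = pd.DataFrame({"drug": ["x"], "ror": [2.0], "p_adj_bh": [0.0], "n_reports": [5]})
        v = dp.volcano_table(df)
        assert np.isfinite(v["neg_log10_p_adj"].iloc[0])

    def test_empty(self):
        assert dp.volcano_table(pd.DataFrame()).empty


class TestCompareSources:
    def _panel(self, store, cases, source):
        return dp.signal_panel(cases, store, source=source)

    def test_identical_inputs_fully_corroborated(self, small_store, small_cases):
        p = self._panel(small_store, small_cases, "A")
        comp = dp.compare_sources(p, p)
        pos = comp[comp["overall_positive_a"].fillna(False).astype(bool)]
        assert pos["corroborated"].all()
        assert not comp["discordant"].any()

    def test_one_sided_positive_listed_discordant(self):
        base = dict(n_reports=50, ror=5.0, ror_lcl=3.0, ror_ucl=8.0, prr=4.5, chi2=100.0,
                    ic=2.0, ic025=1.5, ebgm=4.5, ebgm05=3.5, p_adj=1e-5)
        a = pd.DataFrame([{"drug": "X", **base, "overall_positive": True}])
        b = pd.DataFrame([{"drug": "X", **base, "overall_positive": False}])
        comp = dp.compare_sources(a, b)
        assert bool(comp["discordant"].iloc[0]) and not bool(comp["corroborated"].iloc[0])

    def test_shared_planted_signal_corroborated(self):
        panels = []
        for seed, label in ((101, "src-a"), (202, "src-b")):
            cfg = sf.SimConfig(
                n_reports=30_000, drugs=[sf.DrugSpec("SHARED", 0.01, 15.0)],
                background_event_rate=0.02, seed=seed,
            )
            store, _, _ = sf.generate_store(cfg)
            store, _ = fi.deduplicate(store)
            cases = fi.extract_cases(store)
            panels.append(dp.signal_panel(cases, store, source=label))
        comp = dp.compare_sources(*panels)
        assert bool(comp.set_index("drug").loc["SHARED", "corroborated"])


class TestPtComposition:
    def test_single_pt_class_is_100pct(self):
        cases = fi.CaseSet(
            case_ids=frozenset({1, 2}),
            matched_terms={1: {"pneumonitis"}, 2: {"pneumonitis"}},
            suspect_drugs={1: {"MAB1"}, 2: {"MAB2"}},
        )
        out = dp.pt_composition(cases, {"MAB1": "monoclonal antibody", "MAB2": "monoclonal antibody"})
        assert len(out) == 1
        assert out["share"].iloc[0] == pytest.approx(1.0)

    def test_even_split(self):
        cases = fi.CaseSet(
            case_ids=frozenset({1, 2}),
            matched_terms={1: {"a"}, 2: {"b"}},
            suspect_drugs={1: {"D"}, 2: {"D"}},
        )
        out = dp.pt_composition(cases, {"D": "class1"})
        assert sorted(out["share"]) == [0.5, 0.5]

    def test_unmapped_drug_goes_to_other_and_shares_sum_to_one(self, small_cases):
        out = dp.pt_composition(small_cases, {"SIGNALDRUG": "antibacterial"})
        assert "other" in set(out["drug_class"])
        sums = out.groupby("drug_class")["share"].sum()
        assert np.allclose(sums, 1.0)


class TestInvariants:
    @pytest.fixture(scope="class")
    def random_tables(self):
        rng = np.random.default_rng(12345)
        return np.exp(rng.uniform(0, np.log(5000), size=(2000, 4))).astype(int) + 1

    def test_direction_concordance_and_magnitude(self, random_tables):
        for a, b, c, d in random_tables:
            m = dp.compute_signal_metrics(dp.ContingencyTable(int(a), int(b), int(c), int(d)))
            assert np.sign(m.ror - 1) == np.sign(m.prr - 1) == np.sign(m.ic) or m.ror == 1
            if m.ror > 1:
                assert m.ror >= m.prr >= 1.0 - 1e-12

    def test_fisher_matches_enumeration_spot(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0 or (a + b == 0) or (c + d == 0):
                continue
            m = dp.compute_signal_metrics(dp.ContingencyTable(a, b, c, d))
            assert m.fisher_p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12)
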