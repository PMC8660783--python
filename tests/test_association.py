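"""Logistic odds-ratio estimation, subtype/variant-split/sensitivity runs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from panelburden.association import (
    AdjustmentSet,
    build_analysis_table,
    crude_or,
    fit_gene_or,
    run_panel_association,
    run_sensitivity,
    run_subtype_association,
    run_variant_split,
)
from oracles import g_test_p


def table_from_counts(n11, n10, n01, n00, gene="G", study="ABCFS"):
    """Analysis table for a 2x2: exposed/unexposed cases and controls."""
    rows = []
    for case, carrier, n in ((1, True, n11), (1, False, n10), (0, True, n01), (0, False, n00)):
        for i in range(n):
            rows.append({"case": case, f"carrier_{gene}": carrier})
    df = pd.DataFrame(rows)
    df["subject_id"] = [f"S{i}" for i in range(len(df))]
    df["study"] = study
    df["er_status"] = "unknown"
    for cov in ("age", "height", "bmi", "parity", "education", "alcohol"):
        df[cov] = 50.0
    return df.set_index("subject_id", drop=False)


class TestFitGeneOr:
    def test_printed_brca1_counts_match_cross_product(self):
        # 46/1418 exposed/unexposed cases, 6/7405 exposed/unexposed controls
        table = table_from_counts(46, 1418, 6, 7405, gene="BRCA1")
        res = fit_gene_or(table, "BRCA1", AdjustmentSet.unadjusted)
        expected = crude_or(46, 1418, 6, 7405)
        assert expected == pytest.approx(40.0364, abs=5e-4)
        assert res.odds_ratio == pytest.approx(expected, rel=1e-6)
        assert res.ci_low < res.odds_ratio < res.ci_high

    @given(
        n11=st.integers(3, 60), n10=st.integers(20, 400),
        n01=st.integers(3, 60), n00=st.integers(20, 400),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_unadjusted_or_equals_cross_product_property(self, n11, n10, n01, n00):
        table = table_from_counts(n11, n10, n01, n00)
        res = fit_gene_or(table, "G", AdjustmentSet.unadjusted)
        assert res.estimable
        assert res.odds_ratio == pytest.approx(crude_or(n11, n10, n01, n00), rel=1e-6)

    @given(
        n11=st.integers(5, 50), n10=st.integers(30, 300),
        n01=st.integers(5, 50), n00=st.integers(30, 300),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_lrt_p_matches_g_test(self, n11, n10, n01, n00):
        table = table_from_counts(n11, n10, n01, n00)
        res = fit_gene_or(table, "G", AdjustmentSet.unadjusted)
        assert res.p_value == pytest.approx(g_test_p(n11, n10, n01, n00), abs=1e-4)

    def test_zero_control_carriers_not_estimable(self):
        # CDH1-like: one case carrier, none among controls
        table = table_from_counts(1, 1463, 0, 7411, gene="CDH1")
        res = fit_gene_or(table, "CDH1", AdjustmentSet.unadjusted)
        assert not res.estimable
        assert res.odds_ratio is None and res.p_value is None
        assert (res.n_case_carriers, res.n_control_carriers) == (1, 0)

    def test_equal_prevalence_gives_null_or(self):
        table = table_from_counts(50, 950, 50, 950)
        res = fit_gene_or(table, "G", AdjustmentSet.unadjusted)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_wald_ci_structure(self):
        table = table_from_counts(30, 500, 10, 600)
        res = fit_gene_or(table, "G", AdjustmentSet.unadjusted)
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        # Wald CI is symmetric on the log scale
        assert math.log(res.odds_ratio) == pytest.approx(
            (math.log(res.ci_low) + math.log(res.ci_high)) / 2, rel=1e-6
        )

    def test_complete_case_rows_dropped_per_adjustment(self):
        table = table_from_counts(20, 200, 20, 200)
        table.loc[table.index[:50], "age"] = np.nan
        res_full = fit_gene_or(table, "G", AdjustmentSet.unadjusted)
        assert res_full.n_cases + res_full.n_controls == 440
        table["age"] = np.where(
            np.arange(len(table)) < 50, np.nan, 30 + np.arange(len(table)) % 40
        )
        res_age = fit_gene_or(table, "G", AdjustmentSet.age_only)
        assert res_age.n_cases + res_age.n_controls == 390

    def test_collinear_covariates_hard_error(self):
        table = table_from_counts(20, 200, 20, 200)
        rng = np.random.default_rng(0)
        table["age"] = rng.uniform(30, 60, len(table))
        table["height"] = table["age"] * 2.0  # exactly collinear
        with pytest.raises(ValueError, match="collinear"):
            fit_gene_or(table, "G", AdjustmentSet.full)


class TestPanelRun:
    def _two_gene_table(self, rng):
        n = 3000
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "study": "ABCFS",
                "er_status": "unknown",
            }
        ).set_index("subject_id", drop=False)
        df["carrier_STRONG"] = rng.random(n) < 0.05
        df["carrier_NULLG"] = rng.random(n) < 0.05
        logit = -1.0 + 2.0 * df["carrier_STRONG"].to_numpy()
        df["case"] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        for cov in ("age", "height", "bmi", "parity", "education", "alcohol"):
            df[cov] = 50.0
        return df

    def test_strong_effect_sorts_first(self, rng):
        df = self._two_gene_table(rng)
        results = run_panel_association(
            df, ["NULLG", "STRONG"], AdjustmentSet.unadjusted
        )
        assert results[0].gene == "STRONG"
        assert results[0].p_value < results[1].p_value

    def test_all_zero_carriers_all_non_estimable(self):
        table = table_from_counts(0, 100, 0, 100)
        results = run_panel_association(table, ["G"], AdjustmentSet.unadjusted)
        assert not results[0].estimable


class TestSubtype:
    def _er_table(self, rng, beta_neg=2.0, beta_pos=0.0):
        n = 6000
        carrier = rng.random(n) < 0.05
        p_neg = 1 / (1 + np.exp(-(-2.5 + beta_neg * carrier)))
        p_pos = 1 / (1 + np.exp(-(-1.5 + beta_pos * carrier)))
        is_neg = rng.random(n) < p_neg
        is_pos = ~is_neg & (rng.random(n) < p_pos)
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(n)],
                "study": "ABCFS",
                "case": (is_neg | is_pos).astype(int),
                "er_status": np.where(is_neg, "negative", np.where(is_pos, "positive", "unknown")),
                "carrier_G": carrier,
            }
        ).set_index("subject_id", drop=False)
        df.loc[df["case"] == 0, "er_status"] = "unknown"
        for cov in ("age", "height", "bmi", "parity", "education", "alcohol"):
            df[cov] = 50.0
        return df

    def test_subtype_specific_effect_recovered(self, rng):
        df = self._er_table(rng)
        res_neg = run_subtype_association(df, "G", "negative", AdjustmentSet.unadjusted)
        res_pos = run_subtype_association(df, "G", "positive", AdjustmentSet.unadjusted)
        assert res_neg.odds_ratio > 2.5
        assert res_neg.ci_low > 1.0
        assert res_pos.ci_low < 1.0 < res_pos.ci_high

    def test_all_cases_one_subtype_equals_overall_fit(self, rng):
        df = self._er_table(rng, beta_neg=1.0, beta_pos=-50.0)
        df.loc[df["case"] == 1, "er_status"] = "negative"
        res_sub = run_subtype_association(df, "G", "negative", AdjustmentSet.unadjusted)
        res_all = fit_gene_or(df, "G", AdjustmentSet.unadjusted)
        assert res_sub.odds_ratio == pytest.approx(res_all.odds_ratio, rel=1e-9)

    def test_no_subtype_cases_is_error(self):
        table = table_from_counts(5, 50, 5, 50)
        with pytest.raises(ValueError, match="cases"):
            run_subtype_association(table, "G", "negative", AdjustmentSet.unadjusted)


class TestVariantSplit:
    def _split_table(self, n_split_case, n_split_ctrl, n_other_case, n_other_ctrl,
                     n_case, n_ctrl):
        rows = []
        sid = 0

        def add(n, case, stratum):
            nonlocal sid
            for _ in range(n):
                rows.append({"subject_id": f"S{sid}", "case": case, "stratum": stratum})
                sid += 1

        add(n_split_case, 1, "split")
        add(n_other_case, 1, "other")
        add(n_case - n_split_case - n_other_case, 1, "none")
        add(n_split_ctrl, 0, "split")
        add(n_other_ctrl, 0, "other")
        add(n_ctrl - n_split_ctrl - n_other_ctrl, 0, "none")
        df = pd.DataFrame(rows).set_index("subject_id", drop=False)
        df["study"] = "ABCFS"
        df["er_status"] = "unknown"
        df["carrier_G"] = df["stratum"] != "none"
        for cov in ("age", "height", "bmi", "parity", "education", "alcohol"):
            df[cov] = 50.0
        split_ind = pd.Series(df["stratum"] == "split", index=df.index)
        return df, split_ind

    def test_three_cell_table_matches_saturated_mle_oracle(self):
        # saturated 3-group logistic MLE: fitted log-odds equal each cell's
        # observed log-odds, so each stratum OR is its 2x2 cross-product
        df, split_ind = self._split_table(8, 10, 12, 6, 300, 700)
        res = run_variant_split(df, "G", split_ind, AdjustmentSet.unadjusted)
        or_split = crude_or(8, 300 - 8 - 12, 10, 700 - 10 - 6)
        or_other = crude_or(12, 300 - 8 - 12, 6, 700 - 10 - 6)
        assert res.split.odds_ratio == pytest.approx(or_split, rel=1e-5)
        assert res.other.odds_ratio == pytest.approx(or_other, rel=1e-5)
        assert 0.0 < res.equality_p < 1.0

    def test_absent_split_variant_reduces_to_plain_fit(self):
        df, _ = self._split_table(0, 0, 12, 6, 300, 700)
        empty = pd.Series(False, index=df.index)
        res = run_variant_split(df, "G", empty, AdjustmentSet.unadjusted)
        plain = fit_gene_or(df, "G", AdjustmentSet.unadjusted)
        assert res.equality_p is None
        assert not res.split.estimable
        assert res.other.odds_ratio == pytest.approx(plain.odds_ratio, rel=1e-9)

    def test_null_equality_p_is_calibrated(self):
        """Strata simulated with identical true ORs: the equality p-value is
        uniform (KS check at alpha = 0.01 over 200 seeded replicates)."""
        rng = np.random.default_rng(77)
        pvals = []
        while len(pvals) < 200:
            n = 800
            stratum = rng.choice(["none", "split", "other"], size=n, p=[0.84, 0.08, 0.08])
            carrier = stratum != "none"
            p_case = 1 / (1 + np.exp(-(-0.4 + 0.8 * carrier)))
            case = (rng.random(n) < p_case).astype(int)
            df = pd.DataFrame(
                {
                    "subject_id": [f"S{i}" for i in range(n)],
                    "case": case, "stratum": stratum, "carrier_G": carrier,
                    "study": "ABCFS", "er_status": "unknown",
                }
            ).set_index("subject_id", drop=False)
            for cov in ("age", "height", "bmi", "parity", "education", "alcohol"):
                df[cov] = 50.0
            split_ind = pd.Series(df["stratum"] == "split", index=df.index)
            res = run_variant_split(df, "G", split_ind, AdjustmentSet.unadjusted)
            if res.equality_p is not None:
                pvals.append(res.equality_p)
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01


class TestSensitivity:
    def test_exclude_aspree_drops_elderly_rows(self):
        ab = table_from_counts(20, 200, 10, 210)
        asp = table_from_counts(0, 0, 15, 400, study="ASPREE")
        asp.index = [f"A{i}" for i in range(len(asp))]
        asp["subject_id"] = asp.index
        table = pd.concat([ab, asp])
        full = fit_gene_or(table, "G", AdjustmentSet.unadjusted)
        (sens,) = run_sensitivity(table, ["G"], "exclude_aspree", AdjustmentSet.unadjusted)
        assert sens.n_controls == 210 + 10
        assert sens.odds_ratio == pytest.approx(crude_or(20, 200, 10, 210), rel=1e-6)
        assert full.n_controls == 635

    def test_include_multigene_identity_when_no_multigene(self):
        table = table_from_counts(20, 200, 10, 210)
        main = run_panel_association(table, ["G"], AdjustmentSet.unadjusted)
        sens = run_sensitivity(
            table, ["G"], "include_multigene", AdjustmentSet.unadjusted,
            multigene_table=table,
        )
        assert sens[0].odds_ratio == pytest.approx(main[0].odds_ratio, rel=1e-12)

    def test_unknown_mode_rejected(self):
        table = table_from_counts(5, 50, 5, 50)
        with pytest.raises(ValueError, match="unknown sensitivity"):
            run_sensitivity(table, ["G"], "bogus")
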