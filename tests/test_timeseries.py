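"""Differential-expression cascade: normalization, NB test, BH, filters, QC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from helpers import naive_bh

from regnet import (activation_time, bh_adjust, de_test, de_test_all,
                    normalize_libsizes, replicate_correlation, responsive_filter)


class TestNormalizeLibsizes:
    def test_equal_totals_give_unit_factors(self, series_builder):
        series = series_builder({"g1": {("AHL", 0): [10, 10], ("AHL", 60): [10, 10]}})
        assert np.allclose(normalize_libsizes(series), 1.0)

    def test_totals_t_and_4t_give_half_and_two(self, series_builder):
        series = series_builder({"g1": {("AHL", 0): [10, 40]}})
        factors = normalize_libsizes(series)
        assert np.allclose(factors, [0.5, 2.0])

    def test_zero_total_sample_raises(self, series_builder):
        series = series_builder({"g1": {("AHL", 0): [10, 0]}})
        with pytest.raises(ValueError, match="zero total"):
            normalize_libsizes(series)


class TestDETest:
    def test_identical_groups_have_zero_lfc(self, series_builder):
        series = series_builder(
            {"g1": {("AHL", 0): [10, 10, 10], ("AHL", 60): [10, 10, 10]},
             "g2": {("AHL", 0): [5, 6, 7], ("AHL", 60): [5, 6, 7]}})
        res = de_test(series, "AHL", 60, size_factors=pd.Series(
            1.0, index=series.counts.columns))
        assert res.loc["g1", "log2fc"] == 0.0

    def test_fourfold_change_with_continuity_constant(self, series_builder):
        series = series_builder(
            {"g1": {("AHL", 0): [10, 10, 10], ("AHL", 60): [40, 40, 40]},
             "g2": {("AHL", 0): [100, 90, 110], ("AHL", 60): [100, 95, 105]}})
        res = de_test(series, "AHL", 60, size_factors=pd.Series(
            1.0, index=series.counts.columns))
        assert res.loc["g1", "log2fc"] == pytest.approx(math.log2(40.5 / 10.5))

    def test_all_zero_gene_is_null(self, series_builder):
        series = series_builder(
            {"gz": {("AHL", 0): [0, 0, 0], ("AHL", 60): [0, 0, 0]},
             "g2": {("AHL", 0): [10, 12, 9], ("AHL", 60): [11, 10, 12]}})
        res = de_test(series, "AHL", 60)
        assert res.loc["gz", "log2fc"] == 0.0 and res.loc["gz", "pvalue"] == 1.0

    def test_strong_change_is_significant(self, series_builder):
        # unit size factors: with only two genes, total-count normalization
        # would be distorted by g1's large change (composition effect)
        series = series_builder(
            {"g1": {("AHL", 0): [200, 210, 190], ("AHL", 60): [820, 790, 805]},
             "g2": {("AHL", 0): [200, 195, 205], ("AHL", 60): [205, 210, 195]}})
        res = de_test(series, "AHL", 60,
                      size_factors=pd.Series(1.0, index=series.counts.columns))
        assert res.loc["g1", "pvalue"] < 1e-4
        assert res.loc["g2", "pvalue"] > 0.05

    def test_missing_contrast_raises(self, series_builder):
        series = series_builder({"g1": {("AHL", 0): [10, 10], ("AHL", 60): [10, 10]}})
        with pytest.raises(ValueError, match="replicates|contrast"):
            de_test(series, "AHL", 120)

    def test_fdr_at_least_raw_p(self, series_builder, rng):
        data = {f"g{i}": {("AHL", 0): list(rng.poisson(100, 3)),
                          ("AHL", 60): list(rng.poisson(100, 3))} for i in range(50)}
        res = de_test(series_builder(data), "AHL", 60)
        assert (res["fdr"] >= res["pvalue"] - 1e-15).all()
        assert res["fdr"].between(0, 1).all()


class TestBHAdjust:
    def test_textbook_vector(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_enumeration_oracle_and_statsmodels(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 51))
            p = rng.random(n)
            ours = bh_adjust(p)
            assert np.array_equal(ours, np.array(naive_bh(list(p))))
            sm = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, sm, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_in_raw_p_order(self, pvals):
        adj = bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


def _de_table(arm, entries):
    """entries: {gene: {time: (log2fc, fdr)}} -> DEResult-schema frame."""
    rows = []
    for gene, times in entries.items():
        for t, (lfc, fdr) in times.items():
            rows.append({"locus_tag": gene, "arm": arm, "time_min": t,
                         "log2fc": lfc, "pvalue": fdr, "fdr": fdr})
    return pd.DataFrame(rows)


class TestActivationTime:
    def test_first_significant_time_and_direction(self):
        tbl = _de_table("AHL", {"g": {10: (0.2, 0.5), 20: (1.4, 0.01), 60: (2.0, 0.001)}})
        assert activation_time(tbl) == (20, "up")

    def test_never_significant_returns_none(self):
        tbl = _de_table("AHL", {"g": {10: (0.2, 0.5), 60: (0.5, 0.2)}})
        assert activation_time(tbl) == (None, None)

    def test_downregulation_direction(self):
        tbl = _de_table("AHL", {"g": {10: (-1.2, 0.01)}})
        assert activation_time(tbl) == (10, "down")


class TestResponsiveFilter:
    times = (10, 60, 180)

    def build(self, ahl_lfc, dmso_lfc, fdr=0.001):
        """One gene; ahl_lfc per time in self.times, dmso_lfc for 60/180."""
        ahl = _de_table("AHL", {"g": {t: (l, fdr) for t, l in zip(self.times, ahl_lfc)}})
        dmso = _de_table("DMSO", {"g": {60: (dmso_lfc[0], 0.9), 180: (dmso_lfc[1], 0.9)}})
        return ahl, dmso

    def test_ahl_specific_responder_is_responsive(self):
        # strong AHL response, flat control: trajectories separate at 60/180
        calls = responsive_filter(*self.build([2.0, 2.0, 2.0], [0.0, 0.1]))
        row = calls.loc["g"]
        assert row["responsive"] and not row["excluded_by_control"]
        assert row["onset_min"] == 10 and row["direction"] == "up"

    def test_both_arm_change_is_excluded_as_control_artifact(self):
        # gene rises identically in both arms: never separates from control
        calls = responsive_filter(*self.build([2.0, 2.0, 2.0], [1.9, 2.1]))
        row = calls.loc["g"]
        assert row["excluded_by_control"] and not row["responsive"]

    def test_subthreshold_fold_change_not_responsive(self):
        calls = responsive_filter(*self.build([0.8, 0.8, 0.8], [0.0, 0.0]))
        row = calls.loc["g"]
        assert not row["responsive"] and not row["excluded_by_control"]

    def test_late_responder_kept_via_second_control_time(self):
        # onset 180: indistinguishable from control at 60 but separated at 180
        ahl = _de_table("AHL", {"g": {10: (0.0, 0.9), 60: (0.0, 0.9),
                                      180: (2.0, 0.001)}})
        dmso = _de_table("DMSO", {"g": {60: (0.0, 0.9), 180: (0.0, 0.9)}})
        row = responsive_filter(ahl, dmso).loc["g"]
        assert row["responsive"] and row["onset_min"] == 180

    def test_missing_control_contrast_raises(self):
        ahl = _de_table("AHL", {"g": {60: (2.0, 0.001), 180: (2.0, 0.001)}})
        dmso = _de_table("DMSO", {"g": {60: (0.0, 0.9)}})
        with pytest.raises(ValueError, match="control time"):
            responsive_filter(ahl, dmso)

    def test_gene_universe_mismatch_raises(self):
        ahl = _de_table("AHL", {"g": {60: (2.0, 0.001), 180: (2.0, 0.001)}})
        dmso = _de_table("DMSO", {"h": {60: (0.0, 0.9), 180: (0.0, 0.9)}})
        with pytest.raises(ValueError, match="universe"):
            responsive_filter(ahl, dmso)

    def test_relaxing_gates_never_shrinks_responsive_set(self):
        genes = {f"g{i}": {10: (0.5 + 0.2 * i, 0.01 * (i + 1))} for i in range(8)}
        for g in genes.values():
            g[60] = (2.5, 0.5)
            g[180] = (2.5, 0.5)
        ahl = _de_table("AHL", genes)
        dmso = _de_table("DMSO", {g: {60: (0.0, 0.9), 180: (0.0, 0.9)} for g in genes})
        base = set()
        for fdr_max, lfc_min in [(0.01, 1.5), (0.05, 1.5), (0.05, 1.0), (0.2, 0.6)]:
            calls = responsive_filter(ahl, dmso, fdr_max=fdr_max, lfc_min=lfc_min)
            current = set(calls.index[calls["responsive"]])
            assert current >= base
            base = current


class TestReplicateCorrelation:
    def test_identical_replicates_correlate_perfectly(self, series_builder):
        series = series_builder({"g1": {("AHL", 0): [1, 1]},
                                 "g2": {("AHL", 0): [3, 3]},
                                 "g3": {("AHL", 0): [7, 7]}})
        qc = replicate_correlation(series)
        assert qc["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_matches_direct_covariance_formula(self, series_builder):
        series = series_builder({"g1": {("AHL", 0): [1, 3]},
                                 "g2": {("AHL", 0): [3, 7]},
                                 "g3": {("AHL", 0): [7, 15]}})
        x = np.log2(np.array([1, 3, 7]) + 1.0)
        y = np.log2(np.array([3, 7, 15]) + 1.0)
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        qc = replicate_correlation(series)
        assert qc["pearson_r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_replicate_reported_missing(self, series_builder):
        series = series_builder({"g1": {("AHL", 0): [5, 1]},
                                 "g2": {("AHL", 0): [5, 2]},
                                 "g3": {("AHL", 0): [5, 3]}})
        qc = replicate_correlation(series)
        assert np.isnan(qc["pearson_r"].iloc[0])
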