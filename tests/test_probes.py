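"""Probe filtering, probe→gene collapse, and signature restriction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ffpesig.matrix import ExpressionMatrix
from ffpesig.probes import (
    REASON_FOLD_CHANGE,
    REASON_MISSINGNESS,
    ProbeFilterParams,
    collapse_by_mean,
    filter_probes,
    restrict_signature,
    select_max_mean_probe,
)
from ffpesig.resources import signature_genes
from ffpesig.scoring import signature_score


def log2_matrix_from_rows(rows: dict):
    return ExpressionMatrix(pd.DataFrame(rows).T, "log2")


class TestFilterProbes:
    def test_probe_at_exact_20_percent_threshold_retained(self):
        # median 0; |1 - 0| = 1 >= log2(1.5) in exactly 1/5 = 20% of samples
        mat = log2_matrix_from_rows({"p1": [0, 0, 0, 0, 1.0]})
        report = filter_probes(mat)
        assert report.retained_probe_ids == ["p1"]

    def test_probe_below_fold_change_dropped(self):
        # 0.5 < log2(1.5) = 0.58496 everywhere
        mat = log2_matrix_from_rows({"p1": [0, 0, 0, 0, 0.5]})
        report = filter_probes(mat)
        assert report.dropped_probe_ids == {"p1": REASON_FOLD_CHANGE}

    def test_missingness_over_half_dropped_regardless_of_values(self):
        mat = log2_matrix_from_rows({"p1": [np.nan, np.nan, np.nan, 0.0, 9.0]})
        report = filter_probes(mat)
        assert report.dropped_probe_ids == {"p1": REASON_MISSINGNESS}

    def test_exactly_half_missing_is_kept_for_missingness(self):
        mat = log2_matrix_from_rows({"p1": [np.nan, np.nan, 0.0, 5.0]})
        report = filter_probes(mat)
        assert report.retained_probe_ids == ["p1"]

    def test_all_missing_probe_dropped_not_crashed(self):
        mat = log2_matrix_from_rows(
            {"p1": [np.nan, np.nan], "p2": [0.0, 5.0]}
        )
        report = filter_probes(mat, ProbeFilterParams(max_missing_fraction=1.0))
        assert report.dropped_probe_ids["p1"] == REASON_MISSINGNESS
        assert report.retained_probe_ids == ["p2"]

    def test_linear_scale_mode_uses_ratio(self):
        # ratio to median 10: 16/10 = 1.6 >= 1.5 in 1/5 samples
        mat = ExpressionMatrix(
            pd.DataFrame({"p1": [10, 10, 10, 10, 16.0]}).T, "count"
        )
        params = ProbeFilterParams(values_are_log2=False)
        assert filter_probes(mat, params).retained_probe_ids == ["p1"]

    def test_report_is_exhaustive_and_disjoint(self, log2_matrix):
        report = filter_probes(log2_matrix)
        retained, dropped = set(report.retained_probe_ids), set(report.dropped_probe_ids)
        assert retained | dropped == set(log2_matrix.feature_ids)
        assert not retained & dropped

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_limit_behavior_fold_change_near_one(self, seed):
        """fold_change→1+ with full missingness tolerance retains every probe
        having at least one value different from its median."""
        rng = np.random.default_rng(seed)
        vals = np.round(rng.normal(0, 1, size=(10, 6)), 1)
        mat = ExpressionMatrix(pd.DataFrame(vals).astype(float), "log2")
        params = ProbeFilterParams(fold_change=1.0 + 1e-9, max_missing_fraction=1.0)
        report = filter_probes(mat, params)
        for probe in mat.feature_ids:
            row = mat.values.loc[probe]
            expect_retained = (row != row.median()).any()
            assert (probe in report.retained_probe_ids) == expect_retained


class TestCollapseByMean:
    def test_mean_of_two_probes(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"g1_p1": [2.0], "g1_p2": [4.0]}).T,
            "log2",
            {"g1_p1": "g1", "g1_p2": "g1"},
        )
        out = collapse_by_mean(mat)
        assert out.values.loc["g1"].iloc[0] == pytest.approx(3.0)

    def test_single_probe_gene_passes_through(self, log2_matrix):
        fmap = {f: f"gene_{f}" for f in log2_matrix.feature_ids}
        mat = ExpressionMatrix(log2_matrix.values, "log2", fmap)
        out = collapse_by_mean(mat)
        assert np.allclose(out.values.to_numpy(), log2_matrix.values.to_numpy())

    def test_requested_genes_define_output_rows(self, small_cohort):
        sig = small_cohort.config.signature_genes
        out = collapse_by_mean(small_cohort.ff_microarray, sig)
        assert list(out.values.index) == list(sig)
        assert out.values.shape[0] == 18

    def test_gene_without_probes_raises(self, small_cohort):
        with pytest.raises(ValueError, match="NOPE"):
            collapse_by_mean(small_cohort.ff_microarray, ["NOPE"])

    def test_collapse_then_score_equals_score_of_preaveraged(self, rng):
        """Scoring after probe collapse is identical to scoring a matrix that
        was averaged beforehand (composition consistency)."""
        genes = [f"g{i}" for i in range(6)]
        rows, fmap = {}, {}
        for g in genes:
            for p in range(rng.integers(1, 4)):
                pid = f"{g}_p{p}"
                rows[pid] = rng.normal(5, 2, size=5)
                fmap[pid] = g
        mat = ExpressionMatrix(pd.DataFrame(rows).T, "log2", fmap)
        collapsed = collapse_by_mean(mat, genes)
        s1 = signature_score(collapsed, genes).scores
        pre = ExpressionMatrix(collapsed.values.copy(), "log2")
        s2 = signature_score(pre, genes).scores
        assert np.allclose(s1, s2, atol=1e-12)


class TestSelectMaxMeanProbe:
    def test_highest_mean_probe_selected(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"g1_p1": [5.0, 5.2], "g1_p2": [7.2, 7.4]}).T,
            "log2",
            {"g1_p1": "g1", "g1_p2": "g1"},
        )
        out, g2p = select_max_mean_probe(mat, ["g1_p1", "g1_p2"])
        assert g2p == {"g1": "g1_p2"}
        assert out.feature_ids == ["g1_p2"]

    def test_tie_broken_to_lexicographically_smaller_probe(self):
        mat = ExpressionMatrix(
            pd.DataFrame({"g1_pB": [3.0], "g1_pA": [3.0]}).T,
            "log2",
            {"g1_pB": "g1", "g1_pA": "g1"},
        )
        _, g2p = select_max_mean_probe(mat, ["g1_pB", "g1_pA"])
        assert g2p == {"g1": "g1_pA"}

    def test_rows_pass_through_unmodified(self, small_cohort):
        mat = small_cohort.ffpe_microarray
        retained = mat.feature_ids[::2]
        out, g2p = select_max_mean_probe(mat, retained)
        assert set(out.feature_ids) <= set(retained)
        assert len(out.feature_ids) == len(set(g2p))
        for probe in out.feature_ids:
            pd.testing.assert_series_equal(out.values.loc[probe], mat.values.loc[probe])

    def test_empty_retained_set_warns_and_returns_empty(self, small_cohort, caplog):
        with caplog.at_level("WARNING"):
            out, g2p = select_max_mean_probe(small_cohort.ff_microarray, [])
        assert out.n_features == 0 and g2p == {}


class TestRestrictSignature:
    def test_two_dropped_genes_yield_16(self):
        sig = signature_genes()
        available = set(sig) - {"LZTS1", "ZFP106"}
        reduced = restrict_signature(sig, available)
        assert len(reduced) == 16
        assert "LZTS1" not in reduced and "ZFP106" not in reduced
        # order preserved
        assert reduced == [g for g in sig if g in available]

    def test_superset_available_is_identity(self):
        sig = signature_genes()
        assert restrict_signature(sig, set(sig) | {"EXTRA"}) == sig

    def test_single_survivor(self, caplog):
        with caplog.at_level("INFO"):
            reduced = restrict_signature(signature_genes(), {"DUSP4"})
        assert reduced == ["DUSP4"]

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            restrict_signature(["A", "B"], {"C"})
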