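"""NB differential expression: normalization, dispersion, Wald test, calling."""

import numpy as np
import pandas as pd
import pytest

from hybridte import diffexpr as de
from hybridte import synthetic_data as sd

A_COLS = ["A_r1", "A_r2", "A_r3"]
B_COLS = ["B_r1", "B_r2", "B_r3"]


class TestSizeFactors:
    def test_identical_columns_get_unit_factors(self):
        counts = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        sf = de.size_factors_median_of_ratios(counts)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_has_double_factor(self):
        a = pd.Series([10, 20, 30, 40])
        counts = pd.DataFrame({"s1": a, "s2": 2 * a})
        sf = de.size_factors_median_of_ratios(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(2.0)

    def test_families_with_zeros_excluded_from_reference(self):
        # the zero-containing family would otherwise drag s2's factor down
        counts = pd.DataFrame({"s1": [10, 100], "s2": [10, 0]})
        sf = de.size_factors_median_of_ratios(counts)
        assert sf["s1"] == pytest.approx(sf["s2"])

    def test_no_all_positive_family_raises_with_fallback_hint(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            de.size_factors_median_of_ratios(counts)
        sf = de.size_factors_median_of_ratios(counts, pseudo_reference=True)
        assert (sf > 0).all()

    def test_scaling_a_sample_scales_its_factor(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 4)), columns=["s1", "s2", "s3", "s4"]
        )
        sf = de.size_factors_median_of_ratios(counts)
        scaled = counts.copy()
        scaled["s3"] = scaled["s3"] * 5
        sf2 = de.size_factors_median_of_ratios(scaled)
        # factors are defined up to a common constant: ratios scale exactly
        assert sf2["s3"] / sf2["s1"] == pytest.approx(5 * sf["s3"] / sf["s1"], rel=1e-12)
        assert sf2["s2"] / sf2["s1"] == pytest.approx(sf["s2"] / sf["s1"], rel=1e-12)


class TestDispersion:
    def test_constant_counts_have_zero_raw_dispersion(self):
        counts = pd.DataFrame({c: [50, 100] for c in A_COLS})
        sf = pd.Series(1.0, index=A_COLS)
        d = de.estimate_dispersion(counts, sf)
        assert (d["raw"] == 0).all()

    def test_recovers_simulated_dispersion(self):
        counts, _ = sd.gen_two_group_counts(
            n_families=200, frac_de=0.0, dispersion=0.2,
            mean_range=(100.0, 100.0), n_replicates=50, seed=3,
        )
        sf = de.size_factors_median_of_ratios(counts)
        groups = pd.Series(["A"] * 50 + ["B"] * 50, index=counts.columns)
        d = de.estimate_dispersion(counts, sf, groups)
        assert d["alpha"].median() == pytest.approx(0.2, rel=0.5)

    def test_underdispersed_family_is_trend_shrunk_from_zero(self, rng):
        counts = pd.DataFrame(rng.poisson(100, size=(100, 6)), columns=A_COLS + B_COLS)
        counts.iloc[0] = [100, 100, 100, 100, 100, 100]
        sf = pd.Series(1.0, index=counts.columns)
        d = de.estimate_dispersion(counts, sf)
        assert d["raw"].iloc[0] == 0
        assert d["alpha"].iloc[0] >= d["trend"].iloc[0] * 0.99

    def test_single_replicate_group_raises(self):
        counts = pd.DataFrame({"A_r1": [10], "B_r1": [10], "B_r2": [12]})
        sf = pd.Series(1.0, index=counts.columns)
        groups = pd.Series(["A", "B", "B"], index=counts.columns)
        with pytest.raises(ValueError, match="replicate"):
            de.estimate_dispersion(counts, sf, groups)


class TestWald:
    def _fixture(self, rng, n=50):
        counts = pd.DataFrame(rng.poisson(100, size=(n, 6)), columns=A_COLS + B_COLS)
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.DataFrame({"alpha": np.full(n, 1e-10)}, index=counts.index)
        return counts, sf, disp

    def test_identical_groups_give_zero_lfc_p_one(self):
        counts = pd.DataFrame({c: [100, 30] for c in A_COLS + B_COLS})
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.DataFrame({"alpha": [0.05, 0.05]})
        res = de.wald_test(counts[A_COLS], counts[B_COLS], sf, disp)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-10)
        assert np.allclose(res["pvalue"], 1.0, atol=1e-10)

    def test_poisson_limit_matches_poisson_glm(self, rng):
        # alpha -> 0: NB MLE equals the Poisson GLM group-mean estimate
        counts, sf, disp = self._fixture(rng)
        res = de.wald_test(counts[A_COLS], counts[B_COLS], sf, disp, prior_count=0.0)
        lfc_poisson = np.log2(counts[B_COLS].mean(1) / counts[A_COLS].mean(1))
        assert np.abs(res["log2fc"] - lfc_poisson).max() < 1e-6

    def test_swapping_groups_negates_lfc_preserves_p(self, rng):
        counts, sf, _ = self._fixture(rng)
        disp = pd.DataFrame({"alpha": np.full(50, 0.05)}, index=counts.index)
        fwd = de.wald_test(counts[A_COLS], counts[B_COLS], sf, disp)
        rev = de.wald_test(counts[B_COLS], counts[A_COLS], sf, disp)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["pvalue"], rev["pvalue"])

    def test_lfc_recovery_at_simulated_truth(self):
        counts, truth = sd.gen_two_group_counts(
            n_families=500, frac_de=1.0, lfc=2.0, mean_range=(200.0, 200.0),
            dispersion=0.05, seed=9,
        )
        res = de.de_contrast(counts, A_COLS, B_COLS)
        signed = res["log2fc"] * np.sign(truth["true_lfc"])
        assert signed.mean() == pytest.approx(2.0, abs=0.3)

    def test_all_zero_family_not_testable(self):
        counts = pd.DataFrame({c: [0, 100] for c in A_COLS + B_COLS})
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.DataFrame({"alpha": [0.05, 0.05]})
        res = de.wald_test(counts[A_COLS], counts[B_COLS], sf, disp)
        assert np.isnan(res["pvalue"].iloc[0])
        assert np.isfinite(res["pvalue"].iloc[1])

    def test_statistics_stable_under_depth_rescaling(self, rng):
        counts = pd.DataFrame(rng.poisson(300, size=(80, 6)), columns=A_COLS + B_COLS)
        res = de.de_contrast(counts, A_COLS, B_COLS)
        scaled = counts.copy()
        scaled["B_r2"] = scaled["B_r2"] * 4
        res2 = de.de_contrast(scaled, A_COLS, B_COLS)
        assert np.allclose(res["log2fc"], res2["log2fc"], atol=0.05)


class TestBHAndCalling:
    def test_bh_step_up_hand_example(self):
        assert np.allclose(de.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bh_single_and_tied(self):
        assert de.adjust_bh([0.2]) == pytest.approx([0.2])
        assert np.allclose(de.adjust_bh([0.05, 0.05, 0.05]), [0.05, 0.05, 0.05])

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            de.adjust_bh([0.5, 1.5])

    @pytest.mark.parametrize(
        "padj,lfc,status",
        [
            (0.005, 1.2, "over"),
            (0.02, 3.0, "not_de"),  # padj boundary is strict (< 0.01)
            (0.001, -1.0, "under"),  # |lfc| = 1 exactly is DE (inclusive)
            (0.01, 5.0, "not_de"),  # padj exactly at alpha is not DE
            (0.001, 0.9, "not_de"),
        ],
    )
    def test_de_calling_rule(self, padj, lfc, status):
        res = pd.DataFrame({"log2fc": [lfc], "pvalue": [padj], "padj": [padj]})
        assert de.call_de(res)["status"].iloc[0] == status


class TestBias:
    def test_balanced_counts_no_bias(self):
        res = de.bias_test(10, 10)
        assert res.chi2 == 0 and res.pvalue == pytest.approx(1.0)

    @pytest.mark.parametrize("n_over,n_under,chi2", [(15, 5, 5.0), (0, 20, 20.0)])
    def test_gof_statistic_hand_values(self, n_over, n_under, chi2):
        assert de.bias_test(n_over, n_under).chi2 == pytest.approx(chi2)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            de.bias_test(0, 0)


class TestCrossCheck:
    def test_log2fc_agrees_with_independent_nb_implementation(self):
        """Independent route: pydeseq2's NB GLM on the same simulated counts."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, truth = sd.gen_two_group_counts(
            n_families=200, frac_de=0.5, lfc=2.0, seed=21
        )
        res = de.de_contrast(counts, A_COLS, B_COLS)

        metadata = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3}, index=A_COLS + B_COLS
        )
        dds = DeseqDataSet(
            counts=counts.T, metadata=metadata, design="~condition", quiet=True
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        stats.summary()
        ref = stats.results_df["log2FoldChange"]
        corr = np.corrcoef(res["log2fc"], ref.reindex(res.index))[0, 1]
        assert corr > 0.98
        assert np.abs(res["log2fc"] - ref.reindex(res.index)).median() < 0.2
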