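import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from allelic.ase import (FilterThresholds, GeneAseInput, aggregate_gene_counts,
                         bh_fdr, binomial_ase_test, call_ase,
                         expected_major_fraction, filter_het_snvs,
                         filter_rna_counts, wgs_rna_odds_ratio)


def snv_frame(rows):
    """rows of (pos, rna_ref, rna_alt, wgs_raf, wgs_ref_depth, wgs_alt_depth)."""
    return pd.DataFrame(rows, columns=[
        "pos", "rna_ref", "rna_alt", "wgs_raf", "wgs_ref_depth", "wgs_alt_depth"])


def variant_record(**overrides):
    base = dict(chrom="1", pos=100, is_het=True, DP=30.0, QD=5.0, MQ=50.0,
                MQRankSum=0.0, ReadPosRankSum=0.0, FS=5.0)
    base.update(overrides)
    return base


class TestHetSnvFilter:
    def test_clean_het_kept(self):
        kept, log = filter_het_snvs(pd.DataFrame([variant_record()]),
                                    FilterThresholds())
        assert len(kept) == 1 and log["kept"] == 1

    def test_dp_boundary_is_strict(self):
        kept, _ = filter_het_snvs(
            pd.DataFrame([variant_record(DP=15.0), variant_record(DP=16.0)]),
            FilterThresholds())
        assert list(kept["DP"]) == [16.0]

    def test_homozygous_dropped(self):
        kept, log = filter_het_snvs(
            pd.DataFrame([variant_record(is_het=False)]), FilterThresholds())
        assert kept.empty and log["non_het"] == 1

    def test_missing_annotation_dropped_and_logged(self):
        kept, log = filter_het_snvs(
            pd.DataFrame([variant_record(MQRankSum=np.nan)]), FilterThresholds())
        assert kept.empty and log["missing_annotation"] == 1

    def test_missing_annotation_column_errors(self):
        rec = variant_record()
        del rec["FS"]
        with pytest.raises(ValueError, match="FS"):
            filter_het_snvs(pd.DataFrame([rec]), FilterThresholds())

    def test_all_dropped_is_valid_empty(self):
        kept, _ = filter_het_snvs(
            pd.DataFrame([variant_record(FS=80.0)]), FilterThresholds())
        assert kept.empty


class TestRnaFilter:
    def test_total_ten_kept_nine_dropped(self):
        counts = pd.DataFrame({"chrom": "1", "pos": [1, 2],
                               "rna_ref": [6, 5], "rna_alt": [4, 4]})
        kept = filter_rna_counts(counts, FilterThresholds())
        assert list(kept["pos"]) == [1]


class TestAggregation:
    def test_wgs_guided_phasing_on_trisomic_gene(self):
        gene = GeneAseInput("g", snv_frame([
            (1, 30, 15, 0.67, 20, 10),
            (2, 10, 20, 0.33, 10, 20)]), major=2, minor=1)
        agg = aggregate_gene_counts(gene)
        assert (agg.rna_major, agg.rna_minor) == (50, 25)
        assert (agg.wgs_major, agg.wgs_minor) == (40, 20)

    def test_pseudo_phasing_on_disomic_gene(self):
        gene = GeneAseInput("g", snv_frame([(1, 12, 8, 0.5, 15, 15)]),
                            major=1, minor=1)
        agg = aggregate_gene_counts(gene)
        assert (agg.rna_major, agg.rna_minor) == (12, 8)

    def test_tie_goes_to_reference_allele(self):
        gene = GeneAseInput("g", snv_frame([(1, 10, 10, 0.5, 12, 18)]),
                            major=1, minor=1)
        agg = aggregate_gene_counts(gene)
        assert (agg.rna_major, agg.rna_minor) == (10, 10)
        assert (agg.wgs_major, agg.wgs_minor) == (12, 18)  # ref counted major

    def test_raf_half_excluded_on_unbalanced_segment(self):
        gene = GeneAseInput("g", snv_frame([
            (1, 30, 15, 0.5, 20, 20), (2, 30, 15, 0.7, 25, 12)]),
            major=2, minor=1)
        agg = aggregate_gene_counts(gene)
        assert agg.n_skipped == 1 and agg.n_snvs == 1
        assert (agg.rna_major, agg.rna_minor) == (30, 15)

    def test_invariant_to_snv_order(self):
        rng = np.random.default_rng(4)
        rows = [(i, int(rng.integers(0, 40)), int(rng.integers(0, 40)),
                 float(rng.choice([0.3, 0.7])), 20, 10) for i in range(8)]
        gene = GeneAseInput("g", snv_frame(rows), major=2, minor=1)
        shuffled = GeneAseInput("g", snv_frame(rows[::-1]), major=2, minor=1)
        a, b = aggregate_gene_counts(gene), aggregate_gene_counts(shuffled)
        assert (a.rna_major, a.rna_minor) == (b.rna_major, b.rna_minor)

    def test_missing_segment_errors(self):
        with pytest.raises(ValueError, match="segment"):
            aggregate_gene_counts(GeneAseInput("g", snv_frame([])))


class TestExpectedFraction:
    @pytest.mark.parametrize("major,minor,expected", [
        (1, 1, 0.5), (2, 1, 2 / 3), (3, 1, 0.75)])
    def test_copy_ratio(self, major, minor, expected):
        assert expected_major_fraction(major, minor) == pytest.approx(expected)

    def test_loh_and_empty_rejected(self):
        with pytest.raises(ValueError):
            expected_major_fraction(2, 0)
        with pytest.raises(ValueError):
            expected_major_fraction(0, 0)


class TestBinomialTest:
    def test_mode_gives_one(self):
        assert binomial_ase_test(5, 10, 0.5) == 1.0

    def test_extreme_tail_exact(self):
        assert binomial_ase_test(10, 10, 0.5) == pytest.approx(
            2 * 0.5 ** 10, abs=1e-15)

    @pytest.mark.parametrize("k", range(13))
    def test_matches_exact_reference_at_asymmetric_null(self, k):
        ours = binomial_ase_test(k, 12, 2 / 3)
        ref = binomtest(k, 12, 2 / 3, alternative="two-sided").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(1, 60), st.data())
    def test_symmetric_null_is_symmetric(self, n, data):
        k = data.draw(st.integers(0, n))
        assert binomial_ase_test(k, n, 0.5) == binomial_ase_test(n - k, n, 0.5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_ase_test(0, 0, 0.5)
        with pytest.raises(ValueError):
            binomial_ase_test(3, 2, 0.5)
        with pytest.raises(ValueError):
            binomial_ase_test(1, 2, 1.0)


class TestBhFdr:
    def test_single_value(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 200))
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), ref, atol=1e-12)

    def test_stable_under_permutation(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_monotone_in_p_after_sorting(self):
        rng = np.random.default_rng(9)
        p = np.sort(rng.uniform(size=100))
        q = bh_fdr(p)
        assert np.all(np.diff(q) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))


class TestOddsRatio:
    def test_identical_ratios_give_one(self):
        assert wgs_rna_odds_ratio(20, 10, 20, 10) == pytest.approx(1.0)

    def test_pseudocount_arithmetic(self):
        assert wgs_rna_odds_ratio(40, 10, 20, 10) == pytest.approx(
            (40.5 / 10.5) / (20.5 / 10.5))

    def test_zero_counts_stay_finite(self):
        orr = wgs_rna_odds_ratio(10, 0, 10, 10)
        assert np.isfinite(orr) and orr > 1


class TestCallAse:
    def gene(self, gid, ref, alt, major, minor, raf=0.5, wgs=(20, 20), cpm=10.0):
        return GeneAseInput(gid, snv_frame([(1, ref, alt, raf, *wgs)]),
                            major=major, minor=minor, cpm=cpm)

    def test_trisomic_gene_at_copy_ratio_is_cnv_driven(self):
        res, _ = call_ase([self.gene("g1", 66, 34, 2, 1, raf=0.67, wgs=(40, 20))])
        assert res["ase_class"].iloc[0] == "CNV_DRIVEN_ASE"

    def test_balanced_disomic_gene(self):
        res, _ = call_ase([self.gene("g1", 50, 50, 1, 1)])
        assert res["ase_class"].iloc[0] == "BALANCED"

    def test_extreme_disomic_imbalance_is_cnv_independent(self):
        res, _ = call_ase([self.gene("g1", 95, 5, 1, 1)])
        row = res.iloc[0]
        assert row["ase_class"] == "CNV_INDEPENDENT_ASE"
        assert row["odds_ratio"] > 2

    def test_trisomic_gene_off_copy_ratio_is_cnv_independent(self):
        res, _ = call_ase([self.gene("g1", 97, 3, 2, 1, raf=0.67, wgs=(40, 20))])
        assert res["ase_class"].iloc[0] == "CNV_INDEPENDENT_ASE"

    def test_low_cpm_not_testable(self):
        res, log = call_ase([self.gene("g1", 95, 5, 1, 1, cpm=0.5)])
        assert res["ase_class"].iloc[0] == "NOT_TESTABLE"
        assert log["low_cpm"] == 1

    def test_loh_segment_not_testable(self):
        res, log = call_ase([self.gene("g1", 95, 5, 2, 0)])
        assert res["ase_class"].iloc[0] == "NOT_TESTABLE"
        assert log["loh_segment"] == 1

    def test_unmapped_gene_not_testable(self):
        res, log = call_ase([GeneAseInput("g1", snv_frame([(1, 50, 50, 0.5, 20, 20)]))])
        assert res["ase_class"].iloc[0] == "NOT_TESTABLE"
        assert log["no_segment"] == 1

    def test_low_rna_coverage_not_testable(self):
        res, log = call_ase([self.gene("g1", 5, 4, 1, 1)])
        assert res["ase_class"].iloc[0] == "NOT_TESTABLE"
        assert log["no_covered_snv"] == 1

    def test_output_sorted_and_q_monotone(self):
        genes = [self.gene(f"g{i}", 50 + 5 * i, 50 - 5 * i, 1, 1)
                 for i in range(8)]
        res, _ = call_ase(genes[::-1])
        assert list(res["gene_id"]) == sorted(res["gene_id"])
        tested = res.dropna(subset=["p_model1"]).sort_values("p_model1")
        assert np.all(np.diff(tested["q_model1"]) >= -1e-12)
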