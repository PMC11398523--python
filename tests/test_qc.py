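"""Exome/array QC filters: thresholds, outlier detection, sex inference,
PCA-based ancestry assignment, and the exact HWE test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bgeeval.io_formats import MISSING, ParameterError
from bgeeval.qc import (ArrayQCThresholds, GenotypeQCThresholds,
                        SampleCoverageThresholds, array_qc, assign_ancestry,
                        filter_genotypes, filter_sample_coverage, filter_sites,
                        hwe_exact_test, hwe_exact_test_bruteforce,
                        hwe_normalized_pca, infer_sex, ld_prune,
                        mad_outlier_filter)


class TestGenotypeFilters:
    def make_single(self, g, dp, gq, ad):
        arr = lambda v: np.array([[v]])
        return filter_genotypes(arr(g), arr(dp), arr(gq),
                                arr(ad[0]), arr(ad[1]))

    def test_good_het_kept(self):
        out, rep = self.make_single(1, 30, 99, (15, 15))
        assert out[0, 0] == 1 and rep["removed_total"] == 0

    def test_low_allele_balance_het_removed(self):
        out, rep = self.make_single(1, 30, 99, (27, 3))
        assert out[0, 0] == MISSING and rep["het_allele_balance"] == 1

    def test_homalt_allele_balance_removed(self):
        out, rep = self.make_single(2, 20, 99, (5, 15))
        assert out[0, 0] == MISSING and rep["homalt_allele_balance"] == 1

    def test_depth_and_quality_thresholds(self):
        out, rep = self.make_single(1, 9, 99, (5, 4))
        assert out[0, 0] == MISSING and rep["low_dp"] == 1
        out, rep = self.make_single(1, 10, 19, (5, 5))
        assert out[0, 0] == MISSING and rep["low_gq"] == 1
        out, _ = self.make_single(1, 10, 20, (5, 5))
        assert out[0, 0] == 1  # both thresholds exactly met pass

    def test_missing_ad_leaves_ab_rules_unevaluated(self):
        out, rep = filter_genotypes(np.array([[1]]), np.array([[30]]),
                                    np.array([[99]]), np.array([[np.nan]]),
                                    np.array([[np.nan]]))
        assert out[0, 0] == 1
        assert rep["ab_unevaluated_missing_ad"] == 1

    def test_idempotent_on_filtered_output(self, rng):
        n = 300
        g = rng.integers(0, 3, (10, n)).astype(np.int8)
        dp = rng.integers(0, 40, (10, n))
        gq = rng.integers(0, 100, (10, n))
        alt = rng.integers(0, 20, (10, n))
        ref = rng.integers(0, 20, (10, n))
        once, _ = filter_genotypes(g, dp, gq, ref, alt)
        twice, rep = filter_genotypes(once, dp, gq, ref, alt)
        assert np.array_equal(once, twice)
        assert rep["removed_total"] == 0

    def test_reversed_ab_bounds_rejected(self):
        with pytest.raises(ParameterError):
            GenotypeQCThresholds(het_ab_range=(0.8, 0.2))


class TestSiteFilters:
    @pytest.mark.parametrize(
        "n_alleles,vqsr,lcr,target,kept",
        [(2, True, False, True, True),     # clean biallelic site
         (7, True, False, True, False),    # >6 alleles
         (2, False, False, True, False),   # VQSR fail
         (2, True, True, True, False),     # LCR only: disjunctive removal
         (2, True, False, False, False),   # off-target
         (6, True, False, True, True)])    # 6 alleles allowed
    def test_disjunctive_rule_enumeration(self, n_alleles, vqsr, lcr, target,
                                          kept):
        from bgeeval.io_formats import make_site_table
        sites = make_site_table(["chr1"], [100], af=[0.1])
        out, keep = filter_sites(sites, [n_alleles], [vqsr], [lcr], [target])
        assert keep[0] == kept


class TestSampleCoverage:
    def rec(self, **kw):
        base = dict(exome_fraction_10x=0.95, wgs_coverage=2.1,
                    chimera_rate=0.01, contamination_rate=0.01)
        base.update(kw)
        return pd.DataFrame([base])

    def test_clean_sample_passes(self):
        assert filter_sample_coverage(self.rec())["passed"].iloc[0]

    @pytest.mark.parametrize("field,value,reason", [
        ("exome_fraction_10x", 0.89, "exome_fraction"),
        ("wgs_coverage", 0.9, "wgs_coverage"),
        ("chimera_rate", 0.06, "chimera"),
        ("contamination_rate", 0.06, "contamination")])
    def test_failures_carry_reason(self, field, value, reason):
        out = filter_sample_coverage(self.rec(**{field: value}))
        assert not out["passed"].iloc[0]
        assert out["reasons"].iloc[0] == reason

    @pytest.mark.parametrize("field,value", [
        ("exome_fraction_10x", 0.90), ("wgs_coverage", 1.0),
        ("chimera_rate", 0.05), ("contamination_rate", 0.05)])
    def test_boundaries_pass(self, field, value):
        assert filter_sample_coverage(self.rec(**{field: value}))["passed"].iloc[0]


class TestMadOutliers:
    def test_identical_values_skip_zero_mad(self):
        m = pd.DataFrame({"x": np.ones(20)})
        passed, flags = mad_outlier_filter(m, np.zeros(20))
        assert passed.all() and not flags.any().any()

    def test_degenerate_stratum_with_one_extreme(self):
        vals = [0.0] * 9 + [100.0]
        m = pd.DataFrame({"x": vals})
        passed, _ = mad_outlier_filter(m, np.zeros(10))
        assert passed.all()  # MAD is 0 -> metric skipped

    def test_planted_outlier_flagged_low_false_rate(self, rng):
        x = rng.normal(size=1000)
        x[0] = 10.0
        passed, flags = mad_outlier_filter(pd.DataFrame({"x": x}),
                                           np.zeros(1000))
        assert not passed.iloc[0]
        assert flags["x"].iloc[1:].mean() < 0.02

    def test_small_stratum_skipped(self):
        m = pd.DataFrame({"x": [0, 0, 0, 0, 100.0]})
        passed, _ = mad_outlier_filter(m, np.zeros(5))
        assert passed.all()

    def test_median_center_switch(self, rng):
        x = np.concatenate([rng.normal(size=200), [50.0]])
        for center in ("mean", "median"):
            passed, _ = mad_outlier_filter(pd.DataFrame({"x": x}),
                                           np.zeros(201), center=center)
            assert not passed.iloc[-1]


class TestSexInference:
    def test_hemizygous_male_coded_diploid(self):
        p = np.full(100, 0.3)
        rng = np.random.default_rng(0)
        g = 2 * (rng.random((5, 100)) < p).astype(int)  # no hets
        f, labels = infer_sex(g, p)
        assert np.allclose(f, 1.0)
        assert (labels == "male").all()

    def test_female_at_hwe(self, rng):
        p = rng.uniform(0.1, 0.5, 500)
        g = (rng.random((20, 500)) < p).astype(int) + \
            (rng.random((20, 500)) < p).astype(int)
        f, labels = infer_sex(g, p)
        assert np.all(np.abs(f) < 0.2)
        assert (labels == "female").all()

    def test_exact_threshold_undetermined(self):
        # construct a sample whose F is exactly 0.6: E_het=0.5 per site,
        # 10 of 25 sites het -> O/E = 10/12.5 = 0.8 ... use direct algebra:
        # with p=0.5 at 25 sites, E_het=12.5; O_het=5 -> F=0.6
        p = np.full(25, 0.5)
        g = np.zeros((1, 25), dtype=int)
        g[0, :5] = 1
        f, labels = infer_sex(g, p)
        assert f[0] == pytest.approx(0.6)
        assert labels[0] == "undetermined"

    def test_no_sites_rejected(self):
        with pytest.raises(ParameterError):
            infer_sex(np.empty((3, 0)), np.empty(0))


class TestPca:
    def two_pop_genotypes(self, rng, n_per=60, m=300):
        p1 = rng.uniform(0.05, 0.3, m)
        p2 = rng.uniform(0.7, 0.95, m)
        g1 = rng.binomial(2, p1, (n_per, m))
        g2 = rng.binomial(2, p2, (n_per, m))
        return np.vstack([g1, g2])

    def test_pc1_separates_populations(self, rng):
        g = self.two_pop_genotypes(rng)
        scores, _, _, _ = hwe_normalized_pca(g)
        pc1_a, pc1_b = scores[:60, 0], scores[60:, 0]
        # the two populations occupy disjoint PC1 ranges
        assert max(pc1_a.max(), pc1_b.max()) > \
            min(pc1_a.min(), pc1_b.min())  # sanity: nonconstant
        assert pc1_a.max() < pc1_b.min() or pc1_b.max() < pc1_a.min()

    def test_duplicate_samples_identical_scores(self, rng):
        g = self.two_pop_genotypes(rng)
        g[1] = g[0]
        scores, _, _, _ = hwe_normalized_pca(g)
        assert np.allclose(scores[0], scores[1], atol=1e-9)

    def test_npcs_capped_at_rank(self, rng):
        g = rng.binomial(2, 0.4, (5, 50))
        scores, loadings, _, _ = hwe_normalized_pca(g, n_pcs=30)
        assert scores.shape[1] <= 5

    def test_deterministic_sign_convention(self, rng):
        g = self.two_pop_genotypes(rng)
        s1, l1, _, _ = hwe_normalized_pca(g)
        s2, l2, _, _ = hwe_normalized_pca(g.copy())
        assert np.allclose(s1, s2)

    def test_constant_sites_dropped(self, rng):
        g = self.two_pop_genotypes(rng)
        g[:, 0] = 2
        _, _, _, dropped = hwe_normalized_pca(g)
        assert dropped >= 1


class TestLdPrune:
    def test_duplicate_column_dropped(self, rng):
        g = rng.binomial(2, 0.4, (200, 5))
        g[:, 2] = g[:, 1]
        pos = np.arange(5) * 1000
        kept = ld_prune(g, pos, window_bp=10_000, r2_max=0.5)
        assert 1 in kept and 2 not in kept

    def test_independent_sites_mostly_retained(self, rng):
        g = rng.binomial(2, 0.4, (1000, 100))
        pos = np.arange(100) * 1000
        kept = ld_prune(g, pos, window_bp=100_000, r2_max=0.2)
        assert len(kept) >= 99

    def test_zero_window_retains_all(self, rng):
        g = rng.binomial(2, 0.4, (50, 20))
        g[:, 3] = g[:, 2]
        kept = ld_prune(g, np.arange(20), window_bp=0, r2_max=0.2)
        assert len(kept) == 20


class TestAssignAncestry:
    def test_coincident_cluster_probability_one(self, rng):
        ref = np.vstack([rng.normal(0, 0.01, (60, 10)),
                         rng.normal(5, 0.01, (60, 10))])
        labels = ["A"] * 60 + ["B"] * 60
        out = assign_ancestry(ref[:1], ref, labels)
        assert out.loc[0, "label"] == "A"
        assert out.loc[0, "probability"] == 1.0

    def test_equidistant_sample_unassigned(self, rng):
        a = rng.normal(0, 1e-6, (25, 10)) + np.r_[np.ones(1), np.zeros(9)]
        b = rng.normal(0, 1e-6, (25, 10)) - np.r_[np.ones(1), np.zeros(9)]
        ref = np.vstack([a, b])
        labels = ["A"] * 25 + ["B"] * 25
        out = assign_ancestry(np.zeros((1, 10)), ref, labels)
        assert out.loc[0, "label"] is None
        assert out.loc[0, "probability"] == pytest.approx(0.5)

    def test_zero_threshold_assigns_everyone(self, rng):
        ref = rng.normal(size=(80, 10))
        labels = ["A"] * 40 + ["B"] * 40
        out = assign_ancestry(rng.normal(size=(5, 10)), ref, labels,
                              threshold=0.0)
        assert out["label"].notna().all()


class TestHweExact:
    @pytest.mark.parametrize("het,hom_rare,hom_common", [
        (0, 0, 50), (5, 2, 10), (0, 5, 5), (10, 0, 0), (3, 1, 40),
        (20, 10, 20), (1, 0, 1), (7, 7, 7)])
    def test_matches_bruteforce_enumeration(self, het, hom_rare, hom_common):
        got = hwe_exact_test(het, hom_rare, hom_common)
        want = hwe_exact_test_bruteforce(het, hom_rare, hom_common)
        assert got == pytest.approx(want, rel=1e-9)

    @given(st.integers(0, 25), st.integers(0, 12), st.integers(0, 12))
    def test_property_matches_bruteforce(self, het, hom_rare, hom_common):
        if het + hom_rare + hom_common == 0:
            return
        got = hwe_exact_test(het, hom_rare, hom_common)
        want = hwe_exact_test_bruteforce(het, hom_rare, hom_common)
        assert got == pytest.approx(want, rel=1e-9)


class TestArrayQC:
    def make_clean(self, rng, n=60, m=500):
        # enough sites that per-sample FHET noise stays well inside 0.2
        p = rng.uniform(0.2, 0.5, m)
        return rng.binomial(2, p, (n, m)).astype(np.int8)

    def test_perfect_data_retained(self, rng):
        g = self.make_clean(rng)
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        samp, site, _ = array_qc(g, is_case=labels)
        assert samp.all() and site.all()

    def test_low_call_rate_snp_removed_in_stage_one(self, rng):
        g = self.make_clean(rng)
        g[:4, 0] = MISSING  # 93% call rate at 60 samples
        samp, site, rep = array_qc(g)
        assert not site[0]
        assert rep["snp_call_rate_95"] == 1

    def test_hwe_violating_control_snp_removed(self, rng):
        g = self.make_clean(rng, n=100)
        g[:, 0] = 1  # all het: extreme HWE violation, p << 1e-6
        labels = np.zeros(100, bool)
        samp, site, rep = array_qc(g, is_case=labels)
        assert not site[0]
        assert rep["hwe_controls"] >= 1

    def test_sex_discordant_sample_removed(self, rng):
        g = self.make_clean(rng)
        rep_sex = np.array(["female"] * 60, dtype=object)
        inf_sex = rep_sex.copy()
        inf_sex[3] = "male"
        samp, _, rep = array_qc(g, reported_sex=rep_sex, inferred_sex=inf_sex)
        assert not samp[3] and samp.sum() == 59
        assert rep["sample_sex_discordant"] == 1

    def test_differential_missingness_removed(self, rng):
        g = self.make_clean(rng, n=100)
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        # 4% missing in cases vs 0 in controls: passes both call-rate
        # stages (98% overall) but fails the 2% differential cutoff
        g[:2, 1] = MISSING
        samp, site, rep = array_qc(g, is_case=labels)
        assert not site[1]
        assert rep["differential_missingness"] >= 1
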