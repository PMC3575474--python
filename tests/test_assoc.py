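import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixscan.assoc import (
    AssocError,
    SnpCounts,
    allelic_test,
    conditional_test,
    genotype_model_fit,
    haplotype_em,
    hwe_chi2_p,
    ld_pairwise,
    logistic_adjusted,
    meta_fixed_effects,
    or_from_freqs,
    qc_filter,
)

from oracles import haplotype_ml_direct


def simulate_counts(rng, n_case, n_ctrl, freq, or_per_allele=1.0):
    """Genotype counts under HWE in controls and multiplicative risk."""
    geno_probs = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq ** 2])
    ctrl = rng.multinomial(n_ctrl, geno_probs)
    w = geno_probs * or_per_allele ** np.arange(3)
    case = rng.multinomial(n_case, w / w.sum())
    return SnpCounts(tuple(case), tuple(ctrl))


class TestAllelicTest:
    def test_equal_frequencies_give_unit_or(self):
        res = allelic_test(SnpCounts((25, 50, 25), (25, 50, 25)))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0)
        assert res.ci_low < 1 < res.ci_high

    def test_counted_allele_swap_inverts_or(self):
        c = SnpCounts((10, 40, 50), (30, 40, 30))
        swapped = SnpCounts((50, 40, 10), (30, 40, 30), counted_allele="A")
        r1, r2 = allelic_test(c), allelic_test(swapped)
        assert r1.odds_ratio * r2.odds_ratio == pytest.approx(1.0, abs=1e-12)

    def test_zero_cell_gets_haldane_correction(self):
        res = allelic_test(SnpCounts((0, 0, 50), (50, 0, 0)))
        assert "haldane_correction" in res.flags
        assert np.isfinite(res.odds_ratio)

    def test_monomorphic_flagged(self):
        res = allelic_test(SnpCounts((50, 0, 0), (60, 0, 0)))
        assert "monomorphic" in res.flags
        assert np.isnan(res.odds_ratio)

    def test_type_one_error_calibration(self):
        # 1-df chi-square without continuity correction, N=500/500
        rng = np.random.default_rng(17)
        n_sim, n = 10_000, 500
        freq = 0.3
        case_g = rng.binomial(2, freq, size=(n_sim, n))
        ctrl_g = rng.binomial(2, freq, size=(n_sim, n))
        a = case_g.sum(axis=1)
        c = ctrl_g.sum(axis=1)
        b, d = 2 * n - a, 2 * n - c
        tot = a + b + c + d
        chi2 = tot * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        rate = np.mean(chi2 > 3.841458820694124)
        assert abs(rate - 0.05) < 0.01

    def test_or_from_published_frequencies(self):
        assert round(or_from_freqs(0.374, 0.428), 2) == 0.80


class TestGenotypeModelFit:
    def test_dominant_collapse_hand_example(self):
        # carriers 90/10 in cases vs 60/40 in controls: OR = 6.0
        fits = genotype_model_fit(SnpCounts((10, 40, 50), (40, 40, 20)))
        assert fits.loc["dominant", "odds_ratio"] == pytest.approx(6.0)

    def test_aic_recovers_dominant_generator(self):
        rng = np.random.default_rng(18)
        hits = 0
        for _ in range(40):
            freq = 0.3
            probs = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq ** 2])
            w = probs * np.array([1.0, 3.0, 3.0])  # dominant OR=3
            case = rng.multinomial(1000, w / w.sum())
            ctrl = rng.multinomial(1000, probs)
            fits = genotype_model_fit(SnpCounts(tuple(case), tuple(ctrl)))
            hits += fits.index[fits["best"]][0] == "dominant"
        assert hits >= 28

    def test_null_data_rarely_prefers_saturated_model(self):
        rng = np.random.default_rng(19)
        saturated = 0
        for _ in range(60):
            counts = simulate_counts(rng, 400, 400, 0.4)
            fits = genotype_model_fit(counts)
            saturated += fits.index[fits["best"]][0] == "genotypic"
        assert saturated < 30

    def test_complete_separation_flagged(self):
        fits = genotype_model_fit(SnpCounts((0, 0, 100), (100, 0, 0)))
        assert any("separation" in f for f in fits["flags"].loc[["additive"]])

    def test_additive_matches_allelic_or_direction(self):
        counts = SnpCounts((20, 60, 40), (50, 50, 20))
        fits = genotype_model_fit(counts)
        allelic = allelic_test(counts)
        assert (fits.loc["additive", "odds_ratio"] > 1) == (allelic.odds_ratio > 1)


class TestLogisticAdjusted:
    def test_constant_covariate_matches_unadjusted(self):
        rng = np.random.default_rng(20)
        dosage = rng.binomial(2, 0.4, 400)
        pheno = rng.random(400) < 1 / (1 + np.exp(-(-0.5 + 0.4 * dosage)))
        res_adj = logistic_adjusted(dosage, pheno, np.full(400, 0.3))
        res_unadj = logistic_adjusted(dosage, pheno)
        assert res_adj["beta"] == pytest.approx(res_unadj["beta"], abs=1e-6)

    def test_type_one_error_when_phenotype_driven_by_covariate(self):
        rng = np.random.default_rng(21)
        pvals = []
        for _ in range(60):
            cov = rng.uniform(0, 1, 500)
            dosage = rng.binomial(2, 0.3, 500)
            pheno = rng.random(500) < 1 / (1 + np.exp(-(-1 + 2 * cov)))
            pvals.append(logistic_adjusted(dosage, pheno, cov)["p_value"])
        assert np.mean(np.array(pvals) < 0.05) < 0.15

    def test_confounding_by_ancestry_is_reduced(self):
        # ancestry drives both dosage and phenotype; adjustment shrinks beta
        rng = np.random.default_rng(22)
        shrunk = 0
        for _ in range(30):
            M = rng.uniform(0, 1, 600)
            dosage = rng.binomial(2, 0.2 + 0.6 * M)
            pheno = rng.random(600) < 1 / (1 + np.exp(-(-1.5 + 2.5 * M)))
            adj = abs(logistic_adjusted(dosage, pheno, M)["beta"])
            unadj = abs(logistic_adjusted(dosage, pheno)["beta"])
            shrunk += adj < unadj
        assert shrunk >= 27


class TestHaplotypeEM:
    def test_single_snp_frequencies_equal_allele_frequencies(self):
        g = np.array([[0], [1], [1], [2], [2], [2]])
        res = haplotype_em(g)
        assert res.frequency_of((1,)) == pytest.approx(8 / 12, abs=1e-9)

    def test_double_homozygotes_are_phase_unambiguous(self):
        g = np.array([[0, 0], [2, 2], [2, 2], [0, 2]])
        res = haplotype_em(g)
        assert res.frequency_of((1, 1)) == pytest.approx(4 / 8, abs=1e-7)
        assert res.frequency_of((0, 0)) == pytest.approx(2 / 8, abs=1e-7)
        assert res.frequency_of((0, 1)) == pytest.approx(2 / 8, abs=1e-7)

    def test_loglik_non_decreasing(self):
        rng = np.random.default_rng(23)
        g = rng.integers(0, 3, size=(30, 3))
        res = haplotype_em(g)
        assert np.all(np.diff(res.loglik_trace) >= -1e-9)
        assert res.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_direct_likelihood_maximisation(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(rng.integers(6, 20), 2))
        res = haplotype_em(g)
        direct = haplotype_ml_direct(g)
        assert res.loglik == pytest.approx(direct, abs=1e-6)

    def test_too_many_snps_rejected(self):
        with pytest.raises(AssocError):
            haplotype_em(np.zeros((4, 5), dtype=int))

    def test_all_missing_individuals_dropped(self):
        g = np.array([[1, 1], [-1, -1], [2, 0]])
        res = haplotype_em(g)
        assert list(res.kept) == [0, 2]


class TestConditionalTest:
    def test_conditioning_on_target_is_an_error(self):
        pheno = np.array([0, 1] * 20)
        dosage = np.tile([0, 1, 2, 1], 10)
        with pytest.raises(AssocError):
            conditional_test(pheno, dosage, dosage)

    def test_causal_snp_explains_tag_signal(self):
        rng = np.random.default_rng(24)
        resolved = 0
        for _ in range(30):
            hap_freqs = {(1, 1): 0.35, (0, 0): 0.55, (1, 0): 0.05, (0, 1): 0.05}
            haps = list(hap_freqs)
            pr = np.array(list(hap_freqs.values()))
            idx = rng.choice(4, size=(1200, 2), p=pr)
            g = np.array(haps)[idx].sum(axis=1)  # (n, 2): causal, tag
            logit = -1.2 + 0.8 * g[:, 0]
            pheno = rng.random(1200) < 1 / (1 + np.exp(-logit))
            res = conditional_test(pheno, g[:, 1], g[:, 0])
            resolved += res["p_value"] > 0.05
        assert resolved >= 27

    def test_independent_causals_stay_significant(self):
        rng = np.random.default_rng(25)
        kept = 0
        for _ in range(20):
            g = rng.binomial(2, 0.4, size=(1500, 2))
            logit = -1.5 + 0.6 * g[:, 0] + 0.6 * g[:, 1]
            pheno = rng.random(1500) < 1 / (1 + np.exp(-logit))
            res = conditional_test(pheno, g[:, 1], g[:, 0])
            kept += res["p_value"] < 0.05
        assert kept >= 18

    def test_haplotype_mode_runs(self):
        rng = np.random.default_rng(26)
        g = rng.integers(0, 3, size=(200, 2))
        hap = haplotype_em(g)
        pheno = rng.random(200) < 0.4
        res = conditional_test(pheno, hap, g[:, 0], mode="haplotype")
        assert 0 <= res["p_value"] <= 1 and res["df"] >= 1


class TestLdPairwise:
    def test_perfect_coupling(self):
        g = np.repeat([[0, 0], [1, 1], [2, 2]], [20, 20, 20], axis=0)
        res = ld_pairwise(g[:, 0], g[:, 1])
        assert res["r2"] == pytest.approx(1.0, abs=1e-6)
        assert res["d_prime"] == pytest.approx(1.0, abs=1e-6)

    def test_balanced_coupling_hand_example(self):
        # haplotypes (AB, Ab, aB, ab) = (0.5, 0, 0, 0.5): D = 0.25, r2 = 1
        g = np.repeat([[2, 2], [0, 0], [1, 1]], [25, 25, 50], axis=0)
        res = ld_pairwise(g[:, 0], g[:, 1])
        assert res["D"] == pytest.approx(0.25, abs=1e-6)
        assert res["r2"] == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_have_negligible_ld(self):
        rng = np.random.default_rng(27)
        r2s = []
        for _ in range(40):
            g1 = rng.binomial(2, 0.4, 1000)
            g2 = rng.binomial(2, 0.5, 1000)
            r2s.append(ld_pairwise(g1, g2)["r2"])
        assert np.median(r2s) < 0.01

    def test_monomorphic_rejected(self):
        with pytest.raises(AssocError):
            ld_pairwise(np.zeros(50, int), np.ones(50, int))


class TestMetaFixedEffects:
    def test_identical_studies_combine_to_common_or(self):
        res = meta_fixed_effects([(0.8, 0.7, 0.92), (0.8, 0.7, 0.92)])
        assert res["odds_ratio"] == pytest.approx(0.8, abs=1e-9)
        assert res["ci_high"] - res["ci_low"] < 0.92 - 0.7

    def test_published_two_study_combination(self):
        res = meta_fixed_effects([(0.75, 0.66, 0.86), (0.84, 0.79, 0.88)])
        assert res["odds_ratio"] == pytest.approx(0.826, abs=1e-3)

    def test_single_study_unchanged(self):
        res = meta_fixed_effects([(0.9, 0.8, 1.01)])
        assert res["odds_ratio"] == pytest.approx(0.9)
        # CI re-symmetrised on the log scale around the point estimate
        assert res["ci_low"] == pytest.approx(0.8, abs=0.01)

    def test_inverted_ci_rejected(self):
        with pytest.raises(AssocError):
            meta_fixed_effects([(0.9, 1.2, 0.8), (0.8, 0.7, 0.9)])


class TestQcFilter:
    def test_clean_matrix_untouched(self):
        rng = np.random.default_rng(28)
        g = rng.binomial(2, 0.4, size=(200, 10)).astype(np.int8)
        pheno = np.repeat([True, False], 100)
        filt, ind, snp, report = qc_filter(g, pheno)
        assert len(report) == 0
        assert filt.shape == g.shape

    def test_high_missingness_snp_removed(self):
        rng = np.random.default_rng(29)
        g = rng.binomial(2, 0.4, size=(200, 50)).astype(np.int8)
        g[:22, 0] = -1  # 11% missing at SNP 0; individuals stay under 5%
        pheno = np.repeat([True, False], 100)
        _, _, snp, report = qc_filter(g, pheno)
        assert 0 not in snp
        row = report[report["item"] == 0].iloc[0]
        assert row["reason"] == "missingness"

    def test_heterozygote_deficit_fails_control_hwe(self):
        g = np.concatenate([
            np.random.default_rng(30).binomial(2, 0.5, size=(100, 1)),
            np.repeat([[0], [2]], 50, axis=0),
        ], axis=0).astype(np.int8)
        pheno = np.repeat([True, False], 100)
        assert hwe_chi2_p(50, 0, 50) < 1e-20
        _, _, snp, report = qc_filter(g, pheno)
        assert len(snp) == 0
        assert (report["reason"] == "hwe").any()

    def test_rare_allele_removed(self):
        g = np.zeros((300, 1), dtype=np.int8)
        g[0, 0] = 1  # MAF 1/600
        pheno = np.repeat([True, False], 150)
        _, _, snp, report = qc_filter(g, pheno)
        assert len(snp) == 0
        assert (report["reason"] == "maf").any()

    def test_individual_filter_applies_before_snp_filters(self):
        # a sloppy individual drives SNP missingness; dropping them first
        # rescues the SNPs
        g = np.random.default_rng(31).binomial(2, 0.4, size=(20, 10)).astype(np.int8)
        g[0, :] = -1
        pheno = np.repeat([True, False], 10)
        _, ind, snp, report = qc_filter(g, pheno, miss_snp=0.04, miss_ind=0.05)
        assert 0 not in ind  # sloppy individual removed first ...
        assert len(snp) == 10  # ... which rescues every SNP
        assert (report["item_type"] == "snp").sum() == 0


class TestOrInvariance:
    @given(st.integers(1, 80), st.integers(1, 80), st.integers(1, 80),
           st.integers(1, 80))
    @settings(max_examples=40, deadline=None)
    def test_allele_swap_inverts_or(self, n0c, n2c, n0t, n2t):
        counts = SnpCounts((n0c, 5, n2c), (n0t, 5, n2t))
        flipped = SnpCounts((n2c, 5, n0c), (n2t, 5, n0t), counted_allele="A")
        r1, r2 = allelic_test(counts), allelic_test(flipped)
        assert r1.odds_ratio * r2.odds_ratio == pytest.approx(1.0, abs=1e-9)
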