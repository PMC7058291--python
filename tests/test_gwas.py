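"""GWAS stage: QC filters, HWE exact test vs enumeration, logistic
association calibration, inflation factor, significance tiers."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest

from clustomics import (
    GenotypeMatrix,
    genomic_inflation,
    genotype_pcs,
    hwe_chi2_test,
    hwe_exact_test,
    logistic_assoc,
    qc_samples,
    qc_snps,
    significance_report,
)


def make_genotypes(dosage, subjects=None, snp_ids=None):
    dosage = np.asarray(dosage, float)
    n, m = dosage.shape
    subjects = subjects or [f"S{i}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j}" for j in range(m)]
    ann = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(m) + 1, "gene": ""},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(subjects=subjects, snp_ids=snp_ids, dosage=dosage, annotations=ann)


class TestSampleQC:
    def test_call_rate_threshold(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(5, 100)).astype(float)
        d[0, :6] = np.nan  # call rate 0.94
        g = make_genotypes(d)
        out, rep = qc_samples(g)
        assert "S0" in rep.dropped_call_rate
        assert out.n_subjects == 4

    def test_zero_sd_disables_het_filter(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], (6, 25))
        g = make_genotypes(d)
        out, rep = qc_samples(g)
        assert rep.het_filter_disabled
        assert out.n_subjects == 6

    def test_planted_het_outlier_dropped(self):
        rng = np.random.default_rng(1)
        # panel with het rate ~0.3; one subject fully heterozygous
        d = (rng.random((50, 200)) < 0.3).astype(float)
        d[d == 1] = 1.0
        d[0] = 1.0
        g = make_genotypes(d)
        out, rep = qc_samples(g)
        assert "S0" in rep.dropped_heterozygosity

    def test_all_dropped_raises(self):
        d = np.full((3, 100), np.nan)
        d[:, 0] = 1.0
        with pytest.raises(ValueError, match="every subject"):
            qc_samples(make_genotypes(d))


class TestSnpQC:
    def test_three_filters(self):
        rng = np.random.default_rng(2)
        n = 2000
        good = rng.binomial(2, 0.5, n).astype(float)  # MAF .5, HWE fine
        low_maf = rng.binomial(2, 0.04, n).astype(float)
        # HWE catastrophic: heterozygote-free with common minor allele
        hwe_bad = np.zeros(n)
        hwe_bad[:200] = 2.0
        low_call = good.copy()
        low_call[: int(0.1 * n)] = np.nan
        d = np.column_stack([good, low_maf, hwe_bad, low_call])
        g = make_genotypes(d, snp_ids=["good", "low_maf", "hwe_bad", "low_call"])
        out, rep = qc_snps(g)
        assert out.snp_ids == ["good"]
        assert rep.n_fail_maf >= 1
        assert rep.n_fail_call_rate >= 1
        assert rep.n_fail_hwe >= 1


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Exact-fraction brute force over all heterozygote counts with the
    same allele totals; independent of the implementation under test."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    common = 2 * n - rare
    probs = {}
    denom = comb(2 * n, rare)
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = (common - h) // 2
        # multinomial genotypes / binomial alleles
        num = (
            Fraction(factorial(n), factorial(hom_r) * factorial(h) * factorial(hom_c))
            * Fraction(2**h)
        )
        probs[h] = Fraction(num, denom)
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHWEExact:
    def test_monomorphic_returns_one(self):
        assert hwe_exact_test(0, 0, 50) == 1.0
        assert hwe_exact_test(50, 0, 0) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(3, 4, 3), (1, 1, 1), (5, 0, 5), (0, 10, 0), (2, 5, 1), (4, 1, 4), (7, 2, 1)],
    )
    def test_matches_enumeration_oracle(self, counts):
        got = hwe_exact_test(*counts)
        want = hwe_enumeration_oracle(*counts)
        assert got == pytest.approx(want, rel=1e-10)

    def test_all_small_tables_up_to_twenty_alleles(self):
        """Full sweep: every genotype table with <= 10 diploids agrees with
        the exact-fraction enumeration."""
        for n in range(1, 11):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    assert hwe_exact_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        hwe_enumeration_oracle(n_AA, n_Aa, n_aa), rel=1e-9
                    )

    def test_large_balanced_counts_agree_with_chi2(self):
        p_exact = hwe_exact_test(2500, 5000, 2500)
        assert p_exact >= 0.5
        # chi-square statistic on the same counts is ~0
        assert hwe_chi2_test(2500, 5000, 2500) > 0.99

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestLogisticAssociation:
    def test_null_p_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(3)
        n, m = 2000, 400
        g = make_genotypes(rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float))
        y = rng.random(n) < 0.3
        res = logistic_assoc(g, y, n_pcs=0)
        assert res["converged"].all()
        assert kstest(res["p"], "uniform").pvalue > 0.01
        frac = (res["p"] < 0.05).mean()
        assert 0.02 < frac < 0.08

    def test_constant_dosage_flagged(self):
        rng = np.random.default_rng(4)
        d = np.column_stack([np.full(200, 1.0), rng.binomial(2, 0.3, 200)]).astype(float)
        g = make_genotypes(d)
        y = rng.random(200) < 0.5
        res = logistic_assoc(g, y, n_pcs=0)
        assert not res.loc[0, "converged"]
        assert np.isnan(res.loc[0, "p"])
        assert res.loc[1, "converged"]

    def test_effect_recovery_coverage(self):
        """Planted log-odds inside its own 95% Wald CI in >= 90% of replicates."""
        rng = np.random.default_rng(5)
        beta_true = 0.4
        hits = 0
        reps = 50
        for _ in range(reps):
            n = 800
            dose = rng.binomial(2, 0.3, n).astype(float)
            eta = -0.5 + beta_true * dose
            y = rng.random(n) < 1 / (1 + np.exp(-eta))
            res = logistic_assoc(make_genotypes(dose[:, None]), y, n_pcs=0)
            b, se = res.loc[0, "beta"], res.loc[0, "se"]
            if abs(b - beta_true) < 1.96 * se:
                hits += 1
        assert hits >= 0.9 * reps

    def test_missing_subjects_reduce_n_used(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.4, 300).astype(float)
        d[:30] = np.nan
        res = logistic_assoc(make_genotypes(d[:, None]), rng.random(300) < 0.5, n_pcs=0)
        assert res.loc[0, "n_used"] == 270

    def test_pcs_deflate_structured_lambda(self):
        """Population-structure null: genotype PCs pull lambda toward 1."""
        rng = np.random.default_rng(7)
        n, m = 1200, 600
        pop = rng.random(n) < 0.5
        maf_a = rng.uniform(0.1, 0.5, m)
        shift = rng.normal(0, 0.08, m)
        maf_b = np.clip(maf_a + shift, 0.05, 0.95)
        d = np.where(
            pop[:, None], rng.binomial(2, maf_a, (n, m)), rng.binomial(2, maf_b, (n, m))
        ).astype(float)
        y = rng.random(n) < np.where(pop, 0.45, 0.2)  # outcome tracks structure
        g = make_genotypes(d)
        lam_without = genomic_inflation(logistic_assoc(g, y, n_pcs=0))
        lam_with = genomic_inflation(logistic_assoc(g, y, n_pcs=8))
        assert lam_without > 1.1
        assert lam_with < lam_without
        assert abs(lam_with - 1) < abs(lam_without - 1)

    def test_outcome_single_class_rejected(self):
        g = make_genotypes(np.zeros((10, 1)))
        with pytest.raises(ValueError, match="both classes"):
            logistic_assoc(g, np.zeros(10), n_pcs=0)


class TestInflationAndReport:
    def test_lambda_exact_at_half(self):
        res = pd.DataFrame({"p": np.full(200, 0.5)})
        assert genomic_inflation(res) == pytest.approx(1.0, abs=1e-12)

    def test_lambda_monotone_under_p_halving(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 500)
        lam1 = genomic_inflation(pd.DataFrame({"p": p}))
        lam2 = genomic_inflation(pd.DataFrame({"p": p / 2}))
        assert lam2 > lam1

    def test_minimum_result_count(self):
        with pytest.raises(ValueError):
            genomic_inflation(pd.DataFrame({"p": [0.5] * 99}))

    def test_tier_assignment(self):
        res = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c", "d"],
                "p": [4e-8, 1e-6, 1e-5, np.nan],
                "chrom": "1",
                "pos": [1, 2, 3, 4],
                "gene": "",
                "n_used": 10,
                "beta": 0.0,
                "se": 1.0,
            }
        )
        rep = significance_report(res)
        assert list(rep["tier"]) == ["genome-wide", "relaxed", "", ""]
        assert rep.loc[0, "minus_log10_p"] == pytest.approx(-np.log10(4e-8))

    def test_genotype_pcs_shape_and_centering(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, 0.3, size=(100, 50)).astype(float)
        pcs = genotype_pcs(d, 8)
        assert pcs.shape == (100, 8)
        assert np.allclose(pcs.mean(axis=0), 0, atol=1e-9)
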