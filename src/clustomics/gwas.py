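"""Self-contained GWAS stage at desk scale.

Sample QC (call rate, heterozygosity outliers), SNP QC (call rate, MAF,
Hardy-Weinberg exact test), additive-model logistic association with
age/sex/BMI and genotype principal-component covariates, the genomic
inflation factor, and a Manhattan-style significance table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix
from .glm import mass_univariate_logistic

logger = logging.getLogger(__name__)

__all__ = [
    "qc_samples",
    "qc_snps",
    "hwe_exact_test",
    "hwe_chi2_test",
    "genotype_pcs",
    "AdditiveLogisticGWAS",
    "logistic_assoc",
    "genomic_inflation",
    "significance_report",
    "SampleQCReport",
    "SnpQCReport",
]

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(chi2.median(1))

GENOME_WIDE_P = 5e-8
RELAXED_P = 5e-6


@dataclass
class SampleQCReport:
    n_input: int
    dropped_call_rate: list = field(default_factory=list)
    dropped_heterozygosity: list = field(default_factory=list)
    het_filter_disabled: bool = False

    @property
    def n_after(self) -> int:
        return self.n_input - len(set(self.dropped_call_rate) | set(self.dropped_heterozygosity))


@dataclass
class SnpQCReport:
    n_input: int
    n_fail_call_rate: int = 0
    n_fail_maf: int = 0
    n_fail_hwe: int = 0
    n_after: int = 0


def qc_samples(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    het_sd_multiplier: float = 5.0,
) -> tuple[GenotypeMatrix, SampleQCReport]:
    """Drop subjects with low call rate or outlying heterozygosity.

    Heterozygosity is the fraction of non-missing genotypes equal to 1;
    subjects beyond ``mean +/- 5 SD`` of the population are removed.  When
    the heterozygosity SD is zero (e.g. all subjects identical) that
    filter is disabled with a logged note rather than dropping everyone.
    """
    if g.n_subjects < 2:
        raise ValueError("need at least 2 subjects for sample QC")
    report = SampleQCReport(n_input=g.n_subjects)
    call = g.call_rate_subjects()
    called = ~np.isnan(g.dosage)
    with np.errstate(invalid="ignore"):
        het = np.where(called.sum(1) > 0, (g.dosage == 1).sum(1) / called.sum(1), np.nan)

    drop = call < call_rate_min
    report.dropped_call_rate = [s for s, d in zip(g.subjects, drop) if d]

    sd = np.nanstd(het)
    if sd == 0.0 or np.isnan(sd):
        report.het_filter_disabled = True
        logger.info("heterozygosity SD is zero; heterozygosity filter disabled")
    else:
        mean = np.nanmean(het)
        out = np.abs(het - mean) > het_sd_multiplier * sd
        report.dropped_heterozygosity = [s for s, d in zip(g.subjects, out) if d]
        drop = drop | np.where(np.isnan(het), False, out)

    if drop.all():
        raise ValueError("sample QC would drop every subject")
    return g.subset(subject_mask=~drop), report


def qc_snps(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, SnpQCReport]:
    """Remove SNPs failing call-rate, MAF, or HWE exact-test filters."""
    report = SnpQCReport(n_input=g.n_snps)
    call = g.call_rate_snps()
    maf = g.minor_allele_freq()
    hwe_p = np.ones(g.n_snps)
    for j in range(g.n_snps):
        col = g.dosage[:, j]
        col = col[~np.isnan(col)]
        hwe_p[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    fail_call = call < call_rate_min
    with np.errstate(invalid="ignore"):
        fail_maf = ~(maf >= maf_min)  # NaN MAF (all-missing SNP) fails too
    fail_hwe = hwe_p < hwe_p_min
    report.n_fail_call_rate = int(fail_call.sum())
    report.n_fail_maf = int(fail_maf.sum())
    report.n_fail_hwe = int(fail_hwe.sum())
    keep = ~(fail_call | fail_maf | fail_hwe)
    report.n_after = int(keep.sum())
    return g.subset(snp_mask=keep), report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose probability does not exceed that of the
    observed count.  Monomorphic SNPs return p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative and sum to >= 1")
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    if rare == 0:
        return 1.0

    # log P(het = h | n, rare) up to a shared constant:
    # N! / (n_hom_rare! h! n_hom_common!) * 2^h
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa][0]
    return float(min(prob[prob <= obs * (1 + 1e-12)].sum(), 1.0))


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Asymptotic 1-df chi-square HWE test (offered as an alternative)."""
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, 1))


def genotype_pcs(dosage: np.ndarray, n_components: int = 8) -> np.ndarray:
    """Principal components of the centered, MAF-scaled dosage matrix.

    Missing genotypes are mean-imputed; each SNP column is centered at
    ``2p`` and scaled by ``sqrt(2p(1-p))`` before the SVD.
    """
    D = np.asarray(dosage, float).copy()
    with np.errstate(invalid="ignore"):
        p = np.nanmean(D, axis=0) / 2.0
    inds = np.where(np.isnan(D))
    D[inds] = np.take(2.0 * p, inds[1])
    scale = np.sqrt(np.clip(2.0 * p * (1.0 - p), 1e-12, None))
    Z = (D - 2.0 * p) / scale
    n_components = min(n_components, *Z.shape)
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    return U[:, :n_components] * S[:n_components]


class AdditiveLogisticGWAS(BaseEstimator):
    """Per-SNP additive logistic regression with covariates.

    ``fit(g, y, covariates)`` regresses the binary outcome on each SNP's
    allele dosage plus the supplied covariate table and, when
    ``n_pcs > 0``, the top genotype principal components computed
    internally from the post-QC dosage matrix.  Wald two-sided p-values
    on the dosage coefficient; subjects missing a SNP are dropped for
    that SNP only; separation or non-convergence flags the SNP (p set
    missing) instead of silently dropping it.

    Fitted attributes: ``results_`` (association table, one row per SNP),
    ``lambda_`` (genomic inflation factor), ``pcs_``.
    """

    def __init__(self, n_pcs: int = 8, tol: float = 1e-8, max_iter: int = 50):
        self.n_pcs = n_pcs
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, g: GenotypeMatrix, y, covariates: pd.DataFrame | None = None) -> "AdditiveLogisticGWAS":
        y = np.asarray(y, float)
        if len(y) != g.n_subjects:
            raise ValueError("outcome length does not match subject count")
        if y.min() == y.max():
            raise ValueError("outcome must contain both classes")
        cov_parts = []
        if covariates is not None:
            if covariates.isna().any().any():
                raise ValueError("covariates must be complete")
            cov_parts.append(covariates.to_numpy(float))
        if self.n_pcs > 0:
            self.pcs_ = genotype_pcs(g.dosage, self.n_pcs)
            cov_parts.append(self.pcs_)
        else:
            self.pcs_ = None
        C = np.column_stack(cov_parts) if cov_parts else None

        res = mass_univariate_logistic(
            g.dosage, y, covariates=C, feature_ids=list(g.snp_ids),
            tol=self.tol, max_iter=self.max_iter,
        )
        res = res.join(g.annotations.reset_index(drop=True)[["chrom", "pos", "gene"]])
        self.results_ = res
        valid = res["p"].dropna()
        self.lambda_ = genomic_inflation(res) if len(valid) >= 100 else float("nan")
        return self


def logistic_assoc(
    g: GenotypeMatrix,
    outcome,
    covariates: pd.DataFrame | None = None,
    n_pcs: int = 8,
) -> pd.DataFrame:
    """Functional wrapper over :class:`AdditiveLogisticGWAS`."""
    return AdditiveLogisticGWAS(n_pcs=n_pcs).fit(g, outcome, covariates).results_


def genomic_inflation(results: pd.DataFrame) -> float:
    """Genomic inflation factor: median association chi-square over its
    null median (0.4549)."""
    p = results["p"].dropna().to_numpy(float)
    if p.size < 100:
        raise ValueError("need >= 100 valid p-values for a stable lambda")
    stats = chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def significance_report(
    results: pd.DataFrame,
    genome_wide_p: float = GENOME_WIDE_P,
    relaxed_p: float = RELAXED_P,
) -> pd.DataFrame:
    """Manhattan-style table: chrom, pos, -log10 p and significance tier.

    Tiers: ``genome-wide`` (p < 5e-8), ``relaxed`` (p < 5e-6), else blank.
    """
    if results.empty:
        raise ValueError("results table is empty")
    out = results.copy()
    p = out["p"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["minus_log10_p"] = -np.log10(p)
    tier = np.where(p < genome_wide_p, "genome-wide", np.where(p < relaxed_p, "relaxed", ""))
    out["tier"] = np.where(np.isnan(p), "", tier)
    cols = ["feature_id", "chrom", "pos", "gene", "n_used", "beta", "se", "p",
            "minus_log10_p", "tier"]
    return out[[c for c in cols if c in out.columns]]
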