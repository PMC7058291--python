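"""Synthetic cohort generator.

Emulates the statistical structure of a population-biobank metabolic-disease
study so every downstream stage (phenotype QC, clustering, GWAS, MWAS) is
testable without any external download:

* traits drawn per subject from the multivariate normal of a planted
  cluster (4 clusters by default, weights matching the observed sizes);
* self-reported disease flags drawn from logistic risk models on the
  standardized traits, producing the observed low/high prevalence gradient;
* one causal SNP with per-cluster minor allele frequencies plus
  cluster-independent null SNPs;
* plasma-like 1D NMR spectra: Gaussian/Lorentzian peaks over a smooth
  non-negative baseline with white noise, with lipoprotein-methyl, leucine
  and GlycA amplitudes depressed in the low-prevalence cluster.

All randomness is routed through per-stage children of a single
:class:`numpy.random.SeedSequence`, so a config's seed determines every
output stream bit-for-bit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import ConfigurationError, SnpSpec, SpectrumModel, SyntheticConfig
from .datatypes import DISEASE_COLUMNS, CohortTable, GenotypeMatrix, SpectrumSet

__all__ = [
    "generate_phenotypes",
    "generate_disease_status",
    "generate_genotypes",
    "generate_spectra",
    "generate_cohort",
    "select_metabolome_subset",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream ``stream`` for a config seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _psd_factor(cov: np.ndarray, traits: list[str]) -> np.ndarray:
    """Symmetric square root of a PSD covariance; raises naming the block."""
    cov = np.asarray(cov, float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ConfigurationError(f"covariance not symmetric (trait block: {', '.join(traits)})")
    vals, vecs = np.linalg.eigh(cov)
    if vals.min() < -1e-8 * max(1.0, abs(vals.max())):
        raise ConfigurationError(
            f"covariance not positive semi-definite (trait block: {', '.join(traits)})"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_phenotypes(config: SyntheticConfig) -> CohortTable:
    """Draw the phenotype table: cluster labels, AGE/SEX, trait block.

    Traits come from each planted cluster's multivariate normal in
    original clinical units; missing entries are injected uniformly at
    random at ``config.missing_rate``.  ``cluster_truth`` (1-based) is
    retained for downstream evaluation.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    n, k = config.n_subjects, config.n_clusters

    labels = rng.choice(k, size=n, p=np.asarray(config.cluster_weights, float))
    age = np.empty(n)
    sex = np.empty(n, dtype=int)
    traits = np.empty((n, len(config.trait_names)))

    for c in range(k):
        mask = labels == c
        m = int(mask.sum())
        if m == 0:
            continue
        mu = np.array([config.trait_means[t][c] for t in config.trait_names], float)
        L = _psd_factor(config.covariance(c), config.trait_names)
        traits[mask] = mu + rng.standard_normal((m, len(mu))) @ L.T
        age[mask] = np.clip(rng.normal(config.age_mean[c], config.age_sd[c], m), 20.0, 90.0)
        # SEX coding: 1 = female, 2 = male
        sex[mask] = 1 + (rng.random(m) < config.male_fraction[c])

    if config.missing_rate > 0:
        miss = rng.random(traits.shape) < config.missing_rate
        traits[miss] = np.nan

    data = pd.DataFrame(traits, columns=config.trait_names)
    data.insert(0, "SEX", sex)
    data.insert(0, "AGE", age)
    data["cluster_truth"] = labels + 1
    data.index = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    return CohortTable(data=data, trait_columns=list(config.trait_names), disease_columns=[])


def generate_disease_status(
    cohort: CohortTable,
    disease_models: dict,
    seed: int,
) -> CohortTable:
    """Draw Bernoulli disease flags from logistic models on z-scored traits.

    Each model's linear predictor is ``intercept + sum(coef * z(trait))``
    where z-scoring uses the realized overall mean/SD of the cohort.
    Missing trait values contribute 0 on the standardized scale (mean
    imputation), so flags are never missing.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    data = cohort.data.copy()
    z = {}
    for name, model in disease_models.items():
        eta = np.full(len(data), float(model.intercept))
        for trait, coef in model.coefficients.items():
            if trait not in data.columns:
                raise ConfigurationError(f"disease model {name!r} names unknown trait {trait!r}")
            if trait not in z:
                col = data[trait].to_numpy(float)
                mu, sd = np.nanmean(col), np.nanstd(col)
                zs = (col - mu) / (sd if sd > 0 else 1.0)
                z[trait] = np.nan_to_num(zs, nan=0.0)
            eta += coef * z[trait]
        data[name] = rng.random(len(data)) < expit(eta)
    return CohortTable(
        data=data,
        trait_columns=list(cohort.trait_columns),
        disease_columns=list(disease_models),
        stage=cohort.stage,
    )


def generate_genotypes(
    cohort: CohortTable,
    snp_panel: list[SnpSpec],
    n_null_snps: int = 0,
    null_maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw allele dosages: causal SNPs cluster-stratified, nulls common.

    Causal SNP dosages are Binomial(2, MAF of the subject's planted
    cluster); null SNPs get one MAF each, drawn uniformly from
    ``null_maf_range``, independent of cluster.  Null columns that come
    out monomorphic (possible only at tiny n) are redrawn once and
    otherwise dropped with a warning; a configured MAF of zero is a
    configuration error caught up front.
    """
    truth = cohort.cluster_truth
    if truth is None:
        raise ValueError("cohort lacks cluster_truth; generate phenotypes first")
    for snp in snp_panel:
        for maf in snp.maf_per_cluster:
            if not (0 < maf <= 0.5):
                raise ConfigurationError(f"{snp.snp_id}: MAF {maf} outside (0, 0.5]")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    n = cohort.n_subjects
    labels0 = truth.to_numpy(int) - 1

    cols, ids, ann = [], [], []
    for snp in snp_panel:
        maf = np.asarray(snp.maf_per_cluster, float)[labels0]
        cols.append(rng.binomial(2, maf).astype(float))
        ids.append(snp.snp_id)
        ann.append((snp.chrom, snp.pos, snp.gene))

    lo, hi = null_maf_range
    dropped = 0
    for j in range(n_null_snps):
        maf = rng.uniform(lo, hi)
        col = rng.binomial(2, maf, size=n).astype(float)
        if col.min() == col.max():  # monomorphic guard
            col = rng.binomial(2, maf, size=n).astype(float)
        if col.min() == col.max():
            dropped += 1
            continue
        cols.append(col)
        ids.append(f"null{j:05d}")
        ann.append((str(j % 22 + 1), 1_000_000 + 1000 * j, ""))
    if dropped:
        warnings.warn(f"dropped {dropped} monomorphic null SNP columns")

    dosage = np.column_stack(cols) if cols else np.empty((n, 0))
    if missing_rate > 0:
        miss = rng.random(dosage.shape) < missing_rate
        dosage[miss] = np.nan

    annotations = pd.DataFrame(ann, columns=["chrom", "pos", "gene"], index=pd.Index(ids, name="snp_id"))
    return GenotypeMatrix(
        subjects=list(cohort.data.index),
        snp_ids=ids,
        dosage=dosage,
        annotations=annotations,
    )


def _peak_shape(ppm: np.ndarray, center: float, width: float, shape: str) -> np.ndarray:
    if shape == "gaussian":
        return np.exp(-0.5 * ((ppm - center) / width) ** 2)
    if shape == "lorentzian":
        return width**2 / ((ppm - center) ** 2 + width**2)
    raise ConfigurationError(f"unknown peak shape {shape!r}")


def synthetic_baseline(ppm: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth, non-negative instrument baseline (broad hump + offset)."""
    return amplitude * (0.3 + 0.7 * np.exp(-(((ppm - 2.8) / 2.0) ** 2)))


def generate_spectra(
    cohort: CohortTable,
    model: SpectrumModel,
    seed: int = 0,
    allele_counts: pd.Series | None = None,
) -> SpectrumSet:
    """Simulate subject spectra: peaks + smooth baseline + white noise.

    Each peak's amplitude is the subject's cluster mean perturbed by
    ``amp_rel_sd`` relative Gaussian scatter (clipped at zero).  The ppm
    axis is stored in decreasing order, the plotting convention for NMR.
    ``allele_counts`` (0/1/2 per subject) is attached to the metadata as
    ``rs651821_C_count`` when given.
    """
    truth = cohort.cluster_truth
    if truth is None:
        raise ValueError("cohort lacks cluster_truth; generate phenotypes first")
    ppm = np.linspace(model.ppm_max, model.ppm_min, model.n_points)
    for pk in model.peaks:
        if not (ppm.min() <= pk.center <= ppm.max()):
            raise ConfigurationError(
                f"peak {pk.name!r} center {pk.center} ppm outside axis "
                f"[{ppm.min()}, {ppm.max()}]"
            )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    n = cohort.n_subjects
    labels0 = truth.to_numpy(int) - 1

    intensity = np.tile(synthetic_baseline(ppm, model.baseline_amplitude), (n, 1))
    for pk in model.peaks:
        mean_amp = np.asarray(pk.amp_per_cluster, float)[labels0]
        amp = np.clip(rng.normal(mean_amp, model.amp_rel_sd * np.abs(mean_amp)), 0.0, None)
        intensity += amp[:, None] * _peak_shape(ppm, pk.center, pk.width, pk.shape)[None, :]
    if model.noise_sd > 0:
        intensity += rng.normal(0.0, model.noise_sd, size=intensity.shape)

    meta = pd.DataFrame(
        {
            "AGE": cohort.data["AGE"].to_numpy(float),
            "SEX": cohort.data["SEX"].to_numpy(int),
            "cluster_label": truth.to_numpy(int),
        },
        index=cohort.data.index,
    )
    if allele_counts is not None:
        meta["rs651821_C_count"] = allele_counts.reindex(meta.index).to_numpy(float)
    return SpectrumSet(ppm=ppm, intensity=intensity, meta=meta)


def generate_cohort(config: SyntheticConfig, n_null_snps: int = 0) -> tuple[CohortTable, GenotypeMatrix]:
    """Phenotypes + disease flags + genotypes in one deterministic call."""
    cohort = generate_phenotypes(config)
    cohort = generate_disease_status(cohort, config.disease_models, seed=config.seed)
    genotypes = generate_genotypes(
        cohort,
        config.snp_panel,
        n_null_snps=n_null_snps,
        missing_rate=config.missing_rate,
        seed=config.seed,
    )
    return cohort, genotypes


def select_metabolome_subset(
    cohort: CohortTable,
    n_low: int = 144,
    n_control: int = 73,
    low_cluster: int = 2,
    bmi_range: tuple[float, float] = (18.0, 24.0),
    seed: int = 0,
) -> CohortTable:
    """Pick the metabolome subsample: low-prevalence-cluster cases vs controls.

    Mirrors the study design in which plasma NMR was run for a stringently
    selected subset (normal BMI; the lifestyle criteria of the original
    selection have no synthetic counterpart and are represented by the BMI
    window alone).  Returns ``n_low`` subjects from ``low_cluster`` and
    ``n_control`` from the remaining clusters, sampled without replacement.
    """
    truth = cohort.cluster_truth
    if truth is None:
        raise ValueError("cohort lacks cluster_truth")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(4,)))
    bmi = cohort.data["BMI"] if "BMI" in cohort.data.columns else None
    eligible = pd.Series(True, index=cohort.data.index)
    if bmi is not None:
        eligible &= bmi.between(*bmi_range)
    low_pool = cohort.data.index[eligible & (truth == low_cluster)]
    ctl_pool = cohort.data.index[eligible & (truth != low_cluster)]
    if len(low_pool) < n_low or len(ctl_pool) < n_control:
        raise ValueError(
            f"not enough eligible subjects ({len(low_pool)} low / {len(ctl_pool)} control)"
        )
    chosen = np.concatenate(
        [
            rng.choice(low_pool.to_numpy(), size=n_low, replace=False),
            rng.choice(ctl_pool.to_numpy(), size=n_control, replace=False),
        ]
    )
    data = cohort.data.loc[chosen]
    return CohortTable(
        data=data,
        trait_columns=list(cohort.trait_columns),
        disease_columns=list(cohort.disease_columns),
        stage=cohort.stage,
    )
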