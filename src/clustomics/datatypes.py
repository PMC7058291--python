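"""Core data containers shared across the pipeline.

The phenome travels as a :class:`CohortTable` (a subject-by-trait pandas
table plus bookkeeping), genotypes as a :class:`GenotypeMatrix` (allele
dosages 0/1/2 with NaN for missing), and NMR data as a :class:`SpectrumSet`
(a common ppm axis with one intensity row per subject).  Association stages
return plain :class:`pandas.DataFrame` tables with a fixed column contract
(see :data:`ASSOCIATION_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Processing stages of a phenotype table, in the only admissible order.
STAGE_ORDER = ("raw", "filtered", "imputed", "normalized", "pruned")

#: Column contract for per-feature association tables (GWAS and MWAS).
ASSOCIATION_COLUMNS = ("feature_id", "beta", "se", "p", "p_adj", "n_used", "converged")

#: Disease-status flags carried by a cohort.
DISEASE_COLUMNS = ("diabetes", "dyslipidemia", "hypertension")

MISSING_SENTINEL = "NA"


class PipelineOrderError(RuntimeError):
    """A QC stage was applied to a table in the wrong processing state."""


@dataclass
class CohortTable:
    """Subjects-by-traits table with disease flags.

    Parameters
    ----------
    data
        DataFrame indexed by unique subject id.  Must contain ``AGE`` and
        ``SEX`` (coded 1 = female, 2 = male), one numeric column per
        quantitative trait, and one boolean column per disease.  Missing
        trait values are ``NaN`` in memory (written as ``NA`` on disk).
    trait_columns
        Names of the quantitative trait columns, in a fixed order.
    disease_columns
        Names of the boolean disease-flag columns.
    stage
        Processing stage tag; QC operations check and advance it so the
        filter -> impute -> normalize -> prune order cannot be violated.
    """

    data: pd.DataFrame
    trait_columns: list[str]
    disease_columns: list[str] = field(default_factory=lambda: list(DISEASE_COLUMNS))
    stage: str = "raw"

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("subject_id index must be unique")
        if self.stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [c for c in self.trait_columns if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait columns absent from table: {missing}")
        for c in self.trait_columns:
            if not np.issubdtype(self.data[c].dtype, np.number):
                raise ValueError(f"trait column {c!r} is not numeric")

    # -- convenience views -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def traits(self) -> pd.DataFrame:
        """The quantitative trait block, in declared column order."""
        return self.data[self.trait_columns]

    @property
    def cluster_truth(self) -> pd.Series | None:
        if "cluster_truth" in self.data.columns:
            return self.data["cluster_truth"]
        return None

    # -- stage bookkeeping -------------------------------------------------
    def require_stage(self, expected: str) -> None:
        if self.stage != expected:
            raise PipelineOrderError(
                f"operation requires a {expected!r} table, got {self.stage!r}; "
                f"pipeline order is {' -> '.join(STAGE_ORDER)}"
            )

    def advance(self, data: pd.DataFrame, stage: str, trait_columns: list[str] | None = None) -> "CohortTable":
        """Return a copy with new data and the next stage tag."""
        if STAGE_ORDER.index(stage) != STAGE_ORDER.index(self.stage) + 1:
            raise PipelineOrderError(f"cannot advance {self.stage!r} -> {stage!r}")
        return replace(
            self,
            data=data,
            stage=stage,
            trait_columns=list(trait_columns if trait_columns is not None else self.trait_columns),
        )

    def copy(self) -> "CohortTable":
        return replace(self, data=self.data.copy())


@dataclass
class GenotypeMatrix:
    """Subjects-by-SNPs allele dosage matrix with per-SNP annotations.

    ``dosage`` holds floats restricted to {0, 1, 2, NaN}; NaN encodes a
    missing (no-call) genotype.  ``annotations`` is indexed by snp_id with
    columns ``chrom``, ``pos`` and ``gene`` (empty string when intergenic).
    """

    subjects: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subjects), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.subjects)} subjects x {len(self.snp_ids)} SNPs"
            )
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage values must be 0, 1, 2 or NaN")
        if list(self.annotations.index) != list(self.snp_ids):
            raise ValueError("annotation index must match snp_ids order")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def call_rate_subjects(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def minor_allele_freq(self) -> np.ndarray:
        """Per-SNP minor allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def subset(self, subject_mask=None, snp_mask=None) -> "GenotypeMatrix":
        subject_mask = np.ones(self.n_subjects, bool) if subject_mask is None else np.asarray(subject_mask)
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            subjects=[s for s, keep in zip(self.subjects, subject_mask) if keep],
            snp_ids=[s for s, keep in zip(self.snp_ids, snp_mask) if keep],
            dosage=self.dosage[np.ix_(subject_mask, snp_mask)],
            annotations=self.annotations.loc[snp_mask],
        )


@dataclass
class SpectrumSet:
    """A set of 1D NMR spectra on a common chemical-shift axis.

    ``ppm`` must be strictly monotone (either direction); ``intensity`` is
    subjects x points in arbitrary units; ``meta`` is indexed by subject id
    and carries at least ``AGE`` and ``SEX``, plus ``cluster_label`` and
    optionally ``rs651821_C_count`` for the association stages.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        d = np.diff(self.ppm)
        if self.ppm.size < 2 or not ((d > 0).all() or (d < 0).all()):
            raise ValueError("ppm axis must be strictly monotone")
        if self.intensity.shape != (len(self.meta), self.ppm.size):
            raise ValueError("intensity shape inconsistent with meta/ppm")
        if not np.isfinite(self.intensity).all():
            raise ValueError("intensity contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.meta)

    @property
    def n_points(self) -> int:
        return self.ppm.size

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(self.ppm.copy(), self.intensity.copy(), self.meta.copy())


@dataclass
class PCAModel:
    """Exact PCA of the trait matrix (loadings, scores, variance profile)."""

    loadings: pd.DataFrame          # traits x components, orthonormal columns
    scores: pd.DataFrame            # subjects x components
    explained_variance: np.ndarray  # fraction per component, non-increasing
    mean: pd.Series                 # per-trait centering constants


@dataclass
class ClusterModel:
    """Fitted k-means partition of the cohort (labels are 1..k)."""

    k: int
    centers: np.ndarray
    assignment: pd.Series          # per-subject label in 1..k
    inertia: float
    silhouette_mean: float
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.assignment)
        if labels.size and not ((labels >= 1) & (labels <= self.k)).all():
            raise ValueError("assignment labels must lie in 1..k")
        if not np.isfinite(self.centers).all():
            raise ValueError("cluster centers must be finite")


@dataclass
class StabilityReport:
    """Jaccard stability of a reference partition over random restarts."""

    n_repeats: int
    mean_jaccard: np.ndarray   # per reference cluster, in [0, 1]
    overall_mean: float        # mean of the per-cluster means
    pooled_mean: float         # mean over every (cluster, repeat) pair


@dataclass
class QCReport:
    """Bookkeeping for the phenotype QC stages."""

    n_input: int = 0
    n_excluded_outlier: int = 0
    n_after: int = 0
    imputed_cells: int = 0
    #: (trait_removed, partner_trait, correlation, loading_kept, loading_removed)
    removed_traits: list[tuple] = field(default_factory=list)
    skipped_traits: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_excluded_outlier": int(self.n_excluded_outlier),
            "n_after": int(self.n_after),
            "imputed_cells": int(self.imputed_cells),
            "removed_traits": [
                {
                    "trait": t,
                    "partner": p,
                    "correlation": float(r),
                    "loading_kept": float(lk),
                    "loading_removed": float(lr),
                }
                for t, p, r, lk, lr in self.removed_traits
            ],
            "skipped_traits": list(self.skipped_traits),
        }
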