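"""Phenotype preprocessing: outlier exclusion, stratified imputation,
covariate-adjusted normalization, and redundancy pruning.

The four stages run in a fixed order — filter -> impute -> normalize ->
prune — enforced by stage tags on the :class:`~clustomics.datatypes.CohortTable`.
Each stage is an estimator with sklearn semantics (``fit`` learns the
parameters, ``transform`` applies them, fitted attributes end in ``_``);
the module-level functions are thin wrappers for one-shot use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .datatypes import CohortTable, QCReport

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "OutlierFilter",
    "StratifiedMedianImputer",
    "CovariateNormalizer",
    "RedundantTraitPruner",
    "filter_outliers",
    "impute_missing",
    "stratified_normalize",
    "prune_redundant_traits",
    "run_qc_pipeline",
]


@dataclass
class QCConfig:
    """Tunable QC thresholds.

    iqr_multiplier / sd_multiplier: a subject is excluded when any trait
    lies outside ``[Q1 - iqr_multiplier*IQR, Q3 + iqr_multiplier*IQR]``
    OR beyond ``mean +/- sd_multiplier*SD``.  corr_threshold: trait pairs
    above this (absolute by default) Pearson correlation are pruned down
    to one member.
    """

    iqr_multiplier: float = 3.0
    sd_multiplier: float = 4.0
    corr_threshold: float = 0.6
    strata: tuple[str, ...] = ("age_band", "SEX")
    age_band_width: float = 10.0
    use_absolute_corr: bool = True
    loading_components: int = 2

    def __post_init__(self) -> None:
        if self.iqr_multiplier <= 0 or self.sd_multiplier <= 0:
            raise ValueError("multipliers must be positive")
        if not (0 < self.corr_threshold < 1):
            raise ValueError("corr_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Stage 1: outlier exclusion
# ---------------------------------------------------------------------------

class OutlierFilter(BaseEstimator):
    """Exclude subjects with any extreme trait value.

    Bounds are computed per trait on the table passed to :meth:`fit`
    (type-7 linearly interpolated quartiles; SD with n-1 denominator).
    A value triggers exclusion when it lies outside the IQR fence OR the
    SD fence; missing values never trigger exclusion.  Constant traits
    (zero IQR and zero SD) are skipped with a logged warning.
    """

    def __init__(self, iqr_multiplier: float = 3.0, sd_multiplier: float = 4.0):
        self.iqr_multiplier = iqr_multiplier
        self.sd_multiplier = sd_multiplier

    def fit(self, cohort: CohortTable) -> "OutlierFilter":
        cohort.require_stage("raw")
        bounds = {}
        skipped = []
        for trait in cohort.trait_columns:
            col = cohort.data[trait].to_numpy(float)
            vals = col[~np.isnan(col)]
            if vals.size == 0:
                skipped.append(trait)
                continue
            q1, q3 = np.percentile(vals, [25, 75])  # type-7 interpolation
            iqr = q3 - q1
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            if iqr == 0.0 and sd == 0.0:
                logger.warning("trait %s is constant; skipped as outlier criterion", trait)
                skipped.append(trait)
                continue
            mean = vals.mean()
            bounds[trait] = (
                min(q1 - self.iqr_multiplier * iqr, mean - self.sd_multiplier * sd),
                max(q3 + self.iqr_multiplier * iqr, mean + self.sd_multiplier * sd),
                q1 - self.iqr_multiplier * iqr,
                q3 + self.iqr_multiplier * iqr,
                mean - self.sd_multiplier * sd,
                mean + self.sd_multiplier * sd,
            )
        self.bounds_ = bounds
        self.skipped_traits_ = skipped
        return self

    def transform(self, cohort: CohortTable) -> tuple[CohortTable, QCReport]:
        cohort.require_stage("raw")
        exclude = np.zeros(cohort.n_subjects, dtype=bool)
        for trait, (_, _, iqr_lo, iqr_hi, sd_lo, sd_hi) in self.bounds_.items():
            col = cohort.data[trait].to_numpy(float)
            with np.errstate(invalid="ignore"):
                out_iqr = (col < iqr_lo) | (col > iqr_hi)
                out_sd = (col < sd_lo) | (col > sd_hi)
            exclude |= np.where(np.isnan(col), False, out_iqr | out_sd)
        report = QCReport(
            n_input=cohort.n_subjects,
            n_excluded_outlier=int(exclude.sum()),
            n_after=int((~exclude).sum()),
            skipped_traits=list(self.skipped_traits_),
        )
        filtered = cohort.advance(cohort.data.loc[~exclude].copy(), "filtered")
        return filtered, report

    def fit_transform(self, cohort: CohortTable) -> tuple[CohortTable, QCReport]:
        return self.fit(cohort).transform(cohort)


# ---------------------------------------------------------------------------
# Stage 2: stratified median imputation
# ---------------------------------------------------------------------------

class StratifiedMedianImputer(BaseEstimator):
    """Fill missing trait values with the median of the (age-band x sex)
    stratum; strata with fewer than ``min_stratum_size`` observed values
    fall back to the overall trait median."""

    def __init__(self, age_band_width: float = 10.0, min_stratum_size: int = 5):
        self.age_band_width = age_band_width
        self.min_stratum_size = min_stratum_size

    def _strata(self, cohort: CohortTable) -> pd.Series:
        age = cohort.data["AGE"]
        sex = cohort.data["SEX"]
        if age.isna().any() or sex.isna().any():
            raise ValueError("strata columns AGE/SEX must be complete")
        band = (age // self.age_band_width).astype(int)
        return band.astype(str) + "|" + sex.astype(int).astype(str)

    def fit(self, cohort: CohortTable) -> "StratifiedMedianImputer":
        cohort.require_stage("filtered")
        strata = self._strata(cohort)
        medians: dict[str, dict] = {}
        overall: dict[str, float] = {}
        for trait in cohort.trait_columns:
            col = cohort.data[trait]
            if col.isna().all():
                raise ValueError(f"trait {trait!r} is entirely missing; cannot impute")
            overall[trait] = float(col.median())
            grp = col.groupby(strata)
            med = grp.median()
            counts = grp.count()
            medians[trait] = {
                s: float(med[s]) if counts[s] >= self.min_stratum_size else overall[trait]
                for s in med.index
            }
        self.stratum_medians_ = medians
        self.overall_medians_ = overall
        return self

    def transform(self, cohort: CohortTable) -> tuple[CohortTable, QCReport]:
        cohort.require_stage("filtered")
        strata = self._strata(cohort)
        data = cohort.data.copy()
        imputed = 0
        for trait in cohort.trait_columns:
            col = data[trait]
            miss = col.isna()
            if not miss.any():
                continue
            fill = strata[miss].map(
                lambda s: self.stratum_medians_[trait].get(s, self.overall_medians_[trait])
            )
            data.loc[miss, trait] = fill.astype(float)
            imputed += int(miss.sum())
        report = QCReport(n_input=cohort.n_subjects, n_after=cohort.n_subjects, imputed_cells=imputed)
        return cohort.advance(data, "imputed"), report

    def fit_transform(self, cohort: CohortTable) -> tuple[CohortTable, QCReport]:
        return self.fit(cohort).transform(cohort)


# ---------------------------------------------------------------------------
# Stage 3: covariate-adjusted z-scoring
# ---------------------------------------------------------------------------

class CovariateNormalizer(BaseEstimator):
    """Regress age and sex out of each trait, then z-score the residuals.

    ``fit`` stores the per-trait least-squares coefficients and the
    residual mean/SD so the identical transform can be replayed on new
    subjects.  Residual SD uses the n-denominator so the transformed
    training traits have SD exactly 1.
    """

    def __init__(self, covariate_columns: tuple[str, ...] = ("AGE", "SEX")):
        self.covariate_columns = covariate_columns

    def _design(self, cohort: CohortTable) -> np.ndarray:
        cols = [np.ones(cohort.n_subjects)]
        cols += [cohort.data[c].to_numpy(float) for c in self.covariate_columns]
        return np.column_stack(cols)

    def fit(self, cohort: CohortTable) -> "CovariateNormalizer":
        cohort.require_stage("imputed")
        X = self._design(cohort)
        coef: dict[str, np.ndarray] = {}
        scale: dict[str, tuple[float, float]] = {}
        for trait in cohort.trait_columns:
            y = cohort.data[trait].to_numpy(float)
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ b
            sd = resid.std()
            if sd < 1e-12:
                raise ValueError(f"trait {trait!r} has zero residual variance after adjustment")
            coef[trait] = b
            scale[trait] = (float(resid.mean()), float(sd))
        self.coef_ = coef
        self.scale_ = scale
        return self

    def transform(self, cohort: CohortTable) -> CohortTable:
        cohort.require_stage("imputed")
        X = self._design(cohort)
        data = cohort.data.copy()
        for trait in cohort.trait_columns:
            resid = data[trait].to_numpy(float) - X @ self.coef_[trait]
            mu, sd = self.scale_[trait]
            data[trait] = (resid - mu) / sd
        return cohort.advance(data, "normalized")

    def fit_transform(self, cohort: CohortTable) -> CohortTable:
        return self.fit(cohort).transform(cohort)


# ---------------------------------------------------------------------------
# Stage 4: redundancy pruning
# ---------------------------------------------------------------------------

class RedundantTraitPruner(BaseEstimator):
    """Drop one member of every highly correlated trait pair.

    PCA is run on the normalized trait block; for every pair with Pearson
    correlation above the threshold (absolute value by default), the
    member with the smaller Euclidean norm of its variance-scaled
    (PC1, PC2) loadings is removed.  Pairs are processed in descending
    correlation order; a pair whose member was already dropped is skipped.
    Ties on loading norm are broken by column order (the later column is
    dropped).
    """

    def __init__(
        self,
        corr_threshold: float = 0.6,
        use_absolute_corr: bool = True,
        loading_components: int = 2,
    ):
        self.corr_threshold = corr_threshold
        self.use_absolute_corr = use_absolute_corr
        self.loading_components = loading_components

    def fit(self, cohort: CohortTable) -> "RedundantTraitPruner":
        cohort.require_stage("normalized")
        traits = cohort.trait_columns
        self.removed_ = []
        self.kept_traits_ = list(traits)
        if len(traits) < 2:
            return self
        M = cohort.traits.to_numpy(float)
        n_comp = min(self.loading_components, len(traits), M.shape[0])
        pca = PCA(n_components=n_comp, svd_solver="full").fit(M)
        # variance-scaled loadings: eigvec entry * sqrt(eigenvalue)
        load = pca.components_.T * np.sqrt(pca.explained_variance_)
        norms = {t: float(np.linalg.norm(load[i])) for i, t in enumerate(traits)}

        corr = np.corrcoef(M, rowvar=False)
        pairs = []
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                r = corr[i, j]
                mag = abs(r) if self.use_absolute_corr else r
                if mag > self.corr_threshold:
                    pairs.append((mag, r, traits[i], traits[j]))
        pairs.sort(key=lambda x: (-x[0], x[2], x[3]))

        alive = set(traits)
        for _, r, a, b in pairs:
            if a not in alive or b not in alive:
                continue
            # drop the member with the smaller loading norm; tie -> later column
            drop, keep = (a, b) if norms[a] < norms[b] else (b, a)
            alive.discard(drop)
            self.removed_.append((drop, keep, float(r), norms[keep], norms[drop]))
        self.kept_traits_ = [t for t in traits if t in alive]
        return self

    def transform(self, cohort: CohortTable) -> tuple[CohortTable, QCReport]:
        cohort.require_stage("normalized")
        dropped = {t for t, *_ in self.removed_}
        data = cohort.data.drop(columns=[c for c in dropped if c in cohort.data.columns])
        report = QCReport(
            n_input=cohort.n_subjects,
            n_after=cohort.n_subjects,
            removed_traits=list(self.removed_),
        )
        pruned = cohort.advance(data, "pruned", trait_columns=list(self.kept_traits_))
        return pruned, report

    def fit_transform(self, cohort: CohortTable) -> tuple[CohortTable, QCReport]:
        return self.fit(cohort).transform(cohort)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def filter_outliers(cohort: CohortTable, config: QCConfig | None = None):
    config = config or QCConfig()
    return OutlierFilter(config.iqr_multiplier, config.sd_multiplier).fit_transform(cohort)


def impute_missing(cohort: CohortTable, config: QCConfig | None = None):
    config = config or QCConfig()
    return StratifiedMedianImputer(config.age_band_width).fit_transform(cohort)


def stratified_normalize(cohort: CohortTable):
    """Returns (normalized cohort, fitted CovariateNormalizer)."""
    norm = CovariateNormalizer()
    return norm.fit_transform(cohort), norm


def prune_redundant_traits(cohort: CohortTable, config: QCConfig | None = None):
    config = config or QCConfig()
    return RedundantTraitPruner(
        config.corr_threshold, config.use_absolute_corr, config.loading_components
    ).fit_transform(cohort)


def run_qc_pipeline(cohort: CohortTable, config: QCConfig | None = None):
    """filter -> impute -> normalize -> prune, returning the pruned table,
    the filtered (original-units) table, and the merged QCReport."""
    config = config or QCConfig()
    filtered, rep1 = filter_outliers(cohort, config)
    imputed, rep2 = impute_missing(filtered, config)
    normalized, _ = stratified_normalize(imputed)
    pruned, rep3 = prune_redundant_traits(normalized, config)
    report = QCReport(
        n_input=rep1.n_input,
        n_excluded_outlier=rep1.n_excluded_outlier,
        n_after=rep1.n_after,
        imputed_cells=rep2.imputed_cells,
        removed_traits=rep3.removed_traits,
        skipped_traits=rep1.skipped_traits,
    )
    return pruned, filtered, report
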