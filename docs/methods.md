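# Methods

This note documents the models behind `clustomics`, the parameter choices
that matter, what the synthetic cohort does and does not emulate, and the
numerical conventions that a re-implementation would need to match.

## The analysis model

The pipeline asks a population-epidemiology question: does a cohort
contain a phenotypic stratum with jointly reduced prevalence of diabetes,
dyslipidemia and hypertension, and what genomic and metabolomic features
characterize it?

The phenome is a subjects × traits table of anthropometric and clinical
chemistry values (BMI, lipids, glycemic markers, blood pressure, renal
and hepatic markers) with self-reported disease flags. The analysis
proceeds in a fixed order enforced by stage tags on the table:

**filter → impute → normalize → prune → cluster → characterize**,
followed by the two association stages.

### Phenotype QC

* **Outlier exclusion.** A subject is excluded when *any* trait value
  falls outside `[Q1 − 3·IQR, Q3 + 3·IQR]` **or** beyond
  `mean ± 4·SD`, with fences computed on the input table. The two rules
  are combined with OR (either suffices), quartiles use type-7 linear
  interpolation, and the SD uses the n−1 denominator; none of these
  conventions is canonical, so they are fixed here explicitly. Missing
  values never trigger exclusion; constant traits are skipped with a
  logged warning rather than treated as a criterion.
* **Imputation.** Missing trait values take the median of their
  (10-year age band × sex) stratum; strata with fewer than 5 observed
  values fall back to the overall trait median. Stratified medians were
  chosen for robustness over model-based imputation; multiple imputation
  is out of scope.
* **Normalization.** Each trait is regressed on age and sex (ordinary
  least squares), and the residuals are z-scored (n denominator, so the
  training table has SD exactly 1). Clustering therefore operates on
  age/sex-adjusted standardized residuals, making traits with different
  units commensurable. The fitted coefficients and scale are stored so
  the identical transform can be replayed on held-out subjects.
* **Redundancy pruning.** PCA is run on the normalized trait block; for
  every pair with Pearson |r| > 0.6 the member with the smaller
  Euclidean norm of its variance-scaled (PC1, PC2) loadings
  (eigenvector entry × √eigenvalue) is dropped. Pairs are processed in
  descending |r|; pairs with an already-dropped member are skipped; ties
  break by column order. Whether the threshold applies to signed r or
  |r|, and how many components feed the loading norm, are configurable
  (`use_absolute_corr`, `loading_components`) because either reading is
  defensible; |r| and two components are the defaults.

### Clustering

* **k-means.** Lloyd's algorithm with Euclidean distance, k-means++ or
  uniform-random data-point initialization, convergence when the
  assignment stabilizes (cap 300 iterations). Inertia is asserted
  non-increasing across iterations on every fit. An emptied cluster is
  re-seeded at the point farthest from its assigned center. `n_init`
  independent starts keep the lowest-inertia solution (10 for the
  user-facing `kmeans_fit`; a single-start mode exists for studying the
  optimizer itself). The implementation is in-house because this
  contract (per-iteration assertion, documented empty-cluster rule) is
  not exposed by library implementations; a library k-means serves as an
  independent cross-check in the test suite.
* **Choosing k.** Mean silhouette width per k over a fixed subsample of
  at most 5,000 subjects (the silhouette needs the O(n²) distance
  matrix; at n ≈ 20,000 the full matrix is wasteful and the subsampled
  estimate is accurate to ±0.01). Ties go to the smallest k.
* **Stability.** The reference partition is compared against repeats
  refit from random centers (each repeat best-of-10 random starts —
  single-start repeats would measure Lloyd's local-optimum rate, not the
  stability of the data partition). Repeat clusters are matched to
  reference clusters greedily by maximum Jaccard (largest entry first,
  row/column elimination); Hungarian matching is available as an option.
  The per-cluster mean over repeats is reported along with two
  aggregates (mean of per-cluster means, and the pooled mean over all
  cluster × repeat pairs), since either convention may be wanted.
* **Characterization.** Per cluster: n, trait mean (SD) in original
  units, disease counts and prevalence percentages rounded to one
  decimal. The "low-prevalence cluster" is identified programmatically
  as the cluster minimizing mean prevalence across the three diseases.
  Within-cluster diseased-vs-control comparisons use Welch's two-sample
  t-test, two-sided; a cluster with no diseased subjects yields blank
  comparison columns, not an error.

### GWAS stage

Sample QC drops subjects with call rate < 0.95 or heterozygosity
(fraction of non-missing genotypes equal to 1) beyond 5 SD of the
population mean; a zero heterozygosity SD disables that filter with a
log note. SNP QC drops markers with call rate < 0.95, MAF < 5%, or
Hardy–Weinberg exact p < 10⁻⁵. The HWE test is the exact conditional
test (sum of probabilities of heterozygote counts no more probable than
the observed one, conditioning on allele counts), computed in log space;
the asymptotic χ² test is provided as an alternative. Relatedness and
ancestry filtering are out of scope — the generator produces unrelated
subjects.

Association fits, per SNP, `outcome ~ intercept + dosage + covariates`
by iteratively reweighted least squares (relative deviance tolerance
10⁻⁸, cap 50 iterations), with a two-sided Wald test on the dosage
coefficient. Subjects missing a SNP are dropped for that SNP only
(`n_used` records the count). Separation or non-convergence flags the
SNP with a missing p-value rather than dropping the row. Covariates are
standardized internally for conditioning (the dosage test is invariant
to this). When requested, the top genotype principal components —
computed from the centered, `√(2p(1−p))`-scaled, mean-imputed dosage
matrix — are appended as covariates (default 8); these internal PCs are
an approximation of the external PCA a production GWAS would use. The
genomic inflation factor is λ = median(χ²₁ quantiles of 1 − p) / 0.4549.
Significance tiers: genome-wide 5×10⁻⁸; relaxed 5×10⁻⁶ (a relaxed tier
of 10⁻⁵ also circulates; 5×10⁻⁶ is the default and both are arguments).

### MWAS stage

Spectra enter post-Fourier-transform; FID processing (line broadening,
phasing) is out of scope. Preprocessing:

* **Water excision** removes all points with 4 ≤ ppm ≤ 5.
* **airPLS baseline.** The baseline z of a spectrum y minimizes
  `Σ wᵢ(yᵢ − zᵢ)² + λ·Σ(Δ²z)²`. Weights are re-estimated each
  iteration t: wᵢ = 0 where the residual d = y − z is non-negative
  (signal), `exp(t·|dᵢ|/|d⁻|₁)` below the baseline, with the endpoints
  pinned at the maximum weight; iteration stops when the
  negative-residual mass falls below 0.1% of the total signal or at
  `max_iter` (default 15). λ defaults to 10⁵ (grid-searchable): on a
  1,500-point grid this recovers a known quadratic baseline under a
  sharp peak to < 2% RMS in signal-free regions, and as λ → ∞ the
  baseline tends to the straight-line fit of the non-peak points.
* **Alignment** is rigid: each spectrum is shifted by whole grid points
  (≤ 0.02 ppm by default) to maximize cross-correlation with a
  reference (the pointwise median spectrum by default), candidate
  shifts scanned in order of increasing magnitude so ties resolve to no
  shift. This replaces wavelet-based peak alignment with a simpler
  procedure of identical intent (peak registration); it cannot correct
  local, peak-specific shifts.

Association runs per ppm grid point (tests at the grid resolution;
optional uniform binning, default off, bin width 0.001 ppm when on).
The cluster-membership model is logistic:
`member ~ intensity + age + sex` (sex follows the {1, 2} coding and
enters as a two-level category). P-values are Benjamini–Yekutieli
adjusted — `p_adj(i) = min_{j≥i} [m·c(m)·p₍ⱼ₎/j]`, `c(m) = Σ 1/k`,
monotone-enforced, capped at 1 — valid under the strong dependence of
neighboring spectral points. Non-converged points keep a missing
adjusted p but still count toward m. The significance mask uses
FDR < 10⁻³. The allele-dosage model is linear
(`intensity ~ C-count + age + sex`, vectorized OLS) and is reported
**unadjusted** by design, matching the companion-analysis convention;
its `p_adj` column simply copies `p`.

## The synthetic cohort

The generator produces data with the statistical structure the analysis
assumes, so every stage is testable without a data access agreement.

* **Traits** are multivariate normal per planted cluster (4 clusters,
  weights 4405/4496/4401/3490 ÷ 16,792). Cluster trait means are the
  published per-cluster values in original units (e.g. triglycerides
  64.6 mg/dL in cluster 2 vs 152 mg/dL in cluster 4). Within-cluster
  covariance is **diagonal**, with SDs equal to the published
  per-cluster SDs scaled by a dispersion factor of **0.2**. Two
  deliberate choices are folded in here:
  1. *Dispersion.* At the published within-cluster SDs the four
     clusters overlap so heavily that no clustering method can recover
     them (the nearest pair sits ≈ 1.5 Mahalanobis units apart; the
     Bayes-optimal assignment error alone exceeds what an ARI ≥ 0.8
     criterion tolerates, and the silhouette criterion collapses to
     k = 2). Real data evades this because the published clusters were
     *defined* by k-means on that data. A generator, by contrast, must
     plant recoverable structure: dispersion 0.2 makes silhouette
     select k = 4 with a clear margin (0.44 vs 0.33 at k = 2) and
     yields ARI ≈ 0.93, robustly across seeds. Passing tests therefore
     demonstrate that the pipeline recovers planted structure of
     published-scale mean separation — not that real biobank clusters
     are this crisp.
  2. *Correlation.* The planted cluster structure already induces
     strong observed inter-trait correlations (traits whose cluster
     means co-vary correlate at |r| > 0.6 in the pooled sample, which
     is exactly what the redundancy-pruning stage consumes). Planting
     an additional physiological within-cluster correlation matrix on
     top pushes most of the panel past the pruning threshold and
     strips the informative traits, so the default keeps within-cluster
     covariance diagonal; `physiological_corr()` remains available.
* **Disease flags** are Bernoulli draws from logistic models on the
  z-scored traits. Intercepts and coefficients were calibrated once so
  the realized per-cluster prevalences match the published gradient —
  dyslipidemia ≈ (5.6, 2.7, 5.3, 9.7)%, hypertension ≈ (8.3, 4.3, 6.9,
  17.1)%, diabetes ≈ (1.8, 1.1, 1.4, 4.4)% — with cluster 2 lowest and
  cluster 4 highest for every disease. Self-reported status has no
  generative description, so a trait-driven logistic model is the
  simplest mechanism producing the right gradient.
* **Genotypes.** The causal variant rs651821 draws
  Binomial(2, MAF of the subject's cluster) with per-cluster MAFs
  (0.2843, 0.2419, 0.2715, 0.2877); null SNPs draw one common MAF each
  from U(0.05, 0.5), independent of cluster. Linkage disequilibrium is
  not simulated — no implemented stage uses LD.
* **Spectra** are sums of Gaussian (optionally Lorentzian — line shapes
  are a free choice) peaks over a smooth non-negative baseline plus
  white noise, on a 0.5–5.0 ppm axis (2,250 points, stored in the
  descending-ppm plotting convention). Peak amplitudes are cluster
  means with 10% relative subject scatter; lipoprotein-methyl
  (0.86 ppm), leucine (0.955 ppm) and GlycA (2.04 ppm) amplitudes are
  lowest in cluster 2. `select_metabolome_subset` mirrors the
  stringent metabolome subsampling design (144 low-prevalence-cluster
  subjects vs 73 controls with BMI 18–24); the original lifestyle
  criteria (smoking, alcohol, exercise) have no synthetic counterpart
  and are represented by the BMI window alone.
* **Determinism.** All streams are children of one `SeedSequence`, so a
  config's seed fixes every output bit-for-bit. The default seed is
  20200305.

What the generator does **not** emulate: LD and population structure in
the genome (a two-subpopulation fixture is constructed ad hoc in the
tests for the PC-correction property), FID-level NMR artifacts
(phase/lineshape distortions, peak-specific shifts), measurement
batch effects, and relatedness. Conclusions from passing tests are
accordingly about algorithmic correctness and calibration, not about
field performance on raw instrument data.

## Problem sizes and numerical conventions

The shipped checks run the cluster-recovery block at n = 20,000
subjects, the GWAS null at 2,000 subjects × 1,000 SNPs, the planted-SNP
panel at 10,000 subjects × 1,001 SNPs, and the MWAS blocks at 217
subjects × 2,000 points (20 null replicates) — sizes chosen so the full
suite and the acceptance script each finish in well under a minute of
compute per block on one CPU while keeping every statistical criterion
well-powered.

Other conventions: p-values are floored at 10⁻³⁰⁰ (never exactly 0);
Wald χ² uses the N(0,1) reference; the sex covariate's {1, 2} coding is
centered internally; the silhouette subsample is drawn once per
selection run; k-means ties and pruning ties break deterministically by
index order; dosage values are validated to {0, 1, 2, NaN} on
construction.

## Known limitations

* The association stages are mass-univariate; no mixed models, no
  kinship correction, no imputation of genotypes.
* The internal genotype PCs are computed on the analyzed panel itself;
  with few SNPs they capture noise as readily as structure.
* Greedy Jaccard matching can differ from the optimal assignment when
  several clusters overlap strongly (the Hungarian option exists for
  that case).
* Redundancy pruning is greedy in correlation order; a surviving pair
  can in principle exceed the threshold when each member anchored the
  removal of the other's partner. The pruner asserts and logs this
  rather than resolving it.
* `prevalence_pct` rounds half-to-even (Python's `round`); printed
  tables that round half-up could differ in the last digit for exact
  .x5 cases (none of the worked examples hit one).
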