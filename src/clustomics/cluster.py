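"""PCA, k-means phenotype clustering, silhouette-based model selection,
Jaccard stability, and cluster characterization tables.

The clusterer is a self-contained Lloyd's-algorithm implementation (the
contract here asserts per-iteration inertia monotonicity and documents the
empty-cluster rule, which off-the-shelf implementations do not expose);
silhouette and PCA come from scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_ind
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .datatypes import ClusterModel, CohortTable, PCAModel, StabilityReport

__all__ = [
    "run_pca",
    "PhenotypeKMeans",
    "kmeans_fit",
    "select_k_silhouette",
    "assess_stability_jaccard",
    "summarize_clusters",
    "compare_diseased_vs_controls",
    "identify_low_prevalence_cluster",
    "ClusterSummary",
    "prevalence_pct",
]

_SILHOUETTE_CAP = 5000  # subsample cap for the O(n^2) distance matrix


def _trait_matrix(table) -> tuple[np.ndarray, list, list]:
    if isinstance(table, CohortTable):
        X = table.traits.to_numpy(float)
        return X, list(table.data.index), list(table.trait_columns)
    X = np.asarray(table, float)
    return X, list(range(X.shape[0])), [f"t{j}" for j in range(X.shape[1])]


def run_pca(table) -> PCAModel:
    """Exact full-rank SVD PCA of the trait block.

    Loadings columns are orthonormal eigenvectors with the sign convention
    that each column's largest-magnitude entry is positive; scores times
    loadings-transpose reconstructs the centered input at full rank.
    """
    X, index, traits = _trait_matrix(table)
    if np.isnan(X).any():
        raise ValueError("NaN in trait matrix; impute before PCA")
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
    loadings = pca.components_.T.copy()          # traits x components
    scores = pca.transform(X)
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return PCAModel(
        loadings=pd.DataFrame(loadings, index=traits, columns=comp_names),
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
        explained_variance=pca.explained_variance_ratio_.copy(),
        mean=pd.Series(pca.mean_, index=traits),
    )


class PhenotypeKMeans(BaseEstimator, ClusterMixin):
    """Lloyd's k-means with Euclidean distance.

    Parameters
    ----------
    n_clusters : number of clusters k (>= 2).
    init : ``"k-means++"`` or ``"random"`` (k distinct data rows chosen
        uniformly — the restart scheme used for stability assessment).
    n_init : number of independent initializations; the solution with the
        lowest inertia is kept (standard k-means practice).
    max_iter : iteration cap (convergence = assignments unchanged).
    random_state : seed for initialization.

    Notes
    -----
    Inertia is asserted non-increasing across iterations on every fit.
    If a cluster empties during iteration, its center is re-seeded at the
    point farthest from its assigned center.
    """

    def __init__(self, n_clusters: int = 4, init: str = "k-means++",
                 n_init: int = 1, max_iter: int = 300,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def _init_centers(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.init == "k-means++":
            seed = int(rng.integers(0, 2**31 - 1))
            centers, _ = kmeans_plusplus(X, self.n_clusters, random_state=seed)
            return centers.astype(float)
        if self.init == "random":
            idx = rng.choice(X.shape[0], size=self.n_clusters, replace=False)
            return X[idx].astype(float).copy()
        raise ValueError(f"unknown init {self.init!r}")

    @staticmethod
    def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
        # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; clip tiny negatives
        d = (X**2).sum(1)[:, None] - 2.0 * X @ centers.T + (centers**2).sum(1)[None, :]
        return np.clip(d, 0.0, None)

    def fit(self, X, y=None) -> "PhenotypeKMeans":
        X, _, _ = _trait_matrix(X)
        n, k = X.shape[0], self.n_clusters
        if not (2 <= k <= n):
            raise ValueError(f"need 2 <= k <= n (k={k}, n={n})")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_init)):
            labels, centers, inertia, n_iter = self._run_lloyd(X, rng)
            if best is None or inertia < best[2]:
                best = (labels, centers, inertia, n_iter)
        self.labels_, self.cluster_centers_, self.inertia_, self.n_iter_ = best
        return self

    def _run_lloyd(self, X: np.ndarray, rng: np.random.Generator):
        n, k = X.shape[0], self.n_clusters
        centers = self._init_centers(X, rng)

        labels = np.full(n, -1)
        inertia_prev = np.inf
        for it in range(self.max_iter):
            d = self._sq_dists(X, centers)
            new_labels = d.argmin(axis=1)
            inertia = d[np.arange(n), new_labels].sum()
            assert inertia <= inertia_prev + 1e-6 * max(1.0, inertia_prev), (
                "k-means inertia increased between iterations"
            )
            inertia_prev = inertia
            if (new_labels == labels).all():
                break
            labels = new_labels
            for c in range(k):
                members = X[labels == c]
                if len(members):
                    centers[c] = members.mean(axis=0)
                else:
                    # empty cluster: re-seed at the point farthest from its center
                    far = d[np.arange(n), labels].argmax()
                    centers[c] = X[far]
                    labels[far] = c
        d = self._sq_dists(X, centers)
        labels = d.argmin(axis=1)
        inertia = float(d[np.arange(n), labels].sum())
        return labels, centers, inertia, it + 1

    def predict(self, X) -> np.ndarray:
        X, _, _ = _trait_matrix(X)
        return self._sq_dists(X, self.cluster_centers_).argmin(axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def _silhouette(X: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                cap: int = _SILHOUETTE_CAP) -> float:
    if len(np.unique(labels)) < 2:
        return float("nan")
    if X.shape[0] > cap:
        idx = rng.choice(X.shape[0], size=cap, replace=False)
        Xs, ls = X[idx], labels[idx]
        if len(np.unique(ls)) < 2:
            return float("nan")
        return float(silhouette_score(Xs, ls))
    return float(silhouette_score(X, labels))


def kmeans_fit(table, k: int, seed: int | None = None, init: str = "k-means++") -> ClusterModel:
    """Fit k-means and package the result with a mean silhouette score.

    Labels in the returned :class:`ClusterModel` are 1-based.
    """
    X, index, _ = _trait_matrix(table)
    est = PhenotypeKMeans(n_clusters=k, init=init, n_init=10, random_state=seed).fit(X)
    rng = np.random.default_rng(seed)
    sil = _silhouette(X, est.labels_, rng)
    return ClusterModel(
        k=k,
        centers=est.cluster_centers_,
        assignment=pd.Series(est.labels_ + 1, index=index, name="cluster"),
        inertia=est.inertia_,
        silhouette_mean=sil,
        seed=seed,
    )


def select_k_silhouette(table, k_range=range(2, 8), seed: int | None = None):
    """Choose k by the average-silhouette criterion.

    Fits k-means for each k in ``k_range`` and evaluates the mean
    silhouette width on a fixed subsample of at most 5000 subjects (the
    full distance matrix is quadratic in n).  Returns ``(k_best,
    per_k_silhouette)``; ties go to the smallest k.
    """
    X, _, _ = _trait_matrix(table)
    k_range = list(k_range)
    if any(k < 2 or k >= X.shape[0] for k in k_range):
        raise ValueError("k_range must lie within [2, n-1]")
    rng = np.random.default_rng(seed)
    sub = (
        rng.choice(X.shape[0], size=_SILHOUETTE_CAP, replace=False)
        if X.shape[0] > _SILHOUETTE_CAP
        else np.arange(X.shape[0])
    )
    per_k: dict[int, float] = {}
    for k in k_range:
        est = PhenotypeKMeans(
            n_clusters=k, random_state=int(rng.integers(0, 2**31 - 1))
        ).fit(X)
        labels = est.labels_[sub]
        per_k[k] = (
            float(silhouette_score(X[sub], labels))
            if len(np.unique(labels)) > 1
            else float("-inf")
        )
    k_best = k_range[0]
    for k in k_range:
        if per_k[k] > per_k[k_best]:
            k_best = k
    return k_best, per_k


# ---------------------------------------------------------------------------
# Jaccard stability
# ---------------------------------------------------------------------------

def jaccard_matrix(ref_labels: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """k x k Jaccard indices |A∩B| / |A∪B| between reference and repeat clusters."""
    J = np.zeros((k, k))
    ref_sets = [ref_labels == c for c in range(1, k + 1)]
    rep_sets = [labels == c for c in range(1, k + 1)]
    for i, a in enumerate(ref_sets):
        for j, b in enumerate(rep_sets):
            inter = np.logical_and(a, b).sum()
            union = np.logical_or(a, b).sum()
            J[i, j] = inter / union if union else 0.0
    return J


def match_clusters(J: np.ndarray, method: str = "greedy") -> np.ndarray:
    """Per-reference-cluster matched Jaccard values.

    ``greedy`` repeatedly takes the globally largest entry and removes its
    row and column; ``hungarian`` maximizes the total matched Jaccard.
    """
    k = J.shape[0]
    if method == "hungarian":
        rows, cols = linear_sum_assignment(-J)
        out = np.zeros(k)
        out[rows] = J[rows, cols]
        return out
    if method != "greedy":
        raise ValueError(f"unknown matching method {method!r}")
    J = J.copy()
    out = np.zeros(k)
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(J), J.shape)
        out[i] = J[i, j]
        J[i, :] = -1.0
        J[:, j] = -1.0
    return out


def assess_stability_jaccard(
    table,
    reference: ClusterModel,
    n_repeats: int = 1000,
    seed: int | None = None,
    matching: str = "greedy",
    n_init: int = 10,
) -> StabilityReport:
    """Cluster stability over random-center restarts.

    Refits k-means ``n_repeats`` times, each repeat drawing ``n_init``
    fresh uniformly random center sets and keeping the lowest-inertia
    solution, then matches the repeat's clusters to the reference
    partition by maximum Jaccard and averages per reference cluster.
    ``overall_mean`` averages the per-cluster means; ``pooled_mean``
    averages over every (cluster, repeat) pair — the two coincide here
    but both are reported.
    """
    X, _, _ = _trait_matrix(table)
    k = reference.k
    ref_labels = np.asarray(reference.assignment)
    rng = np.random.default_rng(seed)
    per_cluster = np.zeros((n_repeats, k))
    for r in range(n_repeats):
        est = PhenotypeKMeans(
            n_clusters=k, init="random", n_init=n_init,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(X)
        J = jaccard_matrix(ref_labels, est.labels_ + 1, k)
        per_cluster[r] = match_clusters(J, matching)
    mean_jaccard = per_cluster.mean(axis=0)
    return StabilityReport(
        n_repeats=n_repeats,
        mean_jaccard=mean_jaccard,
        overall_mean=float(mean_jaccard.mean()),
        pooled_mean=float(per_cluster.mean()),
    )


# ---------------------------------------------------------------------------
# Cluster characterization
# ---------------------------------------------------------------------------

def prevalence_pct(cases: int, n: int) -> float:
    """Disease prevalence as a percentage, one decimal place."""
    if n <= 0:
        raise ValueError("n must be positive")
    return round(100.0 * cases / n, 1)


@dataclass
class ClusterSummary:
    """Per-cluster characterization in original units."""

    n: pd.Series                 # subjects per cluster
    trait_mean: pd.DataFrame     # traits x clusters
    trait_sd: pd.DataFrame
    disease_n: pd.DataFrame      # diseases x clusters
    disease_pct: pd.DataFrame    # prevalence %, 1 decimal

    def to_markdown(self) -> str:
        lines = ["| Trait | " + " | ".join(f"Cluster {c}" for c in self.n.index) + " |"]
        lines.append("|" + "---|" * (len(self.n) + 1))
        lines.append("| n | " + " | ".join(str(int(v)) for v in self.n) + " |")
        for t in self.trait_mean.index:
            cells = [
                f"{self.trait_mean.loc[t, c]:.4g} ({self.trait_sd.loc[t, c]:.3g})"
                for c in self.n.index
            ]
            lines.append(f"| {t}, mean (SD) | " + " | ".join(cells) + " |")
        for d in self.disease_n.index:
            cells = [
                f"{int(self.disease_n.loc[d, c])} ({self.disease_pct.loc[d, c]:.1f})"
                for c in self.n.index
            ]
            lines.append(f"| {d}, n (%) | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def summarize_clusters(cohort: CohortTable, model: ClusterModel) -> ClusterSummary:
    """Table-style cluster characterization: n, trait mean (SD) in original
    units, disease counts and prevalence percentages (one decimal)."""
    if not cohort.disease_columns:
        raise ValueError("cohort has no disease flags")
    assign = model.assignment.reindex(cohort.data.index)
    clusters = list(range(1, model.k + 1))
    n = pd.Series({c: int((assign == c).sum()) for c in clusters})
    trait_mean = pd.DataFrame(index=cohort.trait_columns, columns=clusters, dtype=float)
    trait_sd = pd.DataFrame(index=cohort.trait_columns, columns=clusters, dtype=float)
    disease_n = pd.DataFrame(index=cohort.disease_columns, columns=clusters, dtype=float)
    disease_pct = pd.DataFrame(index=cohort.disease_columns, columns=clusters, dtype=float)
    for c in clusters:
        sub = cohort.data[assign == c]
        trait_mean[c] = sub[cohort.trait_columns].mean()
        trait_sd[c] = sub[cohort.trait_columns].std(ddof=1)
        for d in cohort.disease_columns:
            cases = int(sub[d].sum())
            disease_n.loc[d, c] = cases
            disease_pct.loc[d, c] = prevalence_pct(cases, len(sub)) if len(sub) else np.nan
    return ClusterSummary(n=n, trait_mean=trait_mean, trait_sd=trait_sd,
                          disease_n=disease_n, disease_pct=disease_pct)


def compare_diseased_vs_controls(cohort: CohortTable, model: ClusterModel, cluster: int) -> pd.DataFrame:
    """Within-cluster diseased-vs-control comparison (Welch's t, two-sided).

    "Diseased" means positive for any disease flag.  Clusters with no
    diseased subjects yield blank (NaN) comparison columns, not an error.
    """
    assign = model.assignment.reindex(cohort.data.index)
    sub = cohort.data[assign == cluster]
    diseased = sub[cohort.disease_columns].any(axis=1)
    rows = {}
    for trait in ["AGE", "SEX", *cohort.trait_columns]:
        a = sub.loc[~diseased, trait].to_numpy(float)
        b = sub.loc[diseased, trait].to_numpy(float)
        if len(b) == 0 or len(a) == 0:
            rows[trait] = (np.mean(a) if len(a) else np.nan, np.std(a, ddof=1) if len(a) > 1 else np.nan,
                           np.nan, np.nan, np.nan)
            continue
        stat = ttest_ind(a, b, equal_var=False)
        rows[trait] = (a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1), stat.pvalue)
    return pd.DataFrame(
        rows, index=["control_mean", "control_sd", "diseased_mean", "diseased_sd", "p"]
    ).T


def identify_low_prevalence_cluster(summary: ClusterSummary) -> int:
    """The cluster minimizing mean disease prevalence across all diseases."""
    return int(summary.disease_pct.mean(axis=0).idxmin())
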