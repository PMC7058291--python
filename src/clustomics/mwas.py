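"""NMR spectral preprocessing and metabolome-wide association.

Preprocessing: water-region excision (4-5 ppm), adaptive iteratively
reweighted penalized least squares (airPLS) baseline correction, and rigid
cross-correlation alignment of spectra to a reference.  Association: per
ppm point, logistic regression of cluster membership on intensity with age
and sex as confounders under Benjamini-Yekutieli FDR control, and the
companion linear model of intensity on minor-allele count (reported
unadjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator

from .datatypes import SpectrumSet
from .glm import benjamini_yekutieli, mass_univariate_linear, mass_univariate_logistic

__all__ = [
    "remove_water_region",
    "airpls",
    "airpls_baseline",
    "align_spectra",
    "LogisticMWAS",
    "AlleleDosageMWAS",
    "mwas_logistic",
    "mwas_linear_allele",
    "MWASResult",
    "bin_spectra",
    "annotate_ppm",
    "PPM_ASSIGNMENTS",
]

#: Static chemical-shift lookup used only to label output rows.
PPM_ASSIGNMENTS = {
    0.86: "VLDL/LDL lipoprotein CH3",
    0.955: "leucine",
    1.02: "valine",
    1.28: "lipid CH2 / triglyceride",
    1.33: "lactate CH3",
    1.48: "alanine",
    1.92: "acetate",
    2.04: "GlycA (glycoprotein N-acetyl)",
    2.22: "acetone",
    3.04: "creatinine",
    3.40: "glucose ring",
    3.72: "glucose ring",
    4.11: "lactate CH",
}


def annotate_ppm(ppm: float, tolerance: float = 0.03) -> str:
    """Nearest catalogued resonance within ``tolerance`` ppm, else ''."""
    best, dist = "", tolerance
    for center, name in PPM_ASSIGNMENTS.items():
        d = abs(ppm - center)
        if d <= dist:
            best, dist = name, d
    return best


def remove_water_region(s: SpectrumSet, lo: float = 4.0, hi: float = 5.0) -> SpectrumSet:
    """Delete all points with lo <= ppm <= hi (the water resonance band)."""
    keep = ~((s.ppm >= lo) & (s.ppm <= hi))
    if not keep.any():
        raise ValueError("no points remain after water-region removal")
    return SpectrumSet(ppm=s.ppm[keep], intensity=s.intensity[:, keep], meta=s.meta)


def airpls(y: np.ndarray, lam: float = 1e5, max_iter: int = 15) -> np.ndarray:
    """Estimate one spectrum's baseline by airPLS.

    The baseline z minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2``
    (second-difference Whittaker penalty).  Weights are re-estimated each
    iteration: points above the baseline get weight 0, points below get
    ``exp(t |d_i| / |d|_1)`` where d is the negative part of the residual
    and t the iteration number; the end points keep a large weight to pin
    the baseline.  Iteration stops when the negative-residual mass drops
    below 0.1% of the total signal.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = np.asarray(y, float)
    m = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(m - 2, m), format="csc")
    H = (lam * (D.T @ D)).tocsc()
    w = np.ones(m)
    z = y.copy()
    for t in range(1, max_iter + 1):
        W = sparse.diags(w, 0, format="csc")
        z = spsolve(W + H, w * y)
        d = y - z
        neg = d < 0
        dssn = np.abs(d[neg]).sum()
        if dssn < 0.001 * np.abs(y).sum() or t == max_iter:
            break
        w[~neg] = 0.0
        w[neg] = np.exp(t * np.abs(d[neg]) / dssn)
        w[0] = w[-1] = np.exp(t * np.abs(d[neg]).max() / dssn)
    return z


def airpls_baseline(
    s: SpectrumSet, lam: float = 1e5, max_iter: int = 15
) -> tuple[SpectrumSet, np.ndarray]:
    """Baseline-correct every spectrum; returns (corrected set, baselines)."""
    if s.n_points < 10:
        raise ValueError("need at least 10 points per spectrum")
    baselines = np.vstack([airpls(row, lam=lam, max_iter=max_iter) for row in s.intensity])
    return SpectrumSet(ppm=s.ppm, intensity=s.intensity - baselines, meta=s.meta), baselines


def align_spectra(
    s: SpectrumSet,
    reference="median",
    max_shift_ppm: float = 0.02,
) -> tuple[SpectrumSet, np.ndarray]:
    """Rigid alignment: shift each spectrum (whole grid points) to maximize
    cross-correlation with the reference.

    ``reference`` is a subject row index or ``"median"`` (the pointwise
    median spectrum).  Candidate shifts are scanned in order of increasing
    magnitude so exact ties resolve to the smallest shift (identical
    spectra stay put).  Shifted-in edge samples take the edge value.
    Returns (aligned set, applied shifts in grid points).
    """
    step = abs(float(np.median(np.diff(s.ppm))))
    max_shift = int(round(max_shift_ppm / step))
    ref = (
        np.median(s.intensity, axis=0)
        if isinstance(reference, str) and reference == "median"
        else s.intensity[int(reference)]
    )
    ref_c = ref - ref.mean()
    candidates = sorted(range(-max_shift, max_shift + 1), key=abs)

    aligned = np.empty_like(s.intensity)
    shifts = np.zeros(s.n_subjects, dtype=int)
    for i, row in enumerate(s.intensity):
        best_shift, best_score = 0, -np.inf
        for k in candidates:
            shifted = _shift_row(row, k)
            score = float(np.dot(shifted - shifted.mean(), ref_c))
            if score > best_score + 1e-12:
                best_score, best_shift = score, k
        shifts[i] = best_shift
        aligned[i] = _shift_row(row, best_shift)
    return SpectrumSet(ppm=s.ppm, intensity=aligned, meta=s.meta), shifts


def _shift_row(row: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return row.copy()
    out = np.empty_like(row)
    if k > 0:
        out[k:] = row[:-k]
        out[:k] = row[0]
    else:
        out[:k] = row[-k:]
        out[k:] = row[-1]
    return out


def bin_spectra(s: SpectrumSet, width_ppm: float = 0.001) -> SpectrumSet:
    """Uniform binning: average intensity within consecutive ppm bins."""
    ascending = s.ppm[0] < s.ppm[-1]
    ppm = s.ppm if ascending else s.ppm[::-1]
    inten = s.intensity if ascending else s.intensity[:, ::-1]
    edges = np.arange(ppm[0], ppm[-1] + width_ppm, width_ppm)
    idx = np.clip(np.digitize(ppm, edges) - 1, 0, len(edges) - 2)
    centers, cols = [], []
    for b in np.unique(idx):
        sel = idx == b
        centers.append(ppm[sel].mean())
        cols.append(inten[:, sel].mean(axis=1))
    new_ppm = np.array(centers)
    new_int = np.column_stack(cols)
    if not ascending:
        new_ppm, new_int = new_ppm[::-1], new_int[:, ::-1]
    return SpectrumSet(ppm=new_ppm, intensity=new_int, meta=s.meta)


@dataclass
class MWASResult:
    """Per-ppm-point association with an FDR significance mask.

    ``table`` columns: ppm, beta, se, p, p_adj, sign, significant,
    n_used, converged, assignment.  ``fdr_threshold`` is the adjusted-p
    cutoff used for the mask (None when no adjustment was applied).
    """

    table: pd.DataFrame
    fdr_threshold: float | None

    def significant_points(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def fdr_plot_table(self) -> pd.DataFrame:
        """(ppm, -log10 p_adj, sign) table for external plotting."""
        t = self.table
        with np.errstate(divide="ignore"):
            mlp = -np.log10(t["p_adj"].to_numpy(float))
        return pd.DataFrame({"ppm": t["ppm"], "minus_log10_p_adj": mlp, "sign": t["sign"]})


def _covariate_matrix(meta: pd.DataFrame) -> np.ndarray:
    # SEX follows the {1, 2} coding; as a two-level category one centered
    # dummy column is equivalent
    return np.column_stack(
        [meta["AGE"].to_numpy(float), (meta["SEX"].to_numpy(float) == 2).astype(float)]
    )


class LogisticMWAS(BaseEstimator):
    """Metabolome-wide logistic association with cluster membership.

    For every ppm point fits ``member ~ intensity + age + sex`` where
    ``member`` indicates the target cluster (default: the lowest label
    present is NOT assumed — pass ``target_cluster``).  P-values are
    Benjamini-Yekutieli adjusted over the full point count (non-converged
    points keep NaN but still count toward m) and masked at
    ``fdr_threshold``.
    """

    def __init__(self, target_cluster: int = 2, fdr_threshold: float = 1e-3,
                 min_class_size: int = 20):
        self.target_cluster = target_cluster
        self.fdr_threshold = fdr_threshold
        self.min_class_size = min_class_size

    def fit(self, s: SpectrumSet) -> "LogisticMWAS":
        if "cluster_label" not in s.meta.columns:
            raise ValueError("meta lacks cluster_label")
        y = (s.meta["cluster_label"].to_numpy(int) == self.target_cluster).astype(float)
        n1 = int(y.sum())
        if min(n1, len(y) - n1) < self.min_class_size:
            raise ValueError(
                f"both classes need >= {self.min_class_size} subjects "
                f"(got {n1} vs {len(y) - n1})"
            )
        res = mass_univariate_logistic(
            s.intensity, y, covariates=_covariate_matrix(s.meta),
            feature_ids=[f"{p:.4f}" for p in s.ppm],
        )
        res["ppm"] = s.ppm
        res["p_adj"] = benjamini_yekutieli(res["p"].to_numpy(float))
        res["sign"] = np.sign(res["beta"])
        res["significant"] = res["p_adj"] < self.fdr_threshold
        res["significant"] = res["significant"].fillna(False)
        res["assignment"] = [annotate_ppm(p) for p in s.ppm]
        self.result_ = MWASResult(table=res, fdr_threshold=self.fdr_threshold)
        return self


class AlleleDosageMWAS(BaseEstimator):
    """Linear association of intensity with minor-allele count.

    Per ppm point fits ``intensity ~ C_count + age + sex``; raw p-values
    are reported without multiplicity adjustment (``p_adj = p``), matching
    the companion analysis design.
    """

    def __init__(self, allele_column: str = "rs651821_C_count",
                 significance_p: float = 1e-3):
        self.allele_column = allele_column
        self.significance_p = significance_p

    def fit(self, s: SpectrumSet) -> "AlleleDosageMWAS":
        if self.allele_column not in s.meta.columns:
            raise ValueError(f"meta lacks {self.allele_column}")
        res = mass_univariate_linear(
            s.intensity,
            s.meta[self.allele_column].to_numpy(float),
            covariates=_covariate_matrix(s.meta),
            feature_ids=[f"{p:.4f}" for p in s.ppm],
        )
        res["ppm"] = s.ppm
        res["p_adj"] = res["p"]  # deliberately unadjusted
        res["sign"] = np.sign(res["beta"])
        res["significant"] = (res["p_adj"] < self.significance_p).fillna(False)
        res["assignment"] = [annotate_ppm(p) for p in s.ppm]
        self.result_ = MWASResult(table=res, fdr_threshold=None)
        return self


def mwas_logistic(s: SpectrumSet, target_cluster: int = 2,
                  fdr_threshold: float = 1e-3) -> MWASResult:
    """Functional wrapper over :class:`LogisticMWAS`."""
    return LogisticMWAS(target_cluster, fdr_threshold).fit(s).result_


def mwas_linear_allele(s: SpectrumSet, allele_column: str = "rs651821_C_count") -> MWASResult:
    """Functional wrapper over :class:`AlleleDosageMWAS`."""
    return AlleleDosageMWAS(allele_column).fit(s).result_
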