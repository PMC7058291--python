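"""Spectral preprocessing and metabolome-wide association."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, spearmanr

from clustomics import (
    SpectrumSet,
    airpls,
    airpls_baseline,
    align_spectra,
    annotate_ppm,
    bin_spectra,
    default_config,
    generate_phenotypes,
    generate_spectra,
    mwas_linear_allele,
    mwas_logistic,
    remove_water_region,
)


def make_set(ppm, intensity, cluster=None, allele=None, age=None, sex=None):
    intensity = np.atleast_2d(np.asarray(intensity, float))
    n = intensity.shape[0]
    rng = np.random.default_rng(0)
    meta = pd.DataFrame(
        {
            "AGE": age if age is not None else rng.uniform(30, 70, n),
            "SEX": sex if sex is not None else rng.integers(1, 3, n),
        },
        index=pd.Index([f"S{i}" for i in range(n)], name="subject_id"),
    )
    if cluster is not None:
        meta["cluster_label"] = np.asarray(cluster, int)
    if allele is not None:
        meta["rs651821_C_count"] = np.asarray(allele, float)
    return SpectrumSet(ppm=np.asarray(ppm, float), intensity=intensity, meta=meta)


class TestWaterRegion:
    def test_band_removed_exactly(self):
        ppm = np.arange(0.0, 10.0, 0.01)
        s = make_set(ppm, np.ones((3, ppm.size)))
        out = remove_water_region(s)
        in_band = ((ppm >= 4) & (ppm <= 5)).sum()
        assert out.n_points == s.n_points - in_band
        assert not ((out.ppm >= 4) & (out.ppm <= 5)).any()
        assert out.n_subjects == 3

    def test_axis_entirely_in_band_raises(self):
        ppm = np.linspace(4.1, 4.9, 50)
        s = make_set(ppm, np.ones((2, 50)))
        with pytest.raises(ValueError, match="no points remain"):
            remove_water_region(s)

    def test_idempotent(self):
        ppm = np.linspace(0.5, 6.0, 300)
        s = make_set(ppm, np.random.default_rng(1).normal(size=(2, 300)))
        once = remove_water_region(s)
        twice = remove_water_region(once)
        np.testing.assert_array_equal(once.ppm, twice.ppm)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_subject_permutation_equivariance(self):
        ppm = np.linspace(0.5, 6.0, 200)
        X = np.random.default_rng(2).normal(size=(5, 200))
        s = make_set(ppm, X)
        perm = [3, 1, 4, 0, 2]
        sp = SpectrumSet(ppm=ppm, intensity=X[perm], meta=s.meta.iloc[perm])
        a = remove_water_region(s).intensity[perm]
        b = remove_water_region(sp).intensity
        np.testing.assert_array_equal(a, b)


class TestAirPLS:
    def test_flat_spectrum_fully_corrected(self):
        ppm = np.linspace(0.5, 5.0, 200)
        s = make_set(ppm, np.full((2, 200), 7.0))
        corrected, baselines = airpls_baseline(s)
        np.testing.assert_allclose(corrected.intensity, 0.0, atol=1e-8)
        np.testing.assert_allclose(baselines, 7.0, atol=1e-8)

    def test_quadratic_baseline_recovered_within_two_percent(self):
        ppm = np.linspace(0.5, 5.0, 1500)
        true_base = 5 + 0.8 * (ppm - 2.5) ** 2
        peak = 20 * np.exp(-0.5 * ((ppm - 2.0) / 0.05) ** 2)
        rng = np.random.default_rng(3)
        y = true_base + peak + rng.normal(0, 0.05, ppm.size)
        z = airpls(y, lam=1e5)
        free = np.abs(ppm - 2.0) > 0.3
        rms = np.sqrt(np.mean((z[free] - true_base[free]) ** 2))
        assert rms / np.sqrt(np.mean(true_base[free] ** 2)) < 0.02

    def test_infinite_smoothness_limit_is_straight_line(self):
        ppm = np.linspace(0, 10, 800)
        base = 1.0 + 0.3 * ppm
        y = base + 15 * np.exp(-0.5 * ((ppm - 5) / 0.1) ** 2)
        z = airpls(y, lam=1e10, max_iter=30)
        free = np.abs(ppm - 5) > 0.6
        line = np.polyval(np.polyfit(ppm[free], y[free], 1), ppm)
        assert np.abs(z[free] - line[free]).max() < 1e-3

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            airpls(np.ones(50), lam=0.0)

    def test_minimum_points(self):
        ppm = np.linspace(1, 2, 5)
        s = make_set(ppm, np.ones((1, 5)))
        with pytest.raises(ValueError, match="10 points"):
            airpls_baseline(s)


class TestAlignment:
    def test_identical_spectra_zero_shift(self):
        ppm = np.linspace(5.0, 0.5, 400)
        row = np.exp(-0.5 * ((ppm - 2.0) / 0.05) ** 2)
        s = make_set(ppm, np.tile(row, (4, 1)))
        _, shifts = align_spectra(s)
        assert (shifts == 0).all()

    def test_planted_shift_recovered(self):
        ppm = np.linspace(5.0, 0.5, 400)
        row = np.exp(-0.5 * ((ppm - 2.0) / 0.1) ** 2)
        shifted = np.roll(row, 3)
        s = make_set(ppm, np.vstack([row, shifted]), age=[50, 50], sex=[1, 1])
        aligned, shifts = align_spectra(s, reference=0, max_shift_ppm=0.1)
        assert shifts[0] == 0
        assert shifts[1] == -3
        np.testing.assert_allclose(aligned.intensity[1][5:-5], row[5:-5], atol=1e-10)

    def test_pure_noise_shifts_bounded(self):
        rng = np.random.default_rng(4)
        ppm = np.linspace(5.0, 0.5, 500)
        s = make_set(ppm, rng.normal(size=(6, 500)))
        _, shifts = align_spectra(s, max_shift_ppm=0.02)
        step = abs(np.median(np.diff(s.ppm)))
        assert (np.abs(shifts) <= int(round(0.02 / step))).all()


class TestLogisticMWAS:
    def planted_set(self, n1=144, n0=73, effect=0.8, seed=5):
        rng = np.random.default_rng(seed)
        ppm = np.linspace(4.0, 0.5, 2000)
        cluster = np.array([2] * n1 + [1] * n0)
        glyca = np.exp(-0.5 * ((ppm - 2.04) / 0.018) ** 2)
        amp = np.where(cluster == 2, 8.0, 8.0 + effect)
        X = amp[:, None] * glyca[None, :] + rng.normal(0, 0.3, (n1 + n0, 2000))
        return make_set(ppm, X, cluster=cluster)

    def test_by_adjustment_hand_oracle(self):
        from clustomics import benjamini_yekutieli

        p = np.array([0.01, 0.02, 0.03])
        # c(3) = 11/6; adjusted all equal 3 * 11/6 * 0.01 = 0.055
        np.testing.assert_allclose(benjamini_yekutieli(p), [0.055, 0.055, 0.055])

    def test_planted_glyca_effect_detected_with_negative_sign(self):
        res = mwas_logistic(self.planted_set(), target_cluster=2)
        sig = res.significant_points()
        assert len(sig) > 0
        # detection concentrated within 2 sigma of the planted 2.04 band
        assert (np.abs(sig["ppm"] - 2.04) <= 0.04).all()
        assert (np.abs(sig["ppm"] - 2.04) <= 0.01).any()
        assert (sig["sign"] == -1).all()
        assert (sig["assignment"] == "GlycA (glycoprotein N-acetyl)").all()

    def test_null_spectra_rarely_flag_anything(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            ppm = np.linspace(4.0, 0.5, 500)
            X = rng.normal(size=(120, 500))
            cluster = np.array([2] * 70 + [1] * 50)
            res = mwas_logistic(make_set(ppm, X, cluster=cluster), target_cluster=2)
            hits += len(res.significant_points()) > 0
        assert hits == 0

    def test_class_size_guard(self):
        ppm = np.linspace(4.0, 0.5, 50)
        s = make_set(ppm, np.random.default_rng(6).normal(size=(30, 50)),
                     cluster=[2] * 25 + [1] * 5)
        with pytest.raises(ValueError, match=">= 20"):
            mwas_logistic(s, target_cluster=2)

    def test_mask_implies_threshold(self):
        res = mwas_logistic(self.planted_set(), target_cluster=2)
        t = res.table
        assert (t.loc[t["significant"], "p_adj"] < 1e-3).all()
        valid = t["p_adj"].notna()
        assert (t.loc[valid, "p_adj"] >= t.loc[valid, "p"] - 1e-15).all()


class TestAlleleMWAS:
    def test_exact_linear_signal_recovered(self):
        rng = np.random.default_rng(7)
        ppm = np.linspace(3.0, 0.5, 100)
        allele = np.array([0.0, 1, 2] * 20)
        X = np.tile(2.0 * allele[:, None], (1, 100))
        X += rng.normal(0, 1e-10, X.shape)
        s = make_set(ppm, X, allele=allele,
                     age=rng.uniform(30, 70, 60), sex=rng.integers(1, 3, 60))
        res = mwas_linear_allele(s)
        assert np.allclose(res.table["beta"], 2.0, atol=1e-6)
        assert (res.table["p"] < 1e-100).all()
        # deliberately unadjusted
        pd.testing.assert_series_equal(res.table["p_adj"], res.table["p"], check_names=False)

    def test_permuted_alleles_uniform_p(self):
        rng = np.random.default_rng(8)
        ppm = np.linspace(3.0, 0.5, 400)
        X = rng.normal(size=(150, 400))
        allele = rng.permutation(np.repeat([0, 1, 2], 50)).astype(float)
        res = mwas_linear_allele(make_set(ppm, X, allele=allele))
        assert kstest(res.table["p"].dropna(), "uniform").pvalue > 0.01

    def test_profiles_correlate_when_loci_shared(self):
        """Cluster MWAS and allele MWAS highlight the same loci when the
        allele count tracks cluster membership."""
        rng = np.random.default_rng(9)
        n = 220
        ppm = np.linspace(3.0, 0.5, 600)
        cluster = np.array([2] * 120 + [1] * 100)
        # allele count anti-correlated with cluster-2 membership
        allele = np.where(cluster == 2, rng.binomial(2, 0.15, n), rng.binomial(2, 0.5, n)).astype(float)
        peaks = sum(
            np.exp(-0.5 * ((ppm - c) / 0.08) ** 2) for c in (0.86, 1.28, 1.7, 2.04, 2.5, 2.8)
        )
        # intensity rises with allele count and with non-membership in cluster 2
        amp = 6.0 + 0.5 * allele + 0.8 * (cluster != 2)
        X = amp[:, None] * peaks[None, :] + rng.normal(0, 0.5, (n, ppm.size))
        s = make_set(ppm, X, cluster=cluster, allele=allele)
        log_res = mwas_logistic(s, target_cluster=2)
        lin_res = mwas_linear_allele(s)
        a = -np.log10(np.clip(log_res.table["p"].to_numpy(float), 1e-300, 1))
        b = -np.log10(np.clip(lin_res.table["p"].to_numpy(float), 1e-300, 1))
        rho = spearmanr(a, b).statistic
        assert rho > 0.5


class TestUtilities:
    def test_binning_halves_resolution(self):
        ppm = np.linspace(0.5, 1.5, 100)
        s = make_set(ppm, np.random.default_rng(10).normal(size=(3, 100)))
        out = bin_spectra(s, width_ppm=0.05)
        assert out.n_points < s.n_points
        assert out.n_subjects == 3

    def test_ppm_annotation(self):
        assert annotate_ppm(2.045) == "GlycA (glycoprotein N-acetyl)"
        assert annotate_ppm(9.0) == ""
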