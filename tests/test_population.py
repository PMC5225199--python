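"""Metric matrix, PCA with significance and bootstrap, clustering, baselines."""
import math

import numpy as np
import pandas as pd
import pytest

from arbormetry.population import (
    bootstrap_coefficients,
    broken_stick_thresholds,
    build_metric_matrix,
    normalize_and_exclude,
    random_branching_baselines,
    regress_excluded,
    run_pca,
    significant_components,
    variance_fraction,
    ward_clustering,
)
from arbormetry.synthetic import planted_factor_matrix


def z_matrix(df):
    return normalize_and_exclude(df, manual_exclusions=())


class TestMetricMatrix:
    def test_row_count_and_normalization(self):
        df = build_metric_matrix(planted_factor_matrix(n_cells=43, seed=0))
        mm = z_matrix(df)
        assert len(mm.normalized) == 43
        np.testing.assert_allclose(mm.normalized.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(mm.normalized.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_flagged(self):
        df = planted_factor_matrix(n_cells=30, seed=1)
        df["flat"] = 3.14
        mm = z_matrix(df)
        assert mm.exclusions.get("flat") == "near-constant"

    def test_incomplete_cells_dropped(self):
        df = planted_factor_matrix(n_cells=20, seed=2)
        df.iloc[3, 0] = np.nan
        out = build_metric_matrix(df)
        assert len(out) == 19
        assert out.attrs["dropped_cells"] == [3]

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            build_metric_matrix(planted_factor_matrix(n_cells=2, seed=0))


class TestExclusion:
    def test_duplicate_column_excluded(self):
        df = planted_factor_matrix(n_cells=40, seed=3)
        df["dup"] = df["metric_00"] * 2.0
        mm = normalize_and_exclude(df, manual_exclusions=("dup",))
        assert mm.exclusions.get("dup") == "redundant"
        assert "metric_00" in mm.included

    def test_independent_columns_retained(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        mm = normalize_and_exclude(df, manual_exclusions=("a", "b"))
        assert mm.exclusions == {}

    def test_exclusion_requires_manual_listing(self):
        # a strongly correlated metric not on the geometric-relation list
        # stays in (correlation alone is not sufficient)
        df = planted_factor_matrix(n_cells=40, seed=5)
        df["dup"] = df["metric_00"] + 1e-6 * np.arange(40)
        mm = normalize_and_exclude(df, manual_exclusions=())
        assert "dup" in mm.included

    def test_segment_count_redundant_with_node_count(self):
        # the canonical example: segments = nodes + endings tracks nodes
        rng = np.random.default_rng(6)
        nodes = rng.integers(50, 300, size=40)
        endings = nodes + rng.integers(1, 10, size=40)
        df = pd.DataFrame(
            {
                "n_nodes": nodes,
                "n_segments": nodes + endings,
                "other": rng.normal(size=40),
            }
        )
        mm = normalize_and_exclude(df, manual_exclusions=("n_segments",))
        assert mm.exclusions.get("n_segments") == "redundant"

    def test_all_excluded_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.full(10, 2.0)})
        with pytest.raises(ValueError):
            normalize_and_exclude(df)


class TestPCA:
    def test_published_fraction_arithmetic(self):
        # eigenvalues 6.9 and 4.1 over 27 metrics: 26% and 15%, jointly >40%
        f1 = variance_fraction(6.9, 27)
        f2 = variance_fraction(4.1, 27)
        assert round(100 * f1) == 26
        assert round(100 * f2) == 15
        assert 100 * (f1 + f2) > 40

    def test_trace_identity(self):
        mm = z_matrix(planted_factor_matrix(n_cells=40, seed=7))
        res = run_pca(mm)
        assert res.eigenvalues.sum() == pytest.approx(res.n_metrics, rel=1e-9)
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_non_increasing(self):
        mm = z_matrix(planted_factor_matrix(n_cells=40, seed=8))
        res = run_pca(mm)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_isotropic_data_fractions_flat(self):
        # for isotropic data the ordered sample eigenvalues crowd the
        # Marchenko-Pastur bulk around 1, so with many more cells than
        # metrics every variance fraction approaches 1/p
        rng = np.random.default_rng(9)
        for _ in range(5):
            df = pd.DataFrame(rng.normal(size=(20_000, 5)))
            df.columns = [f"m{i}" for i in range(5)]
            res = run_pca(z_matrix(df))
            assert np.abs(res.variance_fractions - 0.2).max() < 0.01

    def test_scores_reproduce_components(self):
        mm = z_matrix(planted_factor_matrix(n_cells=40, seed=10))
        res = run_pca(mm)
        recon = res.scores.to_numpy() @ res.components.to_numpy().T
        np.testing.assert_allclose(recon, mm.normalized.to_numpy(), atol=1e-9)


class TestSignificance:
    def test_broken_stick_thresholds_three_metrics(self):
        np.testing.assert_allclose(
            broken_stick_thresholds(3), [11 / 6, 5 / 6, 1 / 3], rtol=1e-12
        )

    def test_single_planted_factor_only_pc1(self):
        df = planted_factor_matrix(n_cells=50, n_metrics=15, n_factors=1,
                                   loading=0.75, n_noise_metrics=3, seed=11)
        mm = z_matrix(df)
        res = run_pca(mm)
        for method in ("random_data_mc", "broken_stick"):
            flags = significant_components(res, method=method, n_null=300, seed=1)
            assert flags[0]
            assert not flags[1:].any()

    def test_pure_noise_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            df = pd.DataFrame(rng.normal(size=(40, 12)),
                              columns=[f"m{i}" for i in range(12)])
            res = run_pca(z_matrix(df))
            flags = significant_components(res, method="random_data_mc",
                                           n_null=300, alpha=0.05, seed=seed)
            hits += int(flags.any())
        assert hits <= 1  # zero significant PCs in >=90% of seeds

    def test_small_null_rejected(self):
        res = run_pca(z_matrix(planted_factor_matrix(n_cells=30, seed=12)))
        with pytest.raises(ValueError):
            significant_components(res, n_null=10)


class TestBootstrap:
    def test_sign_correction_guarantees_nonnegative_products(self):
        mm = z_matrix(planted_factor_matrix(n_cells=35, seed=13))
        res = run_pca(mm)
        rng = np.random.default_rng(0)
        raw = mm.data[mm.included].to_numpy()
        orig = res.components.to_numpy()[:, :2]
        for _ in range(50):
            idx = rng.integers(0, len(raw), size=len(raw))
            x = raw[idx]
            sd = x.std(0, ddof=1)
            if (sd < 1e-12).any():
                continue
            z = (x - x.mean(0)) / sd
            w, v = np.linalg.eigh(z.T @ z / (len(z) - 1))
            v = v[:, np.argsort(w)[::-1]][:, :2]
            signs = np.sign(np.diag(orig.T @ v))
            signs[signs == 0] = 1
            corrected = v * signs
            dots = np.diag(orig.T @ corrected)
            assert (dots >= 0).all()

    def test_planted_loadings_get_high_z(self):
        df = planted_factor_matrix(n_cells=45, n_metrics=12, n_factors=1,
                                   loading=0.8, n_noise_metrics=4, seed=14)
        mm = z_matrix(df)
        res = run_pca(mm)
        boot = bootstrap_coefficients(mm, res, n_boot=400, n_components=1, seed=2)
        z = boot["z"]["PC1"]
        loaded = [f"metric_{i:02d}" for i in range(8)]
        noise = [f"metric_{i:02d}" for i in range(8, 12)]
        assert (z[loaded] > 2).mean() >= 0.9
        assert (z[noise] < 2).mean() >= 0.9

    def test_deterministic_given_seed(self):
        mm = z_matrix(planted_factor_matrix(n_cells=30, seed=15))
        res = run_pca(mm)
        a = bootstrap_coefficients(mm, res, n_boot=100, seed=5)["z"]
        b = bootstrap_coefficients(mm, res, n_boot=100, seed=5)["z"]
        pd.testing.assert_frame_equal(a, b)


class TestRegressExcluded:
    def test_duplicate_of_loaded_metric_has_high_r2(self):
        df = planted_factor_matrix(n_cells=45, n_metrics=10, n_factors=1,
                                   loading=0.85, n_noise_metrics=2, seed=16)
        df["dup"] = df["metric_00"] * 3.0 + 1.0
        mm = normalize_and_exclude(df, manual_exclusions=("dup",))
        assert "dup" in mm.exclusions
        res = run_pca(mm)
        reg = regress_excluded(mm, res, n_components=1)
        r2 = reg.loc[reg["metric"] == "dup", "r2"].iloc[0]
        assert r2 > 0.4

    def test_noise_metric_has_low_r2(self):
        df = planted_factor_matrix(n_cells=60, n_metrics=10, n_factors=1,
                                   loading=0.8, n_noise_metrics=2, seed=17)
        rng = np.random.default_rng(3)
        df["noise_dup"] = df["metric_00"] + 0.0  # excluded as duplicate
        df["pure_noise"] = rng.normal(size=60)
        mm = normalize_and_exclude(df, manual_exclusions=("noise_dup",))
        res = run_pca(mm)
        white = rng.normal(size=60)
        from scipy.stats import linregress

        fit = linregress(res.scores["PC1"], white)
        assert fit.rvalue**2 < 0.15

    def test_invariant_to_cell_order(self):
        df = planted_factor_matrix(n_cells=40, n_metrics=8, n_factors=1,
                                   loading=0.8, n_noise_metrics=2, seed=18)
        df["dup"] = df["metric_00"] * 2
        mm = normalize_and_exclude(df, manual_exclusions=("dup",))
        res = run_pca(mm)
        reg1 = regress_excluded(mm, res, n_components=1)
        perm = np.random.default_rng(4).permutation(40)
        dfp = df.iloc[perm].reset_index(drop=True)
        mmp = normalize_and_exclude(dfp, manual_exclusions=("dup",))
        reg2 = regress_excluded(mmp, run_pca(mmp), n_components=1)
        np.testing.assert_allclose(
            np.abs(reg1["coefficient"]), np.abs(reg2["coefficient"]), rtol=1e-9
        )
        np.testing.assert_allclose(reg1["r2"], reg2["r2"], atol=1e-9)


class TestWardClustering:
    def _blobs(self, sep, seed=0, n=30, p=6):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, p))
        b = rng.normal(size=(n, p)) + sep / math.sqrt(p)
        df = pd.DataFrame(np.vstack([a, b]), columns=[f"m{i}" for i in range(p)])
        return z_matrix(df)

    def test_two_well_separated_blobs(self):
        res = ward_clustering(self._blobs(10.0))
        assert res.n_clusters == 2
        labels = res.labels
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1

    def test_single_gaussian_not_separable(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(60, 6)), columns=[f"m{i}" for i in range(6)])
        res = ward_clustering(z_matrix(df))
        assert res.n_clusters is None

    def test_permutation_invariance(self):
        mm = self._blobs(10.0, seed=2)
        res1 = ward_clustering(mm)
        perm = np.random.default_rng(5).permutation(len(mm.normalized))
        dfp = mm.data.iloc[perm].reset_index(drop=True)
        res2 = ward_clustering(z_matrix(dfp))
        # memberships identical up to label names
        ref = {}
        for l1, l2 in zip(res1.labels[perm], res2.labels):
            ref.setdefault(l1, l2)
            assert ref[l1] == l2

    def test_newick_serialization_parses(self):
        mm = self._blobs(10.0, seed=3, n=5)
        res = ward_clustering(mm)
        text = res.to_newick()
        assert text.endswith(";") and text.count("(") == len(mm.normalized) - 1


class TestAngleBaselines:
    def test_analytic_values(self):
        base = random_branching_baselines("analytic")
        assert base.pair_angle_mean == pytest.approx(90.0, abs=1e-9)
        assert base.pair_angle_sd == pytest.approx(math.degrees(math.sqrt(math.pi**2 / 4 - 2)))
        assert round(base.pair_angle_sd) == 39
        assert base.tilt_mean == pytest.approx(67.5, abs=1e-9)
        assert round(base.tilt_mean) == 68
        assert round(base.tilt_sd) == 32

    def test_monte_carlo_within_three_se(self):
        n = 10**6
        base = random_branching_baselines("monte_carlo", n_samples=n, seed=0)
        exact = random_branching_baselines("analytic")
        se_pair = exact.pair_angle_sd / math.sqrt(n)
        assert abs(base.pair_angle_mean - exact.pair_angle_mean) < 3 * se_pair
        se_tilt = exact.tilt_sd / math.sqrt(n)
        assert abs(base.tilt_mean - exact.tilt_mean) < 3 * se_tilt
        assert abs(base.pair_angle_sd - exact.pair_angle_sd) < 0.2
        assert abs(base.tilt_sd - exact.tilt_sd) < 0.2

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            random_branching_baselines("monte_carlo", n_samples=100)
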