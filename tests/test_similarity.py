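"""Mahalanobis similarity core: covariance pooling, distances,
classification, leave-one-marker-out attribution."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis

from timehom import SimConfig, simulate_cohort, quantify_cohort
from timehom.evaluation import calibration_exceedance
from timehom.panel import DEFAULT_PANEL
from timehom.similarity import (
    CovarianceModel,
    FeatureMatrix,
    analyze_cohort,
    assemble_features,
    chi2_critical,
    classify_tumor,
    cohort_summary,
    leave_one_marker_out,
    mahalanobis_distances,
    pooled_covariance,
)


def make_matrix(arr, n_regions=5, features=None):
    arr = np.asarray(arr, dtype=float)
    n = arr.shape[0]
    assert n % n_regions == 0
    tumors = np.repeat([f"t{i}" for i in range(n // n_regions)], n_regions)
    regions = np.tile([f"T{j+1}" for j in range(n_regions)], n // n_regions)
    features = features or [f"f{k}" for k in range(arr.shape[1])]
    idx = pd.MultiIndex.from_arrays([tumors, regions], names=["tumor_id", "region"])
    return FeatureMatrix(pd.DataFrame(arr, index=idx, columns=features))


def explicit_inverse_d2(X, cov, correction=True):
    """Brute-force oracle: per-sample distance via an explicit matrix
    inverse (and the scipy implementation as a second path)."""
    inv = np.linalg.inv(cov.matrix)
    out = []
    for (tid, _), row in X.data.iterrows():
        mu = X.data.xs(tid, level=0).mean(axis=0).to_numpy()
        x = row.to_numpy()
        d2 = (x - mu) @ inv @ (x - mu)
        assert d2 == pytest.approx(scipy_mahalanobis(x, mu, inv) ** 2, rel=1e-9)
        if correction:
            n_t = len(X.data.xs(tid, level=0))
            d2 *= n_t / (n_t - 1.0)
        out.append(d2)
    return np.array(out)


class TestAssembly:
    def test_ihc_cohort_dimensions(self, small_samples):
        X = assemble_features(small_samples, DEFAULT_PANEL, source="ihc")
        assert X.data.shape == (4 * 5, 9)
        assert list(X.data.columns) == list(DEFAULT_PANEL.features)

    def test_sqrt_stabilization_applied_to_ihc(self, small_samples):
        raw = assemble_features(small_samples, DEFAULT_PANEL, "ihc", transform=None)
        stab = assemble_features(small_samples, DEFAULT_PANEL, "ihc")
        assert np.allclose(stab.data.to_numpy(), np.sqrt(raw.data.to_numpy()))

    def test_rna_regions_subset(self, small_bundle):
        from timehom.rna import default_gene_sets, gene_set_abundance, normalize_counts

        ab = gene_set_abundance(
            normalize_counts(small_bundle.expression), default_gene_sets()
        )
        X = assemble_features(ab.data, DEFAULT_PANEL, source="rna")
        # T1/T3/T5 per tumor; paratumor samples excluded
        assert X.data.shape == (4 * 3, 9)
        assert set(X.data.index.get_level_values("region")) == {"T1", "T3", "T5"}

    def test_single_region_tumor_rejected(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", "T1"), ("a", "T2"), ("b", "T1")], names=["tumor_id", "region"]
        )
        with pytest.raises(ValueError, match="b"):
            FeatureMatrix(pd.DataFrame(np.ones((3, 2)), index=idx, columns=["x", "y"]))


class TestPooledCovariance:
    def test_full_shrinkage_is_exactly_diagonal(self):
        rng = np.random.default_rng(0)
        X = make_matrix(rng.normal(size=(20, 4)))
        cov = pooled_covariance(X, shrinkage=1.0)
        off = cov.matrix - np.diag(np.diag(cov.matrix))
        assert np.allclose(off, 0.0)

    def test_recovers_known_covariance_at_large_n(self):
        # two uncorrelated unit-variance features
        rng = np.random.default_rng(1)
        n_tumors, m = 2000, 5
        X = make_matrix(rng.normal(size=(n_tumors * m, 2)), n_regions=m)
        cov = pooled_covariance(X, shrinkage=0.0)
        se = 1.0 / np.sqrt(cov.df)
        assert abs(cov.matrix[0, 1]) < 3 * se
        assert cov.matrix[0, 0] == pytest.approx(1.0, abs=3 * np.sqrt(2) * se)
        assert cov.df == n_tumors * m - n_tumors

    def test_duplicating_every_tumor_preserves_estimate(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(20, 3))
        X = make_matrix(arr)
        dup = make_matrix(np.vstack([arr, arr]))
        a = pooled_covariance(X, shrinkage=0.0)
        b = pooled_covariance(dup, shrinkage=0.0)
        assert np.allclose(a.matrix, b.matrix)
        assert b.df == 2 * a.df

    def test_insufficient_degrees_of_freedom_rejected(self):
        X = make_matrix(np.random.default_rng(3).normal(size=(2, 2)), n_regions=2)
        with pytest.raises(ValueError, match="degrees of freedom"):
            pooled_covariance(X)

    def test_auto_shrinkage_meets_condition_bound(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(30, 1))
        # nearly collinear features -> huge condition number unshrunk
        arr = np.hstack([base, base + 1e-6 * rng.normal(size=(30, 1))])
        cov = pooled_covariance(make_matrix(arr), shrinkage="auto", condition_bound=1e4)
        ev = np.linalg.eigvalsh(cov.matrix)
        assert ev.max() / ev.min() <= 1e4 * 1.01
        assert 0 < cov.shrinkage <= 1


class TestDistances:
    def test_euclidean_case_with_identity_covariance(self):
        # oracle mode: centroid at the origin, identity covariance
        arr = np.zeros((2, 9))
        arr[0, 0], arr[0, 1] = 3.0, 4.0
        X = make_matrix(arr, n_regions=2)
        cov = CovarianceModel(np.eye(9), tuple(X.features), 0.0, df=100)
        d2 = mahalanobis_distances(X, cov, centroids={"t0": np.zeros(9)})
        assert d2.iloc[0] == pytest.approx(25.0)
        assert d2.iloc[1] == pytest.approx(0.0)

    def test_region_at_centroid_has_zero_distance(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(10, 3))
        # a region equal to the mean of its siblings sits exactly at the
        # tumor centroid (its own deviation vanishes)
        arr[4] = arr[:4].mean(axis=0)
        X = make_matrix(arr)
        d2 = mahalanobis_distances(X, pooled_covariance(X))
        assert d2.loc[("t0", "T5")] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(6)
        for n_feat in (2, 3, 4):
            X = make_matrix(rng.normal(size=(25, n_feat)))
            cov = pooled_covariance(X, shrinkage=0.1)
            d2 = mahalanobis_distances(X, cov)
            oracle = explicit_inverse_d2(X, cov)
            assert np.allclose(d2.to_numpy(), oracle, rtol=1e-8, atol=1e-10)

    def test_affine_invariance_under_feature_rescaling(self):
        rng = np.random.default_rng(7)
        X = make_matrix(rng.normal(size=(40, 5)))
        scales = np.array([0.01, 1.0, 3.7, 100.0, 0.5])
        Xs = FeatureMatrix(X.data * scales)
        d_a = mahalanobis_distances(X, pooled_covariance(X, shrinkage=0.0))
        d_b = mahalanobis_distances(Xs, pooled_covariance(Xs, shrinkage=0.0))
        assert np.allclose(d_a.to_numpy(), d_b.to_numpy(), atol=1e-6)

    def test_feature_mismatch_rejected(self):
        X = make_matrix(np.random.default_rng(8).normal(size=(10, 2)))
        cov = CovarianceModel(np.eye(3), ("a", "b", "c"), 0.0, df=10)
        with pytest.raises(ValueError, match="mismatch"):
            mahalanobis_distances(X, cov)


class TestClassification:
    def test_all_below_critical_is_homogeneous(self):
        res = classify_tumor(dict(zip("abcde", [3, 5, 8, 10, 12])), "t")
        assert res.homogeneous and res.range_narrow

    def test_one_region_above_critical_is_heterogeneous(self):
        res = classify_tumor(dict(zip("abcde", [3, 5, 8, 10, 25])), "t")
        assert not res.homogeneous
        assert not res.range_narrow  # range 22 > default threshold 11

    def test_default_critical_value_is_rounded_chi_square_upper_1pct(self):
        from scipy import stats

        assert stats.chi2.ppf(0.99, 9) == pytest.approx(21.666, abs=1e-3)
        assert chi2_critical(9, alpha=0.01) == 22.0

    def test_cohort_summary_fractions(self):
        results = [
            classify_tumor({"T1": 1, "T2": 25 if i < 2 else 2}, f"t{i}")
            for i in range(10)
        ]
        summ = cohort_summary(results)
        assert summ["n_homogeneous"] == 8
        assert summ["frac_homogeneous"] == pytest.approx(0.8)
        with pytest.raises(ValueError):
            cohort_summary([])


class TestLeaveOneMarkerOut:
    def test_planted_single_driver_is_top_ranked(self):
        hits = total = 0
        for seed in (101, 102, 103):
            cfg = SimConfig(
                n_tumors=30,
                prop_heterogeneous=0.3,
                n_driver_markers=1,
                driver_effect=4.0,
                seed=seed,
            )
            b = simulate_cohort(cfg)
            X = assemble_features(
                quantify_cohort(b.ihc_fields, b.tls), DEFAULT_PANEL, "ihc"
            )
            for r in analyze_cohort(X):
                if b.truth.heterogeneous[r.tumor_id] and not r.homogeneous:
                    total += 1
                    hits += r.top_driver == b.truth.driver_markers[r.tumor_id][0]
        assert total >= 10
        assert hits / total >= 0.9

    def test_homogeneous_narrow_tumor_has_no_drivers(self):
        rng = np.random.default_rng(9)
        X = make_matrix(rng.normal(size=(50, 4)))
        for r in analyze_cohort(X, critical_value=1e6):
            assert r.homogeneous and r.driver_markers == []

    def test_single_feature_matrix_rejected(self):
        X = make_matrix(np.random.default_rng(10).normal(size=(10, 1)))
        with pytest.raises(ValueError, match="2 features"):
            leave_one_marker_out(X, "t0")


class TestCalibration:
    def test_uncorrected_estimated_centroids_deflate_below_nominal(self):
        # documented deflation of the plain estimator: deviations from an
        # estimated 5-region centroid shrink d^2 by a factor (1 - 1/n)
        out = calibration_exceedance(
            n_regions=10_000, seed=3, oracle=False, centroid_correction=False
        )
        assert out["exceedance"] <= out["nominal"]

    def test_corrected_estimated_centroids_near_nominal(self):
        out = calibration_exceedance(n_regions=10_000, seed=3, oracle=False)
        assert out["exceedance"] == pytest.approx(out["nominal"], abs=2 * out["mc_3se"])
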