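"""Index PCA, frozen-reference projection, and K-means phenotyping."""

import numpy as np
import pandas as pd
import pytest

from nephromorph.morphometry import FEATURES_7
from nephromorph.multivariate import (
    ClusterModel,
    IndexModel,
    apply_scaler,
    cluster_profiles,
    fit_clusters,
    fit_pca,
    fit_scaler,
    predict_clusters,
    project,
    within_cluster_correlations,
    _semantic_labels,
)


def _random_features(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, 7)) * [5, 10, 4, 11, 2, 600, 800]
                        + [15, 37, 8, 34, 6, 3300, 3700], columns=FEATURES_7)


def _two_factor_features(n, seed=0, noise=0.05):
    """Seven features driven by two independent latent factors plus noise."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=n), rng.normal(size=n)
    w1 = np.array([0.0, -0.8, 0.1, 0.9, -0.6, -0.7, 0.8])
    w2 = np.array([-0.9, 0.8, -0.7, 0.0, 0.1, 0.2, 0.0])
    x = np.outer(f1, w1) + np.outer(f2, w2) + noise * rng.normal(size=(n, 7))
    return pd.DataFrame(x, columns=FEATURES_7)


class TestScaler:
    def test_training_z_scores_are_standardized(self):
        df = _random_features(60)
        scaler = fit_scaler(df)
        z = apply_scaler(scaler, df)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_value_at_training_mean_maps_to_zero(self):
        df = _random_features(30)
        scaler = fit_scaler(df)
        at_mean = pd.DataFrame([scaler.mean], columns=FEATURES_7)
        assert np.allclose(apply_scaler(scaler, at_mean).to_numpy(), 0.0)

    def test_constant_feature_rejected_by_name(self):
        df = _random_features(20)
        df["ptc%"] = 5.0
        with pytest.raises(ValueError, match="ptc%"):
            fit_scaler(df)

    def test_test_set_keeps_training_reference(self):
        train = _random_features(50, seed=1)
        scaler = fit_scaler(train)
        shifted = _random_features(50, seed=2) + train.std(ddof=1)  # +1 sd per feature
        z = apply_scaler(scaler, shifted)
        assert (z.mean().abs() > 0.5).all()  # not re-centered on the test set


class TestIndexPca:
    def test_two_factor_data_retains_two_components(self):
        model = fit_pca(_two_factor_features(300, seed=3))
        assert len(model.component_labels) == 2
        assert model.component_labels == ["ChronicityIndex", "InvertedAcuteIndex"]
        assert model.warning is None

    def test_orientation_anchors_positive(self):
        for seed in range(4):
            model = fit_pca(_two_factor_features(200, seed=seed))
            i_coll = FEATURES_7.index("iColl%")
            i_cell = FEATURES_7.index("tCell%")
            assert model.loadings[i_coll, 0] > 0
            assert model.loadings[i_cell, 1] > 0

    def test_loadings_orthonormal_and_scores_uncorrelated(self):
        df = _two_factor_features(250, seed=5)
        model = fit_pca(df)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-12)
        scores = project(model, df)
        r = np.corrcoef(scores.iloc[:, 0], scores.iloc[:, 1])[0, 1]
        assert abs(r) < 1e-10

    def test_projection_reproduces_fit_scores(self):
        df = _two_factor_features(120, seed=6)
        model = fit_pca(df)
        z = apply_scaler(model.scaler, df).to_numpy()
        fit_scores = z @ model.loadings
        again = project(model, df).to_numpy()
        assert np.max(np.abs(again - fit_scores)) < 1e-12

    def test_case_at_training_means_scores_zero(self):
        df = _random_features(40, seed=7)
        model = fit_pca(df)
        at_mean = pd.DataFrame([model.scaler.mean], columns=FEATURES_7)
        assert np.allclose(project(model, at_mean).to_numpy(), 0.0, atol=1e-12)

    def test_serialization_roundtrip_is_exact(self):
        df = _two_factor_features(100, seed=8)
        model = fit_pca(df)
        clone = IndexModel.from_dict(model.to_dict())
        a, b = project(model, df).to_numpy(), project(clone, df).to_numpy()
        assert np.max(np.abs(a - b)) < 1e-15

    def test_feature_mismatch_fails(self):
        model = fit_pca(_random_features(40))
        with pytest.raises(KeyError):
            project(model, pd.DataFrame({"bogus": [1.0]}))

    def test_min_cases_and_fixed_retention(self):
        with pytest.raises(ValueError):
            fit_pca(_random_features(5))
        model = fit_pca(_random_features(40, seed=9), retention=3)
        assert len(model.component_labels) == 3
        assert model.component_labels[2] == "PC3"

    def test_index_recovery_on_synthetic_cohort(self, continuous_report):
        """Chronicity Index tracks latent c; Inverted Acute Index anti-tracks a."""
        from scipy.stats import spearmanr

        scores = continuous_report["scores"]
        meta = continuous_report["meta"]
        assert spearmanr(scores["ChronicityIndex"], meta["chronicity"]).statistic > 0.8
        assert spearmanr(scores["InvertedAcuteIndex"], meta["acuity"]).statistic < -0.8

    def test_index_independence(self, continuous_report):
        s = continuous_report["scores"]
        r = np.corrcoef(s["ChronicityIndex"], s["InvertedAcuteIndex"])[0, 1]
        assert abs(r) < 0.05


class TestClusters:
    def test_same_seed_reproducible(self):
        z = apply_scaler(fit_scaler(_random_features(80)), _random_features(80))
        m1 = fit_clusters(z, k=4, seed=3)
        m2 = fit_clusters(z, k=4, seed=3)
        assert np.array_equal(m1.centroids, m2.centroids)
        assert np.array_equal(m1.training_assignment, m2.training_assignment)

    def test_predict_matches_training_assignment(self):
        df = _two_factor_features(150, seed=10)
        z = apply_scaler(fit_scaler(df), df)
        model = fit_clusters(z, k=3, seed=0)
        assert np.array_equal(predict_clusters(model, z), model.training_assignment)

    def test_centroid_point_predicted_into_its_cluster(self):
        df = _two_factor_features(90, seed=11)
        z = apply_scaler(fit_scaler(df), df)
        model = fit_clusters(z, k=4, seed=0)
        at_centroids = pd.DataFrame(model.centroids, columns=FEATURES_7)
        assert np.array_equal(predict_clusters(model, at_centroids), np.arange(4))

    def test_k_larger_than_n_fails(self):
        df = _random_features(5)
        z = (df - df.mean()) / df.std(ddof=1)
        with pytest.raises(ValueError):
            fit_clusters(z, k=10, seed=0)

    def test_archetype_recovery(self, archetype_report):
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(
            archetype_report["meta"]["archetype"], archetype_report["cluster_labels"]
        )
        assert ari > 0.7
        assert archetype_report["cluster_model"].selected_k == 4

    def test_semantic_labels_follow_centroid_profiles(self):
        names = FEATURES_7
        cent = np.zeros((4, 7))
        cent[0, names.index("iColl%")] = 2.0  # fibrotic profile
        cent[1, names.index("tLumen%")] = 2.0  # dilated lumens
        cent[2, names.index("tCell%")] = 1.5
        cent[2, names.index("tSize")] = 1.5  # preserved tubules
        labels = _semantic_labels(cent, names)
        assert labels == ["chronic_severe", "acute", "intact", "intermediate"]

    def test_serialization_roundtrip(self):
        df = _two_factor_features(100, seed=12)
        z = apply_scaler(fit_scaler(df), df)
        model = fit_clusters(z, k=4, seed=1)
        clone = ClusterModel.from_dict(model.to_dict())
        assert np.array_equal(predict_clusters(clone, z), predict_clusters(model, z))


class TestProfilesAndCorrelations:
    def test_single_cluster_profile_is_global_mean(self):
        df = _random_features(40)
        z = apply_scaler(fit_scaler(df), df)
        prof = cluster_profiles(z, np.zeros(40, dtype=int))
        assert np.allclose(prof.loc[0].to_numpy(), z.mean().to_numpy())

    def test_correlation_diagonal_and_small_cluster_flagged(self):
        df = _random_features(30)
        labels = np.array([0] * 28 + [1] * 2)
        out = within_cluster_correlations(df, labels)
        assert out[1] is None
        mat = out[0]
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)

    def test_acute_cluster_lumen_cell_anticorrelation(self, archetype_report):
        """Within the acute phenotype, dilated lumens come with flattened epithelium."""
        model = archetype_report["cluster_model"]
        labels = archetype_report["cluster_labels"].to_numpy()
        feats = archetype_report["features"][FEATURES_7]
        acute = model.semantic_labels.index("acute")
        mats = within_cluster_correlations(feats, labels)
        assert mats[acute].loc["tLumen%", "tCell%"] < 0
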