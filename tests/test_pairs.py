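"""PAIRS: PCA basis, feature projection, kNN angles, surrogate test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqdisc.config import AnalysisConfig, seeded_rng
from seqdisc.errors import ValidationError
from seqdisc.pairs import (
    fit_pca_basis,
    knn_mean_angles,
    pairs_statistic,
    pairs_surrogate_test,
    per_session_pairs,
    project_features,
)


def brute_force_knn_angles(features, k):
    """All-pairs oracle: explicit angle matrix, per-neuron mean of k smallest."""
    n = features.shape[0]
    out = np.empty(n)
    for i in range(n):
        angles = []
        for j in range(n):
            if i == j:
                continue
            c = float(np.clip(np.dot(features[i], features[j]), -1, 1))
            angles.append(np.degrees(np.arccos(c)))
        out[i] = np.mean(sorted(angles)[:k])
    return out


class TestPcaBasis:
    def test_data_in_low_dim_subspace_captures_all_variance(self):
        rng = np.random.default_rng(0)
        basis_dirs = rng.normal(size=(8, 246))
        coeffs = rng.normal(size=(40, 8))
        vectors = coeffs @ basis_dirs
        b = fit_pca_basis(vectors, 8)
        assert b.variance_captured == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_data_captures_about_8_over_246(self):
        # analytic expectation 8/246; finite samples inflate the top
        # eigenvalues (Marchenko-Pastur edge), hence the asymmetric band
        rng = np.random.default_rng(1)
        vectors = rng.normal(size=(3000, 246))
        b = fit_pca_basis(vectors, 8)
        assert 8 / 246 <= b.variance_captured <= 1.8 * 8 / 246

    def test_components_orthonormal(self):
        rng = np.random.default_rng(2)
        b = fit_pca_basis(rng.normal(size=(50, 246)), 8)
        np.testing.assert_allclose(b.components @ b.components.T, np.eye(8), atol=1e-9)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValidationError):
            fit_pca_basis(np.zeros((8, 246)), 8)


class TestProjectFeatures:
    def test_vector_along_pc1_maps_to_unit_axis(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(60, 246))
        base[:, 0] += np.linspace(-50, 50, 60)  # dominant first direction
        b = fit_pca_basis(base, 8)
        v = b.mean + 3.0 * b.components[0]
        feats, kept = project_features(v[None, :], b)
        expected = np.zeros(8)
        expected[0] = 1.0
        np.testing.assert_allclose(np.abs(feats[0]), expected, atol=1e-9)

    def test_parallel_vectors_map_to_identical_features(self):
        rng = np.random.default_rng(4)
        b = fit_pca_basis(rng.normal(size=(30, 246)), 8)
        v = rng.normal(size=246)
        feats, _ = project_features(np.vstack([b.mean + v, b.mean + 2 * v]), b)
        np.testing.assert_allclose(feats[0], feats[1], atol=1e-9)

    def test_outputs_unit_norm_and_zero_norm_excluded(self):
        rng = np.random.default_rng(5)
        b = fit_pca_basis(rng.normal(size=(30, 246)), 8)
        vecs = np.vstack([rng.normal(size=(5, 246)), b.mean[None, :]])  # last projects to 0
        feats, kept = project_features(vecs, b)
        assert feats.shape[0] == 5 and 5 not in kept.tolist()
        np.testing.assert_allclose(np.linalg.norm(feats, axis=1), 1.0, atol=1e-9)


class TestKnnAngles:
    def test_identical_vectors_have_zero_angle(self):
        f = np.tile(np.array([1.0, 0, 0, 0]), (5, 1))
        np.testing.assert_allclose(knn_mean_angles(f, 3), 0.0, atol=1e-6)

    def test_orthogonal_vectors_have_90_degrees(self):
        f = np.eye(4)
        np.testing.assert_allclose(knn_mean_angles(f, 3), 90.0)

    def test_angle_properties(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=(10, 8))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        theta = knn_mean_angles(f, 3)
        assert np.all((theta >= 0) & (theta <= 180))

    @settings(deadline=None, max_examples=25)
    @given(
        n=st.integers(5, 12),
        k=st.integers(1, 4),
        seed=st.integers(0, 1000),
    )
    def test_matches_brute_force_oracle(self, n, k, seed):
        if k >= n:
            return
        rng = np.random.default_rng(seed)
        f = rng.normal(size=(n, 8))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        np.testing.assert_allclose(
            knn_mean_angles(f, k), brute_force_knn_angles(f, k), atol=1e-9
        )

    def test_k_not_smaller_than_n_rejected(self):
        with pytest.raises(ValidationError):
            knn_mean_angles(np.eye(4), 4)


class TestPairsStatistic:
    def test_identical_population_is_zero(self):
        f = np.tile(np.array([0.0, 1.0, 0, 0]), (12, 1))
        assert pairs_statistic(f, 3) == pytest.approx(0.0, abs=1e-6)

    def test_two_tight_antipodal_clusters_stay_small(self):
        rng = np.random.default_rng(7)
        c = np.zeros(8)
        c[0] = 1.0
        f = np.vstack([c + 0.01 * rng.normal(size=(10, 8)),
                       -c + 0.01 * rng.normal(size=(10, 8))])
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        assert pairs_statistic(f, 3) < 5.0  # neighbours are within-cluster

    def test_median_of_per_neuron_angles(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=(10, 8))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        assert pairs_statistic(f, 3) == pytest.approx(
            np.median(brute_force_knn_angles(f, 3))
        )

    def test_invariant_to_common_rotation(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=(15, 8))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        q, _ = np.linalg.qr(rng.normal(size=(8, 8)))
        assert pairs_statistic(f @ q, 3) == pytest.approx(pairs_statistic(f, 3))


def _unit(rng, n, d=8):
    f = rng.normal(size=(n, d))
    return f / np.linalg.norm(f, axis=1, keepdims=True)


class TestPairsSurrogateTest:
    def test_p_floor_when_observed_beats_all_surrogates(self):
        rng = seeded_rng(10, "pairs-floor")
        centers = _unit(rng, 4)
        f = np.repeat(centers, 5, axis=0) + 0.02 * rng.normal(size=(20, 8))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        cfg = AnalysisConfig(seed=10, pairs_surrogates=500)
        res = pairs_surrogate_test(f, cfg, rng)
        assert res.p_value == pytest.approx(1 / 501)

    def test_surrogates_preserve_coordinate_marginals(self):
        from seqdisc.pairs import _surrogate_features

        rng = seeded_rng(11, "pairs-marg")
        f = _unit(rng, 30)
        raw = _surrogate_features(f, 20, rng, "permute", normalise=False)
        # permutation mode: every surrogate column is exactly a permutation of
        # the corresponding empirical column
        for s in range(20):
            for j in range(8):
                np.testing.assert_allclose(np.sort(raw[s, :, j]), np.sort(f[:, j]))
        surr = _surrogate_features(f, 20, rng, "permute")
        np.testing.assert_allclose(np.linalg.norm(surr, axis=-1), 1.0, atol=1e-9)

    def test_resample_surrogates_draw_from_empirical_marginals(self):
        from seqdisc.pairs import _surrogate_features

        rng = seeded_rng(11, "pairs-marg2")
        f = _unit(rng, 30)
        raw = _surrogate_features(f, 20, rng, "resample", normalise=False)
        for j in range(8):
            assert set(raw[..., j].ravel()) <= set(f[:, j])

    def test_clustered_population_is_significant(self):
        rng = seeded_rng(12, "pairs-power")
        centers = _unit(rng, 4)
        f = np.repeat(centers, 30, axis=0) + 0.1 * rng.normal(size=(120, 8))
        f /= np.linalg.norm(f, axis=1, keepdims=True)
        cfg = AnalysisConfig(seed=12, pairs_surrogates=1000)
        res = pairs_surrogate_test(f, cfg, rng)
        assert res.p_value <= 0.05

    def test_noise_ladder_never_decreases_expected_statistic(self):
        rng = seeded_rng(13, "pairs-ladder")
        centers = _unit(rng, 4)
        stats = []
        for noise in (0.02, 0.1, 0.5, 2.0):
            vals = []
            for _ in range(10):
                f = np.repeat(centers, 10, axis=0) + noise * rng.normal(size=(40, 8))
                f /= np.linalg.norm(f, axis=1, keepdims=True)
                vals.append(pairs_statistic(f, 3))
            stats.append(np.mean(vals))
        assert all(a < b + 1e-9 for a, b in zip(stats, stats[1:]))

    def test_too_few_neurons_rejected(self):
        cfg = AnalysisConfig(seed=0, pairs_surrogates=100)
        with pytest.raises(ValidationError):
            pairs_surrogate_test(np.eye(8), cfg, seeded_rng(0, "few"))


class TestPerSessionPairs:
    def test_session_size_rule_boundary(self):
        rng = seeded_rng(14, "pairs-sess")
        cfg = AnalysisConfig(seed=14, pairs_surrogates=200)
        vectors = {
            "s25": rng.normal(size=(25, 246)),
            "s26": rng.normal(size=(26, 246)),
        }
        res = per_session_pairs(vectors, cfg, rng)
        assert "s25" not in res and "s26" in res

    def test_two_clustered_sessions_both_significant(self):
        rng = seeded_rng(15, "pairs-sess2")
        cfg = AnalysisConfig(seed=15, pairs_surrogates=500)
        dirs = rng.normal(size=(4, 246)) * 10
        def clustered(n):
            picks = rng.integers(0, 4, n)
            return dirs[picks] + rng.normal(size=(n, 246))
        res = per_session_pairs({"a": clustered(40), "b": clustered(40)}, cfg, rng)
        assert set(res) == {"a", "b"}
        assert all(r.p_value <= 0.05 for r in res.values())
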