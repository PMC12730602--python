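"""CSP estimation against closed forms and an independent
whitening-then-rotation oracle."""

import numpy as np
import pytest

from fbcspts import (CSPModel, csp_features, csp_from_covariances, fit_csp,
                     fit_csp_multiclass, trial_covariance)
from fbcspts.csp import multiclass_features, multiclass_partners


def whiten_rotate_oracle(cov_a, cov_b):
    """Independent CSP route: symmetric whitening of the composite
    covariance followed by eigendecomposition of the whitened class-a
    covariance. Returns eigenvalues (ascending) and unmixing rows."""
    comp = cov_a + cov_b
    d, U = np.linalg.eigh(comp)
    P = U @ np.diag(d ** -0.5) @ U.T
    mu, V = np.linalg.eigh(P @ cov_a @ P)
    return mu, (P @ V).T


def random_two_class_problem(rng, n_channels, n_trials=12, n_samples=200):
    a = rng.standard_normal((n_trials, n_channels, n_samples))
    b = rng.standard_normal((n_trials, n_channels, n_samples))
    # impose distinct spatial structure per class
    ma = rng.standard_normal((n_channels, n_channels))
    mb = rng.standard_normal((n_channels, n_channels))
    return np.einsum("ij,tjs->tis", ma, a), np.einsum("ij,tjs->tis", mb, b)


class TestTrialCovariance:
    def test_matches_direct_formula(self, rng):
        X = rng.standard_normal((3, 500))
        C = trial_covariance(X)
        expected = (X @ X.T) / np.trace(X @ X.T)
        np.testing.assert_allclose(C, expected, atol=1e-12)
        assert abs(np.trace(C) - 1.0) < 1e-12
        np.testing.assert_allclose(C, C.T, atol=1e-12)

    def test_uncorrelated_equal_power_channels_give_half_identity(self):
        X = np.array([[1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0]])
        np.testing.assert_allclose(trial_covariance(X), 0.5 * np.eye(2))

    def test_single_channel_normalizes_to_one(self, rng):
        X = rng.standard_normal((1, 50))
        np.testing.assert_allclose(trial_covariance(X), [[1.0]])

    def test_zero_trial_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            trial_covariance(np.zeros((3, 100)))


class TestFitCSP:
    def test_closed_form_diagonal_covariances(self):
        cov_a = np.diag([2.0, 1.0]) / 3.0
        cov_b = np.diag([1.0, 2.0]) / 3.0
        model = csp_from_covariances(cov_a, cov_b, n_pairs=1)
        np.testing.assert_allclose(sorted(model.eigenvalues, reverse=True),
                                   [2 / 3, 1 / 3], atol=1e-12)
        # filters are axis-aligned: each row has a single nonzero entry
        for row in model.filters:
            assert np.sum(np.abs(row) > 1e-9) == 1

    def test_equal_covariances_give_half_eigenvalues(self, rng):
        A = rng.standard_normal((4, 4))
        cov = A @ A.T
        cov /= np.trace(cov)
        model = csp_from_covariances(cov, cov.copy(), n_pairs=2)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_matches_whitening_oracle_on_random_problems(self, rng):
        for _ in range(10):
            n_ch = int(rng.integers(2, 7))
            n_pairs = 1 if n_ch < 4 else 2
            data_a, data_b = random_two_class_problem(rng, n_ch)
            model = fit_csp(data_a, data_b, n_pairs=n_pairs)
            cov_a = np.mean([trial_covariance(t) for t in data_a], axis=0)
            cov_b = np.mean([trial_covariance(t) for t in data_b], axis=0)
            mu, _ = whiten_rotate_oracle(cov_a, cov_b)
            expected = np.concatenate([mu[::-1][:n_pairs], mu[:n_pairs]])
            np.testing.assert_allclose(sorted(model.eigenvalues),
                                       sorted(expected), atol=1e-8)
            # simultaneous diagonalization with unit diagonal sums
            Da = model.filters @ cov_a @ model.filters.T
            Db = model.filters @ cov_b @ model.filters.T
            assert np.max(np.abs(Da - np.diag(np.diag(Da)))) < 1e-8
            assert np.max(np.abs(Db - np.diag(np.diag(Db)))) < 1e-8
            np.testing.assert_allclose(np.diag(Da) + np.diag(Db), 1.0,
                                       atol=1e-8)
            np.testing.assert_allclose(np.diag(Da), model.eigenvalues,
                                       atol=1e-8)

    def test_eigenvalue_complementarity_under_class_swap(self, rng):
        data_a, data_b = random_two_class_problem(rng, 5)
        fwd = fit_csp(data_a, data_b, n_pairs=2)
        rev = fit_csp(data_b, data_a, n_pairs=2)
        np.testing.assert_allclose(np.sort(fwd.eigenvalues),
                                   np.sort(1.0 - rev.eigenvalues), atol=1e-10)

    def test_eigenvalues_sorted_by_discriminability(self, rng):
        data_a, data_b = random_two_class_problem(rng, 6)
        model = fit_csp(data_a, data_b, n_pairs=2)
        dist = np.abs(model.eigenvalues - 0.5)
        assert np.all(np.diff(dist) <= 1e-12)

    def test_partners_are_mutual(self, rng):
        data_a, data_b = random_two_class_problem(rng, 6)
        model = fit_csp(data_a, data_b, n_pairs=2)
        for i, j in enumerate(model.partners):
            assert model.partners[j] == i and j != i

    def test_empty_class_raises(self, rng):
        data = rng.standard_normal((4, 3, 100))
        with pytest.raises(ValueError):
            fit_csp(data, data[:0])


def identity_model(n_channels):
    return CSPModel(filters=np.eye(n_channels),
                    patterns=np.eye(n_channels),
                    eigenvalues=np.full(n_channels, 0.5),
                    partners=np.arange(n_channels)[::-1].copy())


class TestCSPFeatures:
    def test_hand_computed_normalized_log_variance(self):
        # channel variances exactly (2, 1)
        row0 = np.sqrt(2.0) * np.array([1.0, -1.0, 1.0, -1.0])
        row1 = np.array([1.0, -1.0, 1.0, -1.0])
        trial = np.stack([row0, row1])
        feats = csp_features(identity_model(2), trial[None])
        np.testing.assert_allclose(feats[0], [np.log(2 / 3), np.log(1 / 3)],
                                   atol=1e-12)

    def test_equal_variances_give_log_one_over_m(self, rng):
        x = rng.standard_normal(400)
        trial = np.stack([x, x[::-1].copy(), -x])
        feats = csp_features(identity_model(3), trial[None])
        np.testing.assert_allclose(feats[0], np.log(1 / 3), atol=1e-12)

    def test_global_scaling_invariance(self, rng):
        data = rng.standard_normal((4, 3, 200))
        model = identity_model(3)
        np.testing.assert_allclose(csp_features(model, data),
                                   csp_features(model, 10.0 * data), atol=1e-10)

    def test_consistent_channel_reordering_invariance(self, rng):
        data_a, data_b = random_two_class_problem(rng, 4)
        model = fit_csp(data_a, data_b, n_pairs=2)
        perm = np.array([2, 0, 3, 1])
        permuted_model = CSPModel(filters=model.filters[:, perm],
                                  patterns=model.patterns[perm],
                                  eigenvalues=model.eigenvalues,
                                  partners=model.partners)
        np.testing.assert_allclose(
            csp_features(model, data_a),
            csp_features(permuted_model, data_a[:, perm, :]), atol=1e-10)

    def test_zero_variance_trial_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            csp_features(identity_model(2), np.ones((1, 2, 50)))


class TestMulticlass:
    def test_four_classes_give_four_models_and_feature_count(self, rng):
        data = rng.standard_normal((20, 6, 150))
        labels = np.arange(20) % 4
        models = fit_csp_multiclass(data, labels, n_pairs=2)
        assert len(models) == 4
        assert [m.target_class for m in models] == [0, 1, 2, 3]
        feats = multiclass_features(models, data)
        assert feats.shape == (20, 4 * 2 * 2)
        partners = multiclass_partners(models)
        assert partners.size == 16 and np.all(partners != np.arange(16))

    def test_two_classes_reduce_to_binary(self, rng):
        data = rng.standard_normal((10, 4, 150))
        labels = np.arange(10) % 2
        models = fit_csp_multiclass(data, labels, n_pairs=1)
        assert len(models) == 1
        direct = fit_csp(data[labels == 0], data[labels == 1], n_pairs=1)
        np.testing.assert_allclose(models[0].eigenvalues, direct.eigenvalues)

    def test_class_with_too_few_trials_raises(self, rng):
        data = rng.standard_normal((5, 4, 100))
        labels = np.array([0, 0, 1, 1, 2])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_csp_multiclass(data, labels)
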