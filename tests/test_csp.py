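"""CSP decomposition: closed forms, independent oracles, feature algebra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import linalg

import mibci
from mibci.csp import (
    class_covariance,
    features_from_covariances,
    fit_csp,
    fit_csp_from_covariances,
    logvar_features,
    select_filters,
    trial_covariances,
)
from mibci.epoching import EpochSet
from mibci.recording import Label


def _epochs_from_trials(trials, labels, fs=250.0, channel_names=()):
    return EpochSet(
        data=np.asarray(trials),
        labels=labels,
        fs=fs,
        time0=0.0,
        channel_names=channel_names,
    )


def _gaussian_epochs(rng, cov, n_trials, n_samples=500, label=Label.LEFT):
    chol = np.linalg.cholesky(cov)
    data = chol @ rng.standard_normal((n_trials, cov.shape[0], n_samples))
    return _epochs_from_trials(data, (label,) * n_trials)


def _random_spd(rng, n):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


class TestClassCovariance:
    def test_identical_trials_give_single_trial_covariance(self, rng):
        trial = rng.standard_normal((4, 600))
        epochs = _epochs_from_trials([trial] * 5, (Label.LEFT,) * 5)
        cov = class_covariance(epochs)
        single = trial_covariances(epochs, normalize=True)[0]
        np.testing.assert_allclose(cov, single, atol=1e-12)

    def test_trace_is_one_by_construction(self, rng):
        epochs = _gaussian_epochs(rng, _random_spd(rng, 6), n_trials=8)
        assert np.trace(class_covariance(epochs)) == pytest.approx(1.0)

    def test_white_noise_approaches_scaled_identity(self, rng):
        epochs = _gaussian_epochs(rng, np.eye(8), n_trials=20, n_samples=10_000)
        cov = class_covariance(epochs)
        np.testing.assert_allclose(cov, np.eye(8) / 8, atol=0.05 / 8)

    def test_fewer_than_two_trials_rejected(self, rng):
        epochs = _gaussian_epochs(rng, np.eye(4), n_trials=1)
        with pytest.raises(ValueError, match="2 trials"):
            class_covariance(epochs)


class TestFitCsp:
    def test_diagonal_covariance_closed_form(self):
        model = fit_csp_from_covariances(np.diag([0.8, 0.2]), np.diag([0.2, 0.8]))
        np.testing.assert_allclose(model.eigvals, [0.8, 0.2], atol=1e-10)
        # filters align with the coordinate axes up to sign/scale
        for row in model.W:
            assert np.min(np.abs(row)) < 1e-8 * np.max(np.abs(row))

    def test_identical_classes_give_half_eigenvalues(self, rng):
        cov = _random_spd(rng, 6)
        model = fit_csp_from_covariances(cov, cov)
        np.testing.assert_allclose(model.eigvals, 0.5, atol=1e-9)

    def test_whitening_identity_on_random_spd_pairs(self, rng):
        for _ in range(5):
            c_l, c_r = _random_spd(rng, 8), _random_spd(rng, 8)
            model = fit_csp_from_covariances(c_l, c_r)
            np.testing.assert_allclose(
                model.W @ (c_l + c_r) @ model.W.T, np.eye(8), atol=1e-8
            )

    def test_eigenvalue_pairing_sums_to_one(self, rng):
        c_l, c_r = _random_spd(rng, 8), _random_spd(rng, 8)
        model = fit_csp_from_covariances(c_l, c_r)
        lam_l = np.diag(model.W @ c_l @ model.W.T)
        lam_r = np.diag(model.W @ c_r @ model.W.T)
        np.testing.assert_allclose(lam_l + lam_r, 1.0, atol=1e-8)
        assert np.all(np.diff(model.eigvals) <= 1e-12)  # sorted descending

    def test_w_times_patterns_is_identity(self, rng):
        model = fit_csp_from_covariances(_random_spd(rng, 8), _random_spd(rng, 8))
        np.testing.assert_allclose(model.W @ model.patterns, np.eye(8), atol=1e-8)

    def test_matches_generalized_eigendecomposition(self, rng):
        """Independent route: scipy's generalized eigh on (C_L, C_L + C_R)."""
        c_l, c_r = _random_spd(rng, 8), _random_spd(rng, 8)
        model = fit_csp_from_covariances(c_l, c_r)
        lam, vecs = linalg.eigh(c_l, c_l + c_r)
        np.testing.assert_allclose(model.eigvals, lam[::-1], atol=1e-9)
        for k in range(8):
            v = vecs[:, ::-1][:, k]
            w = model.W[k]
            cos = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
            assert cos > 1 - 1e-9

    def test_top_filter_matches_brute_force_angle_search(self, rng):
        """2-channel oracle: grid search over filter angle maximizing the
        class-variance ratio."""
        c_l, c_r = _random_spd(rng, 2), _random_spd(rng, 2)
        angles = np.linspace(0, np.pi, 200_001)[:-1]
        ws = np.stack([np.cos(angles), np.sin(angles)])
        ratio = np.einsum("ca,cd,da->a", ws, c_l, ws) / np.einsum(
            "ca,cd,da->a", ws, c_l + c_r, ws
        )
        w_best = ws[:, np.argmax(ratio)]
        model = fit_csp_from_covariances(c_l, c_r)
        w_top = model.W[0]
        cos = abs(w_best @ w_top) / (np.linalg.norm(w_best) * np.linalg.norm(w_top))
        assert cos > 0.999

    def test_trial_order_invariance(self, rng):
        left = _gaussian_epochs(rng, _random_spd(rng, 4), 10, label=Label.LEFT)
        right = _gaussian_epochs(rng, _random_spd(rng, 4), 10, label=Label.RIGHT)
        model = fit_csp(left, right)
        perm = rng.permutation(10)
        model_p = fit_csp(left.select(perm), right.select(perm))
        np.testing.assert_allclose(model.W, model_p.W, atol=1e-10)

    def test_too_few_trials_rejected(self, rng):
        left = _gaussian_epochs(rng, np.eye(4), 1, label=Label.LEFT)
        right = _gaussian_epochs(rng, np.eye(4), 5, label=Label.RIGHT)
        with pytest.raises(ValueError):
            fit_csp(left, right)


class TestSelectFilters:
    def test_first_and_last_two_of_sixteen(self, rng):
        model = fit_csp_from_covariances(_random_spd(rng, 16), _random_spd(rng, 16))
        sel = select_filters(model, m=2)
        assert sel.selected == (0, 1, 14, 15)

    def test_all_filters_at_m_half_channels(self, rng):
        model = fit_csp_from_covariances(_random_spd(rng, 4), _random_spd(rng, 4))
        sel = select_filters(model, m=2)
        assert sel.selected == (0, 1, 2, 3)

    def test_oversized_selection_rejected(self, rng):
        model = fit_csp_from_covariances(_random_spd(rng, 4), _random_spd(rng, 4))
        with pytest.raises(ValueError):
            select_filters(model, m=3)


class TestLogvarFeatures:
    def _fitted_model(self, rng, n=4):
        return select_filters(
            fit_csp_from_covariances(_random_spd(rng, n), _random_spd(rng, n)), m=n // 2
        )

    def test_equal_component_variances_give_log_quarter(self):
        # identity projection on 4 channels with equal per-channel variance
        model = select_filters(
            fit_csp_from_covariances(np.eye(4) * 0.5, np.eye(4) * 0.5), m=2
        )
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 4, 20_000))
        epochs = _epochs_from_trials(x, (Label.LEFT,) * 3)
        feats = logvar_features(model, epochs)
        np.testing.assert_allclose(feats.values, np.log(0.25), atol=0.02)

    def test_known_variance_ratios(self):
        # W = identity (achieved by symmetric equal covariances); plant
        # component variances (3, 1, 1, 1)
        model = select_filters(
            fit_csp_from_covariances(np.eye(4) * 0.5, np.eye(4) * 0.5), m=2
        )
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 4, 200_000))
        x /= x.std(axis=2, keepdims=True)
        x[0, 0] *= np.sqrt(3)
        feats = logvar_features(model, _epochs_from_trials(x, (Label.LEFT,)))
        expected = np.log(np.array([0.5, 1 / 6, 1 / 6, 1 / 6]))
        # model filters may permute/sign-flip axes; compare as sorted sets
        np.testing.assert_allclose(
            np.sort(feats.values[0]), np.sort(expected), atol=0.01
        )

    def test_exp_features_sum_to_one(self, rng):
        model = self._fitted_model(rng)
        x = rng.standard_normal((10, 4, 300))
        feats = logvar_features(model, _epochs_from_trials(x, (Label.LEFT,) * 10))
        np.testing.assert_allclose(
            np.exp(feats.values).sum(axis=1), 1.0, atol=1e-12
        )

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_amplitude_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        model = self._fitted_model(rng)
        x = rng.standard_normal((5, 4, 300))
        base = logvar_features(model, _epochs_from_trials(x, (Label.LEFT,) * 5))
        scaled = logvar_features(
            model, _epochs_from_trials(x * scale, (Label.LEFT,) * 5)
        )
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-9)

    def test_covariance_route_matches_time_domain(self, rng):
        model = self._fitted_model(rng)
        x = rng.standard_normal((6, 4, 400))
        epochs = _epochs_from_trials(x, (Label.LEFT,) * 6)
        covs = trial_covariances(epochs, normalize=False)
        np.testing.assert_allclose(
            features_from_covariances(model, covs),
            logvar_features(model, epochs).values,
            atol=1e-12,
        )

    def test_zero_signal_trial_rejected(self, rng):
        model = self._fitted_model(rng)
        x = np.zeros((2, 4, 300))
        with pytest.raises(ValueError, match="variance"):
            logvar_features(model, _epochs_from_trials(x, (Label.LEFT,) * 2))


class TestTopomapExport:
    def test_planted_left_source_peaks_near_c3(self, erd_epochs, montage):
        model = select_filters(
            fit_csp(
                erd_epochs.restrict(Label.LEFT), erd_epochs.restrict(Label.RIGHT)
            )
        )
        table = mibci.csp_topomap_export(model, montage)
        assert len(table) == 16
        filter_cols = [c for c in table.columns if c.startswith("filter_")]
        assert len(filter_cols) == 4
        # The most discriminative patterns should load on the hand areas:
        # look for C3/C4 (or an immediate neighbor) at an extreme filter.
        neighborhood = {"C3", "C1", "C5", "FC3", "CP3", "C4", "C2", "C6", "FC4", "CP4"}
        peaks = {
            table.loc[np.abs(table[c]).idxmax(), "channel"]
            for c in (filter_cols[0], filter_cols[-1])
        }
        assert peaks & neighborhood
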