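"""Gaussian entropy, mutual information and transfer entropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doaflow import (
    EEGRecording,
    VARModel,
    analytic_te,
    embed,
    gaussian_entropy,
    lagged_stationary_cov,
    mutual_information,
    random_stable_var,
    simulate_var,
    transfer_entropy,
)
from doaflow.infotheory import lagged_covariance, te_from_lagged_cov

LN_2PIE = np.log(2 * np.pi * np.e)


class TestGaussianEntropy:
    @pytest.mark.parametrize(
        "cov,expected",
        [
            ([[1.0]], 0.5 * LN_2PIE),
            (np.eye(2), LN_2PIE),
            ([[1.0, 0.5], [0.5, 1.0]], 0.5 * (2 * LN_2PIE + np.log(0.75))),
        ],
    )
    def test_closed_forms(self, cov, expected):
        assert gaussian_entropy(np.asarray(cov)) == pytest.approx(expected, abs=1e-12)

    @given(
        scale=st.floats(min_value=1.01, max_value=100.0),
        k=st.integers(min_value=1, max_value=5),
    )
    @settings(max_examples=30, deadline=None)
    def test_scaling_adds_half_k_log_c(self, scale, k):
        rng = np.random.default_rng(k)
        a = rng.standard_normal((k + 3, k))
        cov = a.T @ a / (k + 3) + np.eye(k)
        dh = gaussian_entropy(scale * cov) - gaussian_entropy(cov)
        assert dh == pytest.approx(0.5 * k * np.log(scale), rel=1e-9)

    def test_rejects_asymmetric_and_wrong_size(self):
        with pytest.raises(ValueError):
            gaussian_entropy(np.array([[1.0, 0.9], [0.1, 1.0]]))
        with pytest.raises(ValueError):
            gaussian_entropy(np.eye(2), k=3)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            gaussian_entropy(np.zeros((2, 2)))


class TestEmbed:
    def test_disjointness_enforced(self, noise_recording):
        with pytest.raises(ValueError, match="disjoint"):
            embed(noise_recording, ["Fp1"], ["Fp1"], tau=1)

    def test_index_bookkeeping(self):
        rec = EEGRecording(["x", "y"], 1.0, np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        blocks = embed(rec, ["x"], ["y"], tau=1)
        # mean removal over the full series, then lag alignment
        np.testing.assert_allclose(blocks.A_next[:, 0], [0.0, 1.0])
        np.testing.assert_allclose(blocks.A_now[:, 0], [-1.0, 0.0])
        np.testing.assert_allclose(blocks.B_now[:, 0], [-1.0, 0.0])
        assert blocks.A_next.shape[0] == blocks.B_now.shape[0] == 2

    def test_row_count_at_tau2(self, noise_recording):
        from doaflow import make_windows

        w = make_windows(noise_recording, 1.0, 1.0)[0]  # 256 samples
        blocks = embed(noise_recording, ["Fp1"], ["F3"], window=w, tau=2)
        assert blocks.A_next.shape[0] == 254

    def test_tau_bounds(self, noise_recording):
        with pytest.raises(ValueError):
            embed(noise_recording, ["Fp1"], ["F3"], tau=0)


class TestMutualInformation:
    def test_independent_channels_near_zero(self, rng):
        data = rng.standard_normal((100_000, 2))
        rec = EEGRecording(["x", "y"], 256.0, data)
        assert abs(mutual_information(rec, ["x"], ["y"])) < 3e-4

    def test_bivariate_gaussian_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=1_000_000)
        rec = EEGRecording(["x", "y"], 256.0, z)
        expected = -0.5 * np.log(1 - rho**2)
        assert mutual_information(rec, ["x"], ["y"]) == pytest.approx(expected, rel=0.01)

    def test_symmetry(self, noise_recording):
        a = mutual_information(noise_recording, ["Fp1"], ["F3", "P3"])
        b = mutual_information(noise_recording, ["F3", "P3"], ["Fp1"])
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_channel_raises(self):
        data = np.column_stack([np.zeros(100), np.random.default_rng(0).standard_normal(100)])
        rec = EEGRecording(["flat", "y"], 10.0, data)
        with pytest.raises(ValueError):
            mutual_information(rec, ["flat"], ["y"])


def _granger_te(cov2n, n, target, source):
    """Independent oracle: TE of a univariate target equals half the
    log ratio of restricted to full regression residual variances."""
    a = target[0]
    y = a  # A_next position
    def resid_var(predictors):
        idx = np.array(predictors)
        s_yy = cov2n[y, y]
        s_yx = cov2n[y, idx]
        s_xx = cov2n[np.ix_(idx, idx)]
        return s_yy - s_yx @ np.linalg.solve(s_xx, s_yx)
    restricted = resid_var([a + n])
    full = resid_var([a + n] + [s + n for s in source])
    return 0.5 * np.log(restricted / full)


class TestTransferEntropy:
    def test_unidirectional_closed_form(self):
        """y_{t+1} = x_t + e gives T(x->y) = ln(2)/2 analytically."""
        model = VARModel(np.array([[0.0, 0.0], [1.0, 0.0]]), labels=("x", "y"))
        assert analytic_te(model, ["y"], ["x"], tau=1) == pytest.approx(
            0.5 * np.log(2), abs=1e-12
        )

    def test_estimate_matches_closed_form(self):
        model = VARModel(np.array([[0.0, 0.0], [1.0, 0.0]]), labels=("x", "y"))
        rec = simulate_var(model, 100_000, seed=3)
        est = transfer_entropy(rec, ["y"], ["x"], tau=1)
        assert est == pytest.approx(0.5 * np.log(2), rel=0.02)

    def test_decoupled_source_is_zero_on_population_covariance(self):
        F = np.array([[0.5, 0.3, 0.0], [0.2, 0.4, 0.0], [0.0, 0.0, 0.6]])
        model = VARModel(F, labels=("x", "y", "z"))
        assert analytic_te(model, ["x"], ["z"], tau=1) == pytest.approx(0.0, abs=1e-12)
        assert analytic_te(model, ["x", "y"], ["z"], tau=1) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(2, 0), (2, 5), (3, 1), (3, 9)])
    def test_granger_equivalence_on_random_vars(self, n, seed):
        """Population TE for univariate targets equals the Granger
        residual-variance form, an independent linear-regression route."""
        model = random_stable_var(n, seed=seed, coupling=0.8)
        cov2n = lagged_stationary_cov(model, tau=1)
        for tgt in range(n):
            for src in range(n):
                if src == tgt:
                    continue
                te = te_from_lagged_cov(cov2n, n, [tgt], [src])
                oracle = _granger_te(cov2n, n, [tgt], [src])
                assert te == pytest.approx(oracle, abs=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((5000, 3))
        data[:, 1] += 0.6 * np.roll(data[:, 0], 1)
        rec1 = EEGRecording(["x", "y", "z"], 256.0, data)
        scaled = data * np.array([3.0, 0.2, 11.0]) + np.array([5.0, -2.0, 0.7])
        rec2 = EEGRecording(["x", "y", "z"], 256.0, scaled)
        te1 = transfer_entropy(rec1, ["y"], ["x", "z"], tau=1)
        te2 = transfer_entropy(rec2, ["y"], ["x", "z"], tau=1)
        assert te1 == pytest.approx(te2, rel=1e-8)

    def test_estimator_consistency(self):
        """Median absolute error vs the analytic value shrinks with N."""
        model = random_stable_var(3, seed=42, coupling=0.7)
        truth = analytic_te(model, ["ch0"], ["ch1"], tau=1)
        med_errs = []
        for n_samp in (1_000, 10_000, 100_000):
            errs = []
            for seed in range(20):
                rec = simulate_var(model, n_samp, seed=seed)
                errs.append(abs(transfer_entropy(rec, ["ch0"], ["ch1"], tau=1) - truth))
            med_errs.append(np.median(errs))
        assert med_errs[0] > med_errs[1] > med_errs[2]

    def test_lagged_covariance_shape_and_symmetry(self, rng):
        cov = lagged_covariance(rng.standard_normal((1000, 3)), tau=2)
        assert cov.shape == (6, 6)
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
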