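"""Neural-mass model tests: dynamics, transforms, sensitivities, likelihood."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from aislmc import (
    NMMConfig,
    TwoRegionNMM,
    gen_nmm,
    integrate_nmm,
    nmm_derivatives,
    param_inverse,
    param_transform,
    sigmoid_rate,
)
from aislmc.neural_mass import FULL_PARAMS, REDUCED_PARAMS, _phys_vector
from conftest import fd_grad


@pytest.fixture(scope="module")
def cfg():
    return NMMConfig()


@pytest.fixture(scope="module")
def nmm_model(cfg):
    data = gen_nmm(seed=2, sigma_s=0.01, config=cfg)
    return TwoRegionNMM(data, config=cfg)


class TestSigmoid:
    def test_zero_crossing_for_any_parameters(self, rng):
        for _ in range(10):
            r1, r2 = rng.uniform(0.1, 3, 2)
            assert sigmoid_rate(0.0, r1, r2) == pytest.approx(0.0, abs=1e-15)

    def test_saturation_limit(self):
        r1, r2 = 0.56, 1.0
        assert sigmoid_rate(1e3, r1, r2) == pytest.approx(
            1.0 - 1.0 / (1.0 + np.exp(r1 * r2)))

    def test_value_at_threshold(self):
        r1, r2 = 0.8, 2.0
        assert sigmoid_rate(r2, r1, r2) == pytest.approx(
            0.5 - 1.0 / (1.0 + np.exp(r1 * r2)))


class TestTransforms:
    def test_zero_maps_to_defaults(self, cfg):
        phys = param_transform(np.zeros(10), cfg)
        assert phys == {n: cfg.defaults[n] for n in FULL_PARAMS}

    def test_round_trip(self, cfg, rng):
        w = rng.normal(size=10)
        assert np.allclose(param_inverse(param_transform(w, cfg), cfg), w,
                           atol=1e-12)

    def test_unit_shift_scales_connections_by_e(self, cfg):
        """The strong-coupling generator setting w = 1 on both extrinsic
        strengths multiplies the default connections by e."""
        w = np.zeros(10)
        w[:2] = 1.0
        phys = param_transform(w, cfg)
        assert phys["a12"] == pytest.approx(np.e * cfg.defaults["a12"])
        assert phys["a21"] == pytest.approx(np.e * cfg.defaults["a21"])

    def test_inverse_rejects_nonpositive_values(self, cfg):
        values = {n: cfg.defaults[n] for n in REDUCED_PARAMS}
        values["a21"] = -1.0
        with pytest.raises(ValueError):
            param_inverse(values, cfg, backward=False)

    def test_positivity_for_extreme_w(self, cfg):
        phys = param_transform(np.full(10, -50.0), cfg)
        assert all(v > 0 for v in phys.values())


class TestDerivatives:
    def test_rest_is_a_fixed_point_without_input(self, cfg):
        """s(0) = 0 makes the all-zero state invariant when u = 0."""
        quiet = NMMConfig(input_amplitude=0.0)
        phys = _phys_vector(np.zeros(10), quiet, True)
        f = nmm_derivatives(np.zeros(18), 0.1, phys, quiet)
        assert np.allclose(f, 0.0, atol=1e-15)

    def test_unconnected_region_two_stays_at_rest(self, cfg):
        """With the forward connection removed, input to region 1 never
        reaches region 2."""
        phys = _phys_vector(np.zeros(10), cfg, True)
        phys["a21"] = 0.0
        phys["a12"] = 0.0
        rng = np.random.default_rng(0)
        x = np.zeros(18)
        x[:9] = rng.normal(0, 0.5, 9)  # region 1 active, region 2 at rest
        f = nmm_derivatives(x, 0.05, phys, cfg)
        assert np.allclose(f[9:], 0.0, atol=1e-15)

    def test_decoupled_jacobian_is_block_diagonal(self, cfg):
        phys = _phys_vector(np.zeros(10), cfg, True)
        phys["a21"] = 0.0
        phys["a12"] = 0.0
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.3, 18)
        _, A, _ = nmm_derivatives(x, 0.05, phys, cfg, partials=True)
        assert np.allclose(A[:9, 9:], 0.0)
        assert np.allclose(A[9:, :9], 0.0)

    def test_jacobian_matches_finite_differences(self, cfg, rng):
        phys = _phys_vector(rng.normal(0, 0.2, 10), cfg, True)
        x = rng.normal(0, 0.3, 18)
        f0, A, _ = nmm_derivatives(x, 0.07, phys, cfg, partials=True)
        eps = 1e-6
        for i in range(18):
            e = np.zeros(18)
            e[i] = eps
            col = (nmm_derivatives(x + e, 0.07, phys, cfg)
                   - nmm_derivatives(x - e, 0.07, phys, cfg)) / (2 * eps)
            assert np.allclose(A[:, i], col, atol=1e-4 * max(1, np.abs(col).max()))

    def test_alpha_kernel_impulse_peak(self, cfg):
        """One isolated synapse driven by an impulse reproduces the alpha
        function's maximum H_e / e at t = tau_e."""
        ke, ae = cfg.H_e / cfg.tau_e, 1.0 / cfg.tau_e

        def one_synapse(t, y):
            return [y[1], -2 * ae * y[1] - ae * ae * y[0]]

        # impulse of unit area: v(0) = 0, v_dot(0) = H_e / tau_e
        sol = solve_ivp(one_synapse, (0, 5 * cfg.tau_e), [0.0, ke],
                        t_eval=[cfg.tau_e], rtol=1e-10, atol=1e-12)
        assert sol.y[0, 0] == pytest.approx(cfg.H_e / np.e, rel=1e-6)


class TestIntegration:
    def test_no_input_gives_zero_output(self):
        quiet = NMMConfig(input_amplitude=0.0)
        traj = integrate_nmm(np.zeros(10), quiet)
        assert np.allclose(traj.y_hat, 0.0, atol=1e-12)

    def test_noise_sd_does_not_affect_predictions(self, cfg):
        a = integrate_nmm(np.zeros(10), NMMConfig(sigma_s=(0.01, 0.01)))
        b = integrate_nmm(np.zeros(10), NMMConfig(sigma_s=(0.02, 0.02)))
        assert np.array_equal(a.y_hat, b.y_hat)

    def test_solver_self_consistency_under_tighter_tolerances(self, cfg):
        coarse = integrate_nmm(np.zeros(10), cfg)
        fine = integrate_nmm(np.zeros(10), cfg, rtol=cfg.rtol / 10,
                             atol=cfg.atol / 10)
        scale = np.sqrt(np.mean(fine.y_hat**2))
        rms = np.sqrt(np.mean((coarse.y_hat - fine.y_hat)**2))
        assert rms < 0.01 * scale

    def test_observed_channels_are_pyramidal_potentials(self, cfg):
        traj = integrate_nmm(np.zeros(10), cfg)
        assert np.array_equal(traj.y_hat, traj.X[[8, 17]])


class TestLikelihoodAndSensitivities:
    def test_zero_residual_likelihood_is_the_constant(self, nmm_model):
        traj = nmm_model.simulate(np.zeros(10))
        model = TwoRegionNMM(
            type(nmm_model.data)(y=traj.y_hat, noise_sd=0.01),
            config=nmm_model.config)
        n_t = traj.y_hat.shape[1]
        expected = -n_t * np.log(2 * np.pi * 0.01**2) - 0.0
        assert model.log_lik(np.zeros(10)) == pytest.approx(
            n_t * 2 * (-0.5 * np.log(2 * np.pi * 0.01**2)))
        assert model.log_lik(np.zeros(10)) == pytest.approx(expected)

    def test_matches_per_point_gaussian_sum(self, nmm_model):
        """Hand computation: independent Gaussian density per time point."""
        from scipy.stats import norm

        w = np.zeros(10)
        traj = nmm_model.simulate(w)
        y = np.atleast_2d(nmm_model.data.y)
        sd = nmm_model.config.sigma_s
        by_hand = sum(
            norm.logpdf(y[s], loc=traj.y_hat[s], scale=sd[s]).sum()
            for s in range(2))
        assert nmm_model.log_lik(w) == pytest.approx(by_hand, rel=1e-12)

    def test_halving_noise_sd_penalises_residuals(self, nmm_model):
        w = np.full(10, 0.3)  # wrong parameters -> sizeable residuals
        tight = TwoRegionNMM(nmm_model.data,
                             config=NMMConfig(sigma_s=(0.005, 0.005)))
        assert tight.log_lik(w) < nmm_model.log_lik(w)

    def test_gradient_matches_finite_differences(self, nmm_model, rng):
        tight = nmm_model.with_config(rtol=1e-7, atol=1e-9)
        w = rng.normal(0, 0.2, 10)
        _, g, _ = tight.lik_grad_fisher(w)
        g_fd = fd_grad(tight.log_lik, w, eps=1e-4)
        assert np.abs(g - g_fd).max() < 1e-2 * np.abs(g_fd).max()

    def test_fisher_psd_on_prior_draws(self, nmm_model):
        rng = np.random.default_rng(3)
        for _ in range(5):
            w = nmm_model.sample_prior(rng)
            _, _, F = nmm_model.lik_grad_fisher(w)
            eig = np.linalg.eigvalsh(F)
            assert eig.min() >= -1e-8 * max(np.trace(F), 1.0)

    def test_zero_stimulus_zeroes_gradient(self):
        """With no input nothing reaches the observed channels, so every
        parameter sensitivity (and the gradient at matching data) vanishes."""
        quiet = NMMConfig(input_amplitude=0.0, sigma_s=(0.01, 0.01))
        data = gen_nmm(seed=0, sigma_s=0.0, config=quiet)
        model = TwoRegionNMM(data, config=quiet)
        _, g, F = model.lik_grad_fisher(np.zeros(10))
        assert np.allclose(g, 0.0, atol=1e-10)
        assert np.allclose(F, 0.0, atol=1e-10)

    def test_sensitivity_tensor_roundtrip(self, nmm_model, tmp_path):
        from aislmc import StateTrajectory

        traj = nmm_model.simulate(np.zeros(10), sensitivities=True)
        path = tmp_path / "sens.txt"
        traj.save_sensitivities(path)
        back = StateTrajectory.load_sensitivities(path)
        assert back.shape == traj.S.shape
        assert np.allclose(back, traj.S, atol=1e-8)

    def test_integration_failure_is_signalled_not_raised(self, nmm_model):
        from aislmc import EvaluationFailure

        wild = nmm_model.with_config(rtol=1e-13, atol=1e-300)
        # unreasonably tight tolerances exhaust the solver -> -inf, warning
        with pytest.warns(EvaluationFailure):
            ll = wild.log_lik(np.full(10, 4.0))
        assert ll == -np.inf
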