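"""Variance schedule, forward/reverse kernels, guidance and the LDM loss."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from prolatent._rng import substream
from prolatent.diffusion import (DiffusionSchedule, GuidanceSpec, UNet1D,
                                 condition_dropout, ddpm_step, guided_eps,
                                 ldm_loss, make_schedule, q_sample)


class TestSchedule:
    @given(st.integers(1, 200), st.floats(1e-5, 0.05), st.floats(0.05, 0.5),
           st.sampled_from(["linear", "constant"]))
    def test_invariants_for_any_schedule(self, T, lo, hi, kind):
        s = make_schedule(T, kind, lo, hi)
        assert np.all((s.beta > 0) & (s.beta < 1))
        np.testing.assert_allclose(s.alpha + s.beta, 1.0, rtol=0, atol=0)
        assert np.all(np.diff(s.alpha_bar) < 0) or T == 1
        assert s.sigma[0] == 0.0                      # alpha_bar_0 := 1

    def test_constant_beta_closed_form(self):
        s = make_schedule(50, "constant", 0.02, 0.3)
        np.testing.assert_allclose(s.alpha_bar, (1 - 0.02) ** np.arange(1, 51),
                                   rtol=1e-12)

    def test_default_T_is_500(self):
        assert make_schedule().T == 500

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            make_schedule(10, "linear", 0.5, 0.1)
        with pytest.raises(ValueError):
            make_schedule(10, "linear", 0.0, 0.1)
        with pytest.raises(ValueError):
            make_schedule(10, "unknown")


class TestQSample:
    def test_zero_noise_scales_by_sqrt_alpha_bar(self):
        s = make_schedule(10, "constant", 0.1, 0.1)
        z = np.ones((2, 3))
        out = q_sample(z, 4, np.zeros_like(z), s)
        np.testing.assert_allclose(out, np.sqrt(s.alpha_bar[3]) * z)

    def test_pure_noise_component(self):
        s = make_schedule(10, "constant", 0.1, 0.1)
        out = q_sample(np.zeros((1, 4)), 7, np.ones((1, 4)), s)
        np.testing.assert_allclose(out, np.sqrt(1 - s.alpha_bar[6]))

    def test_t_out_of_range(self):
        s = make_schedule(10)
        with pytest.raises(ValueError):
            q_sample(np.zeros((1, 2)), 0, np.zeros((1, 2)), s)
        with pytest.raises(ValueError):
            q_sample(np.zeros((1, 2)), 11, np.zeros((1, 2)), s)

    @pytest.mark.parametrize("t_frac", [0.0, 0.5, 1.0])
    def test_iterated_kernel_matches_marginal(self, t_frac):
        """Monte-Carlo oracle: iterating the per-step noising kernel agrees
        with the one-shot marginal in mean and variance (3 SE), n=10,000."""
        T = 40
        s = make_schedule(T, "linear", 1e-3, 0.05)
        t = max(1, int(round(t_frac * T)))
        n = 10_000
        rng = np.random.default_rng(0)
        z0 = 1.7
        z = np.full(n, z0)
        for step in range(1, t + 1):                   # per-step kernel chain
            z = np.sqrt(1 - s.beta[step - 1]) * z \
                + np.sqrt(s.beta[step - 1]) * rng.standard_normal(n)
        exp_mean = np.sqrt(s.alpha_bar[t - 1]) * z0
        exp_var = 1 - s.alpha_bar[t - 1]
        se_mean = np.sqrt(exp_var / n)
        assert abs(z.mean() - exp_mean) < 3 * se_mean
        se_var = exp_var * np.sqrt(2 / (n - 1))
        assert abs(z.var() - exp_var) < 3 * se_var


class TestDdpmStep:
    def test_zero_beta_limit_is_identity(self):
        s = DiffusionSchedule(beta=np.array([1e-12]))
        z = np.array([[0.3, -0.8]])
        out = ddpm_step(z, 1, np.zeros_like(z), s, np.ones_like(z))
        np.testing.assert_allclose(out, z, atol=1e-9)

    def test_hand_evaluated_single_step(self):
        """T=1, beta=0.5, z1=1, eps_hat=1, gamma=0 -> z0 = sqrt(2)(1 - 0.5/sqrt(0.5))."""
        s = DiffusionSchedule(beta=np.array([0.5]))
        out = ddpm_step(np.array([[1.0]]), 1, np.array([[1.0]]), s,
                        np.array([[0.0]]))
        assert out[0, 0] == pytest.approx(0.41421356, abs=1e-6)

    def test_gamma_scaled_by_sigma(self):
        s = make_schedule(20, "constant", 0.05, 0.05)
        t = 9
        out = ddpm_step(np.zeros((1, 2)), t, np.zeros((1, 2)), s,
                        np.ones((1, 2)))
        np.testing.assert_allclose(out, s.sigma[t - 1])

    def test_final_step_deterministic(self):
        s = make_schedule(20)
        a = ddpm_step(np.ones((1, 2)), 1, np.zeros((1, 2)), s,
                      np.random.default_rng(0).standard_normal((1, 2)))
        b = ddpm_step(np.ones((1, 2)), 1, np.zeros((1, 2)), s,
                      np.random.default_rng(1).standard_normal((1, 2)))
        np.testing.assert_array_equal(a, b)            # sigma_1 = 0


class TestGuidedEps:
    def test_omega_zero_returns_conditional(self, rng):
        e_c = rng.standard_normal((3, 4))
        e_u = rng.standard_normal((3, 4))
        np.testing.assert_array_equal(guided_eps(e_c, e_u, 0.0), e_c)

    def test_equal_estimates_fixed_point(self, rng):
        e = rng.standard_normal((2, 5))
        for omega in (0.0, 0.7, 20.0):
            np.testing.assert_allclose(guided_eps(e, e, omega), e)

    def test_hand_case(self):
        out = guided_eps(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 1.0)
        np.testing.assert_allclose(out, [2.0, -1.0])

    @given(st.floats(0, 50), st.floats(0, 50), st.floats(-3, 3),
           st.floats(-3, 3))
    def test_linear_in_omega_and_arguments(self, w1, w2, a, b):
        e_c, e_u = np.array([a]), np.array([b])
        lhs = guided_eps(e_c, e_u, w1) + guided_eps(e_c, e_u, w2)
        rhs = guided_eps(e_c, e_u, (w1 + w2) / 2) * 2
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            guided_eps(np.zeros(3), np.zeros(4), 1.0)


class TestConditionDropout:
    def test_extreme_probabilities(self, rng):
        labels = np.arange(8)
        np.testing.assert_array_equal(
            condition_dropout(labels, 0.0, rng, null_label=8), labels)
        assert (condition_dropout(labels, 1.0, rng, null_label=8) == 8).all()

    def test_replacement_fraction_binomial(self):
        rng = np.random.default_rng(5)
        labels = np.zeros(10_000, dtype=int)
        out = condition_dropout(labels, 0.5, rng, null_label=9)
        assert 0.48 <= (out == 9).mean() <= 0.52

    def test_guidance_spec_validation(self):
        with pytest.raises(ValueError):
            GuidanceSpec(omega=-1.0)
        with pytest.raises(ValueError):
            GuidanceSpec(p_uncond=1.5)


class TestLdmLoss:
    def test_oracle_predictor_reaches_zero(self):
        """A predictor that returns the exact noise drawn inside the loss."""
        s = make_schedule(10)
        rng = np.random.default_rng(0)
        z0 = rng.standard_normal((16, 4))

        captured = {}

        class Oracle:
            def __call__(self, z_t, t, c):
                ab = s.alpha_bar[np.asarray(t) - 1][:, None]
                z_t = z_t.data if hasattr(z_t, "data") else z_t
                return (z_t - np.sqrt(ab) * z0[captured["idx"]]) / np.sqrt(1 - ab)

        captured["idx"] = np.arange(16)
        loss = ldm_loss(Oracle(), z0, np.zeros(16, dtype=int), s,
                        np.random.default_rng(1))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_zero_predictor_expected_loss_is_latent_dim(self):
        """E||eps||^2 = D for standard normal noise (chi-square mean), n=10,000."""
        s = make_schedule(10)
        D = 6
        z0 = np.zeros((10_000, D))
        loss = ldm_loss(lambda z, t, c: np.zeros_like(z), z0,
                        np.zeros(10_000, dtype=int), s,
                        np.random.default_rng(2))
        se = np.sqrt(2 * D / 10_000)
        assert abs(float(loss.data) - D) < 3 * se

    def test_invariant_to_batch_order(self):
        s = make_schedule(10)
        z0 = np.random.default_rng(3).standard_normal((32, 4))
        labels = np.arange(32) % 8
        a = ldm_loss(lambda z, t, c: np.zeros_like(z), z0, labels, s,
                     np.random.default_rng(7))
        perm = np.random.default_rng(4).permutation(32)
        # same rng draws map to permuted elements only through t/eps pairing,
        # so compare via a deterministic predictor and explicit expectation
        b = ldm_loss(lambda z, t, c: np.zeros_like(z), z0[perm], labels[perm],
                     s, np.random.default_rng(7))
        assert float(a.data) == pytest.approx(float(b.data), rel=1e-6)


class TestUNet:
    def test_output_shape_and_finiteness(self):
        un = UNet1D(16, 8, substream(0, "init"), base_channels=8, n_levels=3)
        z = np.random.default_rng(0).standard_normal((5, 16))
        out = un(z, np.full(5, 3), np.full(5, 8))
        assert out.shape == (5, 16)
        assert np.isfinite(out.data).all()

    def test_label_out_of_range_rejected(self):
        un = UNet1D(8, 4, substream(0, "init"), base_channels=4, n_levels=2)
        z = np.zeros((2, 8))
        with pytest.raises(ValueError):
            un(z, np.ones(2), np.array([5, 0]))

    def test_levels_capped_by_latent_dim(self):
        un = UNet1D(2, 2, substream(0, "init"), base_channels=4, n_levels=4)
        assert un.n_levels == 1
        out = un(np.zeros((3, 2)), np.ones(3), np.zeros(3, dtype=int))
        assert out.shape == (3, 2)

    def test_null_label_embedding_distinct(self):
        un = UNet1D(8, 3, substream(1, "init"), base_channels=4, n_levels=2)
        z = np.random.default_rng(1).standard_normal((1, 8))
        out_c = un(z, np.ones(1), np.array([0]))
        out_u = un(z, np.ones(1), np.array([3]))       # 3 == null identifier
        assert not np.allclose(out_c.data, out_u.data)
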