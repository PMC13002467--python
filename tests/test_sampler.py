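"""Gibbs sampler: conjugate full conditionals, alignment, chain driver."""

import numpy as np
import pytest

from latentsna import (
    PriorSpec,
    SamplerConfig,
    align_reflection,
    initialize_state,
    joint_log_density,
    multi_start_fit,
    run_chain,
    update_Sigma,
    update_behavior_regression,
    update_connectivity_regression,
    update_latents,
    update_sigma2,
    update_tau2,
)
from latentsna.model import edge_residuals

from conftest import make_behav, make_conn, make_state


def _simple_pair(n=2, v=2, p=1, seed=0):
    rng = np.random.default_rng(seed)
    edges = rng.standard_normal((n, v, v))
    edges = edges + edges.transpose(0, 2, 1)
    idx = np.arange(v)
    edges[:, idx, idx] = 0.0
    conn = make_conn(edges)
    behav = make_behav(rng.standard_normal((n, p)))
    return conn, behav


class TestInitialization:
    def test_same_seed_bitwise_identical(self, small_dataset):
        conn, behav, _ = small_dataset
        a = initialize_state(conn, behav, PriorSpec(), 11)
        b = initialize_state(conn, behav, PriorSpec(), 11)
        assert np.array_equal(a.Z, b.Z)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.theta, b.theta)

    def test_different_seeds_differ(self, small_dataset):
        conn, behav, _ = small_dataset
        a = initialize_state(conn, behav, PriorSpec(), 1)
        b = initialize_state(conn, behav, PriorSpec(), 2)
        assert not np.array_equal(a.Z, b.Z)

    def test_sigma_starts_at_identity(self, small_dataset):
        conn, behav, _ = small_dataset
        st = initialize_state(conn, behav, PriorSpec(), 0)
        assert np.array_equal(st.Sigma, np.eye(conn.n_regions + 1))
        assert np.all(np.linalg.eigvalsh(st.Sigma) > 0)

    def test_n_mismatch_raises(self, small_dataset):
        conn, _, _ = small_dataset
        behav = make_behav(np.zeros((5, 1)))
        with pytest.raises(ValueError, match="!= behavior N"):
            initialize_state(conn, behav, PriorSpec(), 0)


class TestConnectivityRegression:
    def test_intercept_posterior_matches_closed_form(self):
        """N=2, V=2, Q=1: moments of a_1 draws match the conjugate normal
        posterior with precision 1 + M/sigma2, M = V(V-1)/2 = 1.  Beta is
        drawn first within the block, so its sampling distribution is
        marginalized analytically."""
        conn, behav = _simple_pair(n=2, v=2, seed=3)
        st = make_state(2, 2, seed=1)
        st.sigma2 = 1.0
        m = 1.0  # observed u<v edges per participant
        resid = conn.edges[:, 0, 1] - st.Z[:, 0] * st.Z[:, 1]

        # beta | state: precision 1 + N*m/sigma2, linear sum(resid - a*m)
        prec_b = 1.0 + 2 * m / st.sigma2
        mean_b = (resid - st.a * m).sum() / st.sigma2 / prec_b
        # a_1 | beta: precision 1 + m/sigma2, mean (resid_1 - beta*m)/s2/prec
        prec_a = 1.0 + m / st.sigma2
        mean_a = (resid[0] - mean_b * m) / st.sigma2 / prec_a
        var_a = 1.0 / prec_a + (m / (st.sigma2 * prec_a)) ** 2 / prec_b

        rng = np.random.default_rng(42)
        draws = np.array([
            update_connectivity_regression(st, conn, rng).a[0]
            for _ in range(10000)
        ])
        assert abs(draws.mean() - mean_a) < 3 * np.sqrt(var_a / 10000)
        assert draws.var() == pytest.approx(var_a, rel=0.1)

    def test_zero_residuals_center_intercepts_at_zero(self):
        st = make_state(3, 3, seed=2)
        st.beta[:] = 0.0
        st.a[:] = 0.0
        edges = np.einsum("iu,iv->iuv", st.Z, st.Z)
        idx = np.arange(3)
        edges[:, idx, idx] = 0.0
        conn = make_conn(edges)
        rng = np.random.default_rng(0)
        draws = np.array([
            update_connectivity_regression(st, conn, rng).a for _ in range(2000)
        ])
        assert np.abs(draws.mean(axis=0)).max() < 0.05

    def test_no_information_limit_recovers_prior(self):
        conn, behav = _simple_pair(n=2, v=3, seed=5)
        st = make_state(2, 3, seed=1, sigma2=1e9)
        rng = np.random.default_rng(1)
        betas = np.array([
            update_connectivity_regression(st, conn, rng).beta[0]
            for _ in range(4000)
        ])
        assert abs(betas.mean()) < 3 / np.sqrt(4000) + 0.02
        assert betas.var() == pytest.approx(1.0, rel=0.1)


class TestNoiseUpdates:
    def test_sigma2_conjugate_gamma_moments(self):
        """Two observed edges with zero residuals: 1/sigma2 ~ gamma(1.5, 0.5)."""
        st = make_state(1, 3, seed=0)
        st.beta[:] = 0.0
        st.a[:] = 0.0
        st.Z = np.array([[1.0, 2.0, 0.5]])
        edges = np.einsum("iu,iv->iuv", st.Z, st.Z)
        edges[:, np.arange(3), np.arange(3)] = 0.0
        mask = np.zeros((1, 3, 3), dtype=bool)
        mask[0, 0, 1] = mask[0, 1, 0] = True
        mask[0, 0, 2] = mask[0, 2, 0] = True   # 2 observed u<v edges
        conn = make_conn(edges, mask=mask)
        rng = np.random.default_rng(0)
        prec_draws = np.array([
            1.0 / update_sigma2(st, conn, rng).sigma2 for _ in range(10000)
        ])
        # gamma(shape=1.5, rate=0.5): mean 3, var 6
        assert prec_draws.mean() == pytest.approx(3.0, abs=3 * np.sqrt(6 / 10000))
        assert prec_draws.var() == pytest.approx(6.0, rel=0.15)
        assert np.all(prec_draws > 0)

    def test_sigma2_consistency_with_known_noise(self):
        rng = np.random.default_rng(8)
        n, v = 60, 20   # N*M = 60*190 = 11400 residuals
        st = make_state(n, v, seed=1)
        st.beta[:] = 0.0
        st.a[:] = 0.0
        edges = np.einsum("iu,iv->iuv", st.Z, st.Z)
        noise = rng.standard_normal((n, v, v)) * np.sqrt(2.0)
        noise = np.triu(noise, 1)
        noise = noise + noise.transpose(0, 2, 1)
        edges = edges + noise
        edges[:, np.arange(v), np.arange(v)] = 0.0
        conn = make_conn(edges)
        draws = np.array([
            update_sigma2(st, conn, np.random.default_rng(k)).sigma2
            for k in range(50)
        ])
        assert abs(draws.mean() - 2.0) / 2.0 < 0.10

    def test_tau2_conjugate_gamma_moments(self):
        """P=1, N=3 with zero residuals: 1/tau2 ~ gamma(0.5 + 1.5, 0.5)."""
        st = make_state(3, 2, seed=0)
        st.gamma[:] = 0.0
        st.b[:] = 0.0
        behav = make_behav((st.theta)[:, None])   # residuals exactly zero
        rng = np.random.default_rng(1)
        prec_draws = np.array([
            1.0 / update_tau2(st, behav, rng).tau2 for _ in range(10000)
        ])
        assert prec_draws.mean() == pytest.approx(4.0, abs=3 * np.sqrt(8 / 10000))
        assert np.all(prec_draws > 0)

    def test_tau2_consistency_with_known_noise(self):
        rng = np.random.default_rng(5)
        n, p = 2500, 4   # NP = 10000
        st = make_state(n, 2, p=p, seed=2)
        st.gamma[:] = 0.0
        st.b[:] = 0.0
        y = st.theta[:, None] + rng.standard_normal((n, p)) * np.sqrt(0.5)
        behav = make_behav(y)
        draws = np.array([
            update_tau2(st, behav, np.random.default_rng(k)).tau2
            for k in range(50)
        ])
        assert abs(draws.mean() - 0.5) / 0.5 < 0.10


class TestBehaviorRegression:
    def test_item_intercept_posterior_closed_form(self):
        """P=1, N=3, theta=0: b_1 posterior is normal with precision
        1 + N/tau2 and mean (N rbar / tau2) / (1 + N/tau2); the preceding
        gamma draw is marginalized analytically."""
        st = make_state(3, 2, seed=1, tau2=2.0)
        st.theta[:] = 0.0
        y = np.array([[0.4], [1.0], [-0.2]])
        behav = make_behav(y)
        n = 3.0
        # gamma | state: precision 1 + N/tau2, residual y - b - theta
        prec_g = 1.0 + n / st.tau2
        mean_g = (y[:, 0] - st.b[0]).sum() / st.tau2 / prec_g
        # b_1 | gamma: precision 1 + N/tau2, mean sum(y - gamma)/tau2/prec
        prec = 1.0 + n / st.tau2
        mean = (y.sum() - n * mean_g) / st.tau2 / prec
        var = 1.0 / prec + (n / (st.tau2 * prec)) ** 2 / prec_g
        rng = np.random.default_rng(0)
        draws = np.array([
            update_behavior_regression(st, behav, rng).b[0]
            for _ in range(10000)
        ])
        assert abs(draws.mean() - mean) < 3 * np.sqrt(var / 10000)
        assert draws.var() == pytest.approx(var, rel=0.1)

    def test_all_zero_residuals_shrink_to_zero(self):
        st = make_state(4, 2, p=2, seed=3)
        y = st.theta[:, None] + 0.0
        behav = make_behav(np.repeat(y, 2, axis=1))
        st.gamma[:] = 0.0
        st.b[:] = 0.0
        rng = np.random.default_rng(2)
        draws = np.array([
            update_behavior_regression(st, behav, rng).b for _ in range(2000)
        ])
        assert np.abs(draws.mean(axis=0)).max() < 0.06

    def test_prior_limit_as_tau2_grows(self):
        st = make_state(3, 2, seed=4, tau2=1e9)
        behav = make_behav(np.array([[5.0], [6.0], [7.0]]))
        rng = np.random.default_rng(3)
        draws = np.array([
            update_behavior_regression(st, behav, rng).gamma[0]
            for _ in range(4000)
        ])
        assert abs(draws.mean()) < 0.06
        assert draws.var() == pytest.approx(1.0, rel=0.1)


class TestSigmaUpdate:
    def test_prior_mean_with_no_participants(self):
        """N=0 rows: draw reduces to IW(I, V+D+2) whose mean is the identity."""
        v = 2
        st = make_state(1, v, seed=0)
        st.Z = np.zeros((0, v))
        st.theta = np.zeros(0)
        rng = np.random.default_rng(0)
        draws = np.stack([
            update_Sigma(st, PriorSpec(), rng).Sigma for _ in range(10000)
        ])
        # IW(I_3, 5) mean = I / (5 - 3 - 1) = I
        assert np.allclose(draws.mean(axis=0), np.eye(v + 1), atol=0.1)

    def test_posterior_mean_closed_form_small_f(self):
        v, n = 2, 5
        rng = np.random.default_rng(9)
        f = rng.standard_normal((n, v + 1))
        st = make_state(n, v, seed=0)
        st.Z = f[:, :v]
        st.theta = f[:, v]
        m0 = v + 1 + 2
        expected = (np.eye(v + 1) + f.T @ f) / (n + m0 - (v + 1) - 1)
        gen = np.random.default_rng(1)
        draws = np.stack([
            update_Sigma(st, PriorSpec(), gen).Sigma for _ in range(10000)
        ])
        assert np.allclose(draws.mean(axis=0), expected, atol=0.12)

    def test_draws_symmetric_positive_definite(self):
        st = make_state(20, 3, seed=2)
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = update_Sigma(st, PriorSpec(), rng)
            assert np.array_equal(out.Sigma, out.Sigma.T)
            assert np.all(np.linalg.eigvalsh(out.Sigma) > 0)


class TestLatentUpdate:
    def test_decoupled_prior_theta_matches_normal_mean_posterior(self):
        """Sigma block-diagonal (zero cross): theta's full conditional is the
        Bayesian normal-mean posterior of the item residuals."""
        n, v, p = 400, 3, 2
        rng = np.random.default_rng(4)
        st = make_state(n, v, p=p, seed=1, tau2=0.5)
        st.gamma[:] = 0.0
        st.b[:] = 0.0
        st.Sigma = np.eye(v + 1)
        y = rng.standard_normal((n, p))
        behav = make_behav(y)
        conn = make_conn(np.zeros((n, v, v)),
                         mask=np.zeros((n, v, v), dtype=bool))
        out = update_latents(st, conn, behav, np.random.default_rng(0))
        prec = p / st.tau2 + 1.0
        expect_mean = y.sum(axis=1) / st.tau2 / prec
        got_means = np.stack([
            update_latents(st, conn, behav, np.random.default_rng(k)).theta
            for k in range(300)
        ]).mean(axis=0)
        assert np.allclose(got_means, expect_mean, atol=4 * np.sqrt(1/prec/300) + 0.02)
        assert out.theta.shape == (n,)

    def test_prior_sampling_limit(self):
        """With effectively no data weight the sweep's stationary law is the
        MVN(0, Sigma) prior (checked through second moments)."""
        n, v = 400, 2
        sigma = np.array([[1.0, 0.5, 0.6],
                          [0.5, 1.0, 0.3],
                          [0.6, 0.3, 1.0]])
        st = make_state(n, v, seed=0, sigma2=1e12, tau2=1e12, Sigma=sigma)
        conn = make_conn(np.zeros((n, v, v)))
        behav = make_behav(np.zeros((n, 1)))
        rng = np.random.default_rng(0)
        samples = []
        for sweep in range(300):
            st = update_latents(st, conn, behav, rng)
            if sweep >= 50:
                samples.append(np.column_stack([st.Z, st.theta]))
        lat = np.concatenate(samples)
        emp = lat.T @ lat / len(lat)
        assert np.allclose(emp, sigma, atol=0.05)

    def test_region_marginal_variant_matches_exact_for_diagonal_sigma(self):
        n, v = 50, 3
        st = make_state(n, v, seed=6)
        conn, behav = _simple_pair(n=n, v=v, seed=2)
        a = update_latents(st, conn, behav, np.random.default_rng(5),
                           region_marginal_prior=False)
        b = update_latents(st, conn, behav, np.random.default_rng(5),
                           region_marginal_prior=True)
        # with Sigma = I both prior treatments coincide exactly
        assert np.allclose(a.Z, b.Z)
        assert np.allclose(a.theta, b.theta)

    def test_non_pd_sigma_raises(self):
        st = make_state(2, 2, seed=0)
        st.Sigma = np.array([[1.0, 2.0, 0], [2.0, 1.0, 0], [0, 0, 1.0]])
        conn, behav = _simple_pair()
        with pytest.raises(ValueError, match="positive definite"):
            update_latents(st, conn, behav, np.random.default_rng(0))


class TestAlignment:
    def test_aligned_state_is_fixed_point(self):
        st = make_state(5, 3, seed=1)
        ref = st.Z.copy()
        out = align_reflection(st, ref)
        assert np.array_equal(out.Z, st.Z)

    def test_negation_involution(self):
        st = make_state(5, 3, seed=2)
        ref = st.Z.copy()
        st2 = st.copy()
        st2.Z = -st2.Z
        back = align_reflection(st2, ref)
        assert np.array_equal(back.Z, st.Z)

    def test_connectivity_term_invariant_under_flip(self):
        n, v = 4, 3
        conn, behav = _simple_pair(n=n, v=v, seed=3)
        st = make_state(n, v, seed=4)
        flipped = st.copy()
        flipped.Z = -flipped.Z
        r1 = edge_residuals(st, conn)
        r2 = edge_residuals(flipped, conn)
        assert np.array_equal(r1, r2)
        # the joint density differs only through the prior cross term
        st.Sigma = np.eye(v + 1)
        flipped.Sigma = np.eye(v + 1)
        d1 = joint_log_density(st, conn, behav)
        d2 = joint_log_density(flipped, conn, behav)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_zero_inner_product_keeps_sign(self):
        st = make_state(1, 2, seed=0)
        st.Z = np.array([[1.0, 0.0]])
        ref = np.array([[0.0, 1.0]])
        out = align_reflection(st, ref)
        assert np.array_equal(out.Z, st.Z)


class TestChainDriver:
    def test_retained_draw_count_bookkeeping(self, small_dataset):
        conn, behav, _ = small_dataset
        cfg = SamplerConfig(n_iterations=100, burn_in=30, thinning=3, seed=0)
        samples = run_chain(conn, behav, config=cfg)
        assert samples.n_draws == (100 - 30) // 3

    def test_identical_seeds_identical_chains(self, small_dataset):
        conn, behav, _ = small_dataset
        cfg = SamplerConfig(n_iterations=60, burn_in=20, seed=9)
        a = run_chain(conn, behav, config=cfg)
        b = run_chain(conn, behav, config=cfg)
        assert np.array_equal(a.cross_cov, b.cross_cov)
        assert np.array_equal(a.Z_mean, b.Z_mean)

    def test_sigma_draw_cross_block_consistency(self, small_fit):
        samples, _ = small_fit
        st = samples.final_state
        v = st.Z.shape[1]
        assert np.array_equal(st.Sigma[:v, v], st.Sigma[v, :v])
        assert np.all(np.linalg.eigvalsh(st.Sigma) > 0)

    def test_signal_regions_positive_after_alignment(self, small_fit):
        samples, truth = small_fit
        means = samples.cross_cov.mean(axis=0)
        for u in truth.signal_regions:
            assert means[u] > 0.3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=10, burn_in=20)
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=15, burn_in=10, thinning=2)


class TestMultiStart:
    def test_score_log_and_best_selection(self, small_dataset):
        conn, behav, _ = small_dataset
        cfg = SamplerConfig(n_iterations=60, burn_in=20, n_starts=3, seed=1)
        state, samples = multi_start_fit(conn, behav, config=cfg,
                                         holdout_fraction=0.1)
        assert len(samples.start_scores) == 3
        assert max(samples.start_scores) == samples.start_scores[
            int(np.argmax(samples.start_scores))]
        assert state.Z.shape == (conn.n_participants, conn.n_regions)

    def test_single_start_reduces_to_one_chain(self, small_dataset):
        conn, behav, _ = small_dataset
        cfg = SamplerConfig(n_iterations=60, burn_in=20, n_starts=1, seed=2)
        state, samples = multi_start_fit(conn, behav, config=cfg,
                                         holdout_fraction=0.2)
        assert len(samples.start_scores) == 1
        assert samples.n_draws == 40

    def test_invalid_holdout_fraction(self, small_dataset):
        conn, behav, _ = small_dataset
        with pytest.raises(ValueError, match="holdout_fraction"):
            multi_start_fit(conn, behav, holdout_fraction=0.9)
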