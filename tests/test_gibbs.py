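import numpy as np
import pytest

from crossprs.errors import DomainError
from crossprs.gibbs import (
    ChainState,
    McmcConfig,
    ModelHyper,
    PHI_GRID_DEFAULT,
    initial_state,
    mh_update_rho,
    rho_log_density,
    run_chain,
    sample_beta_block,
    sample_delta,
    sample_phi,
    sample_psi,
    sample_sigma2,
)
from crossprs.gibbs import _group_index, _sigma_inv_stack
from crossprs.sumstats import LdBlock

from conftest import identity_blocks, make_panel


def fixed_state(panel, psi=1.0, sigma2=1.0, rho=0.0, phi=1.0):
    hyper = ModelHyper(phi_mode="fixed", phi_value=phi)
    state = initial_state(panel, hyper)
    state.psi[:] = psi
    state.sigma2[:] = sigma2
    for c in state.R:
        state.R[c][~np.eye(panel.n_pops, dtype=bool)] = rho
    return state


class TestBetaBlock:
    def test_single_population_closed_form(self, rng):
        """K=1, fixed psi: mean (D+Psi^-1)^-1 b_hat, cov (s2/N)(D+Psi^-1)^-1."""
        m, N, sig2 = 6, 200.0, 0.7
        A = rng.standard_normal((60, m))
        D = np.corrcoef(A, rowvar=False)
        bh = 0.05 * rng.standard_normal(m)
        psi = rng.uniform(0.5, 2.0, m)
        panel = make_panel(bh[:, None], [N])
        state = fixed_state(panel, sigma2=sig2)
        state.psi[:] = psi
        block = LdBlock("P1", 0, np.arange(m), D)
        gid, groups = _group_index(panel)
        stack = _sigma_inv_stack(state, groups)
        draws = np.empty((20000, m))
        for i in range(draws.shape[0]):
            state.beta[:] = 0.0
            draws[i] = sample_beta_block(block, state, panel, rng, stack, gid)
        P = D + np.diag(1.0 / psi)
        mean_cf = np.linalg.solve(P, bh)
        cov_cf = sig2 / N * np.linalg.inv(P)
        se = np.sqrt(np.diag(cov_cf) / draws.shape[0])
        assert np.all(np.abs(draws.mean(0) - mean_cf) < 4.5 * se)
        assert np.abs(np.cov(draws.T) - cov_cf).max() < 0.05 * np.abs(cov_cf).max()

    def test_two_population_joint_conditioning_oracle(self, rng):
        """2 SNPs x 2 pops, D=I: matches explicit 4x4 joint-Gaussian conditioning."""
        N = np.array([100.0, 100.0])
        rho, psi = 0.5, 1.0
        bh = np.array([[0.03, 0.01], [-0.02, 0.04]])
        b_other = np.array([0.05, -0.03])
        panel = make_panel(bh, N)
        state = fixed_state(panel, psi=psi, rho=rho)
        block = LdBlock("P1", 0, np.arange(2), np.eye(2))
        gid, groups = _group_index(panel)
        stack = _sigma_inv_stack(state, groups)
        # oracle: x = (b11, b12, b21, b22); prior blockdiag(psi*C) with
        # C = M Sigma M; condition pop-1 coords on pop-2 values + likelihood
        M = np.diag(1.0 / np.sqrt(N))
        C = M @ np.array([[1.0, rho], [rho, 1.0]]) @ M
        Q = np.linalg.inv(np.kron(np.eye(2), psi * C))
        i1, i2 = [0, 2], [1, 3]
        lik_prec = N[0] * np.eye(2)
        P = Q[np.ix_(i1, i1)] + lik_prec
        mu_oracle = np.linalg.solve(P, lik_prec @ bh[:, 0] - Q[np.ix_(i1, i2)] @ b_other)
        cov_oracle = np.linalg.inv(P)
        draws = np.empty((40000, 2))
        for i in range(draws.shape[0]):
            state.beta[:, 0] = 0.0
            state.beta[:, 1] = b_other
            draws[i] = sample_beta_block(block, state, panel, rng, stack, gid)
        se = np.sqrt(np.diag(cov_oracle) / draws.shape[0])
        assert np.all(np.abs(draws.mean(0) - mu_oracle) < 4.5 * se)
        assert np.abs(np.cov(draws.T) - cov_oracle).max() < 0.05 * cov_oracle.max()

    def test_zero_data_zero_neighbors_zero_mean(self, rng):
        panel = make_panel(np.zeros((4, 2)), [100, 100])
        state = fixed_state(panel, rho=0.4)
        block = LdBlock("P1", 0, np.arange(4), np.eye(4))
        draws = np.empty((5000, 4))
        for i in range(draws.shape[0]):
            state.beta[:] = 0.0
            draws[i] = sample_beta_block(block, state, panel, rng)
        assert np.abs(draws.mean(0)).max() < 4.5 * np.sqrt(1.0 / 100 / draws.shape[0])

    @pytest.mark.parametrize("psi, target", [(1e8, "data"), (1e-8, "zero")])
    def test_shrinkage_limits(self, rng, psi, target):
        """psi -> inf recovers the marginal estimate; psi -> 0 kills it (D=I)."""
        bh = np.array([[0.2], [-0.1], [0.05]])
        panel = make_panel(bh, [1000.0])
        state = fixed_state(panel, psi=psi)
        block = LdBlock("P1", 0, np.arange(3), np.eye(3))
        draws = np.mean(
            [
                sample_beta_block(block, state, panel, rng)
                for _ in range(4000)
            ],
            axis=0,
        )
        expected = bh[:, 0] if target == "data" else np.zeros(3)
        assert np.abs(draws - expected).max() < 2e-3


class TestSigma2:
    def test_zero_beta_reduces_to_pure_inverse_gamma(self, rng):
        """beta = 0: iG((N+S)/2, N/2); check both moments at 1e5 draws."""
        panel = make_panel(np.full((8, 1), 0.1), [50.0])
        blocks = identity_blocks(panel)
        state = fixed_state(panel)
        N, S = 50.0, 8
        shape, scale = (N + S) / 2.0, N / 2.0
        draws = np.empty(100000)
        for i in range(len(draws)):
            state.beta[:] = 0.0
            draws[i] = sample_sigma2(0, state, panel, blocks, rng)
        assert draws.mean() == pytest.approx(scale / (shape - 1.0), rel=0.01)
        var = scale**2 / ((shape - 1.0) ** 2 * (shape - 2.0))
        assert draws.var() == pytest.approx(var, rel=0.05)

    def test_scale_includes_quadratic_terms(self, rng):
        """Nonzero beta shifts the conditional mean by the (D+Psi^-1) form."""
        panel = make_panel(np.array([[0.1], [0.05]]), [200.0])
        blocks = identity_blocks(panel)
        state = fixed_state(panel, psi=0.5)
        beta = np.array([0.08, -0.02])
        N, S = 200.0, 2
        braced = 1.0 - 2.0 * beta @ [0.1, 0.05] + beta @ beta + beta @ np.diag([2.0, 2.0]) @ beta
        shape, scale = (N + S) / 2.0, N / 2.0 * braced
        draws = np.empty(100000)
        for i in range(len(draws)):
            state.beta[:, 0] = beta
            draws[i] = sample_sigma2(0, state, panel, blocks, rng)
        assert draws.mean() == pytest.approx(scale / (shape - 1.0), rel=0.01)


class TestRhoDensity:
    def test_no_shared_snps_constant(self):
        T = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        panel = make_panel(np.full((2, 2), 0.1), [100, 100], T=T)
        state = fixed_state(panel)
        vals = [rho_log_density(r, (0, 1), state, panel) for r in (0.0, 0.3, 0.8)]
        assert np.allclose(vals, vals[0])

    def test_zero_cross_products_monotone_decreasing(self):
        panel = make_panel(np.full((4, 2), 0.1), [100, 100])
        state = fixed_state(panel)
        state.beta[:, 0] = [0.1, 0.0, -0.2, 0.0]
        state.beta[:, 1] = [0.0, 0.15, 0.0, 0.1]   # products all zero
        grid = np.linspace(0.0, 0.95, 40)
        vals = [rho_log_density(r, (0, 1), state, panel) for r in grid]
        assert np.all(np.diff(vals) < 0)

    def test_identical_effects_favor_positive_rho(self):
        panel = make_panel(np.full((6, 2), 0.1), [100, 100])
        state = fixed_state(panel)
        b = np.array([0.1, -0.05, 0.2, 0.07, -0.12, 0.03])
        state.beta[:, 0] = b
        state.beta[:, 1] = b
        grid = np.linspace(0.0, 0.98, 99)
        vals = np.array([rho_log_density(r, (0, 1), state, panel) for r in grid])
        assert grid[np.argmax(vals)] > 0.0

    def test_domain(self):
        panel = make_panel(np.full((2, 2), 0.1), [100, 100])
        state = fixed_state(panel)
        with pytest.raises(DomainError):
            rho_log_density(1.0, (0, 1), state, panel)


class TestMhRho:
    def test_cons_zero_pins_rho(self, rng):
        panel = make_panel(np.full((5, 2), 0.1), [100, 100])
        state = fixed_state(panel)
        state.beta[:] = 0.1
        config = McmcConfig(cons=0.0)
        for _ in range(200):
            mh_update_rho((0, 1), state, config, panel, rng)
        assert state.R[1][0, 1] == 0.0

    def test_out_of_range_proposals_keep_state(self, rng):
        panel = make_panel(np.full((5, 2), 0.1), [100, 100])
        state = fixed_state(panel)
        config = McmcConfig(cons=0.2)
        for _ in range(500):
            mh_update_rho((0, 1), state, config, panel, rng)
            assert 0.0 <= state.R[1][0, 1] <= 0.2
            assert state.R[1][0, 1] == state.R[1][1, 0]

    def test_psd_guard_for_three_populations(self, rng):
        # with r12 = r13 = 0.9, PSD requires r23 >= 0.62; walk must stay above
        panel = make_panel(np.full((6, 3), 0.05), [100, 100, 100])
        state = fixed_state(panel)
        state.R[1][:] = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.7], [0.9, 0.7, 1.0]])
        state.beta[:] = 0.05
        config = McmcConfig(cons=0.99)
        for _ in range(300):
            mh_update_rho((1, 2), state, config, panel, rng)
            assert np.linalg.eigvalsh(state.R[1]).min() > -1e-12
        assert state.R[1][1, 2] >= 0.62 - config.delta_r


class TestPsiDeltaPhi:
    def test_psi_order_and_chi_for_single_population(self, rng):
        """1-pop SNP, sigma2=1, N=100, beta=0.1: chi = N beta^2 = 1.0."""
        panel = make_panel(np.array([[0.1]]), [100.0])
        state = fixed_state(panel)
        state.beta[0, 0] = 0.1
        hyper = ModelHyper(phi_mode="fixed", phi_value=1.0, psi_max=np.inf)
        gid, groups = _group_index(panel)
        stack = _sigma_inv_stack(state, groups)
        btil = state.beta[0] * np.sqrt(panel.N)
        chi = float(btil @ stack[gid[0]] @ btil)
        assert chi == pytest.approx(1.0)
        # with a=1, K_j=2, giG order is 0 (two-population case)
        assert ModelHyper().a - 0.5 * 2 == 0.0
        draws = np.array([
            sample_psi(0, state, panel, hyper, rng) for _ in range(20000)
        ])
        from scipy.stats import geninvgauss
        lam, rate = 1.0 - 0.5, 2.0 * state.delta[0]
        mean = geninvgauss.mean(lam, np.sqrt(rate * chi), scale=np.sqrt(chi / rate))
        assert draws.mean() == pytest.approx(mean, rel=0.05)

    def test_delta_gamma_moments_and_monotonicity(self, rng):
        panel = make_panel(np.array([[0.1]]), [100.0])
        state = fixed_state(panel)
        hyper = ModelHyper()  # a=1, b=1/2 -> shape 3/2
        state.psi[0] = 2.0
        state.phi = 1.0      # rate = 3
        draws = np.array([sample_delta(0, state, hyper, rng) for _ in range(100000)])
        assert draws.mean() == pytest.approx(1.5 / 3.0, rel=0.02)
        state.phi = 10.0     # larger rate -> stochastically smaller
        draws_hi = np.array([sample_delta(0, state, hyper, rng) for _ in range(20000)])
        assert draws_hi.mean() < draws.mean()

    def test_phi_fixed_mode_returns_value(self, rng):
        panel = make_panel(np.array([[0.1]]), [100.0])
        hyper = ModelHyper(phi_mode="fixed", phi_value=1e-2)
        state = initial_state(panel, hyper)
        for _ in range(5):
            assert sample_phi(state, hyper, 1, rng) == 1e-2

    def test_default_grid(self):
        assert ModelHyper().phi_grid == (1e-6, 1e-4, 1e-2, 1.0, "auto")
        assert PHI_GRID_DEFAULT[-1] == "auto"


class TestRunChain:
    def test_default_iteration_counts_scale_with_k(self):
        cfg = McmcConfig().resolve(2)
        assert cfg.n_iter == 2000 and cfg.n_burnin == 1000
        assert McmcConfig().resolve(3).n_iter == 3000

    def test_masked_entries_stay_zero(self, rng):
        T = np.ones((12, 2), dtype=np.uint8)
        T[2, 0] = T[5, 1] = T[9, 1] = 0
        bh = 0.05 * rng.standard_normal((12, 2))
        panel = make_panel(bh, [300.0, 200.0], T=T)
        blocks = identity_blocks(panel, block_size=6)
        summ = run_chain(
            panel, blocks, ModelHyper(phi_mode="fixed", phi_value=1e-2),
            McmcConfig(seed=3, n_iter=60, n_burnin=20),
        )
        assert np.all(summ.beta_mean[T == 0] == 0.0)

    def test_cons_zero_equals_frozen_identity_run(self, rng):
        bh = 0.04 * rng.standard_normal((10, 2))
        panel = make_panel(bh, [300.0, 200.0])
        blocks = identity_blocks(panel, block_size=5)
        hyper = ModelHyper(phi_mode="fixed", phi_value=1e-2)
        a = run_chain(panel, blocks, hyper, McmcConfig(seed=11, n_iter=80, n_burnin=30, cons=0.0))
        b = run_chain(panel, blocks, hyper, McmcConfig(seed=11, n_iter=80, n_burnin=30, update_rho=False))
        assert np.array_equal(a.beta_mean, b.beta_mean)
        assert np.array_equal(a.sigma2_mean, b.sigma2_mean)
        assert np.all(a.rho_mean[1] == np.eye(2))

    def test_deterministic_given_seed(self, rng):
        bh = 0.04 * rng.standard_normal((8, 2))
        panel = make_panel(bh, [300.0, 200.0])
        blocks = identity_blocks(panel, block_size=4)
        hyper = ModelHyper(phi_mode="auto")
        runs = [
            run_chain(panel, blocks, hyper, McmcConfig(seed=7, n_iter=50, n_burnin=20))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0].beta_mean, runs[1].beta_mean)
        assert runs[0].phi_mean == runs[1].phi_mean

    def test_k1_reduction_draw_matches_independent_oracle(self):
        """With frozen shrinkage, the joint code at K=1 must reproduce the
        separately coded single-population sampler draw-for-draw."""
        rng = np.random.default_rng(0)
        m, N, sig2 = 7, 150.0, 1.0
        A = rng.standard_normal((80, m))
        D = np.corrcoef(A, rowvar=False)
        bh = 0.05 * rng.standard_normal(m)
        psi = rng.uniform(0.3, 1.5, m)
        panel = make_panel(bh[:, None], [N])
        state = fixed_state(panel, sigma2=sig2)
        state.psi[:] = psi
        block = LdBlock("P1", 0, np.arange(m), D)

        rng_a = np.random.default_rng(99)
        rng_b = np.random.default_rng(99)
        from scipy.linalg import cho_factor, cho_solve, solve_triangular

        beta_oracle = np.zeros(m)
        for _ in range(5):
            draw = sample_beta_block(block, state, panel, rng_a)
            # independent oracle: textbook single-population conditional
            P = (N / sig2) * (D + sig2 * np.diag(1.0 / (sig2 * psi)))
            c, low = cho_factor(P, lower=True)
            mu = cho_solve((c, low), (N / sig2) * bh)
            z = rng_b.standard_normal(m)
            beta_oracle = mu + solve_triangular(c, z, lower=True, trans="T")
            assert np.allclose(draw, beta_oracle, atol=1e-12)

    def test_sigma_divergence_guard(self, rng):
        # absurd data on the standardized scale forces the guard to trip
        bh = np.full((6, 1), 50.0)
        panel = make_panel(bh, [5000.0])
        blocks = identity_blocks(panel)
        from crossprs.errors import NumericalError
        with pytest.raises(NumericalError):
            run_chain(
                panel, blocks, ModelHyper(phi_mode="fixed", phi_value=1.0),
                McmcConfig(seed=0, n_iter=40, n_burnin=10, sigma2_max=5.0),
            )
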