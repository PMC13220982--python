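"""Kernel machine core: kernel, likelihood, MCMC, PIPs, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from svybkmr import (BKMRConfig, KernelParams, PosteriorDraws, compute_pips,
                     compute_rhat, conditional_pips, group_pips,
                     marginal_loglik, mcmc_fit, posterior_h, rbf_kernel)


def _make_draws(delta, **kwargs):
    """Hand-built PosteriorDraws from an inclusion-indicator matrix."""
    delta = np.asarray(delta, dtype=int)
    t, m = delta.shape
    defaults = dict(r=delta.astype(float), delta=delta, lam=np.ones(t),
                    sigma2=np.ones(t), beta=np.zeros((t, 1)),
                    z_mean=np.zeros(m), z_sd=np.ones(m), varsel=True)
    defaults.update(kwargs)
    return PosteriorDraws(**defaults)


class TestRbfKernel:
    def test_unit_diagonal_and_symmetry(self, rng):
        z = rng.standard_normal((6, 3))
        k = rbf_kernel(z, z, np.array([0.5, 1.0, 0.2]))
        assert np.allclose(np.diag(k), 1.0)
        assert np.allclose(k, k.T)
        assert np.all((k > 0) & (k <= 1))

    def test_zero_scales_give_all_ones(self, rng):
        z = rng.standard_normal((4, 2))
        assert np.allclose(rbf_kernel(z, z, np.zeros(2)), 1.0)

    def test_unit_distance(self):
        k = rbf_kernel(np.array([[0.0]]), np.array([[1.0]]), np.array([1.0]))
        assert k[0, 0] == pytest.approx(np.exp(-1.0))

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros((2, 1)), np.zeros((2, 1)), np.array([-0.1]))


class TestMarginalLoglik:
    def test_single_observation_collapses_to_univariate_normal(self):
        params = KernelParams(r=np.array([0.7]), lam=3.0, sigma2=2.0,
                              beta=np.array([1.0]))
        y, x, z = np.array([0.4]), np.ones((1, 1)), np.array([[0.2]])
        got = marginal_loglik(y, x, z, params)
        want = stats.norm.logpdf(0.4, loc=1.0, scale=np.sqrt(2.0 * (1 + 3.0)))
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_dense_multivariate_normal_oracle(self, rng):
        n, m = 5, 3
        z = rng.standard_normal((n, m))
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        params = KernelParams(r=np.array([0.3, 1.2, 0.0]), lam=4.0,
                              sigma2=0.7, beta=np.array([0.5, -1.0]))
        cov = params.sigma2 * (np.eye(n)
                               + params.lam * rbf_kernel(z, z, params.r))
        want = stats.multivariate_normal.logpdf(y, mean=x @ params.beta,
                                                cov=cov)
        assert marginal_loglik(y, x, z, params) == pytest.approx(want,
                                                                 abs=1e-8)

    def test_lambda_to_zero_recovers_linear_model(self, rng):
        n = 6
        z = rng.standard_normal((n, 2))
        x = np.ones((n, 1))
        y = rng.standard_normal(n)
        params = KernelParams(r=np.array([1.0, 1.0]), lam=1e-12, sigma2=1.3,
                              beta=np.array([0.2]))
        want = stats.norm.logpdf(y, loc=0.2, scale=np.sqrt(1.3)).sum()
        assert marginal_loglik(y, x, z, params) == pytest.approx(want,
                                                                 abs=1e-6)


class TestPosteriorH:
    def _one_draw(self, r, lam, sigma2, beta, m):
        return PosteriorDraws(r=np.array([r]), delta=(np.array([r]) > 0) * 1,
                              lam=np.array([lam]), sigma2=np.array([sigma2]),
                              beta=np.array([[beta]]), z_mean=np.zeros(m),
                              z_sd=np.ones(m), varsel=True)

    def test_conditional_mean_matches_dense_oracle(self, rng):
        n, m, jit = 5, 2, 1e-8
        z = rng.standard_normal((n, m))
        z_new = rng.standard_normal((3, m))
        y = rng.standard_normal(n)
        r, lam, sigma2, beta = np.array([0.8, 0.3]), 5.0, 0.5, 0.7
        draws = self._one_draw(r, lam, sigma2, beta, m)
        got = posterior_h(draws, y, z, z_new, mode="mean", jitter=jit)[0]
        v = np.eye(n) * (1 + jit) + lam * rbf_kernel(z, z, r)
        want = lam * rbf_kernel(z_new, z, r) @ np.linalg.solve(v, y - beta)
        assert np.allclose(got, want, atol=1e-8)

    def test_interpolation_limit(self, rng):
        # tiny noise, huge signal ratio: posterior mean at a training point
        # approaches the centered observation
        n, m = 8, 2
        z = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        draws = self._one_draw(np.array([1.0, 1.0]), 1e6, 1e-6, 0.0, m)
        got = posterior_h(draws, y, z, z[[2]], mode="mean")[0, 0]
        assert got == pytest.approx(y[2], abs=1e-3)

    def test_zero_scales_give_constant_surface(self, rng):
        n, m = 6, 3
        z = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        draws = self._one_draw(np.zeros(m), 2.0, 1.0, 0.0, m)
        out = posterior_h(draws, y, z, rng.standard_normal((4, m)),
                          mode="mean")[0]
        assert np.ptp(out) < 1e-10

    def test_sample_mode_centers_on_conditional_mean(self, rng):
        n, m = 10, 2
        z = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        draws = PosteriorDraws(
            r=np.tile([0.5, 0.5], (400, 1)), delta=np.ones((400, 2), int),
            lam=np.full(400, 3.0), sigma2=np.full(400, 0.4),
            beta=np.zeros((400, 1)), z_mean=np.zeros(m), z_sd=np.ones(m),
            varsel=True)
        z_new = rng.standard_normal((2, m))
        samples = posterior_h(draws, y, z, z_new, mode="sample", seed=1)
        means = posterior_h(draws, y, z, z_new, mode="mean")
        assert np.allclose(samples.mean(axis=0), means[0], atol=0.15)


class TestMcmcFit:
    def test_seed_reproducibility(self, rng):
        z = rng.standard_normal((40, 3))
        y = z[:, 0] + rng.standard_normal(40)
        cfg = BKMRConfig(iters=60, burnin=20, thin=2, seed=5)
        a, b = mcmc_fit(y, z, config=cfg), mcmc_fit(y, z, config=cfg)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.lam, b.lam)

    def test_draw_count_and_shapes(self, rng):
        z = rng.standard_normal((30, 2))
        y = rng.standard_normal(30)
        cfg = BKMRConfig(iters=100, burnin=40, thin=3, seed=2)
        draws = mcmc_fit(y, z, config=cfg)
        assert draws.n_draws == cfg.n_retained == 20
        assert draws.delta.shape == (20, 2)
        assert np.all(draws.sigma2 > 0) and np.all(draws.lam > 0)

    def test_invalid_chain_schedule_rejected(self):
        with pytest.raises(ValueError):
            BKMRConfig(iters=100, burnin=100, thin=2)
        with pytest.raises(ValueError):
            BKMRConfig(iters=101, burnin=40, thin=2)

    def test_missing_values_rejected(self, rng):
        z = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        y[3] = np.nan
        with pytest.raises(ValueError):
            mcmc_fit(y, z, config=BKMRConfig(iters=10, burnin=4, thin=2))

    def test_null_data_keeps_pips_low(self):
        """With no signal, inclusion indicators should rarely switch on."""
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            z = rng.standard_normal((80, 3))
            y = rng.standard_normal(80)
            draws = mcmc_fit(y, z, config=BKMRConfig(iters=600, burnin=300,
                                                     thin=2, seed=seed))
            hits += np.all(compute_pips(draws) < 0.5)
        assert hits >= 2

    def test_standardization_invariance(self, rng):
        """Rescaled exposures give identical chains up to the stored
        transform (power-of-two scaling keeps the internal standardization
        bit-exact)."""
        z = rng.standard_normal((40, 3))
        y = z[:, 0] + rng.standard_normal(40)
        cfg = BKMRConfig(iters=80, burnin=40, thin=2, seed=8)
        a, b = mcmc_fit(y, z, config=cfg), mcmc_fit(y, 4.0 * z, config=cfg)
        assert np.array_equal(a.r, b.r)
        assert np.array_equal(a.sigma2, b.sigma2)
        assert np.allclose(b.z_sd, 4.0 * a.z_sd)

    def test_sigma2_recovery_under_known_noise(self):
        """Posterior 95% interval for sigma2 covers the truth sigma2=1 in
        most short-chain replicates of a smooth-signal simulation."""
        covered = 0
        n_seeds = 12
        for seed in range(n_seeds):
            rng = np.random.default_rng(400 + seed)
            z = rng.standard_normal((90, 3))
            h = 0.8 * z[:, 0] + 0.4 * z[:, 1] ** 2
            y = h + rng.standard_normal(90)
            draws = mcmc_fit(y, z, config=BKMRConfig(iters=700, burnin=300,
                                                     thin=2, seed=seed))
            lo, hi = np.percentile(draws.sigma2, [2.5, 97.5])
            covered += lo <= 1.0 <= hi
        assert covered >= 0.8 * n_seeds


class TestPips:
    def test_hand_count(self):
        draws = _make_draws([[1], [0], [1], [1]])
        assert compute_pips(draws)[0] == pytest.approx(0.75)

    def test_saturated_and_empty(self):
        assert compute_pips(_make_draws(np.ones((5, 2))))[1] == 1.0
        assert compute_pips(_make_draws(np.zeros((5, 2))))[0] == 0.0

    def test_varsel_off_warns_all_ones(self):
        draws = _make_draws(np.zeros((4, 2)), varsel=False)
        with pytest.warns(UserWarning):
            assert np.all(compute_pips(draws) == 1.0)

    def test_group_union_hand_count(self):
        delta = np.array([[1, 0], [0, 0], [0, 1], [1, 1]])
        got = group_pips(_make_draws(delta), [[0, 1]])
        assert got[0] == pytest.approx(0.75)

    def test_singleton_groups_reduce_to_pips(self, rng):
        delta = (rng.random((50, 4)) < 0.4).astype(int)
        draws = _make_draws(delta)
        assert np.allclose(group_pips(draws, [[j] for j in range(4)]),
                           compute_pips(draws))

    def test_group_pip_dominates_members(self, rng):
        delta = (rng.random((60, 5)) < 0.3).astype(int)
        draws = _make_draws(delta)
        pips = compute_pips(draws)
        got = group_pips(draws, [[0, 1, 2], [3, 4]])
        assert got[0] >= pips[:3].max() and got[1] >= pips[3:].max()

    def test_group_validation(self):
        draws = _make_draws(np.ones((3, 3)))
        with pytest.raises(ValueError):
            group_pips(draws, [[]])
        with pytest.raises(ValueError):
            group_pips(draws, [[0, 1], [1, 2]])

    def test_conditional_hand_count(self):
        delta = np.column_stack([[1, 0, 1, 1], [1, 1, 0, 1]])
        got = conditional_pips(_make_draws(delta))
        assert got[0, 1] == pytest.approx(2 / 3)   # delta_j=1 at t in {1,2,4}

    def test_conditional_saturated_column_equals_pip(self, rng):
        delta = np.column_stack([(rng.random(40) < 0.6).astype(int),
                                 np.ones(40, int)])
        draws = _make_draws(delta)
        got = conditional_pips(draws)
        assert got[0, 1] == pytest.approx(compute_pips(draws)[0])

    def test_conditional_undefined_is_nan(self):
        delta = np.column_stack([[1, 1, 0], [0, 0, 0]])
        got = conditional_pips(_make_draws(delta))
        assert np.isnan(got[0, 1]) and np.isnan(got[1, 1])


class TestRhat:
    def test_identical_chains(self):
        # identical halves -> no between-split variance -> exactly 1
        c = np.tile(np.sin(np.arange(50.0)), 2)
        assert compute_rhat([c, c]) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_chains_blow_up(self):
        got = compute_rhat([np.zeros(4) + np.array([0, 1e-9, 0, 1e-9]),
                            np.full(4, 10.0) + np.array([0, 1e-9, 0, 1e-9])])
        assert got > 10

    def test_converged_iid_chains_near_one(self):
        rng = np.random.default_rng(3)
        vals = [compute_rhat([rng.standard_normal(1000) for _ in range(4)])
                for _ in range(20)]
        assert np.mean([0.99 <= v <= 1.02 for v in vals]) >= 0.9

    def test_zero_variance_reported_missing(self):
        assert np.isnan(compute_rhat([np.zeros(8), np.zeros(8)]))

    def test_matches_arviz_split_rhat(self):
        # arviz's split rhat shrinks W by (n-1)/n; ours pins identical
        # chains at exactly 1, so the two agree to O(1/n)
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        chains = rng.standard_normal((4, 500)) + rng.normal(0, 0.1, (4, 1))
        want = float(az.rhat(az.convert_to_dataset(chains),
                             method="split")["x"].values)
        assert compute_rhat(list(chains)) == pytest.approx(want, abs=0.01)
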