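"""Gibbs-sampler full conditionals against closed-form and quadrature oracles."""

import numpy as np
import pytest
from scipy import stats

from hybbr import _kernels
from hybbr.bayesr import (GibbsConfig, GibbsData, MixturePrior,
                          run_gibbs, sample_mixture_proportions,
                          sample_residual_variance, sample_snp_effect)
from hybbr.data_model import VarianceComponents
from hybbr.synthetic_data import inference_inputs, simulate_dataset


def toy_snp(n=60, seed=0, sigma_e2=1.3):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    e0 = rng.standard_normal(n) + 0.4 * z
    w = rng.uniform(0.5, 2.0, n)
    l_i = float(z @ (w * z))
    return z, e0, w, l_i, sigma_e2


def marginal_likelihood_quadrature(z, e0, w, sigma_e2, s2, grid=20001,
                                   span=3.0):
    """Independent oracle: integrate the residual likelihood over g numerically."""
    if s2 == 0.0:
        return float(np.exp(-0.5 * np.sum(w * e0**2) / sigma_e2))
    gs = np.linspace(-span, span, grid)
    dens = np.empty(grid)
    for i, g in enumerate(gs):
        r = e0 - z * g
        dens[i] = np.exp(-0.5 * np.sum(w * r**2) / sigma_e2) * \
            stats.norm.pdf(g, 0.0, np.sqrt(s2))
    return float(np.trapezoid(dens, gs))


class TestSnpFullConditional:
    def test_degenerate_spike_prior(self):
        z, e0, w, l_i, se2 = toy_snp()
        prior = MixturePrior(sigma_g2=1.0, Pr=np.array([1.0, 0, 0, 0]))
        data = type("D", (), {})()
        g = np.array([0.5])
        cls = np.array([3])
        _kernels.seed_kernel_rng(1)
        e = e0 - z * g[0]
        logpr = np.where(prior.Pr > 0, np.log(np.maximum(prior.Pr, 1e-300)),
                         -np.inf)
        k, gnew = _kernels.sample_snp_effect_kernel(
            z, w, e, g[0], logpr, prior.class_var, se2, l_i)
        assert k == 0 and gnew == 0.0

    def test_effect_draw_matches_conjugate_normal(self):
        """Forced largest class: sampled g has the conjugate mean/variance."""
        z, e0, w, l_i, se2 = toy_snp(seed=1)
        prior = MixturePrior(sigma_g2=5.0,
                             Pr=np.array([0.0, 0.0, 0.0, 1.0]))
        s2 = prior.class_var[3]
        r_i = float(z @ (w * e0))
        prec = l_i + se2 / s2
        mean_th, var_th = r_i / prec, se2 / prec
        _kernels.seed_kernel_rng(7)
        ndraw = 20_000
        draws = np.empty(ndraw)
        logpr = np.log(np.maximum(prior.Pr, 1e-300))
        for t in range(ndraw):
            e = e0.copy()
            _, draws[t] = _kernels.sample_snp_effect_kernel(
                z, w, e, 0.0, logpr, prior.class_var, se2, l_i)
        se_mean = np.sqrt(var_th / ndraw)
        assert draws.mean() == pytest.approx(mean_th, abs=3 * se_mean)
        assert draws.var() == pytest.approx(var_th, rel=0.05)

    def test_class_frequencies_match_quadrature_oracle(self):
        z, e0, w, l_i, se2 = toy_snp(n=30, seed=2)
        prior = MixturePrior(sigma_g2=4.0,
                             Pr=np.array([0.4, 0.3, 0.2, 0.1]))
        marg = np.array([marginal_likelihood_quadrature(
            z, e0, w, se2, s2) for s2 in prior.class_var])
        p_oracle = prior.Pr * marg
        p_oracle /= p_oracle.sum()
        _kernels.seed_kernel_rng(11)
        ndraw = 100_000
        counts = np.zeros(4)
        logpr = np.log(prior.Pr)
        for t in range(ndraw):
            e = e0.copy()
            k, _ = _kernels.sample_snp_effect_kernel(
                z, w, e, 0.0, logpr, prior.class_var, se2, l_i)
            counts[k] += 1
        freq = counts / ndraw
        se = np.sqrt(p_oracle * (1 - p_oracle) / ndraw)
        assert np.all(np.abs(freq - p_oracle) < 4 * se + 1e-4)

    def test_python_wrapper_updates_state(self, small_scenario):
        data = small_scenario["data"]
        prior = small_scenario["prior"]
        g = np.zeros(data.m)
        cls = np.zeros(data.m, dtype=np.int64)
        e = data.y - data.X @ np.zeros(data.X.shape[1])
        e = e.copy()
        _kernels.seed_kernel_rng(3)
        k, gnew = sample_snp_effect(5, g, cls, e, data, prior,
                                    data.vc.sigma_e2)
        assert cls[5] == k and g[5] == gnew


class TestOtherConditionals:
    def test_dirichlet_update_moments(self, rng):
        draws = np.array([sample_mixture_proportions((4, 0, 0, 0),
                                                     np.ones(4), rng)
                          for _ in range(20_000)])
        assert np.allclose(draws.sum(axis=1), 1.0)
        assert np.allclose(draws.mean(axis=0), [5 / 8, 1 / 8, 1 / 8, 1 / 8],
                           atol=0.01)
        with pytest.raises(ValueError):
            sample_mixture_proportions((-1, 0, 0, 0), np.ones(4), rng)

    def test_residual_variance_posterior_mean(self, rng):
        n = 1000
        e = rng.standard_normal(n) * np.sqrt(2.0)
        draws = np.array([sample_residual_variance(e, np.ones(n), -2.0, 0.0,
                                                   rng)
                          for _ in range(4000)])
        # posterior mean of e'e/chi2_{n-2} is e'e/(n-4) ~ 2
        assert draws.mean() == pytest.approx(2.0, rel=0.05)

    def test_weighted_residuals_scale_sum_of_squares(self, rng):
        e = rng.standard_normal(500)
        a = np.array([sample_residual_variance(e, np.ones(500), -2, 0,
                                               np.random.default_rng(5))
                      for _ in range(500)])
        b = np.array([sample_residual_variance(e, np.full(500, 0.5), -2, 0,
                                               np.random.default_rng(5))
                      for _ in range(500)])
        assert np.mean(b) == pytest.approx(0.5 * np.mean(a), rel=1e-9)

    def test_polygenic_identity_case_matches_scalar_formula(self):
        n = 400
        rng = np.random.default_rng(9)
        vc = VarianceComponents(0.5, 0.8, 1.0)
        data = GibbsData(rng.standard_normal(n), np.ones((n, 1)),
                         rng.standard_normal((n, 8)), np.ones(n), vc,
                         A=np.eye(n))
        e_base = rng.standard_normal(n) * 1.5
        var_th = 1.0 / (1.0 / vc.sigma_e2 + 1.0 / vc.sigma_a2)
        mean_th = var_th * e_base / vc.sigma_e2
        draws = np.empty((300, n))
        for t in range(300):
            e = e_base.copy()
            draws[t] = data.sample_polygenic(e, np.zeros(n), vc.sigma_e2,
                                             rng)
        assert np.allclose(draws.mean(axis=0), mean_th,
                           atol=4 * np.sqrt(var_th / 300) + 1e-3)
        # spread around the conditional mean, pooled over animals
        assert (draws - mean_th).var() == pytest.approx(var_th, rel=0.05)

    def test_polygenic_zero_variance_returns_zero(self):
        n = 10
        rng = np.random.default_rng(10)
        vc = VarianceComponents(0.5, 0.0, 1.0)
        data = GibbsData(np.zeros(n), np.ones((n, 1)),
                         rng.standard_normal((n, 4)), np.ones(n), vc,
                         A=np.eye(n))
        e = rng.standard_normal(n)
        assert np.array_equal(
            data.sample_polygenic(e, np.zeros(n), 1.0, rng), np.zeros(n))


class TestRunGibbs:
    def test_null_data_stays_in_spike(self):
        rng = np.random.default_rng(21)
        n, m = 200, 150
        Zs = rng.standard_normal((n, m))
        vc = VarianceComponents(1e-4, 0.0, 1.0)
        data = GibbsData(rng.standard_normal(n), np.ones((n, 1)), Zs,
                         np.ones(n), vc)
        prior = MixturePrior(sigma_g2=1.0)
        s = run_gibbs(data, prior, GibbsConfig(iters=600, burnin=300,
                                               chains=1, seed=5))
        # classes 1 and 2 are near-indistinguishable on pure noise; the
        # large-variance classes should be empty and effects near zero
        assert s.P[:, :2].sum(axis=1).mean() > 0.75
        assert s.Pr_mean[3] < 0.1
        assert np.abs(s.g_mean).max() < 0.05

    def test_single_snp_posterior_mean_matches_quadrature(self):
        """1-SNP model, fixed Pr and sigma_e2: E[g | y] by numerical integration."""
        rng = np.random.default_rng(22)
        n = 200
        z = rng.standard_normal(n)
        g_true = 0.08
        se2 = 1.0
        y = z * g_true + rng.standard_normal(n)
        vc = VarianceComponents(1.0, 0.0, se2)
        data = GibbsData(y, np.zeros((n, 0)), z[:, None], np.ones(n), vc)
        prior = MixturePrior(sigma_g2=1.0,
                             Pr=np.array([0.25, 0.25, 0.25, 0.25]))
        s = run_gibbs(data, prior,
                      GibbsConfig(iters=30_000, burnin=5_000, chains=1,
                                  seed=3, update_proportions=False,
                                  update_sigma_e2=False))
        # oracle: posterior over (class, g) with y fixed
        w = np.ones(n)
        marg = [marginal_likelihood_quadrature(z, y, w, se2, s2)
                for s2 in prior.class_var]
        post_k = prior.Pr * np.array(marg)
        post_k /= post_k.sum()
        l_i = float(z @ z)
        r_i = float(z @ y)
        cond_mean = np.array([0.0 if s2 == 0 else r_i / (l_i + se2 / s2)
                              for s2 in prior.class_var])
        oracle = float(post_k @ cond_mean)
        assert s.g_mean[0] == pytest.approx(oracle, rel=0.05)

    def test_residual_consistency_invariant(self, small_scenario):
        data = small_scenario["data"]
        prior = small_scenario["prior"]
        drifts = []

        def hook(it, g, cls, active, Pr, sigma_e2, e, beta, v):
            if it % 50 == 0:
                e_true = data.residual(beta, g, v)
                drifts.append(np.max(np.abs(e - e_true)))

        run_gibbs(data, prior, GibbsConfig(iters=200, burnin=100, chains=1,
                                           seed=8), hooks=[hook])
        assert max(drifts) < 1e-8

    def test_single_class_posterior_mean_equals_blup(self):
        """Degenerate prior on one class turns the sampler into ridge/BLUP."""
        rng = np.random.default_rng(23)
        n, m = 120, 80
        Zs = rng.standard_normal((n, m))
        g_true = rng.standard_normal(m) * 0.1
        y = Zs @ g_true + rng.standard_normal(n)
        vc = VarianceComponents(1.0, 0.0, 1.0)
        data = GibbsData(y, np.ones((n, 1)), Zs, np.ones(n), vc)
        prior = MixturePrior(sigma_g2=2.0, Pr=np.array([0, 0, 0, 1.0]))
        s = run_gibbs(data, prior,
                      GibbsConfig(iters=6000, burnin=1000, chains=1, seed=2,
                                  update_proportions=False,
                                  update_sigma_e2=False))
        lam = vc.sigma_e2 / prior.class_var[3]
        Xa = np.column_stack([np.ones(n), Zs])
        Cmat = Xa.T @ Xa + lam * np.diag([0.0] + [1.0] * m)
        sol = np.linalg.solve(Cmat, Xa.T @ y)
        g_ridge = sol[1:]
        resid = s.g_mean - g_ridge
        assert np.corrcoef(s.g_mean, g_ridge)[0, 1] > 0.99
        assert np.abs(resid).max() < 0.05 * max(1.0, np.abs(g_ridge).max())

    def test_snp_order_exchangeability(self):
        """Permuting variant input order leaves posterior summaries equivalent."""
        geno, pheno, truth, vc, E = simulate_dataset(
            n=300, m=200, Pr_true=np.array([0.9, 0.05, 0.03, 0.02]), seed=31)
        data, aux = inference_inputs(geno, pheno, vc, E, design=False)
        prior = MixturePrior(sigma_g2=truth.mixture_scale)
        cfg = GibbsConfig(iters=1500, burnin=500, chains=1, seed=4)
        s1 = run_gibbs(data, prior, cfg)
        perm = np.random.default_rng(0).permutation(data.m)
        data2 = GibbsData(data.y, data.X, data.Zs[:, perm], data.E_diag, vc)
        s2 = run_gibbs(data2, prior, cfg)
        assert np.corrcoef(s1.gebv, s2.gebv)[0, 1] > 0.98
        assert np.allclose(s1.Pr_mean, s2.Pr_mean, atol=0.05)

    def test_posterior_interval_calibration(self):
        """Simulation-based calibration: 90% intervals for g cover ~90%."""
        n, m = 100, 50
        covered = total = 0
        prior = MixturePrior(sigma_g2=1.0,
                             Pr=np.array([0.6, 0.2, 0.1, 0.1]))
        for rep in range(60):
            rng = np.random.default_rng(1000 + rep)
            Zs = rng.standard_normal((n, m))
            cls = rng.choice(4, size=m, p=prior.Pr)
            g_true = np.where(cls > 0, rng.standard_normal(m), 0.0) * \
                np.sqrt(prior.class_var[cls])
            y = Zs @ g_true + rng.standard_normal(n)
            vc = VarianceComponents(1.0, 0.0, 1.0)
            data = GibbsData(y, np.zeros((n, 0)), Zs, np.ones(n), vc)
            samples = []

            def hook(it, g, **kw):
                if it > 300:
                    samples.append(g.copy())

            run_gibbs(data, prior,
                      GibbsConfig(iters=900, burnin=300, chains=1,
                                  seed=2000 + rep, update_proportions=False,
                                  update_sigma_e2=False), hooks=[hook])
            S = np.asarray(samples)
            lo = np.quantile(S, 0.05, axis=0)
            hi = np.quantile(S, 0.95, axis=0)
            covered += int(np.sum((g_true >= lo) & (g_true <= hi)))
            total += m
        assert 0.85 <= covered / total <= 0.95
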