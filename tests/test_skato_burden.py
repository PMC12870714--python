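import math

import numpy as np
import pytest
from scipy import stats

from sorlscan import skato_burden as sb

from conftest import make_samples
from sorlscan.association import build_covariate_matrix


def null_instance(seed, n=300, m=8, maf_lo=0.02, maf_hi=0.2, intercept_only=True):
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_lo, maf_hi, m)
    G = rng.binomial(2, mafs[None, :] * np.ones((n, 1))).astype(float)
    for j in range(m):
        if G[:, j].std() == 0:
            G[0, j] = 1
    y = rng.binomial(1, 0.5, n).astype(float)
    X = np.ones((n, 1)) if intercept_only else np.column_stack([np.ones(n), rng.normal(size=n)])
    return G, y, X


class TestNullModel:
    def test_intercept_only_balanced_gives_half(self):
        y = np.array([1.0, 0.0] * 50)
        null = sb.fit_null_model(y, np.ones((100, 1)))
        assert np.allclose(null.mu, 0.5)

    def test_residuals_sum_to_zero_with_intercept(self):
        G, y, X = null_instance(0, intercept_only=False)
        null = sb.fit_null_model(y, X)
        assert abs(null.residuals.sum()) < 1e-8

    def test_matches_independent_irls_fit(self):
        # hand-rolled iteratively-reweighted least squares as the oracle
        G, y, X = null_instance(1, intercept_only=False)
        null = sb.fit_null_model(y, X)
        beta = np.zeros(X.shape[1])
        for _ in range(100):
            eta = X @ beta
            mu = 1 / (1 + np.exp(-eta))
            W = mu * (1 - mu)
            beta = beta + np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (y - mu))
        mu_oracle = 1 / (1 + np.exp(-(X @ beta)))
        assert np.allclose(null.mu, mu_oracle, atol=1e-8)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            sb.fit_null_model(np.array([0.0, 1.0, 2.0]), np.ones((3, 1)))


class TestMixtureTail:
    def test_single_eigenvalue_is_chi2(self):
        assert sb.mixture_chisq_pvalue(3.841458820694124, [1.0]) == pytest.approx(0.05, abs=1e-6)

    def test_equal_pair_is_chi2_2df(self):
        assert sb.mixture_chisq_pvalue(5.991464547107979, [1.0, 1.0]) == pytest.approx(
            0.05, abs=1e-5
        )

    def test_scale_invariance(self):
        lam = np.array([0.5, 1.5, 2.0])
        a = sb.mixture_chisq_pvalue(4.0, lam)
        b = sb.mixture_chisq_pvalue(4.0e-4, lam * 1e-4)
        assert a == pytest.approx(b, rel=1e-6)

    def test_monte_carlo_oracle_random_spectra(self, rng):
        # 10^6-draw Monte-Carlo tails, agreement within 3 MC standard errors
        for _ in range(3):
            lam = rng.uniform(0.2, 3.0, 5)
            draws = (lam[None, :] * rng.chisquare(1, size=(10**6, 5))).sum(axis=1)
            for target in (0.5, 0.05, 0.005):
                q = np.quantile(draws, 1 - target)
                mc = (draws > q).mean()
                se = math.sqrt(mc * (1 - mc) / 1e6)
                assert sb.mixture_chisq_pvalue(q, lam) == pytest.approx(mc, abs=3 * se)

    def test_negative_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sb.mixture_chisq_pvalue(1.0, [1.0, -0.5])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sb.mixture_chisq_pvalue(1.0, [0.0, 0.0])


class TestWeights:
    def test_beta_weights_finite_and_decreasing(self):
        mafs = np.linspace(1e-6, 0.5, 200)
        w = sb.beta_maf_weights(mafs)
        assert np.all(np.isfinite(w))
        assert np.all(np.diff(w) < 0)

    def test_out_of_range_maf_rejected(self):
        with pytest.raises(ValueError):
            sb.beta_maf_weights(np.array([0.6]))


class TestSkatO:
    def test_rho_one_collapses_to_burden_score_test(self):
        G, y, X = null_instance(5)
        null = sb.fit_null_model(y, X)
        res = sb.skato_test(G, null, rho_grid=(1.0,))
        # independent weighted-count burden score test
        af = G.mean(axis=0) / 2
        w = sb.beta_maf_weights(np.clip(np.minimum(af, 1 - af), 1e-8, 0.5))
        b = float(w @ (G.T @ null.residuals))
        Zs = sb._adjusted_genotypes(G, null, w)
        var_b = float(np.sum(Zs.sum(axis=1) ** 2))
        p_burden = stats.chi2.sf(b**2 / var_b, 1)
        assert res.p_skato == pytest.approx(p_burden, rel=1e-6)

    def test_rho_zero_collapses_to_plain_skat(self):
        G, y, X = null_instance(6)
        null = sb.fit_null_model(y, X)
        res = sb.skato_test(G, null, rho_grid=(0.0,))
        af = G.mean(axis=0) / 2
        w = sb.beta_maf_weights(np.clip(np.minimum(af, 1 - af), 1e-8, 0.5))
        q_skat = float(np.sum(((G * w).T @ null.residuals) ** 2))
        Zs = sb._adjusted_genotypes(G, null, w)
        lam = np.linalg.eigvalsh(Zs.T @ Zs)
        p_skat = sb.mixture_chisq_pvalue(q_skat, np.clip(lam, 0, None))
        assert res.p_skato == pytest.approx(p_skat, rel=1e-6)

    def test_full_grid_endpoints_match_single_rho_runs(self):
        G, y, X = null_instance(7)
        null = sb.fit_null_model(y, X)
        full = sb.skato_test(G, null)
        assert full.p_per_rho[0] == pytest.approx(
            sb.skato_test(G, null, rho_grid=(0.0,)).p_skato, rel=1e-9
        )
        assert full.p_per_rho[-1] == pytest.approx(
            sb.skato_test(G, null, rho_grid=(1.0,)).p_skato, rel=1e-9
        )

    def test_omnibus_at_least_min_per_rho(self):
        for seed in range(5):
            G, y, X = null_instance(seed + 30)
            null = sb.fit_null_model(y, X)
            res = sb.skato_test(G, null)
            assert res.p_skato >= res.p_per_rho.min() - 1e-12
            assert 0 < res.p_skato <= 1

    def test_all_monomorphic_skipped(self):
        null = sb.fit_null_model(np.array([1.0, 0.0] * 10), np.ones((20, 1)))
        res = sb.skato_test(np.ones((20, 3)), null)
        assert res.skip_reason == "all monomorphic"
        assert math.isnan(res.p_skato)

    def test_missing_dosages_mean_imputed(self):
        G, y, X = null_instance(8)
        null = sb.fit_null_model(y, X)
        G_missing = G.copy()
        G_missing[0, 0] = np.nan
        res = sb.skato_test(G_missing, null)
        assert np.isfinite(res.p_skato)

    def test_omnibus_matches_exact_asymptotic_oracle(self):
        # the one-factor combination vs the exact null of the min-p
        # statistic (scores drawn from their limiting MVN), flat weights
        rng = np.random.default_rng(77)
        n, m = 60, 5
        mafs = rng.uniform(0.1, 0.4, m)
        G = rng.binomial(2, mafs[None, :] * np.ones((n, 1))).astype(float)
        eta = 0.9 * (G @ np.array([1.0, 1.0, 0.5, 0, 0])) - 1.0
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        null = sb.fit_null_model(y, np.ones((n, 1)))
        w = np.ones(m)
        res = sb.skato_test(G, null, weights=w)
        Zs = sb._adjusted_genotypes(G, null, w)
        K = Zs.T @ Zs
        L = np.linalg.cholesky(K + 1e-10 * np.trace(K) * np.eye(m))
        B = 200_000
        S = np.random.default_rng(1).standard_normal((B, m)) @ L.T
        eig = sb._per_rho_eigenvalues(Zs, res.rho_grid)
        interp = []
        for lam in eig:
            lam = lam[lam > 0]
            grid = np.concatenate(
                [[0.0], np.geomspace(1e-6 * lam.sum(), lam.sum() * 50 + 100, 300)]
            )
            interp.append((grid, sb._mixture_sf_batch(grid, lam)))
        qm = np.column_stack(
            [(1 - r) * np.sum(S**2, axis=1) + r * np.sum(S, axis=1) ** 2 for r in res.rho_grid]
        )
        pm = np.column_stack(
            [np.interp(qm[:, i], g, pv) for i, (g, pv) in enumerate(interp)]
        ).min(axis=1)
        pmc = (np.sum(pm <= float(res.p_per_rho.min())) + 1) / (B + 1)
        se = math.sqrt(pmc * (1 - pmc) / B)
        assert res.p_skato == pytest.approx(pmc, abs=max(3 * se, 2e-3))

    def test_covariate_adjusted_run_on_synthetic_samples(self):
        samples = make_samples(150, 150)
        X = build_covariate_matrix(samples)
        rng = np.random.default_rng(3)
        G = rng.binomial(2, 0.05, size=(300, 6)).astype(float)
        y = np.array([1.0 if s.is_case else 0.0 for s in samples])
        null = sb.fit_null_model(y, X)
        res = sb.skato_test(G, null, gene="SORL1")
        assert res.gene == "SORL1" and 0 < res.p_skato <= 1
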