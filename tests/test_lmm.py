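"""Unit and property tests for the LMM core: spectral decomposition, REML,
score test and BLUE weights, each against an independent dense oracle."""

import numpy as np
import pytest
from scipy import stats

from cislmm.lmm import (
    CovariateMatrix,
    ExpressionVector,
    GenotypeMatrix,
    blue_weights,
    fit_reml,
    restricted_loglik,
    score_test,
    spectral_decompose,
)
from cislmm.simulate import simulate_expression, simulate_genotypes

from conftest import make_genotype_matrix


def dense_restricted_loglik(Z, e, lam, X=None):
    """Matrix-form REML log-likelihood with explicit determinants/inverses."""
    n = Z.shape[0]
    if X is None:
        X = np.ones((n, 1))
    q = X.shape[1]
    V = lam * Z @ Z.T + np.eye(n)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    b = np.linalg.solve(XVX, X.T @ Vi @ e)
    r = e - X @ b
    s2 = (r @ Vi @ r) / (n - q)
    _, ldV = np.linalg.slogdet(V)
    _, ldXVX = np.linalg.slogdet(XVX)
    _, ldXX = np.linalg.slogdet(X.T @ X)
    return -0.5 * ((n - q) * np.log(2 * np.pi * s2) + ldV + ldXVX - ldXX + (n - q))


# ---------------------------------------------------------------------------
# spectral_decompose
# ---------------------------------------------------------------------------


class TestSpectralDecompose:
    def test_zero_genotypes_give_empty_spectrum(self):
        gm = make_genotype_matrix(np.zeros((12, 4)))
        sd = spectral_decompose(gm, None, np.random.default_rng(0).standard_normal(12))
        assert sd.K == 0
        assert sd.xi.size == 0

    def test_single_snp_eigenvalue_is_centered_crossproduct(self, rng):
        z = rng.uniform(0, 2, size=15)
        gm = make_genotype_matrix(z[:, None])
        sd = spectral_decompose(gm, None, rng.standard_normal(15))
        zc = z - z.mean()
        assert sd.K == 1
        assert np.isclose(sd.xi[0], zc @ zc, atol=1e-10)

    def test_matches_dense_eigensolve(self, rng):
        Z = rng.uniform(0, 2, (20, 5))
        e = rng.standard_normal(20)
        sd = spectral_decompose(Z, None, e)
        X = np.ones((20, 1))
        P0 = np.eye(20) - X @ np.linalg.solve(X.T @ X, X.T)
        w = np.sort(np.linalg.eigvalsh(P0 @ Z @ Z.T @ P0))[::-1]
        np.testing.assert_allclose(sd.xi, w[: sd.K], atol=1e-8)

    def test_rotated_data_preserves_rss(self, rng):
        Z = rng.uniform(0, 2, (25, 6))
        e = rng.standard_normal(25)
        sd = spectral_decompose(Z, None, e)
        ec = e - e.mean()
        assert np.isclose(np.sum(sd.u**2) + sd.tail_ss, ec @ ec, rtol=1e-10)

    def test_rank_deficient_covariates_error_names_columns(self, rng):
        Z = rng.uniform(0, 2, (10, 3))
        bad = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        X = CovariateMatrix(bad, names=["a", "a_doubled"])
        with pytest.raises(ValueError, match="rank deficient"):
            spectral_decompose(Z, X, rng.standard_normal(10))

    def test_too_few_samples_error(self, rng):
        Z = rng.uniform(0, 2, (3, 2))
        X = CovariateMatrix(rng.standard_normal((3, 3)))
        with pytest.raises(ValueError):
            spectral_decompose(Z, X, rng.standard_normal(3))

    def test_misaligned_samples_error(self, small_geno, rng):
        e = ExpressionVector(rng.standard_normal(20), [f"T{i}" for i in range(20)])
        with pytest.raises(ValueError, match="not aligned"):
            spectral_decompose(small_geno, None, e)


# ---------------------------------------------------------------------------
# restricted_loglik
# ---------------------------------------------------------------------------


class TestRestrictedLoglik:
    def test_null_closed_form(self, rng):
        Z = rng.uniform(0, 2, (10, 3))
        e = rng.standard_normal(10)
        sd = spectral_decompose(Z, None, e)
        n_q = sd.dof
        rss = sd.rss
        expected = -0.5 * n_q * (np.log(2 * np.pi * rss / n_q) + 1)
        assert np.isclose(restricted_loglik(sd, 0.0), expected, rtol=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 0.05, 0.3, 1.7, 25.0])
    def test_matches_dense_matrix_form(self, lam, rng):
        Z = rng.uniform(0, 2, (10, 4))
        e = rng.standard_normal(10)
        sd = spectral_decompose(Z, None, e)
        assert np.isclose(
            restricted_loglik(sd, lam), dense_restricted_loglik(Z, e, lam), atol=1e-8
        )

    def test_dense_agreement_with_covariates(self, rng):
        Z = rng.uniform(0, 2, (30, 6))
        X = CovariateMatrix(rng.standard_normal((30, 2)))
        e = rng.standard_normal(30)
        sd = spectral_decompose(Z, X, e)
        Xd = np.column_stack([np.ones(30), X.values])
        for lam in (0.0, 0.4, 3.0):
            assert np.isclose(
                restricted_loglik(sd, lam),
                dense_restricted_loglik(Z, e, lam, Xd),
                atol=1e-8,
            )

    def test_constant_in_lambda_when_no_eigenvalues(self, rng):
        gm = make_genotype_matrix(np.zeros((12, 3)))
        sd = spectral_decompose(gm, None, rng.standard_normal(12))
        vals = [restricted_loglik(sd, lam) for lam in (0.0, 1.0, 100.0)]
        assert np.ptp(vals) == 0.0

    def test_degenerate_phenotype_error(self, rng):
        Z = rng.uniform(0, 2, (8, 2))
        sd = spectral_decompose(Z, None, np.full(8, 3.14))  # constant -> rss 0
        with pytest.raises(ValueError, match="degenerate"):
            restricted_loglik(sd, 0.5)


# ---------------------------------------------------------------------------
# fit_reml
# ---------------------------------------------------------------------------


def _orthogonal_phenotype(Z, n):
    """A phenotype orthogonal to the intercept and to P0 Z (so u = 0, rss > 0)."""
    X = np.ones((n, 1))
    P0 = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    B = np.column_stack([X, P0 @ Z])
    Q, _ = np.linalg.qr(B)
    e = np.random.default_rng(3).standard_normal(n)
    e = e - Q @ (Q.T @ e)
    assert np.linalg.norm(e) > 1e-8
    return e


class TestFitReml:
    def test_orthogonal_data_gives_boundary_fit(self, rng):
        Z = rng.uniform(0, 2, (20, 3))
        e = _orthogonal_phenotype(Z, 20)
        sd = spectral_decompose(Z, None, e)
        fit = fit_reml(sd)
        assert fit.lambda_hat == 0.0
        assert fit.T == 0.0

    def test_strong_signal_matches_fine_grid_oracle(self):
        Z = simulate_genotypes(80, 10, seed=21).dosages
        e = simulate_expression(Z, tau=0.4, seed=22)
        sd = spectral_decompose(Z, None, e)
        fit = fit_reml(sd)
        # independent fine-grid oracle over one million lambdas
        lams = np.concatenate([[0.0], np.logspace(-5, 5, 1_000_001)])
        denom = 1.0 + lams[:, None] * sd.xi[None, :]
        s2 = (np.sum(sd.u**2 / denom, axis=1) + sd.tail_ss) / sd.dof
        ll = -0.5 * (
            sd.dof * np.log(2 * np.pi * s2) + np.log(denom).sum(axis=1) + sd.dof
        )
        lam_star = lams[np.argmax(ll)]
        assert lam_star > 0
        assert abs(fit.lambda_hat - lam_star) / lam_star < 1e-4

    def test_statistic_sign_iff_boundary(self):
        """T >= 0 always; T = 0 exactly when lambda_hat = 0 (both directions)."""
        Z = simulate_genotypes(50, 8, seed=31).dosages
        seen_zero = seen_pos = 0
        for rep in range(300):
            e = simulate_expression(Z, tau=0.08 if rep % 2 else 0.0, seed=1000 + rep)
            fit = fit_reml(spectral_decompose(Z, None, e))
            assert fit.T >= 0.0
            assert (fit.T == 0.0) == (fit.lambda_hat == 0.0)
            assert fit.loglik_alt >= fit.loglik_null - 1e-10
            assert 0.0 <= fit.h2 < 1.0
            seen_zero += fit.T == 0.0
            seen_pos += fit.T > 0.0
        assert seen_zero > 0 and seen_pos > 0

    def test_h2_mapping(self):
        assert fit_reml.__module__  # anchor
        for lam, h2 in [(0.0, 0.0), (1.0, 0.5), (3.0, 0.75)]:
            assert np.isclose(lam / (1 + lam), h2)

    def test_tau2_is_lambda_times_sigma2(self):
        Z = simulate_genotypes(60, 6, seed=41).dosages
        e = simulate_expression(Z, tau=0.3, seed=42)
        fit = fit_reml(spectral_decompose(Z, None, e))
        assert np.isclose(fit.tau2_hat, fit.lambda_hat * fit.sigma2_hat, rtol=1e-12)

    def test_boundary_fraction_matches_mixture_point_mass(self):
        """Under the null, fraction of lambda_hat = 0 agrees with phi_hat."""
        from cislmm.lmm import batch_lrt
        from cislmm.nulldist import fit_mixture, simulate_null_draws

        Z = simulate_genotypes(60, 10, seed=51).dosages
        sd = spectral_decompose(Z, None, np.zeros(60))
        rng = np.random.default_rng(52)
        R = 2000
        E = rng.standard_normal((60, R))
        U2, tails = sd.rotate(E)
        T, _ = batch_lrt(sd.xi, U2, tails, sd.dof)
        frac_zero = np.mean(T == 0.0)
        mix = fit_mixture(simulate_null_draws(sd, 20_000, seed=53))
        assert abs(frac_zero - mix.phi) < 0.04
        assert 0.0 < frac_zero < 1.0

    def test_parameter_recovery(self):
        """Median lambda_hat over replicates tracks tau^2 * tr(Z'P0Z)/(n-q)."""
        from cislmm.lmm import batch_lrt
        from cislmm.simulate import expected_lambda

        Z = simulate_genotypes(465, 100, seed=61).dosages
        tau2 = 0.01
        lam_true = expected_lambda(Z, tau2)
        sd = spectral_decompose(Z, None, np.zeros(465))
        rng = np.random.default_rng(62)
        R = 500
        B = rng.normal(0, np.sqrt(tau2), size=(100, R))
        E = Z @ B + rng.standard_normal((465, R))
        U2, tails = sd.rotate(E)
        _, lam = batch_lrt(sd.xi, U2, tails, sd.dof)
        assert abs(np.median(lam) - lam_true) / lam_true < 0.25


# ---------------------------------------------------------------------------
# score_test
# ---------------------------------------------------------------------------


class TestScoreTest:
    def test_orthogonal_data_gives_null_result(self, rng):
        Z = rng.uniform(0, 2, (20, 3))
        e = _orthogonal_phenotype(Z, 20)
        sd = spectral_decompose(Z, None, e)
        stat, p = score_test(sd)
        assert stat == pytest.approx(0.0, abs=1e-16)
        assert p == 1.0

    def test_liu_matches_monte_carlo_oracle(self):
        Z = simulate_genotypes(30, 5, seed=71).dosages
        e = simulate_expression(Z, tau=0.25, seed=72)
        sd = spectral_decompose(Z, None, e)
        stat, p_liu = score_test(sd, method="liu")
        # independent 1e5-draw simulation of the weighted chi-square tail
        rng = np.random.default_rng(73)
        weights = sd.xi / (2.0 * (sd.rss / sd.dof))
        draws = rng.chisquare(1.0, size=(100_000, weights.size)) @ weights
        p_mc = np.mean(draws >= stat)
        se = np.sqrt(max(p_mc * (1 - p_mc), 1e-10) / 100_000)
        assert abs(p_liu - p_mc) < max(4 * se, 0.005)

    def test_mc_mode_reproducible(self):
        Z = simulate_genotypes(30, 5, seed=71).dosages
        e = simulate_expression(Z, tau=0.25, seed=72)
        sd = spectral_decompose(Z, None, e)
        _, p1 = score_test(sd, method="mc", n_draws=20_000, seed=5)
        _, p2 = score_test(sd, method="mc", n_draws=20_000, seed=5)
        assert p1 == p2


# ---------------------------------------------------------------------------
# blue_weights
# ---------------------------------------------------------------------------


class TestBlueWeights:
    def test_zero_lambda_gives_zero_vector(self, rng):
        Z = rng.uniform(0, 2, (20, 4))
        e = _orthogonal_phenotype(Z, 20)
        fit = fit_reml(spectral_decompose(Z, None, e))
        assert fit.lambda_hat == 0.0
        w = blue_weights(Z, None, e, fit)
        assert np.all(w.beta == 0.0)

    def _dense_blue(self, Z, e, lam, X=None):
        n = Z.shape[0]
        if X is None:
            X = np.ones((n, 1))
        V = lam * Z @ Z.T + np.eye(n)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ e)
        return lam * Z.T @ Vi @ (e - X @ b)

    def test_matches_dense_evaluation(self):
        Z = simulate_genotypes(10, 3, seed=82).dosages
        e = simulate_expression(Z, tau=0.8, seed=182)
        fit = fit_reml(spectral_decompose(Z, None, e))
        assert fit.lambda_hat > 0
        w = blue_weights(Z, None, e, fit)
        np.testing.assert_allclose(
            w.beta, self._dense_blue(Z, e, fit.lambda_hat), atol=1e-8
        )

    def test_ridge_identity(self):
        """Woodbury: beta = (Z'Z + I/lam)^-1 Z' r with r the GLS-adjusted phenotype."""
        Z = simulate_genotypes(40, 6, seed=83).dosages
        e = simulate_expression(Z, tau=0.4, seed=84)
        fit = fit_reml(spectral_decompose(Z, None, e))
        lam = fit.lambda_hat
        assert lam > 0
        n = Z.shape[0]
        X = np.ones((n, 1))
        V = lam * Z @ Z.T + np.eye(n)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ e)
        r = e - X @ b
        ridge = np.linalg.solve(Z.T @ Z + np.eye(Z.shape[1]) / lam, Z.T @ r)
        w = blue_weights(Z, None, e, fit)
        np.testing.assert_allclose(w.beta, ridge, atol=1e-8)

    def test_allele_recoding_flips_one_weight(self):
        Z = simulate_genotypes(50, 5, seed=85).dosages
        e = simulate_expression(Z, tau=0.4, seed=86)
        fit = fit_reml(spectral_decompose(Z, None, e))
        w = blue_weights(Z, None, e, fit)
        Z2 = Z.copy()
        Z2[:, 2] = 2.0 - Z2[:, 2]
        fit2 = fit_reml(spectral_decompose(Z2, None, e))
        assert np.isclose(fit2.lambda_hat, fit.lambda_hat, rtol=1e-6)
        w2 = blue_weights(Z2, None, e, fit2)
        np.testing.assert_allclose(w2.beta[2], -w.beta[2], atol=1e-7)
        np.testing.assert_allclose(
            np.delete(w2.beta, 2), np.delete(w.beta, 2), atol=1e-7
        )

    def test_requires_fit(self, rng):
        Z = rng.uniform(0, 2, (10, 2))
        with pytest.raises(ValueError):
            blue_weights(Z, None, rng.standard_normal(10), None)


class TestGenotypeMatrix:
    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            make_genotype_matrix(np.array([[0.5, 2.5]]))

    def test_rejects_duplicate_variant_ids(self, rng):
        gm = make_genotype_matrix(rng.uniform(0, 2, (4, 2)))
        gm.variants.loc[1, "id"] = gm.variants.loc[0, "id"]
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(gm.samples, gm.variants, gm.dosages)

    def test_mean_imputation(self):
        d = np.array([[0.0, np.nan], [2.0, 1.0], [1.0, 1.0]])
        gm = make_genotype_matrix(d).impute_missing()
        assert gm.dosages[0, 1] == 1.0

    def test_maf_definition(self):
        d = np.array([[2.0, 0.2], [2.0, 0.0], [1.8, 0.2]])
        gm = make_genotype_matrix(d)
        f = d.mean(axis=0) / 2
        np.testing.assert_allclose(gm.maf(), np.minimum(f, 1 - f))
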