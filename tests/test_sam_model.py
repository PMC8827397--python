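"""Likelihood, mean structure, priors: oracle checks against independent sums."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import norm

import treesam as ts
from treesam.sam_model import AGE_K, LOG_2PI, design_matrix, log_ndtr


class TestMeanGrowth:
    def test_all_covariates_at_center_gives_intercept(self, tiny_design, tiny_params,
                                                      scheme):
        # constant weights make the antecedent covariates constant = centered 0
        p = tiny_params
        X, _, _ = design_matrix(tiny_design, p.weights_P, p.weights_T)
        # pick the record whose covariates are closest to zero and verify the
        # linear predictor is near the core intercept
        i = int(np.argmin(np.abs(X[:, 1:]).sum(axis=1)))
        mu = float(X[i] @ p.alpha[tiny_design.core_index[i]])
        approx_intercept = p.alpha[tiny_design.core_index[i], 0]
        assert mu == pytest.approx(approx_intercept, abs=np.abs(X[i, 1:]).sum() * 5)

    def test_matches_term_by_term_expansion(self, tiny_design, tiny_params):
        p = tiny_params
        X, _, _ = design_matrix(tiny_design, p.weights_P, p.weights_T)
        i = 17
        c = tiny_design.core_index[i]
        a = p.alpha[c]
        expected = sum(a[k] * X[i, k] for k in range(9))
        got = ts.mean_growth(p, tiny_design,
                             int(tiny_design.years[i]), tiny_design.cores[c])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_slopes_reduce_to_intercept(self, tiny_design, tiny_params):
        p = tiny_params
        alpha = np.zeros_like(p.alpha)
        alpha[:, 0] = 0.7
        alpha[:, AGE_K] = 0.0
        q = ts.SamParams(alpha=alpha, mu_alpha=p.mu_alpha,
                         sigma_alpha=p.sigma_alpha, sigma_obs=p.sigma_obs,
                         weights_P=p.weights_P, weights_T=p.weights_T)
        got = ts.mean_growth(q, tiny_design, int(tiny_design.years[0]),
                             tiny_design.cores[tiny_design.core_index[0]])
        assert got == pytest.approx(0.7)

    def test_unmodeled_record_raises(self, tiny_design, tiny_params):
        with pytest.raises(KeyError):
            ts.mean_growth(tiny_params, tiny_design, 1800, tiny_design.cores[0])


class TestLogLikelihood:
    def test_matches_scipy_normal_sum(self, tiny_design, tiny_params):
        p = tiny_params
        X, _, _ = design_matrix(tiny_design, p.weights_P, p.weights_T)
        mu = np.einsum("ij,ij->i", X, p.alpha[tiny_design.core_index])
        expected = norm.logpdf(tiny_design.G, mu, p.sigma_obs).sum()
        assert ts.log_likelihood(p, tiny_design) == pytest.approx(expected, rel=1e-12)

    def test_single_record_at_its_mode(self):
        # a single observation equal to its mean with sigma 1 contributes
        # -log(sqrt(2 pi))
        assert norm.logpdf(0.0, 0.0, 1.0) == pytest.approx(-0.5 * LOG_2PI)

    def test_additivity_under_duplication(self, tiny_design, tiny_params):
        ll = ts.log_likelihood(tiny_params, tiny_design)
        import copy
        doubled = copy.deepcopy(tiny_design)
        for name in ("core_index", "years", "G", "G_prev_centered",
                     "age_centered", "hi_centered", "year_of_record"):
            setattr(doubled, name, np.concatenate([getattr(tiny_design, name)] * 2))
        assert ts.log_likelihood(tiny_params, doubled) == pytest.approx(2 * ll)

    def test_nonpositive_sigma_is_an_error(self, tiny_design, tiny_params):
        p = tiny_params
        with pytest.raises(ValueError):
            ts.SamParams(alpha=p.alpha, mu_alpha=p.mu_alpha,
                         sigma_alpha=p.sigma_alpha, sigma_obs=-1.0,
                         weights_P=p.weights_P, weights_T=p.weights_T)


class TestLogPrior:
    def test_matches_independent_density_sum(self, tiny_params):
        p = tiny_params
        prior = ts.PriorSpec()
        expected = 0.0
        for k in range(9):
            expected += norm.logpdf(p.alpha[:, k], p.mu_alpha[k],
                                    p.sigma_alpha[k]).sum()
            if k == AGE_K:
                expected -= p.n_cores * float(
                    log_ndtr(-p.mu_alpha[k] / p.sigma_alpha[k]))
        expected += norm.logpdf(p.mu_alpha, 0.0, prior.mu_alpha_sd).sum()
        expected += np.log(2.0)              # truncated age hyper-mean
        expected += -10 * np.log(prior.sigma_upper)
        expected += 2 * gammaln(34)          # Dirichlet(1,...,1) on 34 blocks
        assert ts.log_prior(p, prior) == pytest.approx(expected, rel=1e-12)

    def test_dirichlet_flat_density_is_log_gamma_34(self, tiny_params, scheme):
        """Moving mass around the simplex does not change the flat prior."""
        p1 = ts.log_prior(tiny_params)
        moved = np.random.default_rng(8).dirichlet(np.ones(34))
        q = ts.SamParams(alpha=tiny_params.alpha, mu_alpha=tiny_params.mu_alpha,
                         sigma_alpha=tiny_params.sigma_alpha,
                         sigma_obs=tiny_params.sigma_obs,
                         weights_P=ts.WeightVector("precipitation", moved, scheme),
                         weights_T=tiny_params.weights_T)
        assert ts.log_prior(q) == pytest.approx(p1)

    def test_positive_age_effect_is_out_of_support(self, tiny_params):
        q = tiny_params
        alpha = q.alpha.copy()
        alpha[0, AGE_K] = +0.1
        bad = ts.SamParams(alpha=alpha, mu_alpha=q.mu_alpha,
                           sigma_alpha=q.sigma_alpha, sigma_obs=q.sigma_obs,
                           weights_P=q.weights_P, weights_T=q.weights_T)
        assert ts.log_prior(bad) == -np.inf

    def test_sigma_above_uniform_upper_is_out_of_support(self, tiny_params):
        q = tiny_params
        bad = ts.SamParams(alpha=q.alpha, mu_alpha=q.mu_alpha,
                           sigma_alpha=q.sigma_alpha, sigma_obs=150.0,
                           weights_P=q.weights_P, weights_T=q.weights_T)
        assert ts.log_prior(bad) == -np.inf

    def test_permutation_equivariant_across_cores(self, tiny_params):
        p = tiny_params
        perm = np.random.default_rng(0).permutation(p.n_cores)
        q = ts.SamParams(alpha=p.alpha[perm], mu_alpha=p.mu_alpha,
                         sigma_alpha=p.sigma_alpha, sigma_obs=p.sigma_obs,
                         weights_P=p.weights_P, weights_T=p.weights_T)
        assert ts.log_prior(q) == pytest.approx(ts.log_prior(p), rel=1e-12)


class TestLogPosterior:
    def test_sum_of_components(self, tiny_design, tiny_params):
        lp = ts.log_posterior(tiny_params, tiny_design)
        assert np.isfinite(lp)
        assert lp == pytest.approx(
            ts.log_prior(tiny_params) + ts.log_likelihood(tiny_params, tiny_design))

    def test_out_of_support_propagates(self, tiny_design, tiny_params):
        p = tiny_params
        alpha = p.alpha.copy()
        alpha[:, AGE_K] = +0.5
        bad = ts.SamParams(alpha=alpha, mu_alpha=p.mu_alpha,
                           sigma_alpha=p.sigma_alpha, sigma_obs=p.sigma_obs,
                           weights_P=p.weights_P, weights_T=p.weights_T)
        assert ts.log_posterior(bad, tiny_design) == -np.inf
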