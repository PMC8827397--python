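"""The hierarchical growth model as an evaluable log-posterior.

Likelihood: log-scale ring width G_{t,c} ~ Normal(mu_{t,c}, sigma^2), with a
nine-term mean: intercept, age, antecedent precipitation (P_ant), antecedent
temperature (T_ant), P_ant x T_ant, prior-year growth (autoregressive),
harvesting intensity (HI), HI x P_ant, HI x T_ant.  Core-level coefficients
alpha_{k,c} are drawn from global Normal(mu_alpha_k, sigma_alpha_k^2)
distributions; the age effect alpha_{2,c} is truncated to (-inf, 0].
Hyperpriors are deliberately weak: Normal(0, 100^2) on the global means,
Uniform(0, 100) on every standard deviation, Dirichlet(1, ..., 1) on each
block-weight vector.

The antecedent covariates are recomputed from the current weight vectors and
centered by their sample means across modelled records at every evaluation;
interaction covariates are products of individually centered factors, so
main effects are interpretable at average conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, log_ndtr

from .antecedent import WeightScheme, WeightVector, default_scheme
from .preprocess import ModelDesign

N_COEF = 9
COEF_NAMES = (
    "intercept", "age", "p_ant", "t_ant", "p_x_t",
    "ar", "hi", "hi_x_p", "hi_x_t",
)
AGE_K = 1  # 0-based index of the truncated age coefficient
AR_K = 5   # 0-based index of the autoregressive coefficient

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorSpec:
    """Hyperprior constants (config-overridable)."""

    mu_alpha_sd: float = 100.0     # Normal(0, mu_alpha_sd^2) on global means
    sigma_upper: float = 100.0     # Uniform(0, sigma_upper) on all SDs
    dirichlet_conc: float = 1.0    # symmetric Dirichlet on block weights
    #: also truncate the age hyper-mean to (-inf, 0].  Without this the
    #: truncated hierarchy admits an exponential ridge (huge positive
    #: hyper-mean with matched hyper-SD) that dominates the posterior when
    #: the core-level age effects are concentrated near zero.
    truncate_hyper_mean: bool = True


@dataclass
class SamParams:
    """Full parameter state of the model."""

    alpha: np.ndarray        # (n_cores, 9)
    mu_alpha: np.ndarray     # (9,)
    sigma_alpha: np.ndarray  # (9,) > 0
    sigma_obs: float         # > 0
    weights_P: WeightVector
    weights_T: WeightVector

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        self.mu_alpha = np.asarray(self.mu_alpha, dtype=float)
        self.sigma_alpha = np.asarray(self.sigma_alpha, dtype=float)
        if self.alpha.shape[1] != N_COEF:
            raise ValueError(f"alpha must have {N_COEF} columns")
        if self.mu_alpha.shape != (N_COEF,) or self.sigma_alpha.shape != (N_COEF,):
            raise ValueError(f"mu_alpha and sigma_alpha must have length {N_COEF}")
        if np.any(self.sigma_alpha <= 0) or self.sigma_obs <= 0:
            raise ValueError("all standard deviations must be > 0")

    @property
    def n_cores(self) -> int:
        return self.alpha.shape[0]


def design_matrix(
    design: ModelDesign,
    weights_P: WeightVector,
    weights_T: WeightVector,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-record design matrix at the given weights.

    Returns ``(X, p_ant_years, t_ant_years)`` where X is (n_records, 9) with
    the antecedent covariates centered across records, and the year-level
    arrays hold the *uncentered* antecedent values per window year.
    """
    p_years = design.precip_windows @ weights_P.monthly
    t_years = design.temp_windows @ weights_T.monthly
    p = p_years[design.year_of_record]
    t = t_years[design.year_of_record]
    pc = p - p.mean()
    tc = t - t.mean()
    hi = design.hi_centered
    X = np.column_stack([
        np.ones(design.n_records),
        design.age_centered,
        pc,
        tc,
        pc * tc,
        design.G_prev_centered,
        hi,
        hi * pc,
        hi * tc,
    ])
    return X, p_years, t_years


def mean_growth(params: SamParams, design: ModelDesign, year: int, core_id: str) -> float:
    """Expected log-scale growth mu_{t,c} for one modelled record."""
    i = design.record(year, core_id)  # KeyError if unmodelled
    X, _, _ = design_matrix(design, params.weights_P, params.weights_T)
    c = design.cores.index(core_id)
    return float(X[i] @ params.alpha[c])


def log_likelihood(params: SamParams, design: ModelDesign) -> float:
    """Sum of normal log-densities of G over all modelled records."""
    if params.sigma_obs <= 0:
        raise ValueError("sigma_obs must be > 0")
    if params.n_cores != design.n_cores:
        raise ValueError("parameter state and design disagree on core count")
    X, _, _ = design_matrix(design, params.weights_P, params.weights_T)
    mu = np.einsum("ij,ij->i", X, params.alpha[design.core_index])
    resid = design.G - mu
    n = design.n_records
    s2 = params.sigma_obs ** 2
    return float(-0.5 * n * LOG_2PI - n * np.log(params.sigma_obs)
                 - 0.5 * np.sum(resid ** 2) / s2)


def _dirichlet_logpdf(w: np.ndarray, conc: float) -> float:
    """Symmetric Dirichlet log-density on the simplex; -inf off support."""
    w = np.asarray(w, dtype=float)
    k = w.size
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        return -np.inf
    const = gammaln(k * conc) - k * gammaln(conc)
    if conc == 1.0:
        return float(const)
    if np.any(w == 0):
        return -np.inf
    return float(const + (conc - 1.0) * np.sum(np.log(w)))


def log_prior(params: SamParams, prior: PriorSpec | None = None) -> float:
    """Log prior density; out-of-support states return -inf (not an error)."""
    prior = prior or PriorSpec()
    # support checks
    if (params.sigma_obs <= 0 or params.sigma_obs >= prior.sigma_upper
            or np.any(params.sigma_alpha <= 0)
            or np.any(params.sigma_alpha >= prior.sigma_upper)):
        return -np.inf
    if np.any(params.alpha[:, AGE_K] > 0):
        return -np.inf
    if prior.truncate_hyper_mean and params.mu_alpha[AGE_K] > 0:
        return -np.inf

    total = 0.0
    mu, sig = params.mu_alpha, params.sigma_alpha
    # core-level normals; the age coefficient is truncated to (-inf, 0]
    for k in range(N_COEF):
        z = (params.alpha[:, k] - mu[k]) / sig[k]
        total += float(np.sum(-0.5 * LOG_2PI - np.log(sig[k]) - 0.5 * z ** 2))
        if k == AGE_K:
            # renormalize by P(alpha <= 0) = Phi(-mu/sigma)
            total -= params.n_cores * float(log_ndtr(-mu[k] / sig[k]))
    # hyperpriors
    total += float(np.sum(-0.5 * LOG_2PI - np.log(prior.mu_alpha_sd)
                          - 0.5 * (mu / prior.mu_alpha_sd) ** 2))
    if prior.truncate_hyper_mean:
        total += float(np.log(2.0))  # half-normal renormalization for the age mean
    n_sd = N_COEF + 1
    total += -n_sd * np.log(prior.sigma_upper)
    total += _dirichlet_logpdf(params.weights_P.block_weights, prior.dirichlet_conc)
    total += _dirichlet_logpdf(params.weights_T.block_weights, prior.dirichlet_conc)
    return total


def log_posterior(
    params: SamParams, design: ModelDesign, prior: PriorSpec | None = None
) -> float:
    """log likelihood + log prior; -inf propagates from out-of-support states."""
    lp = log_prior(params, prior)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(params, design)
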