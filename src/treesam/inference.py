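"""Posterior sampling by adaptive Metropolis-within-Gibbs.

Protocol: several independent chains, a burn-in period, thinning of the
retained draws, and the Gelman-Rubin potential scale reduction factor as
the convergence diagnostic.

Update kernels per scan:

* block weights: collapsed Metropolis moves against a marginal likelihood
  in which the coefficients multiplying the proposed variable's antecedent
  (main effect, precipitation x temperature interaction, harvesting
  interaction) and their global means are integrated out analytically;
  the marginalized coefficients are redrawn from their exact joint
  Gaussian conditional afterwards (a valid partially collapsed Gibbs
  step).  Moves mix a stick-breaking coordinate sweep, pairwise mass
  transfers/swaps between random or echo-partner blocks (12 lags apart)
  and a whole-profile year exchange; step sizes adapt toward ~30%
  acceptance during burn-in, and for balanced designs the whole update
  runs in a compiled kernel;
* core-level coefficients: coordinate-wise conjugate normal draws, with
  the age coefficient drawn from its truncated-normal full conditional;
* global means: conjugate normal draws (the age hyper-mean uses a
  random-walk step because the truncated core-level densities carry a
  Phi(-mu/sigma) normalization);
* all standard deviations: random-walk Metropolis on the uniform support.

Chain starting weights are screened against a year-level regression (see
``_start_weights``); draws are bit-reproducible given seeds, and
adaptation runs only during burn-in so the post-burn-in kernel is a fixed
Markov transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_ndtr, logit, ndtr, ndtri

from .antecedent import WeightScheme, WeightVector, default_scheme
from .preprocess import ModelDesign
from .sam_model import (
    AGE_K,
    N_COEF,
    PriorSpec,
    SamParams,
    log_posterior,
)

__all__ = [
    "MCMCSettings",
    "ChainSet",
    "Diagnostics",
    "initialize",
    "run_mcmc",
    "gelman_rubin",
    "compute_diagnostics",
]


@dataclass
class MCMCSettings:
    """Chain protocol: total iterations include the burn-in period."""

    n_chains: int = 3
    n_iter: int = 40_000
    burn_in: int = 10_000
    thin: int = 10
    weight_sweeps: int = 1     # stick sweeps per scan and climate variable
    n_pair_moves: int = 34     # pairwise mass-transfer proposals per sweep
    target_accept: float = 0.3
    init_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("chain counts, iterations and thin must be positive")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn-in must be shorter than the total iterations")

    @property
    def n_retained(self) -> int:
        """Retained draws per chain after burn-in and thinning."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class Diagnostics:
    psrf: dict[str, float]
    ess: dict[str, float]
    threshold: float
    converged: bool


@dataclass
class ChainSet:
    """Retained post-burn-in, post-thinning draws from all chains.

    Arrays in ``draws`` have leading dimensions (n_chains, n_retained).
    """

    draws: dict[str, np.ndarray]
    seeds: list[int]
    settings: MCMCSettings
    scheme: WeightScheme
    core_ids: list[str]
    window_years: np.ndarray
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {v.shape[:2] for v in self.draws.values()}
        if len(lengths) > 1:
            raise ValueError("all monitored arrays must share (chain, draw) shape")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("per-chain seeds must be distinct")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_retained(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (n_chains * n_retained, ...)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def monitored_scalars(self) -> dict[str, np.ndarray]:
        """Scalar traces (chains, draws) for every monitored quantity."""
        out: dict[str, np.ndarray] = {}
        for k in range(N_COEF):
            out[f"mu_alpha[{k + 1}]"] = self.draws["mu_alpha"][:, :, k]
        out["sigma_obs"] = self.draws["sigma_obs"]
        for tag in ("wP", "wT"):
            key = f"{tag}_block"
            if key in self.draws:
                for b in range(self.draws[key].shape[2]):
                    out[f"{tag}[{b + 1}]"] = self.draws[key][:, :, b]
        for tag in ("ant_P", "ant_T"):
            if tag in self.draws:
                for j, year in enumerate(self.window_years):
                    out[f"{tag}[{int(year)}]"] = self.draws[tag][:, :, j]
        return out


# ---------------------------------------------------------------------------
# stick-breaking parameterization of the block-weight simplex
# ---------------------------------------------------------------------------

_Z_CLIP = 35.0


def _sticks_to_weights(z: np.ndarray) -> tuple[np.ndarray, float]:
    """Map stick logits (k-1,) to simplex weights (k,) and the log-Jacobian."""
    v = expit(z)
    one_minus = 1.0 - v
    s = np.concatenate(([1.0], np.cumprod(one_minus)))  # remaining mass
    w = np.empty(z.size + 1)
    w[:-1] = v * s[:-1]
    w[-1] = s[-1]
    with np.errstate(divide="ignore"):
        log_j = float(np.sum(np.log(v) + np.log(one_minus) + np.log(s[:-1])))
    return w, log_j


def _weights_to_sticks(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    remaining = 1.0 - np.concatenate(([0.0], np.cumsum(w[:-1])))
    v = np.clip(w[:-1] / np.maximum(remaining[:-1], 1e-300), 1e-12, 1 - 1e-12)
    return np.clip(logit(v), -_Z_CLIP, _Z_CLIP)


def _dirichlet_term(w: np.ndarray, conc: float) -> float:
    if conc == 1.0:
        return 0.0
    if np.any(w <= 0):
        return -np.inf
    return float((conc - 1.0) * np.sum(np.log(w)))


def _det3(m: np.ndarray) -> float:
    return (m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
            - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
            + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0]))


def _inv3(m: np.ndarray) -> np.ndarray:
    det = _det3(m)
    out = np.empty((3, 3))
    out[0, 0] = m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1]
    out[0, 1] = m[0, 2] * m[2, 1] - m[0, 1] * m[2, 2]
    out[0, 2] = m[0, 1] * m[1, 2] - m[0, 2] * m[1, 1]
    out[1, 0] = m[1, 2] * m[2, 0] - m[1, 0] * m[2, 2]
    out[1, 1] = m[0, 0] * m[2, 2] - m[0, 2] * m[2, 0]
    out[1, 2] = m[0, 2] * m[1, 0] - m[0, 0] * m[1, 2]
    out[2, 0] = m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0]
    out[2, 1] = m[0, 1] * m[2, 0] - m[0, 0] * m[2, 1]
    out[2, 2] = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    out /= det
    return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize(
    design: ModelDesign,
    seed: int | np.random.Generator = 0,
    prior: PriorSpec | None = None,
    scheme: WeightScheme | None = None,
) -> SamParams:
    """Draw an in-support starting state (deterministic given the seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme = scheme or default_scheme()
    mu = rng.normal(0.0, 0.3, size=N_COEF)
    mu[AGE_K] = -abs(rng.normal(0.0, 0.05))
    sigma_alpha = rng.uniform(0.05, 0.8, size=N_COEF)
    alpha = mu + sigma_alpha * rng.normal(size=(design.n_cores, N_COEF))
    alpha[:, AGE_K] = -np.abs(alpha[:, AGE_K])
    return SamParams(
        alpha=alpha,
        mu_alpha=mu,
        sigma_alpha=sigma_alpha,
        sigma_obs=float(rng.uniform(0.05, 1.5)),
        weights_P=WeightVector("precipitation", rng.dirichlet(np.ones(scheme.n_blocks)), scheme),
        weights_T=WeightVector("temperature", rng.dirichlet(np.ones(scheme.n_blocks)), scheme),
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(traces: np.ndarray) -> float:
    """Potential scale reduction factor of per-chain scalar traces (m, n).

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means.  Degenerate cases:
    W = B = 0 returns 1; W = 0 with B > 0 returns +inf; the value is floored
    at 1 (identical chains would otherwise give sqrt((n-1)/n) < 1).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2 or traces.shape[1] < 2:
        raise ValueError("need >= 2 chains of equal length >= 2")
    n = traces.shape[1]
    w = float(np.mean(np.var(traces, axis=1, ddof=1)))
    b = n * float(np.var(np.mean(traces, axis=1), ddof=1))
    if w == 0.0:
        return 1.0 if b == 0.0 else np.inf
    var_hat = (n - 1) / n * w + b / n
    return max(float(np.sqrt(var_hat / w)), 1.0)


def compute_diagnostics(chains: ChainSet, threshold: float = 1.1) -> Diagnostics:
    """PSRF and effective sample size for every monitored scalar."""
    import arviz as az

    scalars = chains.monitored_scalars()
    psrf = {name: gelman_rubin(tr) for name, tr in scalars.items()}
    ess = {}
    for name, tr in scalars.items():
        if np.allclose(tr, tr.reshape(-1)[0]):
            ess[name] = float(tr.size)  # constant trace: no autocorrelation info
        else:
            ess[name] = float(az.ess(tr))
    converged = all(v < threshold for v in psrf.values())
    return Diagnostics(psrf=psrf, ess=ess, threshold=threshold, converged=converged)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class _Adapt:
    """Robbins-Monro adaptation of log step sizes toward a target acceptance."""

    def __init__(self, shape, init_step: float, target: float):
        self.log_step = np.full(shape, np.log(init_step))
        self.target = target
        self.t = 0

    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def update(self, accepted, idx=None) -> None:
        self.t += 1
        gamma = min(0.25, 2.0 / np.sqrt(self.t))
        delta = gamma * (np.asarray(accepted, dtype=float) - self.target)
        if idx is None:
            self.log_step += delta
        else:
            self.log_step[idx] += delta
        np.clip(self.log_step, -12.0, 6.0, out=self.log_step)



# ---------------------------------------------------------------------------
# numba kernels for the balanced collapsed weight update
# ---------------------------------------------------------------------------
# All random numbers are pre-drawn by the caller (numba has no Generator
# support), and step-size adaptation is applied after the kernel returns,
# so runs stay bit-reproducible given seeds.

from numba import njit  # noqa: E402


@njit(cache=True)
def _nb_sticks(z, w):
    """Stick logits -> simplex weights; returns the log-Jacobian."""
    k = z.size
    log_j = 0.0
    s = 1.0
    for j in range(k):
        v = 1.0 / (1.0 + np.exp(-z[j]))
        w[j] = v * s
        log_j += np.log(v) + np.log(1.0 - v) + np.log(s)
        s *= 1.0 - v
    w[k] = s
    return log_j


@njit(cache=True)
def _nb_unsticks(w, z):
    remaining = 1.0
    for j in range(z.size):
        v = w[j] / remaining if remaining > 1e-300 else 1e-12
        if v < 1e-12:
            v = 1e-12
        if v > 1.0 - 1e-12:
            v = 1.0 - 1e-12
        zj = np.log(v / (1.0 - v))
        if zj > 35.0:
            zj = 35.0
        if zj < -35.0:
            zj = -35.0
        z[j] = zj
        remaining -= w[j]


@njit(cache=True)
def _nb_ant(clim_block, bw, year_counts, n, raw, centered):
    y_n, n_blocks = clim_block.shape
    mean = 0.0
    for y in range(y_n):
        acc = 0.0
        for b in range(n_blocks):
            acc += clim_block[y, b] * bw[b]
        raw[y] = acc
        mean += year_counts[y] * acc
    mean /= n
    for y in range(y_n):
        centered[y] = raw[y] - mean


@njit(cache=True)
def _nb_marg3(p, r0_m, o, h, c0, sm2, si2, sh2, s2, a_hyper, n,
              a_mat, k3, b_inv, v_out):
    """Rank-3 collapsed marginal log-likelihood (see the Python twin)."""
    n_cores, y_n = r0_m.shape
    g11 = g12 = g13 = g22 = g23 = g33 = 0.0
    for y in range(y_n):
        u1 = p[y]
        u2 = u1 * o[y]
        u3 = u1 * h[y]
        g11 += u1 * u1
        g12 += u1 * u2
        g13 += u1 * u3
        g22 += u2 * u2
        g23 += u2 * u3
        g33 += u3 * u3
    for c in range(n_cores):
        a1 = a2 = a3 = 0.0
        for y in range(y_n):
            r = r0_m[c, y]
            u1 = p[y]
            a1 += r * u1
            a2 += r * u1 * o[y]
            a3 += r * u1 * h[y]
        a_mat[c, 0] = a1
        a_mat[c, 1] = a2
        a_mat[c, 2] = a3
    # P3 = S^-1 + G/s2 ; K = inv(P3)
    p11 = 1.0 / sm2 + g11 / s2
    p12 = g12 / s2
    p13 = g13 / s2
    p22 = 1.0 / si2 + g22 / s2
    p23 = g23 / s2
    p33 = 1.0 / sh2 + g33 / s2
    det_p = (p11 * (p22 * p33 - p23 * p23) - p12 * (p12 * p33 - p23 * p13)
             + p13 * (p12 * p23 - p22 * p13))
    k3[0, 0] = (p22 * p33 - p23 * p23) / det_p
    k3[0, 1] = (p13 * p23 - p12 * p33) / det_p
    k3[0, 2] = (p12 * p23 - p13 * p22) / det_p
    k3[1, 0] = k3[0, 1]
    k3[1, 1] = (p11 * p33 - p13 * p13) / det_p
    k3[1, 2] = (p12 * p13 - p11 * p23) / det_p
    k3[2, 0] = k3[0, 2]
    k3[2, 1] = k3[1, 2]
    k3[2, 2] = (p11 * p22 - p12 * p12) / det_p
    q = 0.0
    sa1 = sa2 = sa3 = 0.0
    for c in range(n_cores):
        a1 = a_mat[c, 0]
        a2 = a_mat[c, 1]
        a3 = a_mat[c, 2]
        sa1 += a1
        sa2 += a2
        sa3 += a3
        q += (a1 * (k3[0, 0] * a1 + k3[0, 1] * a2 + k3[0, 2] * a3)
              + a2 * (k3[1, 0] * a1 + k3[1, 1] * a2 + k3[1, 2] * a3)
              + a3 * (k3[2, 0] * a1 + k3[2, 1] * a2 + k3[2, 2] * a3))
    s4 = s2 * s2
    r_m_r = c0 / s2 - q / s4
    # gk = G @ K ; v = sA/s2 - gk sA /s4 ; xmx = C (G/s2 - gk G /s4)
    gk11 = g11 * k3[0, 0] + g12 * k3[1, 0] + g13 * k3[2, 0]
    gk12 = g11 * k3[0, 1] + g12 * k3[1, 1] + g13 * k3[2, 1]
    gk13 = g11 * k3[0, 2] + g12 * k3[1, 2] + g13 * k3[2, 2]
    gk21 = g12 * k3[0, 0] + g22 * k3[1, 0] + g23 * k3[2, 0]
    gk22 = g12 * k3[0, 1] + g22 * k3[1, 1] + g23 * k3[2, 1]
    gk23 = g12 * k3[0, 2] + g22 * k3[1, 2] + g23 * k3[2, 2]
    gk31 = g13 * k3[0, 0] + g23 * k3[1, 0] + g33 * k3[2, 0]
    gk32 = g13 * k3[0, 1] + g23 * k3[1, 1] + g33 * k3[2, 1]
    gk33 = g13 * k3[0, 2] + g23 * k3[1, 2] + g33 * k3[2, 2]
    v1 = sa1 / s2 - (gk11 * sa1 + gk12 * sa2 + gk13 * sa3) / s4
    v2 = sa2 / s2 - (gk21 * sa1 + gk22 * sa2 + gk23 * sa3) / s4
    v3 = sa3 / s2 - (gk31 * sa1 + gk32 * sa2 + gk33 * sa3) / s4
    x11 = n_cores * (g11 / s2 - (gk11 * g11 + gk12 * g12 + gk13 * g13) / s4)
    x12 = n_cores * (g12 / s2 - (gk11 * g12 + gk12 * g22 + gk13 * g23) / s4)
    x13 = n_cores * (g13 / s2 - (gk11 * g13 + gk12 * g23 + gk13 * g33) / s4)
    x22 = n_cores * (g22 / s2 - (gk21 * g12 + gk22 * g22 + gk23 * g23) / s4)
    x23 = n_cores * (g23 / s2 - (gk21 * g13 + gk22 * g23 + gk23 * g33) / s4)
    x33 = n_cores * (g33 / s2 - (gk31 * g13 + gk32 * g23 + gk33 * g33) / s4)
    b11 = 1.0 / a_hyper + x11
    b12 = x12
    b13 = x13
    b22 = 1.0 / a_hyper + x22
    b23 = x23
    b33 = 1.0 / a_hyper + x33
    det_b = (b11 * (b22 * b33 - b23 * b23) - b12 * (b12 * b33 - b23 * b13)
             + b13 * (b12 * b23 - b22 * b13))
    b_inv[0, 0] = (b22 * b33 - b23 * b23) / det_b
    b_inv[0, 1] = (b13 * b23 - b12 * b33) / det_b
    b_inv[0, 2] = (b12 * b23 - b13 * b22) / det_b
    b_inv[1, 0] = b_inv[0, 1]
    b_inv[1, 1] = (b11 * b33 - b13 * b13) / det_b
    b_inv[1, 2] = (b12 * b13 - b11 * b23) / det_b
    b_inv[2, 0] = b_inv[0, 2]
    b_inv[2, 1] = b_inv[1, 2]
    b_inv[2, 2] = (b11 * b22 - b12 * b12) / det_b
    quad = r_m_r - (v1 * (b_inv[0, 0] * v1 + b_inv[0, 1] * v2 + b_inv[0, 2] * v3)
                    + v2 * (b_inv[1, 0] * v1 + b_inv[1, 1] * v2 + b_inv[1, 2] * v3)
                    + v3 * (b_inv[2, 0] * v1 + b_inv[2, 1] * v2 + b_inv[2, 2] * v3))
    det_vc = ((1.0 + sm2 * g11 / s2) * ((1.0 + si2 * g22 / s2) * (1.0 + sh2 * g33 / s2)
                                        - si2 * g23 / s2 * sh2 * g23 / s2)
              - sm2 * g12 / s2 * (si2 * g12 / s2 * (1.0 + sh2 * g33 / s2)
                                  - si2 * g23 / s2 * sh2 * g13 / s2)
              + sm2 * g13 / s2 * (si2 * g12 / s2 * sh2 * g23 / s2
                                  - (1.0 + si2 * g22 / s2) * sh2 * g13 / s2))
    logdet = (n * np.log(s2) + n_cores * np.log(det_vc)
              + np.log(det_b) + 3.0 * np.log(a_hyper))
    v_out[0] = v1
    v_out[1] = v2
    v_out[2] = v3
    return -0.5 * (logdet + quad)


@njit(cache=True)
def _nb_weight_update(bw, clim_block, year_counts, n, r0_m, o, h, c0,
                      sm2, si2, sh2, s2, a_hyper,
                      steps_z, eps_z, lunif_z,
                      pair_i, pair_j, full_swap, pair_step, deltas, lunif_pair,
                      do_year_swap, lunif_swap, swap_a, swap_b,
                      acc_z, acc_pair,
                      raw, centered, a_mat, k3, b_inv, v_out):
    """Full weight update for one variable: stick sweep + pair moves +
    year-profile exchange, against the rank-3 collapsed marginal.

    Fills ``raw``/``centered`` (year-level antecedent), the collapsed
    sufficient statistics for the coefficient redraw, and the acceptance
    flags used for step adaptation.  Returns the updated block weights.
    """
    n_blocks = bw.size
    z = np.empty(n_blocks - 1)
    _nb_unsticks(bw, z)
    w_cur = np.empty(n_blocks)
    log_j = _nb_sticks(z, w_cur)
    _nb_ant(clim_block, w_cur, year_counts, n, raw, centered)
    ll = _nb_marg3(centered, r0_m, o, h, c0, sm2, si2, sh2, s2, a_hyper, n,
                   a_mat, k3, b_inv, v_out)
    logp = ll + log_j

    w_prop = np.empty(n_blocks)
    raw_p = np.empty_like(raw)
    cen_p = np.empty_like(centered)
    a_p = np.empty_like(a_mat)
    k_p = np.empty_like(k3)
    b_p = np.empty_like(b_inv)
    v_p = np.empty_like(v_out)

    # --- stick-breaking coordinate sweep ---
    for j in range(z.size):
        zj_old = z[j]
        zj_new = zj_old + steps_z[j] * eps_z[j]
        if zj_new > 35.0:
            zj_new = 35.0
        if zj_new < -35.0:
            zj_new = -35.0
        z[j] = zj_new
        log_j_prop = _nb_sticks(z, w_prop)
        _nb_ant(clim_block, w_prop, year_counts, n, raw_p, cen_p)
        ll_prop = _nb_marg3(cen_p, r0_m, o, h, c0, sm2, si2, sh2, s2,
                            a_hyper, n, a_p, k_p, b_p, v_p)
        if lunif_z[j] < ll_prop + log_j_prop - logp:
            logp = ll_prop + log_j_prop
            ll = ll_prop
            for b in range(n_blocks):
                w_cur[b] = w_prop[b]
            for y in range(raw.size):
                raw[y] = raw_p[y]
                centered[y] = cen_p[y]
            a_mat[:, :] = a_p
            k3[:, :] = k_p
            b_inv[:, :] = b_p
            v_out[:] = v_p
            acc_z[j] = 1
        else:
            z[j] = zj_old
            acc_z[j] = 0

    # --- pairwise transfers / swaps (target in w-space; flat prior) ---
    logp_w = ll
    for m in range(pair_i.size):
        i = pair_i[m]
        j = pair_j[m]
        if i == j:
            acc_pair[m] = -1
            continue
        for b in range(n_blocks):
            w_prop[b] = w_cur[b]
        if full_swap[m] == 1:
            w_prop[i] = w_cur[j]
            w_prop[j] = w_cur[i]
        else:
            delta = pair_step[m] * deltas[m]
            wi = w_cur[i] - delta
            wj = w_cur[j] + delta
            if wi <= 0.0 or wj <= 0.0:
                acc_pair[m] = 0
                continue
            w_prop[i] = wi
            w_prop[j] = wj
        _nb_ant(clim_block, w_prop, year_counts, n, raw_p, cen_p)
        ll_prop = _nb_marg3(cen_p, r0_m, o, h, c0, sm2, si2, sh2, s2,
                            a_hyper, n, a_p, k_p, b_p, v_p)
        if lunif_pair[m] < ll_prop - logp_w:
            logp_w = ll_prop
            for b in range(n_blocks):
                w_cur[b] = w_prop[b]
            for y in range(raw.size):
                raw[y] = raw_p[y]
                centered[y] = cen_p[y]
            a_mat[:, :] = a_p
            k3[:, :] = k_p
            b_inv[:, :] = b_p
            v_out[:] = v_p
            acc_pair[m] = 1
        else:
            acc_pair[m] = 0

    # --- whole-profile year exchange ---
    if do_year_swap == 1 and swap_a.size > 0:
        for b in range(n_blocks):
            w_prop[b] = w_cur[b]
        for m in range(swap_a.size):
            w_prop[swap_a[m]] = w_cur[swap_b[m]]
            w_prop[swap_b[m]] = w_cur[swap_a[m]]
        _nb_ant(clim_block, w_prop, year_counts, n, raw_p, cen_p)
        ll_prop = _nb_marg3(cen_p, r0_m, o, h, c0, sm2, si2, sh2, s2,
                            a_hyper, n, a_p, k_p, b_p, v_p)
        if lunif_swap < ll_prop - logp_w:
            for b in range(n_blocks):
                w_cur[b] = w_prop[b]
            for y in range(raw.size):
                raw[y] = raw_p[y]
                centered[y] = cen_p[y]
            a_mat[:, :] = a_p
            k3[:, :] = k_p
            b_inv[:, :] = b_p
            v_out[:] = v_p
    return w_cur


def _start_weights(
    clim_block_p: np.ndarray,
    clim_block_t: np.ndarray,
    g_year: np.ndarray,
    hi_year: np.ndarray,
    year_w: np.ndarray,
    rng: np.random.Generator,
    n_random: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Choose chain starting weights by screening candidate configurations.

    Candidates per variable: uniform, the positively and negatively
    correlated screening profiles (correlation of the year-mean growth
    anomaly with each block's climate series), and a few Dirichlet draws
    specific to this chain.  Every (P, T) candidate pair is scored by the
    residual sum of squares of a year-level regression of growth anomalies
    on the implied antecedent covariates and their interactions; the best
    pair starts the chain.  This places chains in the basin the likelihood
    favours -- the posterior over weight configurations is strongly
    multimodal, and unscreened starts can strand a chain in a mode hundreds
    of log-units below the dominant one.
    """
    n_blocks = clim_block_p.shape[1]
    y = g_year - np.average(g_year, weights=year_w)

    def screen(clim_block):
        cb = clim_block - clim_block.mean(axis=0)
        sd = cb.std(axis=0)
        ysd = y.std() or 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(sd > 0, (cb * y[:, None]).mean(axis=0) / (sd * ysd), 0.0)
        out = []
        for sign in (1.0, -1.0):
            w = np.maximum(sign * rho, 0.0) + 0.1 / n_blocks
            out.append(w / w.sum())
        return out

    def candidates(clim_block):
        cands = [np.full(n_blocks, 1.0 / n_blocks)]
        cands += screen(clim_block)
        cands += [rng.dirichlet(np.ones(n_blocks)) for _ in range(n_random)]
        return cands

    def centered(clim_block, w):
        series = clim_block @ w
        return series - np.average(series, weights=year_w)

    best = None
    cands_p = candidates(clim_block_p)
    cands_t = candidates(clim_block_t)
    ones = np.ones_like(y)
    for wp in cands_p:
        pc = centered(clim_block_p, wp)
        for wt in cands_t:
            tc = centered(clim_block_t, wt)
            x = np.column_stack([ones, pc, tc, pc * tc, hi_year,
                                 pc * hi_year, tc * hi_year])
            _, rss, _, _ = np.linalg.lstsq(x, y, rcond=None)
            score = float(rss[0]) if rss.size else float(
                np.sum((y - x @ np.linalg.lstsq(x, y, rcond=None)[0]) ** 2))
            if best is None or score < best[0]:
                best = (score, wp, wt)
    return best[1].copy(), best[2].copy()


def _truncated_normal_below_zero(
    mean: np.ndarray, sd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw from Normal(mean, sd^2) truncated to (-inf, 0]."""
    p0 = np.maximum(ndtr(-mean / sd), 1e-300)
    u = rng.uniform(size=np.shape(mean))
    return mean + sd * ndtri(np.clip(u * p0, 1e-300, 1.0))


def run_mcmc(
    design: ModelDesign,
    settings: MCMCSettings | None = None,
    seed: int = 0,
    seeds: list[int] | None = None,
    prior: PriorSpec | None = None,
    scheme: WeightScheme | None = None,
    likelihood: bool = True,
    fix_weights: tuple[WeightVector, WeightVector] | None = None,
    fix_sigma_obs: float | None = None,
    fix_sigma_alpha: np.ndarray | None = None,
    store_alpha: bool = True,
    store_antecedent: bool = True,
) -> ChainSet:
    """Sample the posterior (or, with ``likelihood=False``, the prior).

    ``fix_weights`` / ``fix_sigma_obs`` / ``fix_sigma_alpha`` pin parameters
    for validation sub-models (conjugate-limit checks); pinned parameters
    are never updated and are stored at their fixed values.
    """
    settings = settings or MCMCSettings()
    prior = prior or PriorSpec()
    scheme = scheme or default_scheme()
    if seeds is None:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s) for s in ss.generate_state(settings.n_chains)]
    if len(seeds) != settings.n_chains:
        raise ValueError("need one seed per chain")

    n = design.n_records
    n_cores = design.n_cores
    ci = design.core_index
    yi = design.year_of_record
    n_years = design.window_years.size
    year_counts = np.bincount(yi, minlength=n_years).astype(float)
    n_blocks = scheme.n_blocks
    monthly_map = scheme.monthly_map
    clim_block_p = design.precip_windows @ monthly_map  # (n_years, n_blocks)
    clim_block_t = design.temp_windows @ monthly_map
    # echo partner: the block holding the same calendar months one year
    # further into the past (or one year closer, for the oldest blocks)
    first_lag = np.array([min(b) for b in scheme.blocks])
    sizes = scheme.block_sizes
    echo_partner = np.empty(n_blocks, dtype=int)
    for b, lag in enumerate(first_lag):
        target = lag + 12 if lag + 12 <= 60 else lag - 12
        echo_partner[b] = int(np.argmin(np.abs(first_lag - target)))
    # disjoint block pairs exactly one year apart with equal span: used for
    # whole-profile year-exchange proposals (a symmetric involution)
    lag_index = {(int(lag), int(s)): b for b, (lag, s) in enumerate(zip(first_lag, sizes))}
    year_swap = [
        (b, lag_index[(int(lag) + 12, int(s))])
        for b, (lag, s) in enumerate(zip(first_lag, sizes))
        if (int(lag) + 12, int(s)) in lag_index
    ]
    age = design.age_centered
    gprev = design.G_prev_centered
    hi = design.hi_centered
    G = design.G
    hi_years_init = np.bincount(yi, hi, minlength=n_years) / year_counts
    # balanced design (every core covers every window year once) admits a
    # much faster collapsed-likelihood evaluation via (core, year) matrices
    balanced = (n == n_cores * n_years and
                np.all(np.bincount(ci * n_years + yi, minlength=n) == 1))


    draws: dict[str, list] = {
        "mu_alpha": [], "sigma_alpha": [], "sigma_obs": [],
        "wP_block": [], "wT_block": [],
    }
    if store_alpha:
        draws["alpha"] = []
    if store_antecedent:
        draws["ant_P"] = []
        draws["ant_T"] = []
    acc_counts = {"weights": 0, "weights_total": 0}

    for chain_idx, chain_seed in enumerate(seeds):
        rng = np.random.default_rng(chain_seed)

        # ---- initialization (retry on non-finite log-posterior) ----
        state = None
        for _ in range(settings.init_retries):
            cand = initialize(design, rng, prior, scheme)
            if fix_weights is not None:
                cand.weights_P, cand.weights_T = fix_weights
            if fix_sigma_obs is not None:
                cand.sigma_obs = float(fix_sigma_obs)
            if fix_sigma_alpha is not None:
                cand.sigma_alpha = np.asarray(fix_sigma_alpha, dtype=float)
            lp = log_posterior(cand, design, prior) if likelihood else 0.0
            if np.isfinite(lp):
                state = cand
                break
        if state is None:
            raise RuntimeError("could not find a finite-posterior starting state")

        alpha = state.alpha.copy()
        mu = state.mu_alpha.copy()
        sig_a = state.sigma_alpha.copy()
        sig = state.sigma_obs
        bw_p = state.weights_P.block_weights.copy()
        bw_t = state.weights_T.block_weights.copy()
        if likelihood and fix_weights is None:
            g_year = np.bincount(yi, G, minlength=n_years) / year_counts
            bw_p, bw_t = _start_weights(
                clim_block_p, clim_block_t, g_year, hi_years_init,
                year_counts, rng)
        if likelihood and fix_sigma_obs is None:
            # scale the initial observation SD to the data so the first
            # scans do not behave like a tempered (flattened) likelihood
            sig = float(np.std(G)) * rng.uniform(0.5, 1.0)

        def ant_years(clim_block: np.ndarray, bw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            """Uncentered year-level antecedent values and the record-mean-centered ones."""
            a_years = clim_block @ bw
            mean = float(year_counts @ a_years) / n
            return a_years, a_years - mean

        ant_p_raw, pc_years = ant_years(clim_block_p, bw_p)
        ant_t_raw, tc_years = ant_years(clim_block_t, bw_t)
        pc = pc_years[yi]
        tc = tc_years[yi]

        adapt_zp = _Adapt(n_blocks - 1, 0.4, settings.target_accept)
        adapt_zt = _Adapt(n_blocks - 1, 0.4, settings.target_accept)
        adapt_pair_p = _Adapt((), 0.05, settings.target_accept)
        adapt_pair_t = _Adapt((), 0.05, settings.target_accept)
        adapt_mu2 = _Adapt((), 0.1, settings.target_accept)
        adapt_sa = _Adapt(N_COEF, 0.3, settings.target_accept)
        adapt_so = _Adapt((), 0.2, settings.target_accept)

        conc = prior.dirichlet_conc
        hyper_var = prior.mu_alpha_sd ** 2
        upper = prior.sigma_upper

        hi_years = np.bincount(yi, hi, minlength=n_years) / year_counts

        def weight_sweep(bw, clim_block, r0, other_years, k_main, k_hi,
                         adapt_z, adapt_pair, adapting, beta=1.0):
            """One collapsed weight update for one climate variable.

            The coefficients multiplying this variable's centered antecedent
            x -- its main effect and the precipitation x temperature
            interaction, together with their global means -- are integrated
            out analytically, so the chain can move the lag structure even
            from states where the current coefficient draws carry no signal
            (and independently of the interaction draws, which otherwise
            lock joint weight configurations).  The harvesting interaction
            stays conditioned via the per-core loading ``dc`` (its covariate
            is sparse).  For balanced designs all covariates entering the
            collapse are year-level, which reduces every proposal to a pair
            of (cores x years) mat-vecs and shared 2x2 algebra; unbalanced
            designs fall back to a rank-1 collapse of the main effect only.

            Moves: a stick-breaking coordinate sweep (global), pairwise mass
            transfers/swaps between random or echo-partner blocks, and a
            whole-profile year exchange.
            """
            s2 = sig * sig
            s4 = s2 * s2
            a_hyper = hyper_var  # prior variance of the global means
            s_m2 = sig_a[k_main] ** 2

            if balanced:
                s_pr = np.array([s_m2, sig_a[4] ** 2, sig_a[k_hi] ** 2])
                r0_m = np.zeros((n_cores, n_years))
                r0_m[ci, yi] = r0
                o = other_years
                h = hi_years
                c0 = float((r0_m * r0_m).sum())
                eye3 = np.eye(3)
                s_inv = np.diag(1.0 / s_pr)

                def marg_ll(p):
                    uy = np.column_stack([p, p * o, p * h])
                    a_mat = r0_m @ uy                     # (cores, 3)
                    g3 = uy.T @ uy
                    p3 = s_inv + g3 / s2
                    k3 = _inv3(p3)
                    q = float(((a_mat @ k3) * a_mat).sum())
                    r_m_r = c0 / s2 - q / s4
                    s_a = a_mat.sum(axis=0)
                    gk = g3 @ k3
                    v = s_a / s2 - (gk @ s_a) / s4
                    xmx = n_cores * (g3 / s2 - (gk @ g3) / s4)
                    b3 = eye3 / a_hyper + xmx
                    b_inv = _inv3(b3)
                    quad = r_m_r - float(v @ b_inv @ v)
                    ld_vc = np.log(_det3(eye3 + (s_pr[:, None] * g3) / s2))
                    ld_b = np.log(_det3(b3))
                    logdet = (n * np.log(s2) + n_cores * ld_vc
                              + ld_b + 3.0 * np.log(a_hyper))
                    return -0.5 * (logdet + quad), (a_mat, k3, b_inv, v)

            else:
                d_rec = alpha[ci, k_hi] * hi + alpha[ci, 4] * other_years[yi]

                def marg_ll(p):
                    pr = p[yi]
                    r = r0 - pr * d_rec
                    a_c = np.bincount(ci, pr * r, minlength=n_cores)
                    b_c = np.bincount(ci, pr * pr, minlength=n_cores)
                    denom = s2 + s_m2 * b_c
                    quad = (float(r @ r)
                            - s_m2 * float(np.sum(a_c * a_c / denom))) / s2
                    p_m_r = float(np.sum(a_c / denom))
                    p_m_p = float(np.sum(b_c / denom))
                    shared = 1.0 + a_hyper * p_m_p
                    quad -= a_hyper * p_m_r * p_m_r / shared
                    logdet = (float(np.sum(np.log(denom))) + np.log(shared)
                              + (n - n_cores) * np.log(s2))
                    return -0.5 * (logdet + quad), (a_c, b_c)

            n_acc = 0
            n_tot = 0

            # --- stick-breaking coordinate sweep (target expressed in z) ---
            z = _weights_to_sticks(bw)
            w_cur, log_j = _sticks_to_weights(z)
            raw, centered = ant_years(clim_block, w_cur)
            ll, aux = marg_ll(centered) if likelihood else (0.0, None)
            logp = beta * ll + _dirichlet_term(w_cur, conc) + log_j
            steps = adapt_z.step()
            eps = rng.normal(size=z.size)
            unif = np.log(rng.uniform(size=z.size))
            accepted = np.zeros(z.size, dtype=bool)
            for j in range(z.size):
                z_prop = z.copy()
                z_prop[j] = np.clip(z[j] + steps[j] * eps[j], -_Z_CLIP, _Z_CLIP)
                w_prop, log_j_prop = _sticks_to_weights(z_prop)
                raw_prop, centered_prop = ant_years(clim_block, w_prop)
                if likelihood:
                    ll_prop, aux_prop = marg_ll(centered_prop)
                else:
                    ll_prop, aux_prop = 0.0, None
                logp_prop = beta * ll_prop + _dirichlet_term(w_prop, conc) + log_j_prop
                if unif[j] < logp_prop - logp:
                    z = z_prop
                    logp = logp_prop
                    raw, centered = raw_prop, centered_prop
                    aux = aux_prop
                    accepted[j] = True
            if adapting:
                adapt_z.update(accepted)
            n_acc += int(accepted.sum())
            n_tot += accepted.size
            bw = _sticks_to_weights(z)[0]

            # --- pairwise mass moves (target expressed in w) ---
            # Pairs are random or "echo partners" (blocks 12 lags apart):
            # because consecutive years' windows overlap, a weight profile
            # shifted by one year plus a stronger autoregressive term can
            # mimic the true signal, and echo swaps hop between such modes.
            n_pair = settings.n_pair_moves
            if n_pair > 0:
                if likelihood:
                    ll, aux = marg_ll(centered)
                else:
                    ll = 0.0
                logp_w = beta * ll + _dirichlet_term(bw, conc)
                pair_i = rng.integers(0, n_blocks, size=n_pair)
                use_echo = rng.uniform(size=n_pair) < 0.5
                pair_j = np.where(
                    use_echo,
                    echo_partner[pair_i],
                    (pair_i + rng.integers(1, n_blocks, size=n_pair)) % n_blocks,
                )
                full_swap = rng.uniform(size=n_pair) < 0.25
                deltas = rng.normal(size=n_pair)
                unif = np.log(rng.uniform(size=n_pair))
                pair_acc = 0
                for m in range(n_pair):
                    i, j = int(pair_i[m]), int(pair_j[m])
                    if i == j:
                        continue
                    w_prop = bw.copy()
                    if full_swap[m]:
                        w_prop[i], w_prop[j] = bw[j], bw[i]  # symmetric exchange
                    else:
                        delta = float(adapt_pair.step()) * deltas[m]
                        wi, wj = bw[i] - delta, bw[j] + delta
                        if wi <= 0 or wj <= 0:
                            if adapting:
                                adapt_pair.update(False)
                            continue
                        w_prop[i], w_prop[j] = wi, wj
                    raw_prop, centered_prop = ant_years(clim_block, w_prop)
                    if likelihood:
                        ll_prop, aux_prop = marg_ll(centered_prop)
                    else:
                        ll_prop, aux_prop = 0.0, None
                    logp_prop = beta * ll_prop + _dirichlet_term(w_prop, conc)
                    acc = unif[m] < logp_prop - logp_w
                    if acc:
                        bw = w_prop
                        logp_w = logp_prop
                        raw, centered = raw_prop, centered_prop
                        aux = aux_prop
                    if adapting and not full_swap[m]:
                        adapt_pair.update(acc)
                    pair_acc += acc
                n_acc += pair_acc
                n_tot += n_pair

                # whole-profile year exchange: swaps this year's and the
                # prior year's month weights (jumps between echo modes)
                if year_swap and rng.uniform() < 0.5:
                    w_prop = bw.copy()
                    for i, j in year_swap:
                        w_prop[i], w_prop[j] = bw[j], bw[i]
                    raw_prop, centered_prop = ant_years(clim_block, w_prop)
                    if likelihood:
                        ll_prop, aux_prop = marg_ll(centered_prop)
                    else:
                        ll_prop, aux_prop = 0.0, None
                    logp_prop = beta * ll_prop + _dirichlet_term(w_prop, conc)
                    if np.log(rng.uniform()) < logp_prop - logp_w:
                        bw = w_prop
                        raw, centered = raw_prop, centered_prop
                        aux = aux_prop
            return bw, raw, centered, aux, n_acc, n_tot

        def redraw_rank3(k_main, k_hi, aux):
            """Exact joint redraw of the coefficients a rank-3 collapse removed.

            Global means (core deviations still marginalized) first, then
            the per-core triples given the fresh means; all conditionals are
            Gaussian with shared 3x3 precision.
            """
            cols = [k_main, 4, k_hi]
            if aux is None:  # prior-only run: no data terms
                for k in cols:
                    mu[k] = rng.normal(0.0, np.sqrt(hyper_var))
                    alpha[:, k] = mu[k] + sig_a[k] * rng.normal(size=n_cores)
                return
            a_mat, k3, b_inv, v = aux
            s2 = sig * sig
            mean_mu = b_inv @ v
            l_b = np.linalg.cholesky(b_inv)
            mu_draw = mean_mu + l_b @ rng.normal(size=3)
            for i, k in enumerate(cols):
                mu[k] = mu_draw[i]
            s_inv_mu = mu_draw / sig_a[cols] ** 2
            t_mat = a_mat / s2 + s_inv_mu[None, :]
            mean_c = t_mat @ k3.T
            l_k = np.linalg.cholesky(k3)
            draw = mean_c + rng.normal(size=(n_cores, 3)) @ l_k.T
            for i, k in enumerate(cols):
                alpha[:, k] = draw[:, i]

        def redraw_rank1(k_main, aux):
            """Redraw for the unbalanced fallback (main effect only)."""
            if aux is None:
                mu[k_main] = rng.normal(0.0, np.sqrt(hyper_var))
                alpha[:, k_main] = mu[k_main] + sig_a[k_main] * rng.normal(size=n_cores)
                return
            a_c, b_c = aux
            s3sq = sig_a[k_main] ** 2
            s2 = sig * sig
            denom = s2 + s3sq * b_c
            prec_mu = 1.0 / hyper_var + float(np.sum(b_c / denom))
            mean_mu = float(np.sum(a_c / denom)) / prec_mu
            mu[k_main] = mean_mu + rng.normal() / np.sqrt(prec_mu)
            prec = b_c / s2 + 1.0 / s3sq
            mean_c = (a_c / s2 + mu[k_main] / s3sq) / prec
            alpha[:, k_main] = mean_c + rng.normal(size=n_cores) / np.sqrt(prec)



        n_scans = settings.n_iter
        ch_draws = {k: [] for k in draws}

        swap_a = np.array([a for a, _ in year_swap], dtype=np.int64)
        swap_b = np.array([b for _, b in year_swap], dtype=np.int64)

        def do_weight_update(bw, clim_block, r0, other_years, k_main, k_hi,
                             adapt_z, adapt_pair, adapting):
            """Dispatch: compiled kernel for balanced designs with the flat
            Dirichlet prior, Python fallback otherwise."""
            if not (balanced and likelihood and conc == 1.0):
                return weight_sweep(bw, clim_block, r0, other_years, k_main,
                                    k_hi, adapt_z, adapt_pair, adapting, beta)
            r0_m = np.zeros((n_cores, n_years))
            r0_m[ci, yi] = r0
            c0 = float((r0_m * r0_m).sum())
            n_pair = settings.n_pair_moves
            eps_z = rng.normal(size=n_blocks - 1)
            lunif_z = np.log(rng.uniform(size=n_blocks - 1))
            pair_i = rng.integers(0, n_blocks, size=n_pair)
            use_echo = rng.uniform(size=n_pair) < 0.5
            pair_j = np.where(
                use_echo, echo_partner[pair_i],
                (pair_i + rng.integers(1, n_blocks, size=n_pair)) % n_blocks)
            full_swap = (rng.uniform(size=n_pair) < 0.25).astype(np.int8)
            deltas = rng.normal(size=n_pair)
            lunif_pair = np.log(rng.uniform(size=n_pair))
            pair_step = np.full(n_pair, float(adapt_pair.step()))
            do_swap = 1 if (swap_a.size and rng.uniform() < 0.5) else 0
            lunif_swap = float(np.log(rng.uniform()))
            acc_z = np.zeros(n_blocks - 1, dtype=np.int8)
            acc_pair = np.zeros(max(n_pair, 1), dtype=np.int8)
            raw = np.empty(n_years)
            centered = np.empty(n_years)
            a_mat = np.empty((n_cores, 3))
            k3 = np.empty((3, 3))
            b_inv = np.empty((3, 3))
            v = np.empty(3)
            bw_new = _nb_weight_update(
                bw, clim_block, year_counts, float(n), r0_m, other_years,
                hi_years, c0,
                sig_a[k_main] ** 2, sig_a[4] ** 2, sig_a[k_hi] ** 2,
                sig * sig, hyper_var,
                adapt_z.step(), eps_z, lunif_z,
                pair_i.astype(np.int64), pair_j.astype(np.int64),
                full_swap, pair_step, deltas, lunif_pair,
                do_swap, lunif_swap, swap_a, swap_b,
                acc_z, acc_pair,
                raw, centered, a_mat, k3, b_inv, v)
            if adapting:
                adapt_z.update(acc_z.astype(float))
                for m in range(n_pair):
                    if acc_pair[m] >= 0 and not full_swap[m]:
                        adapt_pair.update(bool(acc_pair[m]))
            n_acc = int(acc_z.sum()) + int((acc_pair[:n_pair] == 1).sum())
            n_tot = (n_blocks - 1) + n_pair
            return bw_new, raw, centered, (a_mat, k3, b_inv, v), n_acc, n_tot

        beta = 1.0
        for scan in range(1, n_scans + 1):
            adapting = settings.burn_in > 0 and scan <= settings.burn_in

            # ---- block weights (collapsed over this variable's coefficients) ----
            # held for a few scans so coefficients and SDs first adapt to
            # the screened starting weights
            warm = likelihood and scan <= min(25, settings.burn_in // 4)
            if fix_weights is None and not warm:
                for _ in range(settings.weight_sweeps):
                    a_rec = alpha[ci]
                    r0_p = G - (a_rec[:, 0] + a_rec[:, 1] * age
                                + a_rec[:, 3] * tc + a_rec[:, 5] * gprev
                                + a_rec[:, 6] * hi + a_rec[:, 8] * hi * tc)
                    bw_p, ant_p_raw, pc_years, aux, n_acc, n_tot = do_weight_update(
                        bw_p, clim_block_p, r0_p, tc_years, 2, 7,
                        adapt_zp, adapt_pair_p, adapting)
                    pc = pc_years[yi]
                    if balanced:
                        redraw_rank3(2, 7, aux)
                    else:
                        redraw_rank1(2, aux)
                    acc_counts["weights"] += n_acc
                    acc_counts["weights_total"] += n_tot

                    a_rec = alpha[ci]
                    r0_t = G - (a_rec[:, 0] + a_rec[:, 1] * age
                                + a_rec[:, 2] * pc + a_rec[:, 5] * gprev
                                + a_rec[:, 6] * hi + a_rec[:, 7] * hi * pc)
                    bw_t, ant_t_raw, tc_years, aux, n_acc, n_tot = do_weight_update(
                        bw_t, clim_block_t, r0_t, pc_years, 3, 8,
                        adapt_zt, adapt_pair_t, adapting)
                    tc = tc_years[yi]
                    if balanced:
                        redraw_rank3(3, 8, aux)
                    else:
                        redraw_rank1(3, aux)
                    acc_counts["weights"] += n_acc
                    acc_counts["weights_total"] += n_tot

            # ---- rebuild the design matrix at the current weights ----
            X = np.column_stack([
                np.ones(n), age, pc, tc, pc * tc, gprev, hi, hi * pc, hi * tc,
            ])

            # ---- core-level coefficients: coordinate-wise conjugate ----
            resid = G - np.einsum("ij,ij->i", X, alpha[ci])
            inv_s2 = 1.0 / (sig * sig) if likelihood else 0.0
            for k in range(N_COEF):
                xk = X[:, k]
                partial = resid + xk * alpha[ci, k]
                prec = (np.bincount(ci, xk * xk, minlength=n_cores) * inv_s2
                        + 1.0 / sig_a[k] ** 2)
                mean_k = (np.bincount(ci, xk * partial, minlength=n_cores) * inv_s2
                          + mu[k] / sig_a[k] ** 2) / prec
                sd_k = 1.0 / np.sqrt(prec)
                if k == AGE_K:
                    alpha[:, k] = _truncated_normal_below_zero(mean_k, sd_k, rng)
                else:
                    alpha[:, k] = mean_k + sd_k * rng.normal(size=n_cores)
                resid = partial - xk * alpha[ci, k]

            # ---- global means ----
            for k in range(N_COEF):
                if k == AGE_K:
                    # truncated core densities: Metropolis on the hyper-mean
                    step = float(adapt_mu2.step())
                    prop = mu[k] + step * rng.normal()

                    def mu2_logp(m):
                        return (-0.5 * np.sum((alpha[:, k] - m) ** 2) / sig_a[k] ** 2
                                - n_cores * float(log_ndtr(-m / sig_a[k]))
                                - 0.5 * m * m / hyper_var)

                    in_support = not (prior.truncate_hyper_mean and prop > 0)
                    acc = in_support and (
                        np.log(rng.uniform()) < mu2_logp(prop) - mu2_logp(mu[k]))
                    if acc:
                        mu[k] = prop
                    if adapting:
                        adapt_mu2.update(acc)
                else:
                    prec = n_cores / sig_a[k] ** 2 + 1.0 / hyper_var
                    mean_k = np.sum(alpha[:, k]) / sig_a[k] ** 2 / prec
                    mu[k] = mean_k + rng.normal() / np.sqrt(prec)

            # ---- core-level SDs ----
            if fix_sigma_alpha is None:
                steps = adapt_sa.step()
                props = sig_a + steps * rng.normal(size=N_COEF)
                unif = np.log(rng.uniform(size=N_COEF))
                accepted = np.zeros(N_COEF, dtype=bool)
                for k in range(N_COEF):
                    s_new = props[k]
                    if not (0.0 < s_new < upper):
                        continue
                    ss_k = float(np.sum((alpha[:, k] - mu[k]) ** 2))

                    def sa_logp(s):
                        out = -n_cores * np.log(s) - 0.5 * ss_k / (s * s)
                        if k == AGE_K:
                            out -= n_cores * float(log_ndtr(-mu[k] / s))
                        return out

                    if unif[k] < sa_logp(s_new) - sa_logp(sig_a[k]):
                        sig_a[k] = s_new
                        accepted[k] = True
                if adapting:
                    adapt_sa.update(accepted)

            # ---- observation SD ----
            if fix_sigma_obs is None:
                step = float(adapt_so.step())
                prop = sig + step * rng.normal()
                if 0.0 < prop < upper:
                    if likelihood:
                        ss = float(resid @ resid)
                        log_ratio = (-n * (np.log(prop) - np.log(sig))
                                     - 0.5 * ss * (1.0 / prop ** 2 - 1.0 / sig ** 2))
                        acc = np.log(rng.uniform()) < log_ratio
                    else:
                        acc = True
                    if acc:
                        sig = prop
                    if adapting:
                        adapt_so.update(acc)
                else:
                    if adapting:
                        adapt_so.update(False)

            # ---- store ----
            if scan > settings.burn_in and (scan - settings.burn_in) % settings.thin == 0:
                ch_draws["mu_alpha"].append(mu.copy())
                ch_draws["sigma_alpha"].append(sig_a.copy())
                ch_draws["sigma_obs"].append(sig)
                ch_draws["wP_block"].append(bw_p.copy())
                ch_draws["wT_block"].append(bw_t.copy())
                if store_alpha:
                    ch_draws["alpha"].append(alpha.copy())
                if store_antecedent:
                    ch_draws["ant_P"].append(ant_p_raw.copy())
                    ch_draws["ant_T"].append(ant_t_raw.copy())

        for key, lst in ch_draws.items():
            draws[key].append(np.asarray(lst))

    stacked = {k: np.stack(v) for k, v in draws.items()}
    acceptance = {}
    if acc_counts["weights_total"]:
        acceptance["weights"] = acc_counts["weights"] / acc_counts["weights_total"]
    return ChainSet(
        draws=stacked,
        seeds=list(seeds),
        settings=settings,
        scheme=scheme,
        core_ids=list(design.cores),
        window_years=design.window_years.copy(),
        acceptance=acceptance,
    )
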