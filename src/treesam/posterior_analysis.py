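"""Turn retained draws into reported products.

Coefficient tables with 95% equal-tailed credible intervals, monthly /
annual / cumulative weight profiles, memory lengths (M50, M90), uncentered
antecedent climate reconstructions, net climate sensitivities, posterior-
predictive fit (R^2) and the autoregressive share of the fit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .antecedent import (
    N_MONTHS,
    WeightVector,
    annual_weights,
    cumulative_weights,
    lag_to_year_month,
    memory_lengths,
)
from .inference import ChainSet, compute_diagnostics
from .preprocess import ModelDesign
from .sam_model import AR_K, COEF_NAMES, N_COEF, design_matrix

CI_LEVEL = 0.95
#: factor converting a weighted monthly precipitation mean to an annual total
PRECIP_ANNUAL_FACTOR = 12.0


def _ci(draws: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    lo = (1.0 - CI_LEVEL) / 2.0
    return (np.quantile(draws, lo, axis=axis),
            np.quantile(draws, 1.0 - lo, axis=axis))


def summarize_coefficients(chains: ChainSet) -> pd.DataFrame:
    """Posterior mean, 95% CI and significance flag per global coefficient.

    An effect is flagged significant when its equal-tailed 95% interval
    excludes zero.
    """
    mu = chains.pooled("mu_alpha")  # (draws, 9)
    if mu.size == 0:
        raise ValueError("empty chains")
    lo, hi = _ci(mu)
    mean = mu.mean(axis=0)
    return pd.DataFrame({
        "k": np.arange(1, N_COEF + 1),
        "name": COEF_NAMES,
        "mean": mean,
        "ci_low": lo,
        "ci_high": hi,
        "significant": (lo > 0) | (hi < 0),
    })


def net_sensitivity_P(alpha3, alpha5, alpha8, t_ant_centered, hi_centered):
    """dG/dP_ant = alpha3 + alpha5 * T_ant + alpha8 * HI (centered covariates)."""
    return alpha3 + alpha5 * np.asarray(t_ant_centered) + alpha8 * np.asarray(hi_centered)


def net_sensitivity_T(alpha4, alpha5, alpha9, p_ant_centered, hi_centered):
    """dG/dT_ant = alpha4 + alpha5 * P_ant + alpha9 * HI (centered covariates)."""
    return alpha4 + alpha5 * np.asarray(p_ant_centered) + alpha9 * np.asarray(hi_centered)


def sensitivity_grid(
    chains: ChainSet,
    p_values: np.ndarray,
    t_values: np.ndarray,
    hi_values: np.ndarray,
) -> pd.DataFrame:
    """Posterior-mean net sensitivities over a grid of centered covariates."""
    mu = chains.pooled("mu_alpha").mean(axis=0)
    rows = []
    for hi in np.asarray(hi_values, dtype=float):
        for t in np.asarray(t_values, dtype=float):
            rows.append({"variable": "P_ant", "partner": t, "hi": hi,
                         "sensitivity": float(net_sensitivity_P(mu[2], mu[4], mu[7], t, hi))})
        for p in np.asarray(p_values, dtype=float):
            rows.append({"variable": "T_ant", "partner": p, "hi": hi,
                         "sensitivity": float(net_sensitivity_T(mu[3], mu[4], mu[8], p, hi))})
    return pd.DataFrame(rows)


def antecedent_series(chains: ChainSet, design: ModelDesign, variable: str) -> pd.DataFrame:
    """Per-year uncentered antecedent climate with 95% CIs.

    Temperature is reported in degC as-is; precipitation (a weighted monthly
    mean, mm) is scaled by 12 to an annual-total scale for comparison with
    recorded yearly precipitation sums.
    """
    if variable not in ("precipitation", "temperature"):
        raise ValueError(f"unknown variable {variable!r}")
    key = "ant_P" if variable == "precipitation" else "ant_T"
    if key in chains.draws:
        series = chains.pooled(key)  # (draws, n_years)
    else:
        windows = (design.precip_windows if variable == "precipitation"
                   else design.temp_windows)
        blocks = chains.pooled("wP_block" if variable == "precipitation" else "wT_block")
        monthly = blocks @ chains.scheme.monthly_map.T
        series = monthly @ windows.T
    if series.shape[1] != design.window_years.size:
        raise ValueError("chains and design disagree on the modelled years")
    if variable == "precipitation":
        series = series * PRECIP_ANNUAL_FACTOR
    lo, hi = _ci(series)
    return pd.DataFrame({
        "year": design.window_years,
        "mean": series.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
    })


def weight_profiles(chains: ChainSet, variable: str) -> pd.DataFrame:
    """Monthly weight posterior summary, one row per months-into-past lag."""
    key = "wP_block" if variable == "precipitation" else "wT_block"
    monthly = chains.pooled(key) @ chains.scheme.monthly_map.T  # (draws, 60)
    lo, hi = _ci(monthly)
    lags = np.arange(1, N_MONTHS + 1)
    ym = [lag_to_year_month(int(lag)) for lag in lags]
    return pd.DataFrame({
        "variable": variable,
        "y": [y for y, _ in ym],
        "m": [m for _, m in ym],
        "months_into_past": lags,
        "mean": monthly.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
    })


def annual_weight_summary(chains: ChainSet, variable: str) -> pd.DataFrame:
    key = "wP_block" if variable == "precipitation" else "wT_block"
    monthly = chains.pooled(key) @ chains.scheme.monthly_map.T
    annual = monthly.reshape(monthly.shape[0], 5, 12).sum(axis=2)
    lo, hi = _ci(annual)
    return pd.DataFrame({
        "variable": variable,
        "y": np.arange(5),
        "mean": annual.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
    })


def cumulative_weight_summary(chains: ChainSet, variable: str) -> pd.DataFrame:
    key = "wP_block" if variable == "precipitation" else "wT_block"
    monthly = chains.pooled(key) @ chains.scheme.monthly_map.T
    cum = np.cumsum(monthly, axis=1)
    lo, hi = _ci(cum)
    return pd.DataFrame({
        "variable": variable,
        "months_into_past": np.arange(1, N_MONTHS + 1),
        "mean": cum.mean(axis=0),
        "ci_low": lo,
        "ci_high": hi,
    })


def memory_table(chains: ChainSet) -> pd.DataFrame:
    """Posterior summaries of M50 / M90 per climate variable.

    Memory lengths are computed per retained draw and then summarized, so
    the interval reflects weight uncertainty.
    """
    rows = []
    for variable, key in (("precipitation", "wP_block"), ("temperature", "wT_block")):
        blocks = chains.pooled(key)
        m50 = np.empty(blocks.shape[0])
        m90 = np.empty(blocks.shape[0])
        for i, bw in enumerate(blocks):
            wv = WeightVector(variable, bw, chains.scheme)
            ml = memory_lengths(wv)
            m50[i], m90[i] = ml.m50, ml.m90
        for name, vals in (("M50", m50), ("M90", m90)):
            lo, hi = _ci(vals)
            rows.append({"variable": variable, "measure": name,
                         "mean": vals.mean(), "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------


def _predicted_means(
    chains: ChainSet, design: ModelDesign, max_draws: int, zero_ar: bool,
    seed: int = 0,
) -> np.ndarray:
    """Posterior-mean replicate per record (mean of mu over a draw subset)."""
    if "alpha" not in chains.draws:
        raise ValueError("chains were run without core-level coefficient storage")
    alpha = chains.pooled("alpha")        # (draws, C, 9)
    wp = chains.pooled("wP_block")
    wt = chains.pooled("wT_block")
    n_draws = alpha.shape[0]
    if n_draws == 0:
        raise ValueError("empty chains")
    rng = np.random.default_rng(seed)
    idx = (np.arange(n_draws) if n_draws <= max_draws
           else rng.choice(n_draws, size=max_draws, replace=False))
    acc = np.zeros(design.n_records)
    for i in idx:
        a = alpha[i].copy()
        if zero_ar:
            a[:, AR_K] = 0.0
        X, _, _ = design_matrix(
            design,
            WeightVector("precipitation", wp[i], chains.scheme),
            WeightVector("temperature", wt[i], chains.scheme),
        )
        acc += np.einsum("ij,ij->i", X, a[design.core_index])
    return acc / idx.size


def fit_r2(chains: ChainSet, design: ModelDesign, max_draws: int = 200) -> float:
    """Squared Pearson correlation of posterior-predicted versus observed G."""
    if np.var(design.G) == 0:
        raise ValueError("observed growth has zero variance")
    pred = _predicted_means(chains, design, max_draws, zero_ar=False)
    r = np.corrcoef(pred, design.G)[0, 1]
    return float(r * r)


def variance_share_ar(chains: ChainSet, design: ModelDesign, max_draws: int = 200) -> float:
    """Percentage of the model fit attributable to the autoregressive term.

    Computed counterfactually: R^2 of the full replicate minus R^2 of a
    replicate with the autoregressive coefficient zeroed at every draw.
    """
    if np.var(design.G) == 0:
        raise ValueError("observed growth has zero variance")
    full = _predicted_means(chains, design, max_draws, zero_ar=False)
    no_ar = _predicted_means(chains, design, max_draws, zero_ar=True)
    r2_full = float(np.corrcoef(full, design.G)[0, 1] ** 2)
    r2_no_ar = float(np.corrcoef(no_ar, design.G)[0, 1] ** 2)
    return 100.0 * (r2_full - r2_no_ar)


# ---------------------------------------------------------------------------
# CSV export bundle
# ---------------------------------------------------------------------------


def export_summary(
    chains: ChainSet,
    design: ModelDesign,
    out_dir: str | Path,
    max_draws: int = 200,
) -> dict[str, Path]:
    """Write the full CSV summary bundle; returns paths by product name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)

    save("coefficients", summarize_coefficients(chains))
    save("weights_monthly", pd.concat([
        weight_profiles(chains, "temperature"),
        weight_profiles(chains, "precipitation"),
    ]))
    save("weights_annual", pd.concat([
        annual_weight_summary(chains, "temperature"),
        annual_weight_summary(chains, "precipitation"),
    ]))
    save("weights_cumulative", pd.concat([
        cumulative_weight_summary(chains, "temperature"),
        cumulative_weight_summary(chains, "precipitation"),
    ]))
    save("memory", memory_table(chains))
    save("antecedent_series", pd.concat([
        antecedent_series(chains, design, "temperature").assign(variable="temperature"),
        antecedent_series(chains, design, "precipitation").assign(variable="precipitation"),
    ]))
    hi_sd = float(np.std(design.hi_centered)) or 0.05
    p_sd = t_sd = 1.0
    save("sensitivity_grid", sensitivity_grid(
        chains,
        p_values=np.linspace(-2 * p_sd, 2 * p_sd, 5),
        t_values=np.linspace(-2 * t_sd, 2 * t_sd, 5),
        hi_values=np.array([0.0, hi_sd, 2 * hi_sd]),
    ))
    r2 = fit_r2(chains, design, max_draws=max_draws)
    ar_share = variance_share_ar(chains, design, max_draws=max_draws)
    diag = compute_diagnostics(chains)
    save("fit", pd.DataFrame([{
        "r2": r2,
        "ar_share_pct": ar_share,
        "psrf_max": max(diag.psrf.values()),
        "converged": diag.converged,
    }]))
    return paths
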