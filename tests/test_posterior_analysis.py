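"""Posterior products: summaries, sensitivities, antecedent series, fit."""

import numpy as np
import pytest

import treesam as ts
from treesam.inference import ChainSet, MCMCSettings
from treesam.posterior_analysis import (
    annual_weight_summary,
    cumulative_weight_summary,
    export_summary,
    sensitivity_grid,
)
from treesam.sam_model import design_matrix


@pytest.fixture(scope="module")
def fitted(tiny_design):
    settings = MCMCSettings(n_chains=2, n_iter=400, burn_in=150, thin=5,
                            n_pair_moves=8)
    return ts.run_mcmc(tiny_design, settings, seed=4)


def _chainset_from_mu(mu_draws, scheme):
    """Minimal ChainSet with given pooled mu_alpha draws (one chain)."""
    d = mu_draws.shape[0]
    return ChainSet(
        draws={
            "mu_alpha": mu_draws[None],
            "sigma_alpha": np.ones((1, d, 9)),
            "sigma_obs": np.full((1, d), 0.1),
            "wP_block": np.full((1, d, 34), 1 / 34),
            "wT_block": np.full((1, d, 34), 1 / 34),
        },
        seeds=[0],
        settings=MCMCSettings(n_iter=d + 1, burn_in=0, thin=1, n_chains=1),
        scheme=scheme,
        core_ids=["c"],
        window_years=np.array([2000]),
    )


class TestSummarizeCoefficients:
    def test_constant_draws_degenerate_interval(self, scheme):
        cs = _chainset_from_mu(np.full((50, 9), 0.5), scheme)
        tab = ts.summarize_coefficients(cs)
        assert np.allclose(tab["mean"], 0.5)
        assert np.allclose(tab["ci_low"], 0.5)
        assert tab["significant"].all()

    def test_symmetric_draws_not_significant(self, scheme):
        rng = np.random.default_rng(0)
        cs = _chainset_from_mu(rng.normal(0, 1, (4000, 9)), scheme)
        tab = ts.summarize_coefficients(cs)
        assert not tab["significant"].any()

    def test_standard_normal_quantiles(self, scheme):
        rng = np.random.default_rng(1)
        cs = _chainset_from_mu(rng.normal(0, 1, (10_000, 9)), scheme)
        tab = ts.summarize_coefficients(cs)
        assert np.allclose(tab["ci_low"], -1.96, atol=0.08)
        assert np.allclose(tab["ci_high"], 1.96, atol=0.08)

    def test_interval_order(self, fitted):
        tab = ts.summarize_coefficients(fitted)
        assert (tab["ci_low"] <= tab["mean"]).all()
        assert (tab["mean"] <= tab["ci_high"]).all()


class TestNetSensitivity:
    def test_no_interactions_returns_main_effect(self):
        assert ts.net_sensitivity_P(0.3, 0.0, 0.0, 1.7, 0.4) == 0.3

    def test_centered_average_conditions(self):
        assert ts.net_sensitivity_P(0.3, 0.5, 0.2, 0.0, 0.0) == 0.3
        assert ts.net_sensitivity_T(0.4, 0.5, 0.2, 0.0, 0.0) == 0.4

    def test_matches_finite_difference_of_mean_growth(self, tiny_design,
                                                      tiny_params):
        """dG/dX_ant from the closed form equals a numerical derivative of
        the nine-term mean."""
        p = tiny_params
        X, _, _ = design_matrix(tiny_design, p.weights_P, p.weights_T)
        i = 11
        c = tiny_design.core_index[i]
        a = p.alpha[c]
        pc, tc, hic = X[i, 2], X[i, 3], X[i, 6]

        def mu_at(pc_v, tc_v):
            return (a[0] + a[1] * X[i, 1] + a[2] * pc_v + a[3] * tc_v
                    + a[4] * pc_v * tc_v + a[5] * X[i, 5] + a[6] * hic
                    + a[7] * hic * pc_v + a[8] * hic * tc_v)

        h = 1e-6
        fd_p = (mu_at(pc + h, tc) - mu_at(pc - h, tc)) / (2 * h)
        fd_t = (mu_at(pc, tc + h) - mu_at(pc, tc - h)) / (2 * h)
        assert ts.net_sensitivity_P(a[2], a[4], a[7], tc, hic) == pytest.approx(
            fd_p, rel=1e-6)
        assert ts.net_sensitivity_T(a[3], a[4], a[8], pc, hic) == pytest.approx(
            fd_t, rel=1e-6)

    def test_grid_export_shape(self, fitted):
        grid = sensitivity_grid(fitted, np.linspace(-1, 1, 3),
                                np.linspace(-1, 1, 3), np.array([0.0, 0.05]))
        assert set(grid["variable"]) == {"P_ant", "T_ant"}
        assert len(grid) == 2 * 2 * 3


class TestAntecedentSeries:
    def test_temperature_reported_as_is(self, fitted, tiny_design):
        out = ts.antecedent_series(fitted, tiny_design, "temperature")
        assert len(out) == tiny_design.window_years.size
        lo = tiny_design.temp_windows.min()
        hi = tiny_design.temp_windows.max()
        assert out["mean"].between(lo, hi).all()

    def test_precipitation_scaled_to_annual_total(self, fitted, tiny_design):
        out = ts.antecedent_series(fitted, tiny_design, "precipitation")
        monthly_mean_scale = tiny_design.precip_windows.mean()
        assert out["mean"].mean() == pytest.approx(12 * monthly_mean_scale,
                                                   rel=0.35)

    def test_interval_order(self, fitted, tiny_design):
        out = ts.antecedent_series(fitted, tiny_design, "temperature")
        assert (out["ci_low"] <= out["mean"]).all()
        assert (out["mean"] <= out["ci_high"]).all()

    def test_unknown_variable_rejected(self, fitted, tiny_design):
        with pytest.raises(ValueError):
            ts.antecedent_series(fitted, tiny_design, "humidity")


class TestWeightSummaries:
    def test_monthly_profile_fixed_zeros_and_mass(self, fitted):
        prof = ts.weight_profiles(fitted, "precipitation")
        assert np.allclose(prof["mean"][:3], 0.0)
        assert prof["mean"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_annual_and_cumulative_consistent(self, fitted):
        annual = annual_weight_summary(fitted, "temperature")
        cum = cumulative_weight_summary(fitted, "temperature")
        assert annual["mean"].sum() == pytest.approx(1.0, abs=1e-9)
        assert cum["mean"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(cum["mean"]) >= -1e-12).all()

    def test_memory_table_m50_below_m90(self, fitted):
        mem = ts.memory_table(fitted)
        wide = mem.pivot(index="variable", columns="measure", values="mean")
        assert (wide["M50"] <= wide["M90"]).all()


class TestFit:
    def test_r2_of_perfect_replicates_is_one(self, tiny_design, fitted):
        pred = tiny_design.G
        r = np.corrcoef(pred, tiny_design.G)[0, 1]
        assert r * r == pytest.approx(1.0)

    def test_r2_in_unit_interval(self, fitted, tiny_design):
        r2 = ts.fit_r2(fitted, tiny_design, max_draws=60)
        assert 0.0 <= r2 <= 1.0

    def test_ar_share_zero_when_ar_coefficient_zero(self, fitted, tiny_design):
        import copy
        cs = copy.deepcopy(fitted)
        cs.draws["alpha"][:, :, :, 5] = 0.0
        assert ts.variance_share_ar(cs, tiny_design, max_draws=40) == pytest.approx(
            0.0, abs=1e-9)

    def test_export_bundle_writes_all_products(self, fitted, tiny_design, tmp_path):
        paths = export_summary(fitted, tiny_design, tmp_path, max_draws=30)
        expected = {"coefficients", "weights_monthly", "weights_annual",
                    "weights_cumulative", "memory", "antecedent_series",
                    "sensitivity_grid", "fit"}
        assert set(paths) == expected
        assert all(p.exists() for p in paths.values())
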