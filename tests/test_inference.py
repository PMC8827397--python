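"""Chain protocol arithmetic, determinism, diagnostics, initialization."""

import numpy as np
import pytest

import treesam as ts
from treesam.inference import MCMCSettings, gelman_rubin


class TestProtocolArithmetic:
    def test_retained_draws(self):
        s = MCMCSettings(n_iter=100, burn_in=40, thin=10)
        assert s.n_retained == 6

    def test_paper_mirror_settings(self):
        s = MCMCSettings(n_chains=3, n_iter=40_000, burn_in=10_000, thin=10)
        assert s.n_retained == 3_000
        assert s.n_chains * s.n_retained == 9_000

    def test_burn_in_must_be_shorter_than_run(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=100)


class TestGelmanRubin:
    def test_identical_chains_floor_at_one(self):
        assert gelman_rubin(np.array([[1.0, 2, 3, 4], [1, 2, 3, 4]])) == 1.0

    def test_degenerate_equal_constants(self):
        assert gelman_rubin(np.zeros((2, 5))) == 1.0

    def test_disjoint_point_masses_are_infinite(self):
        assert gelman_rubin(np.array([[0.0, 0, 0, 0], [10, 10, 10, 10]])) == np.inf

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        traces = rng.normal(size=(3, 200)) + np.array([[0.0], [0.2], [-0.1]])
        n = traces.shape[1]
        w = np.mean([np.var(t, ddof=1) for t in traces])
        b = n * np.var([t.mean() for t in traces], ddof=1)
        expected = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert gelman_rubin(traces) == pytest.approx(expected, rel=1e-12)

    def test_requires_two_chains(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 10)))


class TestInitialize:
    def test_in_support_for_many_seeds(self, tiny_design):
        for seed in range(30):
            p = ts.initialize(tiny_design, seed)
            assert np.all(p.alpha[:, 1] <= 0)
            assert 0 < p.sigma_obs < 100
            assert np.all(p.sigma_alpha > 0)
            assert np.isfinite(ts.log_prior(p))

    def test_deterministic_given_seed(self, tiny_design):
        a = ts.initialize(tiny_design, 5)
        b = ts.initialize(tiny_design, 5)
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.weights_P.block_weights, b.weights_P.block_weights)


@pytest.fixture(scope="module")
def short_chains(tiny_design):
    settings = MCMCSettings(n_chains=2, n_iter=200, burn_in=80, thin=4,
                            n_pair_moves=8)
    return ts.run_mcmc(tiny_design, settings, seed=2)


class TestRunMcmc:
    def test_retained_shape(self, short_chains):
        assert short_chains.n_chains == 2
        assert short_chains.n_retained == 30
        assert short_chains.draws["mu_alpha"].shape == (2, 30, 9)
        assert short_chains.draws["wP_block"].shape[2] == 34

    def test_bit_reproducible(self, tiny_design, short_chains):
        settings = MCMCSettings(n_chains=2, n_iter=200, burn_in=80, thin=4,
                                n_pair_moves=8)
        again = ts.run_mcmc(tiny_design, settings, seed=2)
        for key in short_chains.draws:
            assert np.array_equal(short_chains.draws[key], again.draws[key])

    def test_seeds_distinct_and_recorded(self, short_chains):
        assert len(set(short_chains.seeds)) == 2

    def test_age_truncation_holds_in_every_draw(self, short_chains):
        assert np.all(short_chains.draws["alpha"][:, :, :, 1] <= 0)

    def test_weights_stay_on_simplex(self, short_chains):
        for key in ("wP_block", "wT_block"):
            w = short_chains.pooled(key)
            assert np.all(w >= 0)
            assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_monitored_scalars_include_coefficients_weights_series(self, short_chains):
        scalars = short_chains.monitored_scalars()
        assert "mu_alpha[1]" in scalars
        assert "wP[1]" in scalars and "wT[34]" in scalars
        assert any(name.startswith("ant_P[") for name in scalars)

    def test_diagnostics_structure(self, short_chains):
        diag = ts.compute_diagnostics(short_chains)
        assert all(v >= 1.0 - 1e-6 for v in diag.psrf.values())
        assert all(v > 0 for v in diag.ess.values())

    def test_fixed_weights_are_not_updated(self, tiny_design, scheme):
        bw = np.full(34, 1 / 34)
        wv = (ts.WeightVector("precipitation", bw, scheme),
              ts.WeightVector("temperature", bw, scheme))
        settings = MCMCSettings(n_chains=2, n_iter=60, burn_in=20, thin=2)
        cs = ts.run_mcmc(tiny_design, settings, seed=0, fix_weights=wv)
        assert np.allclose(cs.pooled("wP_block"), 1 / 34)


class TestUnbalancedDesign:
    def test_ragged_core_spans_sample_cleanly(self):
        """Cores covering different year spans use the fallback weight
        kernel; draws stay on the simplex and runs are reproducible."""
        import treesam as ts
        cfg = ts.make_paper_like_fixture("stressed")
        cfg.n_cores, cfg.n_years, cfg.start_year, cfg.seed = 6, 16, 2001, 9
        series, climate, harvest, _ = ts.generate(cfg)
        # truncate half the cores so year coverage is ragged
        for s in series[:3]:
            s.widths = s.widths[6:]
            s.first_year += 6
        design = ts.build_design(series, climate, harvest, (2001, 2016))
        counts = np.bincount(design.core_index)
        assert counts.min() < counts.max()  # genuinely unbalanced
        settings = MCMCSettings(n_chains=2, n_iter=150, burn_in=60, thin=3,
                                n_pair_moves=6)
        cs = ts.run_mcmc(design, settings, seed=5)
        again = ts.run_mcmc(design, settings, seed=5)
        for key in ("wP_block", "wT_block"):
            w = cs.pooled(key)
            assert np.all(w >= 0)
            assert np.allclose(w.sum(axis=1), 1.0, atol=1e-9)
            assert np.array_equal(w, again.pooled(key))
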