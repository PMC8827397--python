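import numpy as np
import pytest

import treesam as ts


@pytest.fixture(scope="session")
def scheme():
    return ts.default_scheme()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic species-site dataset (8 cores x 18 years)."""
    cfg = ts.make_paper_like_fixture("stressed")
    cfg.n_cores = 8
    cfg.n_years = 18
    cfg.start_year = 1999
    cfg.seed = 7
    series, climate, harvest, truth = ts.generate(cfg)
    return cfg, series, climate, harvest, truth


@pytest.fixture(scope="session")
def tiny_design(tiny_dataset):
    cfg, series, climate, harvest, _ = tiny_dataset
    return ts.build_design(
        series, climate, harvest,
        (cfg.start_year, cfg.start_year + cfg.n_years - 1),
    )


@pytest.fixture(scope="session")
def tiny_params(tiny_design, scheme):
    rng = np.random.default_rng(3)
    return ts.SamParams(
        alpha=np.column_stack([
            rng.normal(0.9, 0.1, tiny_design.n_cores),
            -np.abs(rng.normal(0.002, 0.001, tiny_design.n_cores)),
            rng.normal(0.01, 0.002, tiny_design.n_cores),
            rng.normal(0.3, 0.05, tiny_design.n_cores),
            rng.normal(0.01, 0.003, tiny_design.n_cores),
            rng.normal(0.2, 0.05, tiny_design.n_cores),
            rng.normal(-0.8, 0.2, tiny_design.n_cores),
            rng.normal(0.06, 0.02, tiny_design.n_cores),
            rng.normal(1.5, 0.4, tiny_design.n_cores),
        ]),
        mu_alpha=np.array([0.9, -0.002, 0.01, 0.3, 0.01, 0.2, -0.8, 0.06, 1.5]),
        sigma_alpha=np.array([0.1, 0.001, 0.002, 0.05, 0.003, 0.05, 0.2, 0.02, 0.4]),
        sigma_obs=0.1,
        weights_P=ts.WeightVector("precipitation",
                                  np.random.default_rng(4).dirichlet(np.ones(34)),
                                  ts.default_scheme()),
        weights_T=ts.WeightVector("temperature",
                                  np.random.default_rng(5).dirichlet(np.ones(34)),
                                  ts.default_scheme()),
    )
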