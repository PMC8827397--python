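"""Weight simplex, antecedent averaging, and memory-length calculations."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

import treesam as ts
from treesam.antecedent import (
    FIXED_ZERO_LAGS,
    N_MONTHS,
    lag_to_year_month,
    months_into_past,
)


class TestLagMapping:
    def test_bijection_over_all_year_month_pairs(self):
        seen = set()
        for y in range(5):
            for m in range(1, 13):
                lag = months_into_past(y, m)
                assert 1 <= lag <= N_MONTHS
                assert lag_to_year_month(lag) == (y, m)
                seen.add(lag)
        assert seen == set(range(1, N_MONTHS + 1))

    def test_convention_endpoints(self):
        # December of the current year is lag 1; January four years back is 60
        assert months_into_past(0, 12) == 1
        assert months_into_past(4, 1) == 60
        assert months_into_past(0, 9) == 4  # September of the current year

    def test_fixed_zero_lags_are_current_year_oct_dec(self):
        assert {lag_to_year_month(lag) for lag in FIXED_ZERO_LAGS} == {
            (0, 10), (0, 11), (0, 12)}


class TestDefaultScheme:
    def test_block_count_and_coverage(self, scheme):
        assert scheme.n_blocks == 34  # 9 + 12 + 6 + 4 + 3
        covered = sorted(lag for b in scheme.blocks for lag in b)
        assert len(covered) == 57
        assert covered == list(range(4, 61))

    def test_resolution_declines_with_lag(self, scheme):
        # single months for years 0-1, then 2-, 3-, 4-month blocks
        by_year = {}
        for block in scheme.blocks:
            y = lag_to_year_month(min(block))[0]
            by_year.setdefault(y, set()).add(len(block))
        assert by_year == {0: {1}, 1: {1}, 2: {2}, 3: {3}, 4: {4}}

    def test_rejects_overlapping_blocks(self):
        with pytest.raises(ValueError):
            ts.WeightScheme(blocks=((4, 5), (5, 6)))


class TestWeightVector:
    def test_uniform_blocks_split_within_two_month_blocks(self, scheme):
        wv = ts.to_monthly(np.full(34, 1 / 34), scheme)
        two_month = [b for b in scheme.blocks if len(b) == 2]
        for block in two_month:
            for lag in block:
                assert wv.monthly[lag - 1] == pytest.approx(1 / 68)

    def test_point_mass_on_current_september(self, scheme):
        bw = np.zeros(34)
        bw[0] = 1.0  # first block = lag 4 = September of the current year
        wv = ts.to_monthly(bw, scheme)
        assert wv.monthly[3] == 1.0
        assert wv.monthly.sum() == pytest.approx(1.0)

    def test_fixed_zero_months_always_zero(self, scheme):
        wv = ts.to_monthly(np.random.default_rng(0).dirichlet(np.ones(34)), scheme)
        assert np.all(wv.monthly[:3] == 0.0)

    @pytest.mark.parametrize("bad", [
        np.full(33, 1 / 33),                   # wrong length
        -np.ones(34) / 34,                     # negative
        np.full(34, 1 / 20),                   # does not sum to one
    ])
    def test_invalid_block_weights_rejected(self, scheme, bad):
        with pytest.raises(ValueError):
            ts.to_monthly(bad, scheme)


class TestAntecedentValue:
    def test_constant_window_returns_the_constant(self, scheme):
        wv = ts.to_monthly(np.random.default_rng(1).dirichlet(np.ones(34)), scheme)
        assert ts.antecedent_value(np.full(60, 8.3), wv) == pytest.approx(8.3)

    def test_point_mass_picks_out_single_month(self, scheme):
        bw = np.zeros(34)
        bw[0] = 1.0
        wv = ts.to_monthly(bw, scheme)
        window = np.arange(60, dtype=float)
        window[3] = 17.0
        assert ts.antecedent_value(window, wv) == pytest.approx(17.0)

    def test_matches_brute_force_double_sum(self, scheme):
        """Weighted average equals the explicit double loop over (y, m)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            wv = ts.to_monthly(rng.dirichlet(np.ones(34)), scheme)
            window = rng.normal(10, 5, size=60)
            expected = 0.0
            for y in range(5):
                for m in range(1, 13):
                    lag = months_into_past(y, m)
                    expected += window[lag - 1] * wv.monthly[lag - 1]
            assert ts.antecedent_value(window, wv) == pytest.approx(
                expected, abs=1e-12)

    def test_window_length_checked(self, scheme):
        wv = ts.to_monthly(np.full(34, 1 / 34), scheme)
        with pytest.raises(ValueError):
            ts.antecedent_value(np.ones(59), wv)

    def test_convexity_bounds(self, scheme):
        rng = np.random.default_rng(9)
        wv = ts.to_monthly(rng.dirichlet(np.ones(34)), scheme)
        window = rng.normal(size=60)
        v = ts.antecedent_value(window, wv)
        assert window.min() <= v <= window.max()


class TestProfiles:
    def test_annual_weights_point_mass(self, scheme):
        bw = np.zeros(34)
        bw[0] = 1.0
        assert ts.annual_weights(ts.to_monthly(bw, scheme)) == pytest.approx(
            [1, 0, 0, 0, 0])

    def test_annual_weights_uniform_over_free_months(self, scheme):
        bw = scheme.block_sizes / 57
        annual = ts.annual_weights(ts.to_monthly(bw, scheme))
        assert annual == pytest.approx([9 / 57, 12 / 57, 12 / 57, 12 / 57, 12 / 57])

    def test_cumulative_starts_zero_ends_one(self, scheme):
        wv = ts.to_monthly(np.random.default_rng(2).dirichlet(np.ones(34)), scheme)
        cum = ts.cumulative_weights(wv)
        assert np.all(cum[:3] == 0.0)
        assert cum[-1] == pytest.approx(1.0)
        assert np.all(np.diff(cum) >= -1e-15)


class TestMemoryLengths:
    def test_point_mass_memory(self, scheme):
        bw = np.zeros(34)
        bw[0] = 1.0
        ml = ts.memory_lengths(ts.to_monthly(bw, scheme))
        assert (ml.m50, ml.m90) == (4, 4)

    def test_uniform_over_57_free_months(self, scheme):
        """Brute-force count: 50% needs the 29th free cell (lag 32), 90%
        the 52nd (lag 55)."""
        bw = scheme.block_sizes / 57
        ml = ts.memory_lengths(ts.to_monthly(bw, scheme))
        assert (ml.m50, ml.m90) == (32, 55)

    @given(st.integers(0, 2**31 - 1))
    @hyp_settings(max_examples=200, deadline=None)
    def test_m50_never_exceeds_m90(self, seed):
        scheme = ts.default_scheme()
        bw = np.random.default_rng(seed).dirichlet(np.ones(34))
        ml = ts.memory_lengths(ts.to_monthly(bw, scheme))
        assert 1 <= ml.m50 <= ml.m90 <= 60

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            ts.MemoryLengths(m50=40, m90=30)


def test_antecedent_invariant_under_joint_permutation(scheme):
    """The weighted sum is invariant when window and monthly weights are
    permuted together (it is a plain inner product)."""
    rng = np.random.default_rng(11)
    wv = ts.to_monthly(rng.dirichlet(np.ones(34)), scheme)
    window = rng.normal(size=60)
    base = ts.antecedent_value(window, wv)
    perm = rng.permutation(60)
    assert float(window[perm] @ wv.monthly[perm]) == pytest.approx(base, abs=1e-12)
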