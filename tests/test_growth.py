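"""Growth-simulation unit and property tests.

Independent oracles: closed-form stoichiometry for the single-taxon batch,
binomial/multinomial moments for the sampling bottlenecks, and a fixed-step
Euler integrator (conftest) for multi-taxon kinetics.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import soilcosm as sc
from soilcosm.growth import run_replicate_ensemble

from conftest import euler_batch


class TestAssignGrowthRates:
    def test_linear_in_log10_abundance(self, three_taxon_pool):
        pool = sc.assign_growth_rates(three_taxon_pool, 0.01, 0.4)
        # log10 abundances -0.0458, -1.0458, -2: the middle taxon sits at
        # 48.83% of the log-range above the minimum
        assert pool.growth_rate == pytest.approx([0.4, 0.200434, 0.01], abs=1e-3)

    def test_extremes_get_mu_bounds(self, three_taxon_pool):
        pool = sc.assign_growth_rates(three_taxon_pool, 0.05, 0.3)
        assert pool.growth_rate[0] == pytest.approx(0.3)
        assert pool.growth_rate[-1] == pytest.approx(0.05)

    def test_equal_abundances_degenerate_to_mu_max(self):
        pool = sc.TaxonPool(("x", "y"), np.array([0.5, 0.5]), np.array([1.0, 1.0]))
        out = sc.assign_growth_rates(pool, 0.01, 0.4)
        assert np.allclose(out.growth_rate, 0.4)

    def test_collapsed_interval(self, three_taxon_pool):
        out = sc.assign_growth_rates(three_taxon_pool, 0.2, 0.2)
        assert np.allclose(out.growth_rate, 0.2)

    def test_zero_abundance_rejected(self):
        pool = sc.TaxonPool(("x", "y"), np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="zero-abundance"):
            sc.assign_growth_rates(pool)

    def test_rates_bounded(self):
        rng = np.random.default_rng(5)
        a = rng.dirichlet(np.ones(50))
        pool = sc.TaxonPool(tuple(f"t{i}" for i in range(50)), a, np.ones(50))
        out = sc.assign_growth_rates(pool, 0.01, 0.4)
        assert np.all(out.growth_rate >= 0.01 - 1e-12)
        assert np.all(out.growth_rate <= 0.4 + 1e-12)


class TestSetFocalRates:
    def test_override_and_flag(self, three_taxon_pool):
        out = sc.set_focal_rates(three_taxon_pool, ["c"], [0.8])
        assert out.growth_rate[2] == 0.8
        assert out.focal_flags[2]
        assert not out.focal_flags[0]
        assert out.growth_rate[0] == three_taxon_pool.growth_rate[0]

    def test_empty_is_identity(self, three_taxon_pool):
        out = sc.set_focal_rates(three_taxon_pool, [], [])
        assert np.array_equal(out.growth_rate, three_taxon_pool.growth_rate)

    def test_unknown_id_named_in_error(self, three_taxon_pool):
        with pytest.raises(KeyError, match="nope"):
            sc.set_focal_rates(three_taxon_pool, ["nope"], [0.5])

    def test_duplicate_id_rejected(self, three_taxon_pool):
        with pytest.raises(ValueError, match="duplicate"):
            sc.set_focal_rates(three_taxon_pool, ["a", "a"], [0.5, 0.6])

    def test_focal_survive_rate_reassignment(self, three_taxon_pool):
        out = sc.set_focal_rates(three_taxon_pool, ["c"], [0.8])
        out = sc.assign_growth_rates(out)
        assert out.growth_rate[2] == 0.8


class TestSampleInoculum:
    def test_single_taxon_gets_everything(self, single_taxon_pool):
        inoc = sc.sample_inoculum(single_taxon_pool, 200_000, seed=0)
        assert inoc.counts.tolist() == [200_000]
        assert inoc.total == 200_000

    def test_seed_determinism(self, three_taxon_pool):
        a = sc.sample_inoculum(three_taxon_pool, 10_000, seed=42)
        b = sc.sample_inoculum(three_taxon_pool, 10_000, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_rare_taxon_zero_class_probability(self):
        # P(rare taxon absent) = (1 - 1e-5)^200000 ~ 0.135; Monte-Carlo check
        pool = sc.TaxonPool(("rare", "bulk"), np.array([1e-5, 1 - 1e-5]),
                            np.array([0.4, 0.4]))
        rng = np.random.default_rng(7)
        draws = rng.multinomial(200_000, pool.rel_abundance, size=10_000)
        frac_zero = np.mean(draws[:, 0] == 0)
        assert frac_zero == pytest.approx((1 - 1e-5) ** 200_000, abs=0.01)
        # and the API path draws from the same distribution
        inocs = [sc.sample_inoculum(pool, 200_000, seed=s) for s in range(200)]
        assert 0 <= np.mean([i.counts[0] == 0 for i in inocs]) <= 0.3

    def test_invalid_size_rejected(self, three_taxon_pool):
        with pytest.raises(ValueError):
            sc.sample_inoculum(three_taxon_pool, 0)


class TestSimulateBatch:
    def test_no_substrate_no_growth(self, single_taxon_pool):
        inoc = sc.Inoculum(np.array([1000]))
        state = sc.simulate_batch(inoc, single_taxon_pool, sc.GrowthParams(S0=0.0))
        assert state.counts.tolist() == [1000.0]
        assert state.substrate == 0.0

    def test_single_taxon_closed_form(self, single_taxon_pool, default_params):
        # all carbon consumed: N_final = N0 + Y*S0/c_cell, independent of kinetics
        inoc = sc.Inoculum(np.array([200_000]))
        state = sc.simulate_batch(inoc, single_taxon_pool, default_params)
        expected = 200_000 + 0.2 * 2e-4 / 2e-13
        assert state.total == pytest.approx(expected, rel=1e-3)

    def test_final_total_independent_of_kinetics(self, default_params):
        totals = []
        for mu, ks in [(0.05, 1e-6), (0.8, 1e-4)]:
            pool = sc.TaxonPool(("x",), np.array([1.0]), np.array([mu]))
            params = sc.GrowthParams(K_s=ks, Y=default_params.Y,
                                     c_cell=default_params.c_cell, S0=default_params.S0)
            totals.append(sc.simulate_batch(sc.Inoculum(np.array([10_000])), pool, params).total)
        assert totals[0] == pytest.approx(totals[1], rel=1e-3)

    def test_fast_grower_wins_share(self):
        pool = sc.TaxonPool(("fast", "slow"), np.array([0.5, 0.5]),
                            np.array([0.8, 0.1]))
        inoc = sc.Inoculum(np.array([1000, 1000]))
        state = sc.simulate_batch(inoc, pool, sc.GrowthParams(S0=1e-6))
        assert state.counts[0] > state.counts[1]

    def test_equal_rates_preserve_shares(self):
        pool = sc.TaxonPool(("p", "q"), np.array([0.3, 0.7]), np.array([0.3, 0.3]))
        inoc = sc.Inoculum(np.array([3000, 7000]))
        state = sc.simulate_batch(inoc, pool, sc.GrowthParams(S0=1e-6))
        shares = state.counts / state.total
        assert shares == pytest.approx([0.3, 0.7], rel=1e-3)

    def test_zero_start_stays_zero(self):
        pool = sc.TaxonPool(("x", "y"), np.array([0.5, 0.5]), np.array([0.4, 0.8]))
        inoc = sc.Inoculum(np.array([1000, 0]))
        state = sc.simulate_batch(inoc, pool, sc.GrowthParams(S0=1e-6))
        assert state.counts[1] == 0.0

    def test_agrees_with_euler_oracle(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(0.1, 0.8, size=5)
        pool = sc.TaxonPool(tuple("abcde"), np.full(5, 0.2), mu)
        n0 = np.array([500, 1500, 200, 900, 50])
        params = sc.GrowthParams(K_s=5e-8, S0=1e-6)
        state = sc.simulate_batch(sc.Inoculum(n0), pool, params)
        n_ref, s_ref, _ = euler_batch(n0, mu, params)
        assert state.counts == pytest.approx(n_ref, rel=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_mass_balance_random_params(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 6)
        pool = sc.TaxonPool(
            tuple(f"t{i}" for i in range(k)),
            rng.dirichlet(np.ones(k)),
            rng.uniform(0.05, 0.9, size=k),
        )
        params = sc.GrowthParams(
            K_s=10 ** rng.uniform(-8, -5),
            Y=rng.uniform(0.05, 0.5),
            c_cell=10 ** rng.uniform(-13.5, -12.5),
            S0=10 ** rng.uniform(-7, -4),
        )
        n0 = rng.integers(100, 10_000, size=k)
        state = sc.simulate_batch(sc.Inoculum(n0), pool, params)
        consumed = params.S0 - state.substrate
        gained = (state.total - n0.sum()) * params.c_cell / params.Y
        assert gained == pytest.approx(consumed, rel=1e-3)

    def test_total_monotone_in_s0(self, single_taxon_pool):
        inoc = sc.Inoculum(np.array([1000]))
        totals = [
            sc.simulate_batch(inoc, single_taxon_pool, sc.GrowthParams(S0=s0)).total
            for s0 in (1e-8, 1e-7, 1e-6)
        ]
        assert totals == sorted(totals)


class TestSubsampleCounts:
    def test_exact_depth_single_taxon(self):
        state = sc.CommunityState(np.array([5000.0]), 0.0, 1.0)
        sub = sc.subsample_counts(state, depth=5000, seed=0)
        assert sub.counts.tolist() == [5000]

    def test_binomial_moments(self):
        state = sc.CommunityState(np.array([1.8e8, 2e7]), 0.0, 1.0)
        n, p = 200_000, 0.1
        sd = np.sqrt(n * p * (1 - p))
        sub = sc.subsample_counts(state, depth=n, seed=123)
        assert abs(sub.counts[1] - n * p) < 3 * sd

    def test_depth_exceeding_size_rejected(self):
        state = sc.CommunityState(np.array([100.0]), 0.0, 1.0)
        with pytest.raises(ValueError, match="depth"):
            sc.subsample_counts(state, depth=200)

    def test_determinism(self):
        state = sc.CommunityState(np.array([1e6, 2e6, 3e6]), 0.0, 1.0)
        a = sc.subsample_counts(state, depth=1000, seed=9)
        b = sc.subsample_counts(state, depth=1000, seed=9)
        assert np.array_equal(a.counts, b.counts)


class TestReplicateEnsemble:
    def test_shapes_and_determinism(self, three_taxon_pool, default_params):
        kwargs = dict(n_replicates=3, seeds=[1, 2, 3], n_cells=10_000, depth=5_000)
        r1 = run_replicate_ensemble(three_taxon_pool, default_params, **kwargs)
        r2 = run_replicate_ensemble(three_taxon_pool, default_params, **kwargs)
        assert r1.counts.shape == (3, 3)
        assert r1.counts.equals(r2.counts)
        assert (r1.counts.sum(axis=1) == 5_000).all()

    def test_single_taxon_matches_closed_form(self, single_taxon_pool, default_params):
        res = run_replicate_ensemble(single_taxon_pool, default_params,
                                     n_replicates=1, seeds=[0])
        assert res.final_sizes[0] == pytest.approx(200_000 + 0.2 * 2e-4 / 2e-13, rel=1e-3)

    def test_seed_count_mismatch(self, three_taxon_pool, default_params):
        with pytest.raises(ValueError, match="seed"):
            run_replicate_ensemble(three_taxon_pool, default_params,
                                   n_replicates=2, seeds=[1])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n0=st.integers(min_value=10, max_value=100_000),
    log_s0=st.floats(min_value=-8.0, max_value=-4.0),
    mu=st.floats(min_value=0.01, max_value=1.0),
)
def test_single_taxon_stoichiometry_property(n0, log_s0, mu):
    """Final size equals inoculum plus yield-converted carbon, for any kinetics."""
    pool = sc.TaxonPool(("x",), np.array([1.0]), np.array([mu]))
    params = sc.GrowthParams(S0=10 ** log_s0)
    state = sc.simulate_batch(sc.Inoculum(np.array([n0])), pool, params)
    assert state.total == pytest.approx(n0 + params.Y * params.S0 / params.c_cell, rel=1e-3)
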