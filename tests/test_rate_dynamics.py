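import numpy as np
import pytest

from memcoev import (ChainState, ConfigurationError, ContactMap, InvalidInputError,
                     ModelParams, SimulationConfig, SiteClasses, TwoClassParams,
                     all_rates, equilibrate, site_rate, step, synthetic_contact_map)
from memcoev.rate_dynamics import baseline_rates


class TestSiteRate:
    def test_no_mutations_gives_baseline(self, band_map):
        state = ChainState.initial(band_map.L)
        params = ModelParams(r0=4e-4, J=0.02)
        assert site_rate(state, band_map, params, 3) == pytest.approx(4e-4)

    def test_neighbor_at_lag_zero(self, band_map):
        state = ChainState.initial(band_map.L)
        state.mutated[4] = True
        state.last_mutation[4] = state.time
        params = ModelParams(r0=4e-4, J=0.02)
        assert site_rate(state, band_map, params, 3) == pytest.approx(4e-4 + 0.02)

    def test_neighbor_at_unit_lag(self, band_map):
        state = ChainState.initial(band_map.L)
        state.time = 5.0
        state.mutated[4] = True
        state.last_mutation[4] = 4.0
        params = ModelParams(r0=4e-4, J=0.02)
        expected = 4e-4 + 0.02 * np.exp(-1.0)
        assert site_rate(state, band_map, params, 3) == pytest.approx(expected, rel=1e-12)

    def test_non_contacting_mutation_ignored(self, band_map):
        state = ChainState.initial(band_map.L)
        state.mutated[10] = True
        state.last_mutation[10] = 0.0
        params = ModelParams(r0=4e-4, J=0.02)
        assert site_rate(state, band_map, params, 3) == pytest.approx(4e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_matches_naive(self, seed):
        """The cached/vectorized rate equals naive re-summation at 1e-9."""
        rng = np.random.default_rng(seed)
        cmap, classes = synthetic_contact_map(40, [(5, 25)], 3.0, 2, seed=seed)
        state = ChainState.initial(cmap.L)
        state.time = 10.0
        state.mutated = rng.random(cmap.L) < 0.5
        state.last_mutation = np.where(state.mutated, rng.uniform(0, 10, cmap.L), 0.0)
        for params, cls in [
            (ModelParams(r0=4e-4, J=0.02), None),
            (TwoClassParams(r0_unstructured=0.01, J=0.021), classes),
        ]:
            fast = all_rates(state, cmap, params, cls)
            slow = np.array([site_rate(state, cmap, params, i, cls) for i in range(cmap.L)])
            np.testing.assert_allclose(fast, slow, rtol=1e-9)

    def test_rate_never_below_baseline(self):
        rng = np.random.default_rng(1)
        cmap, _ = synthetic_contact_map(30, (), 2.0, 2, seed=1)
        state = ChainState.initial(cmap.L)
        state.time = 3.0
        state.mutated = rng.random(30) < 0.7
        state.last_mutation = np.where(state.mutated, rng.uniform(0, 3, 30), 0.0)
        rates = all_rates(state, cmap, ModelParams(r0=1e-3, J=0.05))
        assert (rates >= 1e-3 - 1e-15).all()


class TestTwoClassBaseline:
    def test_structured_sites_have_zero_baseline(self):
        classes = SiteClasses(np.array([True, False, True]))
        rates = baseline_rates(TwoClassParams(r0_unstructured=0.01, J=0.02), 3, classes)
        np.testing.assert_allclose(rates, [0.0, 0.01, 0.0])

    def test_classes_required(self):
        with pytest.raises(InvalidInputError):
            baseline_rates(TwoClassParams(), 3, None)


class TestStep:
    def test_zero_rates_never_substitute(self, empty_map):
        state = ChainState.initial(empty_map.L)
        config = SimulationConfig(dt=0.1)
        rng = np.random.default_rng(0)
        params = ModelParams(r0=0.0, J=0.0)
        for _ in range(100):
            assert step(state, empty_map, params, config, rng).size == 0
        assert state.counts.sum() == 0

    def test_single_site_bernoulli_frequency(self):
        """p = r0*dt per step: frequency matches Bernoulli(0.05) within 3 SE."""
        cmap = ContactMap(np.zeros((1, 1), dtype=bool))
        config = SimulationConfig(dt=0.1)
        params = ModelParams(r0=0.5, J=0.0)
        state = ChainState.initial(1)
        rng = np.random.default_rng(7)
        n = 20000
        for _ in range(n):
            step(state, cmap, params, config, rng)
        p_hat = state.counts[0] / n
        assert abs(p_hat - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_neighbor_probability_after_substitution(self, band_map):
        """Right after a substitution, a contacting site has p = (r0+J)*dt."""
        config = SimulationConfig(dt=0.01)
        params = ModelParams(r0=4e-4, J=0.02)
        state = ChainState.initial(band_map.L)
        # force a substitution at site 5 by stepping with certainty there
        state.mutated[5] = True
        state.time += config.dt
        state.last_mutation[5] = state.time
        rates = all_rates(state, band_map, params)
        assert rates[6] * config.dt == pytest.approx((4e-4 + 0.02) * config.dt)

    def test_oversized_dt_rejected(self, empty_map):
        state = ChainState.initial(empty_map.L)
        config = SimulationConfig(dt=3.0)
        with pytest.raises(ConfigurationError):
            step(state, empty_map, ModelParams(r0=0.5, J=0.0), config,
                 np.random.default_rng(0))


class TestEquilibrate:
    def test_zero_time_is_pristine(self, band_map):
        config = SimulationConfig(equilibration_time=0.0)
        state = equilibrate(band_map, ModelParams(), config, np.random.default_rng(0))
        assert not state.mutated.any()
        assert state.counts.sum() == 0
        assert state.time == 0.0

    def test_counts_reset_but_lags_preserved(self):
        cmap, _ = synthetic_contact_map(50, (), 2.0, 2, seed=2)
        config = SimulationConfig(dt=0.01, equilibration_time=20.0)
        state = equilibrate(cmap, ModelParams(r0=0.2, J=0.02), config,
                            np.random.default_rng(3))
        assert state.time == 0.0
        assert state.counts.sum() == 0
        assert state.mutated.any()
        lags = state.lags()
        assert (lags[state.mutated] >= 0).all()
        assert (lags[state.mutated] <= 20.0 + 1e-9).all()

    def test_exponential_waiting_time_lags(self):
        """With J=0 the lag CDF at 1 memory-time unit is 1 - exp(-r0)."""
        cmap = ContactMap(np.zeros((2000, 2000), dtype=bool))
        config = SimulationConfig(dt=0.01, equilibration_time=200.0)
        r0 = 0.05
        state = equilibrate(cmap, ModelParams(r0=r0, J=0.0), config,
                            np.random.default_rng(11))
        frac = (state.lags() < 1.0).mean()
        p = 1 - np.exp(-r0)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / cmap.L)

    def test_stationarity_of_total_rate(self):
        """Mean total rate over the two halves of a long run agrees within 3 SE."""
        cmap, _ = synthetic_contact_map(100, (), 3.0, 2, seed=4)
        params = ModelParams(r0=0.05, J=0.02)
        config = SimulationConfig(dt=0.01)
        halves = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            state = equilibrate(cmap, params,
                                SimulationConfig(dt=0.01, equilibration_time=60.0), rng)
            totals = []
            for _ in range(10000):  # 100 further memory-time units
                totals.append(all_rates(state, cmap, params).sum())
                step(state, cmap, params, config, rng)
            totals = np.array(totals)
            halves.append((totals[:5000].mean(), totals[5000:].mean()))
        first, second = np.array(halves).T
        diff = second - first
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se
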