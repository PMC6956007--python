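"""Bernoulli and thinning spike samplers, superimposition, serialization."""

import numpy as np
import pytest
from scipy import stats

import fnspike as fs
from fnspike.errors import InvalidInputError
from fnspike.sampler import bernoulli_fire_probabilities

GRID = fs.TimeGrid(30.0, 0.01)


def constant_rate(value, grid=GRID):
    return fs.RateTrajectory(grid, np.full(grid.n_nodes, value))


class TestSpikeTrain:
    def test_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            fs.SpikeTrain(np.array([2.0, 1.0]), 30.0)
        with pytest.raises(InvalidInputError):
            fs.SpikeTrain(np.array([1.0, 31.0]), 30.0)

    def test_counting_function(self):
        train = fs.SpikeTrain(np.array([1.0, 3.0, 6.0]), 30.0)
        np.testing.assert_array_equal(train.counting_function([0.5, 3.0, 30.0]), [0, 2, 3])


class TestBernoulli:
    def test_per_bin_probability_is_rate_times_dt(self):
        p = bernoulli_fire_probabilities(constant_rate(0.5))
        assert np.all(p == pytest.approx(0.005))

    def test_probability_clipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="fnspike.sampler"):
            p = bernoulli_fire_probabilities(constant_rate(150.0))
        assert np.all(p == 1.0)
        assert any("degraded" in r.message for r in caplog.records)

    def test_near_zero_rate_gives_empty_train(self):
        rate = constant_rate(1e-30)
        train = fs.bernoulli_sample(rate, np.random.default_rng(0))
        assert train.count == 0

    def test_mean_count_matches_rate_integral(self):
        rate = constant_rate(0.1)  # lambda = 3 over 30 ms
        rng = np.random.default_rng(42)
        counts = [fs.bernoulli_sample(rate, rng).count for _ in range(10_000)]
        assert np.mean(counts) == pytest.approx(3.0, abs=3 * np.sqrt(3.0 / 10_000))

    def test_spikes_sit_on_grid_nodes(self):
        rate = constant_rate(5.0)
        train = fs.bernoulli_sample(rate, np.random.default_rng(1))
        nodes = np.rint(train.times / GRID.dt)
        np.testing.assert_allclose(nodes * GRID.dt, train.times, atol=1e-12)


class TestThinning:
    def test_constant_rate_counts_are_poisson(self):
        """Chi-square goodness of fit of thinned counts against Poisson(r*T)."""
        rate = constant_rate(0.2)  # lambda = 6
        rng = np.random.default_rng(5)
        counts = np.array([fs.thinning_sample(rate, rng).count for _ in range(10_000)])
        kmax = 14
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax + 1), 6.0)
        pmf[kmax] = 1.0 - pmf[:kmax].sum()
        chi = stats.chisquare(observed, pmf * counts.size)
        assert chi.pvalue > 0.01

    def test_zero_rate_empty(self):
        train = fs.thinning_sample(constant_rate(1e-300), np.random.default_rng(0))
        assert train.count == 0

    def test_agrees_with_bernoulli_in_mean(self, default_grid):
        """Both samplers target the same inhomogeneous Poisson intensity."""
        spec = fs.random_stimulus(5, 100.0, 1 / 3, np.random.default_rng(2))
        rate = fs.integrate_rate(fs.NOMINAL_PARAMS, spec.waveform(default_grid), default_grid)
        rng = np.random.default_rng(3)
        n = 2000
        cb = np.array([fs.bernoulli_sample(rate, rng).count for _ in range(n)])
        ct = np.array([fs.thinning_sample(rate, rng).count for _ in range(n)])
        se = np.sqrt(cb.var() / n + ct.var() / n)
        assert abs(cb.mean() - ct.mean()) < 3 * se
        assert cb.mean() == pytest.approx(rate.mean_count, abs=3 * np.sqrt(cb.var() / n))

    def test_rate_bound_must_dominate(self):
        with pytest.raises(InvalidInputError):
            fs.thinning_sample(constant_rate(2.0), np.random.default_rng(0), rate_bound=1.0)


class TestISIs:
    def test_constant_rate_isis_exponential(self):
        """Two-sample KS of sampled ISIs against exponential draws."""
        grid = fs.TimeGrid(3000.0, 0.01)
        rate = fs.RateTrajectory(grid, np.full(grid.n_nodes, 0.5))
        rng = np.random.default_rng(8)
        train = fs.bernoulli_sample(rate, rng)
        isis = np.diff(train.times)
        assert isis.size > 1000
        ref = rng.exponential(2.0, isis.size)
        assert stats.ks_2samp(isis, ref).pvalue > 0.01


class TestSuperimpose:
    def test_offset_and_merge(self):
        t1 = fs.SpikeTrain(np.array([1.0, 2.0]), 30.0)
        t2 = fs.SpikeTrain(np.array([0.5]), 30.0)
        np.testing.assert_allclose(fs.superimpose([t1, t2]), [1.0, 2.0, 30.5])

    def test_identity_and_empty(self):
        t1 = fs.SpikeTrain(np.array([1.0, 2.0]), 30.0)
        np.testing.assert_allclose(fs.superimpose([t1]), [1.0, 2.0])
        assert fs.superimpose([]).size == 0

    def test_mixed_windows_rejected(self):
        t1 = fs.SpikeTrain(np.array([1.0]), 30.0)
        t2 = fs.SpikeTrain(np.array([1.0]), 20.0)
        with pytest.raises(InvalidInputError):
            fs.superimpose([t1, t2])

    def test_total_count_preserved(self):
        rng = np.random.default_rng(4)
        trains = [
            fs.bernoulli_sample(constant_rate(1.0), rng) for _ in range(5)
        ]
        merged = fs.superimpose(trains)
        assert merged.size == sum(t.count for t in trains)
        assert np.all(np.diff(merged) >= 0)


class TestSerialization:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        trains = [fs.bernoulli_sample(constant_rate(0.8), rng) for _ in range(3)]
        path = tmp_path / "spikes.csv"
        fs.sampler.save_spike_trains_csv(trains, path)
        back = fs.sampler.load_spike_trains_csv(path, 30.0, n_trials=3)
        for orig, again in zip(trains, back):
            np.testing.assert_array_equal(orig.times, again.times)

    def test_json_round_trip(self):
        rng = np.random.default_rng(6)
        trains = [fs.bernoulli_sample(constant_rate(0.8), rng) for _ in range(3)]
        back = fs.sampler.spike_trains_from_json(fs.sampler.spike_trains_to_json(trains))
        for orig, again in zip(trains, back):
            np.testing.assert_array_equal(orig.times, again.times)
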