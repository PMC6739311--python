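import numpy as np
import pytest

from bowtienet import (
    DirectedNetwork,
    MagnetizationSeries,
    SpinSystem,
    decompose,
    estimate_critical_temperature,
    generate_directed_er,
    heat_bath_sweep,
    pair_correlation_chi,
    simulate_ising,
)
from bowtienet.ising import _heat_bath_probability

from conftest import net_from_links


def core_subgraph(net):
    """Induced subgraph on the CORE, relabeled to 0..n_core-1."""
    core = decompose(net).core
    relabel = {node: k for k, node in enumerate(core.tolist())}
    core_set = set(core.tolist())
    links = [
        (relabel[t], relabel[h])
        for t, h in zip(net.tails.tolist(), net.heads.tolist())
        if t in core_set and h in core_set
    ]
    return net_from_links(core.size, links), core


class TestHeatBathRule:
    def test_zero_temperature_limits(self):
        assert _heat_bath_probability(3, 0.0) == 1.0
        assert _heat_bath_probability(-2, 0.0) == 0.0
        assert _heat_bath_probability(0, 0.0) == 0.5

    def test_zero_field_is_fair_coin_at_any_temperature(self):
        for T in (0.0, 0.5, 2.0, 100.0):
            assert _heat_bath_probability(0, T) == 0.5

    def test_unit_field_at_t2(self):
        # p = 1 / (1 + exp(-2*1/2)) = 1 / (1 + 1/e)
        p = _heat_bath_probability(1, 2.0)
        assert p == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)
        assert p == pytest.approx(0.7311, abs=1e-4)
        # empirical frequency of the acceptance draw over 1e5 updates
        rng = np.random.default_rng(0)
        freq = np.mean(rng.random(100_000) < p)
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(freq - p) <= 3 * se

    def test_sweep_on_isolated_node_is_fair_coin(self):
        # single node, no in-links: every update is a fair coin
        net = DirectedNetwork(1, [], [])
        rng = np.random.default_rng(1)
        system = SpinSystem(network=net, temperature=1.0, spins=np.array([1]))
        ups = 0
        n_sweeps = 2000
        for _ in range(n_sweeps):
            system = heat_bath_sweep(system, rng)
            ups += system.spins[0] == 1
        se = np.sqrt(0.25 / n_sweeps)
        assert abs(ups / n_sweeps - 0.5) <= 3 * se

    def test_sweep_returns_new_system(self):
        net = net_from_links(2, [(0, 1)])
        system = SpinSystem(network=net, temperature=0.0, spins=np.array([1, -1]))
        out = heat_bath_sweep(system, np.random.default_rng(0))
        assert out is not system
        assert system.spins.tolist() == [1, -1]  # input untouched


class TestSimulate:
    def test_aligned_zero_t_core_is_absorbing(self):
        net, _ = core_subgraph(generate_directed_er(2000, 2.0, seed=0))
        system = SpinSystem(
            network=net, temperature=0.0, spins=np.ones(net.n_nodes, dtype=np.int8)
        )
        series = simulate_ising(system, 10, 50, seed=1)
        assert np.all(series.m["all"] == 1.0)

    def test_two_cycle_orders_at_low_temperature(self):
        net = net_from_links(2, [(0, 1), (1, 0)])  # imported-style 2-cycle
        series = simulate_ising(
            SpinSystem(network=net, temperature=0.1), 200, 2000, seed=2
        )
        assert series.time_mean_abs("all") > 0.99

    def test_isolated_node_mean_magnetization_vanishes(self):
        net = DirectedNetwork(1, [], [])
        series = simulate_ising(
            SpinSystem(network=net, temperature=5.0), 100, 20_000, seed=3
        )
        # per-sweep samples are nearly independent fair coins
        assert abs(series.time_mean("all")) < 4 / np.sqrt(20_000)

    def test_source_node_up_frequency_is_half(self):
        # in-degree-0 node: h = 0 at every update, so it holds spin up
        # half the time at any temperature
        net = net_from_links(2, [(0, 1)])
        for T, seed in ((0.0, 4), (2.0, 5)):
            series = simulate_ising(
                SpinSystem(network=net, temperature=T), 100, 50_000,
                subsets={"source": [0]}, seed=seed,
            )
            up = (series.m["source"] > 0).mean()
            # site 0 refreshes with prob 3/4 per sweep: mild autocorrelation
            se = np.sqrt(0.25 / 50_000) * np.sqrt((1 + 0.25) / (1 - 0.25))
            assert abs(up - 0.5) <= 3 * se

    def test_determinism(self):
        net = generate_directed_er(200, 1.5, seed=0)
        a = simulate_ising(SpinSystem(net, 1.0), 50, 50, seed=7)
        b = simulate_ising(SpinSystem(net, 1.0), 50, 50, seed=7)
        assert np.array_equal(a.m["all"], b.m["all"])
        c = simulate_ising(SpinSystem(net, 1.0), 50, 50, seed=8)
        assert not np.array_equal(a.m["all"], c.m["all"])

    def test_spin_flip_symmetry_with_symmetric_draw(self):
        net = generate_directed_er(300, 1.8, seed=1)
        rng = np.random.default_rng(9)
        spins = np.where(rng.random(300) < 0.5, 1, -1).astype(np.int8)
        kwargs = dict(
            sweeps_transient=20, sweeps_observe=100, seed=13, symmetric_draw=True
        )
        up = simulate_ising(SpinSystem(net, 0.7, spins=spins), **kwargs)
        down = simulate_ising(SpinSystem(net, 0.7, spins=-spins), **kwargs)
        assert np.array_equal(up.m["all"], -down.m["all"])

    def test_magnetization_bounds(self):
        net = generate_directed_er(500, 1.9, seed=2)
        series = simulate_ising(SpinSystem(net, 0.5), 100, 200, seed=0)
        assert np.all(np.abs(series.m["all"]) <= 1.0)


class TestPairCorrelationChi:
    @staticmethod
    def _series(values):
        values = np.asarray(values, dtype=float)
        return MagnetizationSeries(
            sweeps=np.arange(values.size),
            m={"x": values},
            subset_sizes={"x": 50},
        )

    def test_frozen_configuration(self):
        assert pair_correlation_chi(self._series([1.0] * 8), 50, "x") == (
            pytest.approx(0.0, abs=1e-24)
        )

    def test_two_point_variance(self):
        series = self._series([-0.1, 0.1] * 6)
        assert pair_correlation_chi(series, 50, "x") == pytest.approx(0.5)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            pair_correlation_chi(self._series([0.1]), 50, "x")


class TestCriticalTemperature:
    T_GRID = np.arange(0.1, 2.1, 0.2)

    def test_tc_increases_with_core_density(self):
        estimates = {}
        for c in (1.1, 2.0):
            sub, _ = core_subgraph(generate_directed_er(20_000, c, seed=0))
            estimates[c] = estimate_critical_temperature(
                sub, np.arange(sub.n_nodes), self.T_GRID, 300, 300, seed=1
            )
        assert estimates[2.0].t_c > estimates[1.1].t_c
        # fully ordered in the T -> 0 limit regardless of connectivity
        for est in estimates.values():
            assert est.mean_abs_m[0] > 0.95

    def test_in_component_lowers_tc(self):
        net = generate_directed_er(20_000, 2.0, seed=0)
        sub, core = core_subgraph(net)
        without = estimate_critical_temperature(
            sub, np.arange(sub.n_nodes), self.T_GRID, 300, 300, seed=1
        )
        with_in = estimate_critical_temperature(
            net, core, self.T_GRID, 300, 300, seed=1
        )
        assert with_in.t_c < without.t_c

    def test_in_component_suppresses_order_near_percolation(self):
        # close to the percolation point the IN component wipes out CORE
        # magnetization at every temperature
        net = generate_directed_er(20_000, 1.1, seed=0)
        sub, core = core_subgraph(net)
        lowest = float(self.T_GRID[0])
        # the sparse 655-node core coarsens slowly: give it a long transient
        ordered = simulate_ising(
            SpinSystem(sub, lowest), 2000, 300,
            subsets={"core": np.arange(sub.n_nodes)}, seed=1,
        )
        disrupted = simulate_ising(
            SpinSystem(net, lowest), 2000, 300, subsets={"core": core}, seed=1
        )
        assert ordered.time_mean_abs("core") > 0.9
        assert disrupted.time_mean_abs("core") < 0.2

    def test_removing_in_enhances_core_magnetization_pointwise(self):
        net = generate_directed_er(10_000, 2.0, seed=3)
        sub, core = core_subgraph(net)
        for T in (0.1, 0.5, 0.9):
            without = simulate_ising(
                SpinSystem(sub, T), 200, 200,
                subsets={"core": np.arange(sub.n_nodes)}, seed=4,
            )
            with_in = simulate_ising(
                SpinSystem(net, T), 200, 200, subsets={"core": core}, seed=4
            )
            assert (
                without.time_mean_abs("core")
                >= with_in.time_mean_abs("core") - 0.05
            )

    def test_boundary_peak_is_error(self):
        sub, _ = core_subgraph(generate_directed_er(5_000, 2.0, seed=0))
        grid = np.array([1.6, 1.8, 2.0])  # entirely above the transition
        with pytest.raises(ValueError, match="outside grid"):
            estimate_critical_temperature(
                sub, np.arange(sub.n_nodes), grid, 100, 100, seed=5
            )
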