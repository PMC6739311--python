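"""IN-node removal experiments.

Fractions f of the IN component are removed uniformly at random and the
CORE's ordering (r_CORE or m_CORE) and pair-correlation response
(C_CORE or chi_CORE) are measured as functions of f.  Removing IN nodes
cannot break the strongly connected CORE, and all measurements use the
ORIGINAL CORE node set: re-partitioning after each removal would
silently change the observable being plotted against f.

A critical removal fraction is reported where the pair-correlation
curve has an interior peak that exceeds both endpoints by at least two
pooled standard errors; smooth decaying curves (already-ordered
networks) yield ``None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bowtie import BowTiePartition, NodeClass
from .ising import SpinSystem, pair_correlation_chi, simulate_ising
from .kuramoto import OscillatorSystem, pair_correlation_C, simulate_kuramoto
from .network import DirectedNetwork

__all__ = [
    "RemovalSweepResult",
    "remove_in_fraction",
    "removal_sweep",
    "detect_critical_fraction",
]


@dataclass
class RemovalSweepResult:
    """Ensemble-averaged CORE observables per removal fraction."""

    f_grid: np.ndarray
    order_mean: np.ndarray  # mean r_CORE (kuramoto) or |m|_CORE (ising)
    order_se: np.ndarray
    pair_mean: np.ndarray  # mean C_CORE or chi_CORE
    pair_se: np.ndarray
    n_seeds: int
    dynamics: str


def remove_in_fraction(
    net: DirectedNetwork,
    partition: BowTiePartition,
    f: float,
    seed: int | None = None,
) -> DirectedNetwork:
    """Remove floor(f * N_IN) IN nodes (at least one when f > 0),
    sampled uniformly without replacement, together with all their links.

    The returned network keeps the original node ids (removed nodes
    become isolated), so the pre-removal partition stays addressable and
    the CORE node set is unchanged.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("removal fraction must lie in [0, 1]")
    in_nodes = partition.nodes_in(NodeClass.IN)
    n_remove = int(np.floor(f * in_nodes.size))
    if f > 0 and in_nodes.size >= 1 and n_remove == 0:
        n_remove = 1
    if n_remove == 0:
        return DirectedNetwork(net.n_nodes, net.tails, net.heads, validate=False)
    rng = np.random.default_rng(seed)
    removed = rng.choice(in_nodes, size=n_remove, replace=False)
    return net.without_nodes(removed)


def _run_kuramoto(net, core, params, seed):
    system = OscillatorSystem(network=net, coupling=params.get("coupling", 10.0))
    series = simulate_kuramoto(
        system,
        dt=params.get("dt"),
        t_transient=params.get("t_transient", 200.0),
        t_observe=params.get("t_observe", 200.0),
        sample_every=params.get("sample_every", 0.5),
        subsets={"core": core},
        seed=seed,
    )
    return series.time_mean("core"), pair_correlation_C(series, core.size, "core")


def _run_ising(net, core, params, seed):
    system = SpinSystem(network=net, temperature=params.get("temperature", 0.0))
    series = simulate_ising(
        system,
        sweeps_transient=params.get("sweeps_transient", 1000),
        sweeps_observe=params.get("sweeps_observe", 1000),
        subsets={"core": core},
        seed=seed,
    )
    return series.time_mean_abs("core"), pair_correlation_chi(
        series, core.size, "core"
    )


def removal_sweep(
    net: DirectedNetwork,
    partition: BowTiePartition,
    dynamics: str,
    f_grid,
    params: dict | None = None,
    seeds=(0,),
) -> RemovalSweepResult:
    """For each f and seed: remove IN nodes, run the chosen dynamics, and
    record the steady-state CORE ordering and pair correlation.

    CORE membership is fixed to the pre-removal partition throughout.
    The per-seed removal, initial conditions, and dynamics all derive
    from that seed, so the sweep is reproducible.
    """
    if dynamics not in ("kuramoto", "ising"):
        raise ValueError("dynamics must be 'kuramoto' or 'ising'")
    run = _run_kuramoto if dynamics == "kuramoto" else _run_ising
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(np.diff(f_grid) <= 0):
        raise ValueError("f_grid must be strictly increasing")
    params = params or {}
    core = partition.core
    if core.size == 0:
        raise ValueError("partition has an empty CORE")
    seeds = list(seeds)

    order = np.empty((f_grid.size, len(seeds)))
    pair = np.empty((f_grid.size, len(seeds)))
    for i, f in enumerate(f_grid):
        for j, seed in enumerate(seeds):
            remnant = remove_in_fraction(net, partition, float(f), seed=seed)
            order[i, j], pair[i, j] = run(remnant, core, params, seed)

    def _se(a):
        if a.shape[1] < 2:
            return np.zeros(a.shape[0])
        return a.std(axis=1, ddof=1) / np.sqrt(a.shape[1])

    return RemovalSweepResult(
        f_grid=f_grid,
        order_mean=order.mean(axis=1),
        order_se=_se(order),
        pair_mean=pair.mean(axis=1),
        pair_se=_se(pair),
        n_seeds=len(seeds),
        dynamics=dynamics,
    )


def detect_critical_fraction(sweep: RemovalSweepResult) -> float | None:
    """Location of a significant interior peak of the pair-correlation
    curve, or None when the curve has no such peak.

    The peak must exceed BOTH endpoints by at least two pooled standard
    errors, so sampling bumps on a monotone curve do not trigger.
    """
    if sweep.f_grid.size < 5:
        raise ValueError("need at least 5 grid points to detect a peak")
    interior = slice(1, -1)
    k = 1 + int(np.argmax(sweep.pair_mean[interior]))
    peak, peak_se = sweep.pair_mean[k], sweep.pair_se[k]
    for end in (0, -1):
        margin = 2.0 * np.hypot(peak_se, sweep.pair_se[end])
        if peak - sweep.pair_mean[end] < margin:
            return None
    return float(sweep.f_grid[k])
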