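"""End-to-end study orchestration: structure-table rows and onset scans.

Defaults are desk-scale; the full-study scale (N = 1e5, 50-network
ensembles, K = 10) is reachable through :class:`StudyConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .bowtie import NodeClass, decompose, external_internal_ratio, link_census
from .ising import SpinSystem, simulate_ising
from .kuramoto import OscillatorSystem, simulate_kuramoto
from .network import generate_directed_er
from .theory import (
    JointDegreeDistribution,
    core_fraction_theory,
    in_core_link_fraction_theory,
    source_fraction_theory,
)

__all__ = [
    "StudyConfig",
    "StructureRow",
    "OnsetScanResult",
    "reproduce_structure_row",
    "onset_scan",
]


@dataclass
class StudyConfig:
    """Knobs for ensemble experiments.

    ``seeds`` must provide at least ``ensemble_size`` entries; the first
    ``ensemble_size`` are used, one per network realization.
    """

    n_nodes: int = 10_000
    mean_in_degree: float = 1.5
    mean_in_degree_grid: list[float] = field(
        default_factory=lambda: [round(1.0 + 0.1 * k, 1) for k in range(11)]
    )
    ensemble_size: int = 5
    seeds: list[int] = field(default_factory=lambda: list(range(50)))
    # Kuramoto
    coupling: float = 10.0
    dt: float | None = None
    t_transient: float = 200.0
    t_observe: float = 200.0
    sample_every: float = 0.5
    # Ising
    temperature: float = 0.0
    sweeps_transient: int = 1000
    sweeps_observe: int = 1000
    # onset criterion: observable must exceed noise_floor_multiplier x floor
    noise_floor_multiplier: float = 3.0

    def __post_init__(self):
        if not self.mean_in_degree_grid:
            raise ValueError("mean_in_degree_grid must be nonempty")
        if len(self.seeds) < self.ensemble_size:
            raise ValueError("need at least ensemble_size seeds")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def manifest(self) -> dict:
        data = asdict(self)
        data["package_version"] = __version__
        payload = json.dumps(data, sort_keys=True)
        data["manifest_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:12]
        return data


@dataclass
class StructureRow:
    """Ensemble summary of the bow-tie census at one (n, c), with the
    matching theory predictions alongside."""

    n_nodes: int
    mean_in_degree: float
    n_networks: int
    source_fraction: float
    source_fraction_se: float
    core_fraction: float
    core_fraction_se: float
    core_core_link_fraction: float
    core_core_link_fraction_se: float
    external_internal_ratio: float | None
    external_internal_ratio_se: float | None
    theory_source_fraction: float
    theory_core_fraction: float
    theory_in_core_link_fraction: float


def reproduce_structure_row(config: StudyConfig) -> StructureRow:
    """Generate an ensemble at (n, c), decompose, census, and average."""
    n, c = config.n_nodes, config.mean_in_degree
    src, core, lcc, ratio = [], [], [], []
    for seed in config.seeds[: config.ensemble_size]:
        net = generate_directed_er(n, c, seed)
        part = decompose(net)
        census = link_census(net, part)
        sizes = part.class_sizes()
        src.append(part.sources.size / n)
        core.append(sizes[NodeClass.CORE] / n)
        total = max(census.total_links, 1)
        lcc.append(census.l_core_core / total)
        if census.l_core_core > 0:
            ratio.append(external_internal_ratio(census))

    def _mean_se(values):
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            return None, None
        se = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0
        return float(arr.mean()), float(se)

    src_m, src_se = _mean_se(src)
    core_m, core_se = _mean_se(core)
    lcc_m, lcc_se = _mean_se(lcc)
    ratio_m, ratio_se = _mean_se(ratio)
    dist = JointDegreeDistribution.poisson(c)
    return StructureRow(
        n_nodes=n,
        mean_in_degree=c,
        n_networks=config.ensemble_size,
        source_fraction=src_m,
        source_fraction_se=src_se,
        core_fraction=core_m,
        core_fraction_se=core_se,
        core_core_link_fraction=lcc_m,
        core_core_link_fraction_se=lcc_se,
        external_internal_ratio=ratio_m,
        external_internal_ratio_se=ratio_se,
        theory_source_fraction=source_fraction_theory(dist),
        theory_core_fraction=core_fraction_theory(dist),
        theory_in_core_link_fraction=in_core_link_fraction_theory(dist),
    )


@dataclass
class OnsetScanResult:
    dynamics: str
    grid: np.ndarray
    curve: np.ndarray  # ensemble-mean ordering observable per grid point
    curve_se: np.ndarray
    noise_floor: float
    threshold: float
    onset: float | None  # smallest grid c whose mean exceeds the threshold
    uncertainty: float  # one grid step


def onset_scan(config: StudyConfig, dynamics: str) -> OnsetScanResult:
    """Sweep the mean in-degree and locate the ordering onset.

    For each grid value the chosen dynamics run on ``ensemble_size``
    fresh networks; the ordering observable is the time-averaged
    whole-network r (Kuramoto) or mean |m| (Ising, T from config).  The
    onset is the smallest grid point whose ensemble mean exceeds
    ``noise_floor_multiplier`` times the finite-size floor (2/sqrt(n)
    for r, 3/sqrt(n) for |m|).
    """
    if dynamics not in ("kuramoto", "ising"):
        raise ValueError("dynamics must be 'kuramoto' or 'ising'")
    n = config.n_nodes
    floor = 2.0 / np.sqrt(n) if dynamics == "kuramoto" else 3.0 / np.sqrt(n)
    threshold = config.noise_floor_multiplier * floor
    grid = np.asarray(config.mean_in_degree_grid, dtype=float)
    curve = np.empty(grid.size)
    curve_se = np.empty(grid.size)
    seeds = config.seeds[: config.ensemble_size]
    for i, c in enumerate(grid):
        values = []
        for seed in seeds:
            net = generate_directed_er(n, float(c), seed)
            if dynamics == "kuramoto":
                series = simulate_kuramoto(
                    OscillatorSystem(network=net, coupling=config.coupling),
                    dt=config.dt,
                    t_transient=config.t_transient,
                    t_observe=config.t_observe,
                    sample_every=config.sample_every,
                    seed=seed,
                )
                values.append(series.time_mean("all"))
            else:
                series = simulate_ising(
                    SpinSystem(network=net, temperature=config.temperature),
                    sweeps_transient=config.sweeps_transient,
                    sweeps_observe=config.sweeps_observe,
                    seed=seed,
                )
                values.append(series.time_mean_abs("all"))
        arr = np.asarray(values)
        curve[i] = arr.mean()
        curve_se[i] = arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0

    above = np.flatnonzero(curve > threshold)
    onset = float(grid[above[0]]) if above.size else None
    step = float(np.diff(grid).max()) if grid.size > 1 else 0.0
    return OnsetScanResult(
        dynamics=dynamics,
        grid=grid,
        curve=curve,
        curve_se=curve_se,
        noise_floor=floor,
        threshold=threshold,
        onset=onset,
        uncertainty=step,
    )
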