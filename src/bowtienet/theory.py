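"""Percolation theory for uncorrelated directed random networks.

Predicts the fraction of SOURCE nodes, the fraction of CORE nodes and
the expected number of IN-to-CORE links from a joint in/out-degree
distribution, via the branching probabilities

* ``x_c`` — probability that an in-link comes from a finite in-component,
* ``y_c`` — probability that an out-link leads to a finite out-component,

each the smallest fixed point in [0, 1] of its self-consistency
equation.  For independent Poisson(c) in- and out-degrees both reduce to
``u = exp(-c (1 - u))``, with u = 1 (no giant component) for c <= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "JointDegreeDistribution",
    "BranchingProbabilities",
    "solve_branching_probabilities",
    "source_fraction_theory",
    "in_core_links_theory",
    "in_core_link_fraction_theory",
    "core_fraction_theory",
]

_TAIL_TOL = 1e-10
_RESIDUAL_TOL = 1e-12


@dataclass
class BranchingProbabilities:
    x_c: float  # in-link from a finite in-component
    y_c: float  # out-link to a finite out-component


class JointDegreeDistribution:
    """Joint distribution P(q_in, q_out) as a finite table.

    Rows index q_in, columns q_out.  The table is normalized at
    construction; a warning is raised if the truncated tail mass of a
    Poisson construction exceeds 1e-10.  Correlated (non-product) tables
    are accepted but the theory treats them with the same edge-following
    equations, which is exact for uncorrelated networks only; such
    tables are flagged experimental.
    """

    def __init__(self, table: np.ndarray, *, _from_poisson: float | None = None):
        table = np.asarray(table, dtype=float)
        if table.ndim != 2:
            raise ValueError("table must be 2-D (q_in rows, q_out columns)")
        if np.any(table < 0):
            raise ValueError("probabilities must be nonnegative")
        total = table.sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"table mass {total} is not 1 within tolerance")
        self.table = table / total
        self.poisson_mean = _from_poisson
        self.p_in = self.table.sum(axis=1)
        self.p_out = self.table.sum(axis=0)
        if _from_poisson is None:
            outer = np.outer(self.p_in, self.p_out)
            if not np.allclose(outer, self.table, atol=1e-12):
                warnings.warn(
                    "correlated joint degree table: theory assumes in/out "
                    "independence and is experimental here",
                    stacklevel=2,
                )

    @classmethod
    def poisson(cls, c: float, q_max: int | None = None) -> "JointDegreeDistribution":
        """Independent Poisson(c) in- and out-degrees, truncated at q_max."""
        if c < 0:
            raise ValueError("mean degree must be >= 0")
        if q_max is None:
            q_max = int(max(50, np.ceil(c + 12.0 * np.sqrt(max(c, 1e-12)))))
        q = np.arange(q_max + 1)
        pmf = stats.poisson.pmf(q, c)
        tail = 1.0 - pmf.sum()
        if tail > _TAIL_TOL:
            warnings.warn(
                f"Poisson truncation at q_max={q_max} leaves tail mass "
                f"{tail:.3e} > {_TAIL_TOL:.0e}; increase q_max",
                stacklevel=2,
            )
        table = np.outer(pmf, pmf)
        table /= table.sum()
        return cls(table, _from_poisson=float(c))

    @property
    def mean_in_degree(self) -> float:
        q = np.arange(self.p_in.size)
        return float(q @ self.p_in)

    @property
    def mean_out_degree(self) -> float:
        q = np.arange(self.p_out.size)
        return float(q @ self.p_out)


def _smallest_fixed_point(g) -> float:
    """Smallest root of u = g(u) on [0, 1] for a convex, increasing
    probability generating function g with g(1) = 1.

    f(v) = g(v) - v is convex with f(0) >= 0 and f(1) = 0, so it has at
    most one interior root, crossed from above.  We look for a point
    where f < 0 (which exists iff g'(1) > 1, i.e. supercritical); if
    none is found down to machine scale the smallest fixed point is 1.
    Plain iteration from 0 is not used because its convergence rate
    degenerates near criticality.
    """
    f = lambda v: g(v) - v
    hi = None
    for delta in 10.0 ** -np.arange(1.0, 14.0):
        if f(1.0 - delta) < 0.0:
            hi = 1.0 - delta
            break
    if hi is None:
        return 1.0  # subcritical: only fixed point in [0, 1] is 1
    u = optimize.brentq(f, 0.0, hi, xtol=1e-16, rtol=8.9e-16, maxiter=200)
    if abs(g(u) - u) >= _RESIDUAL_TOL:
        raise RuntimeError(
            f"fixed point residual {abs(g(u) - u):.3e} exceeds {_RESIDUAL_TOL:.0e}"
        )
    return float(u)


def solve_branching_probabilities(
    dist: JointDegreeDistribution,
) -> BranchingProbabilities:
    """Solve the finite-component self-consistency equations.

    Following an in-link backwards reaches a node with probability
    proportional to its out-degree; its in-component is finite iff every
    in-link of that node also comes from a finite in-component:

        x = sum_{q_in,q_out} q_out P(q_in,q_out) x**q_in / <q>
        y = sum_{q_in,q_out} q_in  P(q_in,q_out) y**q_out / <q>

    For independent Poisson(c) both collapse to u = exp(-c (1 - u)).
    Subcritical distributions (c <= 1) return x = y = 1.
    """
    mean_q = dist.mean_in_degree
    if not np.isclose(mean_q, dist.mean_out_degree, rtol=1e-6):
        raise ValueError(
            "mean in-degree and mean out-degree differ: not a consistent "
            "directed network distribution"
        )
    if mean_q == 0:
        return BranchingProbabilities(x_c=1.0, y_c=1.0)

    c = dist.poisson_mean
    if c is not None:
        g = lambda u: float(np.exp(-c * (1.0 - u)))
        u = _smallest_fixed_point(g)
        return BranchingProbabilities(x_c=u, y_c=u)

    q_in = np.arange(dist.table.shape[0])
    q_out = np.arange(dist.table.shape[1])
    w_x = (dist.table * q_out[None, :]).sum(axis=1) / mean_q  # over q_in
    w_y = (dist.table * q_in[:, None]).sum(axis=0) / mean_q  # over q_out
    x = _smallest_fixed_point(lambda u: float(w_x @ np.power(u, q_in)))
    y = _smallest_fixed_point(lambda u: float(w_y @ np.power(u, q_out)))
    return BranchingProbabilities(x_c=x, y_c=y)


def source_fraction_theory(dist: JointDegreeDistribution) -> float:
    """Expected fraction of SOURCE nodes.

    A node is a SOURCE iff it has q_in = 0 and at least one of its
    out-links leads to the giant out-component (so that it reaches the
    CORE): sum over q_out of P(0, q_out) (1 - y_c**q_out).
    """
    y = solve_branching_probabilities(dist).y_c
    q_out = np.arange(dist.table.shape[1])
    return float(dist.table[0, :] @ (1.0 - np.power(y, q_out)))


def in_core_links_theory(dist: JointDegreeDistribution, n_nodes: int) -> float:
    """Expected number of IN-to-CORE links in a network of ``n_nodes``.

    N * sum_{q_in,q_out} q_in x_c P(q_in,q_out)
        * (1 - y_c**q_out) * (1 - x_c**(q_in - 1))
    """
    bp = solve_branching_probabilities(dist)
    x, y = bp.x_c, bp.y_c
    q_in = np.arange(dist.table.shape[0])
    q_out = np.arange(dist.table.shape[1])
    # q_in = 0 rows vanish through the q_in factor; clip the exponent to
    # keep x**(q_in - 1) well defined there
    pow_x = 1.0 - np.power(x, np.maximum(q_in - 1, 0))
    pow_x[q_in == 0] = 0.0
    row = q_in * x * pow_x  # over q_in
    col = 1.0 - np.power(y, q_out)  # over q_out
    return float(n_nodes * (row @ dist.table @ col))


def in_core_link_fraction_theory(dist: JointDegreeDistribution) -> float:
    """L_IN-CORE / L with L = N <q_in>."""
    mean_q = dist.mean_in_degree
    if mean_q == 0:
        return 0.0
    return in_core_links_theory(dist, 1) / mean_q


def core_fraction_theory(dist: JointDegreeDistribution) -> float:
    """Expected fraction of CORE nodes.

    A node is in the CORE iff at least one in-link comes from the giant
    in-component and at least one out-link leads to the giant
    out-component: sum P(q_in,q_out)(1 - x_c**q_in)(1 - y_c**q_out);
    for Poisson(c) this closes to (1 - y_c)**2 and vanishes at c <= 1.
    """
    bp = solve_branching_probabilities(dist)
    if dist.poisson_mean is not None:
        return float((1.0 - bp.y_c) ** 2)
    q_in = np.arange(dist.table.shape[0])
    q_out = np.arange(dist.table.shape[1])
    row = 1.0 - np.power(bp.x_c, q_in)
    col = 1.0 - np.power(bp.y_c, q_out)
    return float(row @ dist.table @ col)
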