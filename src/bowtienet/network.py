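"""Directed networks: construction, ER sampling, and edge-list I/O.

The single structural substrate used throughout the package is
:class:`DirectedNetwork` — a simple-directed graph on nodes ``0..n-1``
with no self-loops and no duplicate links.  The ER sampler builds an
undirected skeleton over all labeled pairs and then orients each link
with a fair coin, so reciprocal pairs cannot occur by construction.
Imported edge lists may contain reciprocal pairs; these are preserved
and counted, never rejected.

Randomness uses ``numpy.random.default_rng`` (PCG64).  The sampler
consumes the stream in a documented order (skeleton first, then one
Bernoulli(1/2) direction draw per link in sorted-pair order), so a
given ``(n, mean_in_degree, seed)`` triple always reproduces the same
link set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "DirectedNetwork",
    "EdgeListReport",
    "generate_directed_er",
    "read_edge_list",
    "write_edge_list",
]


class DirectedNetwork:
    """A simple directed graph on integer nodes ``0 .. n_nodes-1``.

    Parameters
    ----------
    n_nodes
        Number of nodes (>= 1).  Isolated nodes are allowed.
    tails, heads
        Parallel integer arrays; link ``k`` points ``tails[k] -> heads[k]``.
    validate
        If True (default), reject self-loops, duplicates and out-of-range
        ids.  Links are stored sorted lexicographically by (tail, head).
    """

    def __init__(self, n_nodes: int, tails, heads, *, validate: bool = True):
        n_nodes = int(n_nodes)
        if n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        tails = np.asarray(tails, dtype=np.int64).ravel()
        heads = np.asarray(heads, dtype=np.int64).ravel()
        if tails.shape != heads.shape:
            raise ValueError("tails and heads must have equal length")
        if validate and tails.size:
            if tails.min(initial=0) < 0 or heads.min(initial=0) < 0:
                raise ValueError("negative node id in link list")
            if max(tails.max(initial=0), heads.max(initial=0)) >= n_nodes:
                raise ValueError("node id out of range for n_nodes")
            if np.any(tails == heads):
                raise ValueError("self-loops are not allowed")
        # canonical order: sort by (tail, head)
        if tails.size:
            order = np.lexsort((heads, tails))
            tails = tails[order]
            heads = heads[order]
            if validate:
                key = tails * n_nodes + heads
                if np.any(np.diff(key) == 0):
                    raise ValueError("duplicate directed links are not allowed")
        self.n_nodes = n_nodes
        self.tails = tails
        self.heads = heads
        self._in_adj = None
        self._out_adj = None

    # -- basic accessors -------------------------------------------------

    @property
    def n_links(self) -> int:
        return int(self.tails.size)

    @property
    def mean_in_degree(self) -> float:
        """L / N — equals the mean out-degree."""
        return self.n_links / self.n_nodes

    @property
    def links(self) -> set[tuple[int, int]]:
        """Link set as Python tuples (convenient for small graphs only)."""
        return set(zip(self.tails.tolist(), self.heads.tolist()))

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.heads, minlength=self.n_nodes)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.tails, minlength=self.n_nodes)

    def has_reciprocal_links(self) -> bool:
        key = set((self.tails * self.n_nodes + self.heads).tolist())
        rev = set((self.heads * self.n_nodes + self.tails).tolist())
        return bool(key & rev)

    def count_reciprocal_pairs(self) -> int:
        key = set((self.tails * self.n_nodes + self.heads).tolist())
        rev = set((self.heads * self.n_nodes + self.tails).tolist())
        return len(key & rev) // 2

    # -- adjacency -------------------------------------------------------

    def in_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR of in-neighbors: for node n, ``indices[indptr[n]:indptr[n+1]]``
        are the nodes m with a link m -> n."""
        if self._in_adj is None:
            self._in_adj = _build_csr(self.heads, self.tails, self.n_nodes)
        return self._in_adj

    def out_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR of out-neighbors of each node."""
        if self._out_adj is None:
            self._out_adj = _build_csr(self.tails, self.heads, self.n_nodes)
        return self._out_adj

    def to_sparse(self) -> sparse.csr_matrix:
        """Adjacency matrix A with A[m, n] = 1 iff link m -> n exists."""
        data = np.ones(self.n_links, dtype=np.int8)
        return sparse.csr_matrix(
            (data, (self.tails, self.heads)), shape=(self.n_nodes, self.n_nodes)
        )

    def without_nodes(self, nodes) -> "DirectedNetwork":
        """Copy with all links incident to ``nodes`` removed.

        Node ids are preserved (the removed nodes become isolated), so
        partitions computed on the original network remain addressable.
        """
        drop = np.zeros(self.n_nodes, dtype=bool)
        drop[np.asarray(list(nodes), dtype=np.int64)] = True
        keep = ~(drop[self.tails] | drop[self.heads])
        return DirectedNetwork(
            self.n_nodes, self.tails[keep], self.heads[keep], validate=False
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return (
            self.n_nodes == other.n_nodes
            and np.array_equal(self.tails, other.tails)
            and np.array_equal(self.heads, other.heads)
        )

    def __repr__(self) -> str:
        return f"DirectedNetwork(n_nodes={self.n_nodes}, n_links={self.n_links})"


def _build_csr(keys: np.ndarray, values: np.ndarray, n: int):
    counts = np.bincount(keys, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    order = np.argsort(keys, kind="stable")
    return indptr, values[order].astype(np.int64)


# ---------------------------------------------------------------------------
# ER sampling
# ---------------------------------------------------------------------------

#: above this size the pairwise-Bernoulli skeleton sampler switches to the
#: distributionally identical geometric-skip sampler
_DENSE_SAMPLER_MAX_N = 10_000


def generate_directed_er(
    n_nodes: int, mean_in_degree: float, seed: int
) -> DirectedNetwork:
    """Sample a directed ER network with expected ``n_nodes * mean_in_degree`` links.

    An undirected skeleton is drawn by including each of the C(n, 2)
    labeled pairs independently with probability ``2 c / (n - 1)``, after
    which every kept pair ``(i, j)`` with ``i < j`` is oriented ``i -> j``
    and reversed with probability 1/2.  Reciprocal links are therefore
    absent by construction.

    For ``n_nodes <= 10**4`` the skeleton is sampled pair-by-pair in
    lexicographic order; for larger networks a geometric-skip sampler
    over the same linearized pair order is used.  The two procedures
    draw from the same distribution but consume the RNG stream
    differently, so seeds are portable only at fixed ``n_nodes`` regime.
    """
    n = int(n_nodes)
    c = float(mean_in_degree)
    if n < 2:
        raise ValueError("n_nodes must be >= 2")
    if c < 0:
        raise ValueError("mean_in_degree must be >= 0")
    p = 2.0 * c / (n - 1)
    if p > 1.0:
        raise ValueError(
            f"link probability 2*{c}/({n}-1) = {p:.4g} exceeds 1; "
            "reduce mean_in_degree or increase n_nodes"
        )
    rng = np.random.default_rng(seed)
    if p == 0.0:
        return DirectedNetwork(n, [], [], validate=False)

    if n <= _DENSE_SAMPLER_MAX_N:
        i_list, j_list = _skeleton_dense(n, p, rng)
    else:
        i_list, j_list = _skeleton_geometric(n, p, rng)

    # one fair-coin direction draw per link, consumed in sorted-pair order
    reverse = rng.random(i_list.size) < 0.5
    tails = np.where(reverse, j_list, i_list)
    heads = np.where(reverse, i_list, j_list)
    return DirectedNetwork(n, tails, heads, validate=False)


def _skeleton_dense(n: int, p: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli draw for every pair (i, j), i < j, in lexicographic order."""
    i_parts, j_parts = [], []
    for i in range(n - 1):
        u = rng.random(n - 1 - i)
        js = np.flatnonzero(u < p) + i + 1
        if js.size:
            i_parts.append(np.full(js.size, i, dtype=np.int64))
            j_parts.append(js.astype(np.int64))
    if not i_parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(i_parts), np.concatenate(j_parts)


def _skeleton_geometric(n: int, p: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-skip sampling over the linearized pair index (sparse case)."""
    n_pairs = n * (n - 1) // 2
    positions = []
    last = -1
    while True:
        remaining = n_pairs - last - 1
        if remaining <= 0:
            break
        size = int(max(1024, 1.2 * remaining * p))
        gaps = rng.geometric(p, size=size)
        idx = last + np.cumsum(gaps)
        inside = idx < n_pairs
        if not inside.all():
            positions.append(idx[inside])
            break
        positions.append(idx)
        last = int(idx[-1])
    if not positions:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    k = np.concatenate(positions).astype(np.int64)
    return _pair_from_index(k, n)


def _pair_from_index(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert the lexicographic linearization of pairs (i, j), i < j."""
    # offset(i) = i*(n-1) - i*(i-1)/2 is the index of pair (i, i+1)
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * k)) / 2.0).astype(np.int64)
    # float inversion can be off by one near row boundaries
    for _ in range(2):
        off = i * (n - 1) - i * (i - 1) // 2
        i = np.where(off > k, i - 1, i)
        off_next = (i + 1) * (n - 1) - (i + 1) * i // 2
        i = np.where(k >= off_next, i + 1, i)
    off = i * (n - 1) - i * (i - 1) // 2
    j = k - off + i + 1
    return i, j


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------


@dataclass
class EdgeListReport:
    """Provenance of an imported edge list."""

    node_map: dict[int, int] = field(default_factory=dict)  # original id -> internal
    n_duplicates: int = 0
    n_reciprocal_pairs: int = 0


def read_edge_list(
    path, *, one_based: bool = False, return_report: bool = False
):
    """Read a plain-text directed edge list ("tail head" per line).

    Lines starting with ``#`` are ignored.  Node ids are remapped to
    ``0..n-1`` in sorted order of the original ids; duplicates are
    collapsed with a warning, reciprocal pairs preserved and counted.

    Returns the network, or ``(network, EdgeListReport)`` when
    ``return_report`` is true.
    """
    tails, heads = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two tokens")
            try:
                t, h = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer token"
                ) from exc
            if one_based:
                t, h = t - 1, h - 1
            if t == h:
                raise ValueError(f"{path}: line {lineno}: self-loop {t}->{h}")
            tails.append(t)
            heads.append(h)
    if not tails:
        raise ValueError(f"{path}: empty edge list")

    original_ids = sorted(set(tails) | set(heads))
    node_map = {orig: new for new, orig in enumerate(original_ids)}
    t_arr = np.array([node_map[t] for t in tails], dtype=np.int64)
    h_arr = np.array([node_map[h] for h in heads], dtype=np.int64)

    n = len(original_ids)
    key = t_arr * n + h_arr
    unique_key, first = np.unique(key, return_index=True)
    n_dup = key.size - unique_key.size
    if n_dup:
        warnings.warn(
            f"{path}: collapsed {n_dup} duplicate link(s)", stacklevel=2
        )
        order = np.sort(first)
        t_arr, h_arr = t_arr[order], h_arr[order]

    net = DirectedNetwork(n, t_arr, h_arr)
    if return_report:
        report = EdgeListReport(
            node_map=node_map,
            n_duplicates=int(n_dup),
            n_reciprocal_pairs=net.count_reciprocal_pairs(),
        )
        return net, report
    return net


def write_edge_list(net: DirectedNetwork, path) -> None:
    """Write one "tail head" pair per line (0-based ids)."""
    with open(path, "w") as fh:
        fh.write(f"# directed edge list: {net.n_nodes} nodes, {net.n_links} links\n")
        for t, h in zip(net.tails.tolist(), net.heads.tolist()):
            fh.write(f"{t} {h}\n")
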