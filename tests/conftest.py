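import numpy as np
import pytest

from bowtienet import DirectedNetwork


def net_from_links(n, links):
    links = list(links)
    tails = [t for t, _ in links]
    heads = [h for _, h in links]
    return DirectedNetwork(n, tails, heads)


@pytest.fixture
def three_cycle():
    return net_from_links(3, [(0, 1), (1, 2), (2, 0)])


@pytest.fixture
def three_cycle_with_feeder():
    return net_from_links(4, [(0, 1), (1, 2), (2, 0), (3, 0)])


def brute_force_bowtie(n, links):
    """Transitive-closure classifier for tiny graphs; independent of the
    package's BFS/SCC implementation."""
    reach = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(reach, True)
    for t, h in links:
        reach[t, h] = True
    for _ in range(n):  # Floyd–Warshall style saturation
        reach = reach | (reach @ reach)

    mutual = reach & reach.T
    sccs = []
    seen = set()
    for v in range(n):
        if v in seen:
            continue
        comp = frozenset(np.flatnonzero(mutual[v]).tolist())
        sccs.append(comp)
        seen |= comp
    max_size = max(len(s) for s in sccs)
    core = min(
        (s for s in sccs if len(s) == max_size), key=lambda s: min(s)
    )

    classes = {}
    core_arr = sorted(core)
    for v in range(n):
        if v in core:
            classes[v] = "CORE"
            continue
        to_core = any(reach[v, c] for c in core_arr)
        from_core = any(reach[c, v] for c in core_arr)
        if to_core:
            classes[v] = "IN"
        elif from_core:
            classes[v] = "OUT"
    in_nodes = [v for v, c in classes.items() if c == "IN"]
    out_nodes = [v for v, c in classes.items() if c == "OUT"]
    for v in range(n):
        if v in classes:
            continue
        from_in = any(reach[i, v] for i in in_nodes)
        to_out = any(reach[v, o] for o in out_nodes)
        if from_in and to_out:
            classes[v] = "TUBE"
        elif from_in:
            classes[v] = "TENDRIL_FROM_IN"
        elif to_out:
            classes[v] = "TENDRIL_TO_OUT"
        else:
            classes[v] = "DISCONNECTED"

    q_in = np.zeros(n, dtype=int)
    q_out = np.zeros(n, dtype=int)
    for t, h in links:
        q_out[t] += 1
        q_in[h] += 1
    sources = {v for v in in_nodes if q_in[v] == 0}
    sinks = {v for v in out_nodes if q_out[v] == 0}
    return classes, sources, sinks
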