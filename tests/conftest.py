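import networkx as nx
import pytest

import netvuln as nv


@pytest.fixture(scope="session")
def karate() -> nx.Graph:
    return nv.karate_graph()


def two_joined_triangles() -> nx.Graph:
    """Two triangles joined by a single edge (6 nodes, 7 edges)."""
    return nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])


@pytest.fixture(scope="session")
def zoo() -> dict:
    """Small named graphs (<= 8 nodes) used for brute-force oracle checks."""
    return {
        "triangle": nx.cycle_graph(3),
        "path4": nx.path_graph(4),
        "path5": nx.path_graph(5),
        "path8": nx.path_graph(8),
        "star5": nx.star_graph(4),
        "star7": nx.star_graph(6),
        "K4": nx.complete_graph(4),
        "K5": nx.complete_graph(5),
        "K6": nx.complete_graph(6),
        "two_triangles": two_joined_triangles(),
    }


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive: recompute everything per step)


def brute_lcc_sizes_node_removal(g: nx.Graph, order) -> list[int]:
    h = g.copy()
    sizes = []
    for v in order:
        h.remove_node(v)
        if h.number_of_nodes() == 0:
            sizes.append(0)
        else:
            sizes.append(max(len(c) for c in nx.connected_components(h)))
    return sizes


def brute_lcc_sizes_edge_removal(g: nx.Graph, order) -> list[int]:
    h = g.copy()
    sizes = []
    for e in order:
        h.remove_edge(*e)
        sizes.append(max(len(c) for c in nx.connected_components(h)))
    return sizes


def brute_links_to_half(g: nx.Graph, order) -> int:
    v0 = max(len(c) for c in nx.connected_components(g))
    h = g.copy()
    for i, e in enumerate(order, start=1):
        h.remove_edge(*e)
        if max(len(c) for c in nx.connected_components(h)) <= v0 / 2:
            return i
    return g.number_of_edges()


def set_partitions(nodes):
    """All partitions of a node list (Bell-number enumeration)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in set_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [[first] + p[i]] + p[i + 1 :]
        yield [[first]] + p


def eq6_modularity(g: nx.Graph, comms) -> float:
    """Direct double-sum evaluation of the modularity formula, independent of
    the library implementation."""
    m = g.number_of_edges()
    nodes = list(g.nodes())
    label = {}
    for c, mem in enumerate(comms):
        for v in mem:
            label[v] = c
    k = dict(g.degree())
    total = 0.0
    for i in nodes:
        for j in nodes:
            if label[i] == label[j]:
                a_ij = 1.0 if g.has_edge(i, j) else 0.0
                total += a_ij - k[i] * k[j] / (2.0 * m)
    return total / (2.0 * m)
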