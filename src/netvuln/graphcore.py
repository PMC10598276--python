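"""Topological indicators and robustness curves for undirected simple graphs.

Every quantity here is defined on an unweighted, undirected simple graph
``G = (V, E)`` with ``n = |V|`` nodes, ``m = |E|`` edges, adjacency ``A`` and
degrees ``k_i``:

* average shortest path  ``ASP = sum_{s,t} d(s,t) / n(n-1)`` (ordered pairs,
  restricted to the largest connected component),
* degree assortativity ``r`` (Pearson correlation of degrees across edges),
* density ``d = 2m / n(n-1)``,
* diameter (maximum shortest-path distance, on the LCC),
* transitivity ``T = 3 * #triangles / #triads``,
* global efficiency ``e = mean of 1/d(i,j)`` over ordered pairs, with
  ``1/d = 0`` for disconnected pairs,
* modularity ``M = 1/2m * sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)`` for a
  detected community partition,
* node / edge robustness ``R_n``, ``R_e``: the mean fraction of original nodes
  in the largest connected subgraph over a full removal sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "UndefinedIndicatorError",
    "CommunityPartition",
    "IndicatorProfile",
    "RobustnessCurve",
    "largest_connected_component",
    "distance_summary",
    "degree_assortativity",
    "density",
    "transitivity",
    "modularity_value",
    "community_modularity",
    "indicator_profile",
    "robustness_curve",
    "profiles_to_frame",
]


class UndefinedIndicatorError(ValueError):
    """An indicator is mathematically undefined on this graph (e.g. the
    degree-degree correlation of a regular graph)."""


def _key(v: Hashable) -> str:
    return str(v)


def _edge_key(e: tuple) -> tuple:
    u, v = e
    return (u, v) if _key(u) <= _key(v) else (v, u)


def check_graph(g: nx.Graph) -> nx.Graph:
    """Validate the simple-undirected-graph invariants (no self-loops,
    n >= 1)."""
    if g.is_directed() or g.is_multigraph():
        raise TypeError("expected an undirected simple graph")
    if g.number_of_nodes() < 1:
        raise ValueError("graph must have at least one node")
    if nx.number_of_selfloops(g):
        raise ValueError("graph must not contain self-loops")
    return g


# ---------------------------------------------------------------------------
# components


def largest_connected_component(g: nx.Graph) -> tuple[nx.Graph, int]:
    """Induced subgraph on the largest connected component and its size.

    Ties between equally large components are broken by the smallest sorted
    node-identifier sequence, so the result is deterministic.
    """
    check_graph(g)
    comps = list(nx.connected_components(g))
    top = max(len(c) for c in comps)
    cands = [c for c in comps if len(c) == top]
    best = min(cands, key=lambda c: sorted(_key(v) for v in c))
    return g.subgraph(best).copy(), top


# ---------------------------------------------------------------------------
# scalar indicators


def distance_summary(g: nx.Graph) -> tuple[float, int, float]:
    """(ASP, diameter, efficiency).

    ASP and diameter are computed within the largest connected component;
    efficiency averages ``1/d(i,j)`` over *all* ordered node pairs of ``g``
    with 0 for disconnected pairs.  A singleton LCC yields ASP = diameter = 0.
    """
    lcc, size = largest_connected_component(g)
    if size == 1:
        asp, diam = 0.0, 0
    else:
        asp = nx.average_shortest_path_length(lcc)
        diam = nx.diameter(lcc)
    eff = nx.global_efficiency(g) if g.number_of_nodes() > 1 else 0.0
    return asp, diam, eff


def degree_assortativity(g: nx.Graph) -> float:
    """Pearson degree-degree correlation over edges, in [-1, 1].

    Raises :class:`UndefinedIndicatorError` when all edge-endpoint degrees are
    identical (zero variance, e.g. regular graphs), where the correlation has
    no value; callers that batch-profile networks record the condition instead
    of a silent 0.
    """
    check_graph(g)
    if g.number_of_edges() < 1:
        raise UndefinedIndicatorError("assortativity requires at least one edge")
    degs = {d for _, d in g.degree() if d > 0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_assortativity_coefficient(g)
    if not math.isfinite(r):
        raise UndefinedIndicatorError(
            "assortativity undefined: zero degree variance across edges"
        )
    return float(r)


def density(g: nx.Graph) -> float:
    """Edge density 2m / n(n-1)."""
    check_graph(g)
    if g.number_of_nodes() < 2:
        raise ValueError("density requires at least two nodes")
    return nx.density(g)


def transitivity(g: nx.Graph) -> float:
    """Global clustering coefficient 3 * #triangles / #triads (0 when the
    graph has no triads)."""
    check_graph(g)
    return nx.transitivity(g)


# ---------------------------------------------------------------------------
# communities / modularity


@dataclass(frozen=True)
class CommunityPartition:
    """A hard partition of the node set into communities."""

    membership: Mapping[Hashable, int]

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def as_sets(self) -> list[set]:
        out: dict[int, set] = {}
        for v, c in self.membership.items():
            out.setdefault(c, set()).add(v)
        return [out[c] for c in sorted(out)]


def modularity_value(g: nx.Graph, partition: CommunityPartition | Iterable[set]) -> float:
    """Evaluate ``M = 1/2m sum_ij (A_ij - k_i k_j/2m) delta(c_i,c_j)`` for a
    given partition."""
    check_graph(g)
    if g.number_of_edges() < 1:
        raise ValueError("modularity requires at least one edge")
    comms = partition.as_sets() if isinstance(partition, CommunityPartition) else list(partition)
    return nx.community.modularity(g, comms, weight=None)


def community_modularity(
    g: nx.Graph, seed: int = 0, method: str = "greedy"
) -> tuple[CommunityPartition, float]:
    """Detect communities and score the partition.

    ``method="greedy"`` (default) is the classic Clauset-Newman-Moore greedy
    agglomerative modularity maximisation, run through igraph's
    ``community_fastgreedy`` on a deterministically ordered copy of the graph
    (nodes sorted by identifier, edges lexicographic), so repeated runs are
    identical.  ``method="louvain"`` uses seeded Louvain instead.
    """
    check_graph(g)
    if g.number_of_edges() < 1:
        raise ValueError("community detection requires at least one edge")
    if method == "greedy":
        nodes = sorted(g.nodes(), key=_key)
        index = {v: i for i, v in enumerate(nodes)}
        edges = sorted(
            (tuple(sorted((index[u], index[v]))) for u, v in g.edges()),
        )
        h = ig.Graph(n=len(nodes), edges=edges)
        clustering = h.community_fastgreedy().as_clustering()
        membership = {nodes[i]: c for i, c in enumerate(clustering.membership)}
    elif method == "louvain":
        comms = nx.community.louvain_communities(g, seed=seed, weight=None)
        membership = {v: c for c, nodes_ in enumerate(comms) for v in nodes_}
    else:
        raise ValueError(f"unknown community detection method: {method!r}")
    part = CommunityPartition(membership)
    return part, modularity_value(g, part)


# ---------------------------------------------------------------------------
# indicator profile


@dataclass(frozen=True)
class IndicatorProfile:
    """The seven topological indicators of one network, plus its size.

    Indicators that are undefined on the given graph are NaN with the reason
    recorded in ``flags`` — never silently zero.
    """

    n: int
    m: int
    asp: float
    assortativity: float
    density: float
    diameter: float
    transitivity: float
    efficiency: float
    modularity: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "m": self.m,
            "asp": self.asp,
            "assortativity": self.assortativity,
            "density": self.density,
            "diameter": self.diameter,
            "transitivity": self.transitivity,
            "efficiency": self.efficiency,
            "modularity": self.modularity,
        }


def indicator_profile(g: nx.Graph, seed: int = 0, method: str = "greedy") -> IndicatorProfile:
    """Assemble the full indicator profile of one network."""
    check_graph(g)
    flags: list[str] = []
    n, m = g.number_of_nodes(), g.number_of_edges()

    asp, diam, eff = distance_summary(g)
    _, lcc_size = largest_connected_component(g)
    if lcc_size == 1:
        flags.append("singleton_lcc_distances_zero")
    if not nx.is_connected(g):
        flags.append("disconnected_distances_on_lcc")

    try:
        r = degree_assortativity(g)
    except UndefinedIndicatorError:
        r = float("nan")
        flags.append("assortativity_undefined")

    try:
        d = density(g)
    except ValueError:
        d = float("nan")
        flags.append("density_undefined")

    t = transitivity(g)
    if sum(1 for _, k in g.degree() if k >= 2) == 0:
        flags.append("no_triads")

    if m >= 1:
        _, mod = community_modularity(g, seed=seed, method=method)
    else:
        mod = float("nan")
        flags.append("modularity_undefined")

    return IndicatorProfile(
        n=n, m=m, asp=asp, assortativity=r, density=d, diameter=float(diam),
        transitivity=t, efficiency=eff, modularity=mod, flags=tuple(flags),
    )


def profiles_to_frame(profiles: Mapping[str, IndicatorProfile]) -> pd.DataFrame:
    """Indicator profiles as one row per network, column order
    name, N, E, ASP, r, D, d, M, T (D = diameter, d = density)."""
    rows = []
    for name, p in profiles.items():
        rows.append(
            {"name": name, "N": p.n, "E": p.m, "ASP": p.asp, "r": p.assortativity,
             "D": p.diameter, "d": p.density, "M": p.modularity, "T": p.transitivity}
        )
    return pd.DataFrame(rows, columns=["name", "N", "E", "ASP", "r", "D", "d", "M", "T"])


# ---------------------------------------------------------------------------
# robustness curves (union-find sweep)


class _DisjointSet:
    """Union-find over dynamically added elements, tracking the largest
    component size and the number of components among present elements."""

    __slots__ = ("parent", "size", "max_size", "n_components")

    def __init__(self) -> None:
        self.parent: dict = {}
        self.size: dict = {}
        self.max_size = 0
        self.n_components = 0

    def add(self, x) -> None:
        if x not in self.parent:
            self.parent[x] = x
            self.size[x] = 1
            self.n_components += 1
            if self.max_size < 1:
                self.max_size = 1

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.n_components -= 1
        if self.size[ra] > self.max_size:
            self.max_size = self.size[ra]


def lcc_sizes_after_node_removals(g: nx.Graph, order: Sequence) -> list[int]:
    """LCC size after removing ``order[:j]`` for j = 1..n, via a reverse
    union-find sweep (nodes are re-added from the back of the order)."""
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}
    dsu = _DisjointSet()
    present: set = set()
    sizes_rev = [0]  # state after all nodes removed
    for v in reversed(order[1:]):
        dsu.add(v)
        present.add(v)
        for w in adj[v]:
            if w in present:
                dsu.union(v, w)
        sizes_rev.append(dsu.max_size)
    return sizes_rev[::-1]


def lcc_sizes_after_edge_removals(g: nx.Graph, order: Sequence[tuple]) -> list[int]:
    """LCC node count after removing the first j edges of ``order``, for
    j = 1..m.  All nodes stay present, so the floor is 1 (isolated nodes)."""
    dsu = _DisjointSet()
    for v in g.nodes():
        dsu.add(v)
    sizes_rev = [dsu.max_size]  # state with every listed edge removed
    for u, v in reversed(order[1:]):
        dsu.union(u, v)
        sizes_rev.append(dsu.max_size)
    return sizes_rev[::-1]


@dataclass(frozen=True)
class RobustnessCurve:
    """``S`` over the removal grid and the scalar robustness index.

    ``S[j]`` is the fraction of *original* nodes in the largest connected
    subgraph after the first ``j + 1`` removals; ``index`` is the mean of
    ``S`` over the full grid (``R_n`` for node removals, ``R_e`` for edges).
    """

    fractions: np.ndarray
    S: np.ndarray
    index: float
    mode: str


def robustness_curve(g: nx.Graph, removal_order: Sequence, mode: str = "node") -> RobustnessCurve:
    """Robustness curve and index for a full removal sequence.

    ``removal_order`` must be a permutation of the nodes (``mode="node"``) or
    edges (``mode="edge"``) of ``g``.  ``S`` is normalised by the original
    node count so values are comparable across steps.
    """
    check_graph(g)
    n = g.number_of_nodes()
    if mode == "node":
        if set(removal_order) != set(g.nodes()) or len(removal_order) != n:
            raise ValueError("removal_order is not a permutation of the node set")
        sizes = lcc_sizes_after_node_removals(g, list(removal_order))
        steps = n
    elif mode == "edge":
        m = g.number_of_edges()
        order = [_edge_key(e) for e in removal_order]
        if len(order) != m or {_edge_key(e) for e in g.edges()} != set(order):
            raise ValueError("removal_order is not a permutation of the edge set")
        sizes = lcc_sizes_after_edge_removals(g, order)
        steps = m
    else:
        raise ValueError(f"mode must be 'node' or 'edge', got {mode!r}")
    S = np.asarray(sizes, dtype=float) / n
    fractions = np.arange(1, steps + 1) / steps
    return RobustnessCurve(fractions=fractions, S=S, index=float(S.mean()), mode=mode)
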