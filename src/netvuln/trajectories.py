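"""Batched growth and depletion simulations.

A growth run starts from the edgeless graph on the original node set and
restores edges in descending score order, split into (by default) 100
near-equal contiguous batches; a depletion run removes the same batches from
the full graph.  The trajectory records connectivity after every batch.
Centralities are never recalculated between batches.

``links_to_half_lcc`` is the single-edge-granularity statistic that feeds the
discriminant-analysis labels: the smallest number of individual edge removals
(descending score order) after which the largest connected component holds at
most half of its original node count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .attacks import EdgeScores, ranked_edges
from .graphcore import (
    check_graph,
    largest_connected_component,
    lcc_sizes_after_edge_removals,
)

__all__ = [
    "Batching",
    "Trajectory",
    "make_batches",
    "grow",
    "deplete",
    "links_to_half_lcc",
]


@dataclass(frozen=True)
class Batching:
    """Contiguous groups of a descending-score edge list; group sizes differ
    by at most one and empty groups are dropped."""

    batches: tuple[tuple[tuple, ...], ...]

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def all_edges(self) -> list[tuple]:
        return [e for b in self.batches for e in b]


@dataclass(frozen=True)
class Trajectory:
    """Per-batch connectivity record of a growth or depletion run."""

    steps: tuple[int, ...]
    edges_present: tuple[int, ...]
    lcc_size: tuple[int, ...]
    n_components: tuple[int, ...]
    lcc_diameter: tuple[int, ...]
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "edges_present": self.edges_present,
                "lcc_size": self.lcc_size,
                "n_components": self.n_components,
                "lcc_diameter": self.lcc_diameter,
            }
        )


def make_batches(scored_edges: EdgeScores, n_batches: int = 100) -> Batching:
    """Split the descending-score edge list into ``n_batches`` contiguous
    groups; a remainder of r spreads one extra edge over the first r groups."""
    if n_batches < 1:
        raise ValueError("n_batches must be >= 1")
    order = ranked_edges(scored_edges)
    m = len(order)
    if m == 0:
        raise ValueError("cannot batch an empty edge list")
    q, r = divmod(m, n_batches)
    sizes = [q + 1] * r + [q] * (n_batches - r)
    batches, start = [], 0
    for s in sizes:
        if s == 0:
            continue
        batches.append(tuple(order[start : start + s]))
        start += s
    return Batching(batches=tuple(batches))


def _record(g: nx.Graph, with_diameter: bool) -> tuple[int, int, int]:
    comps = list(nx.connected_components(g))
    lcc = max(comps, key=len) if comps else set()
    diam = 0
    if with_diameter and len(lcc) > 1:
        diam = nx.diameter(g.subgraph(lcc))
    return len(lcc), len(comps), diam


def _check_cover(g_nodes: set, batching: Batching, edge_set: set) -> None:
    batch_edges = batching.all_edges()
    if len(batch_edges) != len(edge_set) or set(batch_edges) != edge_set:
        raise ValueError("batching does not cover exactly the original edge set")


def grow(nodes: Iterable, batching: Batching, with_diameter: bool = True) -> Trajectory:
    """Grow from the edgeless graph on ``nodes`` by adding batches in order;
    the final state restores the original edge set."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    node_set = set(g.nodes())
    for batch in batching.batches:
        for u, v in batch:
            if u not in node_set or v not in node_set:
                raise ValueError("batch contains an edge outside the node set")
    steps, present, lcc, ncomp, diam = [], [], [], [], []
    count = 0
    for i, batch in enumerate(batching.batches, start=1):
        g.add_edges_from(batch)
        count += len(batch)
        a, b, c = _record(g, with_diameter)
        steps.append(i)
        present.append(count)
        lcc.append(a)
        ncomp.append(b)
        diam.append(c)
    return Trajectory(
        steps=tuple(steps), edges_present=tuple(present), lcc_size=tuple(lcc),
        n_components=tuple(ncomp), lcc_diameter=tuple(diam), mode="grow",
    )


def deplete(g: nx.Graph, batching: Batching, with_diameter: bool = True) -> Trajectory:
    """Remove batches in descending-score order from the full graph; the
    terminal state is edgeless."""
    check_graph(g)
    from .attacks import _edge_key

    _check_cover(set(g.nodes()), batching, {_edge_key(e) for e in g.edges()})
    h = g.copy()
    steps, present, lcc, ncomp, diam = [], [], [], [], []
    count = h.number_of_edges()
    for i, batch in enumerate(batching.batches, start=1):
        h.remove_edges_from(batch)
        count -= len(batch)
        a, b, c = _record(h, with_diameter)
        steps.append(i)
        present.append(count)
        lcc.append(a)
        ncomp.append(b)
        diam.append(c)
    return Trajectory(
        steps=tuple(steps), edges_present=tuple(present), lcc_size=tuple(lcc),
        n_components=tuple(ncomp), lcc_diameter=tuple(diam), mode="deplete",
    )


def links_to_half_lcc(
    g: nx.Graph, scored_edges: EdgeScores, direction: str = "descending"
) -> int:
    """Smallest number of single-edge removals after which the LCC holds at
    most half of its original node count.

    Removals follow the score order one edge at a time (``descending`` by
    default, matching attack semantics).  The baseline is the original LCC
    size, so disconnected inputs behave sensibly.  Returns m with a warning
    in the degenerate case where the threshold is never crossed.
    """
    check_graph(g)
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("graph has no edges")
    if direction not in ("descending", "ascending"):
        raise ValueError("direction must be 'descending' or 'ascending'")
    order = ranked_edges(scored_edges)
    if direction == "ascending":
        order = order[::-1]
    _, v0 = largest_connected_component(g)
    sizes = lcc_sizes_after_edge_removals(g, order)
    half = v0 / 2.0
    for i, s in enumerate(sizes):
        if s <= half:
            return i + 1
    warnings.warn("LCC never fell to half its original size; returning m", stacklevel=2)
    return m
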