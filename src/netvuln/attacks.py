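"""Centrality-based attack models.

Node attacks rank nodes by a criterion (random, degree, betweenness,
closeness, clustering coefficient) and remove them in descending order of the
score.  Edge scores for the growth/depletion stage are products of endpoint
centralities, ``w^m_{x,y} = C_m(x) * C_m(y)``, with two extras: ``ipa``
(inverse preferential attachment, ``1/(k_x k_y)``, realised as a score so
that descending order adds/removes low-degree-product edges first) and
``random`` (seeded uniform scores).

All centralities are *static*: computed once on the original network and
never recalculated during removal.  Ties are broken everywhere by the
ascending string form of the node identifier (lexicographic pairs for edges),
which makes every ranking reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np

from .graphcore import check_graph

__all__ = [
    "NODE_CRITERIA",
    "EDGE_CRITERIA",
    "RankedTargets",
    "EdgeScores",
    "node_centrality",
    "rank_nodes",
    "remove_fraction",
    "score_edges",
    "ranked_edges",
    "attachment_probability",
    "fractional_attack_robustness",
]

NODE_CRITERIA = ("random", "degree", "betweenness", "closeness", "clustering")
EDGE_CRITERIA = ("random", "degree", "betweenness", "closeness", "clustering", "ipa")


def _key(v: Hashable) -> str:
    return str(v)


def _edge_key(e: tuple) -> tuple:
    u, v = e
    return (u, v) if _key(u) <= _key(v) else (v, u)


@dataclass(frozen=True)
class RankedTargets:
    """An ordered removal list (a permutation of the node set) with the score
    that produced it."""

    order: tuple
    scores: Mapping[Hashable, float]
    criterion: str


@dataclass(frozen=True)
class EdgeScores:
    """Per-edge weights for one scoring criterion; keys are
    lexicographically normalised node pairs."""

    scores: Mapping[tuple, float]
    criterion: str


def node_centrality(g: nx.Graph, criterion: str, seed: int | None = None) -> dict:
    """One finite score per node for the given attack criterion.

    Betweenness uses unnormalised pair counts; closeness is the raw
    reciprocal distance sum ``1 / sum_i d(v, i)`` computed within the node's
    component (0 for isolated nodes); clustering of degree-<2 nodes is 0.
    """
    check_graph(g)
    if criterion == "degree":
        return {v: float(k) for v, k in g.degree()}
    if criterion == "betweenness":
        return {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=False).items()}
    if criterion == "closeness":
        out = {}
        for v in g.nodes():
            dist = nx.single_source_shortest_path_length(g, v)
            total = sum(dist.values())
            out[v] = 1.0 / total if total > 0 else 0.0
        return out
    if criterion == "clustering":
        return {v: float(c) for v, c in nx.clustering(g).items()}
    if criterion == "random":
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes(), key=_key)
        return dict(zip(nodes, rng.random(len(nodes))))
    raise ValueError(f"unknown attack criterion: {criterion!r}")


def rank_nodes(g: nx.Graph, criterion: str, seed: int = 0) -> RankedTargets:
    """Nodes in descending score order (seeded uniform shuffle for
    ``random``), ties by ascending identifier."""
    check_graph(g)
    if criterion == "random":
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes(), key=_key)
        order = tuple(nodes[i] for i in rng.permutation(len(nodes)))
        scores = {v: float(len(order) - i) for i, v in enumerate(order)}
        return RankedTargets(order=order, scores=scores, criterion=criterion)
    scores = node_centrality(g, criterion)
    order = tuple(sorted(g.nodes(), key=lambda v: (-scores[v], _key(v))))
    return RankedTargets(order=order, scores=scores, criterion=criterion)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def remove_fraction(g: nx.Graph, targets: RankedTargets, fraction: float) -> nx.Graph:
    """Remove the first round(fraction * n) ranked nodes (at least one
    whenever fraction > 0) and return the attacked graph."""
    check_graph(g)
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = g.number_of_nodes()
    k = _round_half_away(fraction * n)
    if fraction > 0:
        k = max(k, 1)
    k = min(k, n)
    h = g.copy()
    h.remove_nodes_from(targets.order[:k])
    return h


def score_edges(g: nx.Graph, criterion: str, seed: int = 0) -> EdgeScores:
    """Score every edge under one criterion, on the original graph.

    Centrality criteria use the endpoint product; ``ipa`` scores
    ``1/(k_x k_y)`` so that descending order realises
    low-degree-product-first addition; ``random`` draws seeded uniform
    weights.
    """
    check_graph(g)
    if g.number_of_edges() < 1:
        raise ValueError("graph has no edges to score")
    if criterion not in EDGE_CRITERIA:
        raise ValueError(f"unknown edge criterion: {criterion!r}")
    edges = sorted((_edge_key(e) for e in g.edges()), key=lambda e: (_key(e[0]), _key(e[1])))
    if criterion == "random":
        rng = np.random.default_rng(seed)
        return EdgeScores(scores=dict(zip(edges, rng.random(len(edges)))), criterion=criterion)
    if criterion == "ipa":
        deg = dict(g.degree())
        return EdgeScores(
            scores={(u, v): 1.0 / (deg[u] * deg[v]) for u, v in edges}, criterion=criterion
        )
    cent = node_centrality(g, criterion)
    scores = {(u, v): cent[u] * cent[v] for u, v in edges}
    if criterion == "clustering" and all(s == 0.0 for s in scores.values()):
        warnings.warn(
            "all clustering coefficients are zero; edge order falls back to the "
            "lexicographic tie rule",
            stacklevel=2,
        )
    return EdgeScores(scores=scores, criterion=criterion)


def ranked_edges(scores: EdgeScores) -> list[tuple]:
    """Edges in descending score order, ties lexicographic."""
    return sorted(scores.scores, key=lambda e: (-scores.scores[e], _key(e[0]), _key(e[1])))


def attachment_probability(scores: Mapping) -> dict:
    """Normalise non-negative scores to attachment probabilities
    ``Pi(s_i) = s_i / sum_j s_j``."""
    vals = list(scores.values())
    if any(s < 0 for s in vals):
        raise ValueError("attachment scores must be non-negative")
    total = float(sum(vals))
    if total <= 0:
        raise ValueError("at least one score must be positive")
    return {k: v / total for k, v in scores.items()}


def fractional_attack_robustness(
    g: nx.Graph,
    criterion: str,
    fractions: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5),
    seed: int = 0,
) -> "pd.DataFrame":
    """Remove a fraction of nodes by one criterion, then measure R_n and R_e
    of the attacked network.

    The removal order *inside* the robustness curves is the same static
    criterion ranking (node ranking / edge scores computed on the original
    graph) restricted to the surviving nodes and edges.
    """
    import pandas as pd

    from .graphcore import robustness_curve

    targets = rank_nodes(g, criterion, seed=seed)
    edge_crit = criterion if criterion in EDGE_CRITERIA else "random"
    escores = score_edges(g, edge_crit, seed=seed)
    rows = []
    for f in fractions:
        attacked = remove_fraction(g, targets, f)
        if attacked.number_of_nodes() == 0:
            rows.append({"criterion": criterion, "fraction": f, "R_n": 0.0, "R_e": 0.0})
            continue
        node_order = [v for v in targets.order if attacked.has_node(v)]
        rn = robustness_curve(attacked, node_order, mode="node").index
        if attacked.number_of_edges() > 0:
            surviving = {_edge_key(e) for e in attacked.edges()}
            edge_order = [e for e in ranked_edges(escores) if e in surviving]
            re_ = robustness_curve(attacked, edge_order, mode="edge").index
        else:
            re_ = 0.0
        rows.append({"criterion": criterion, "fraction": f, "R_n": rn, "R_e": re_})
    return pd.DataFrame(rows)
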