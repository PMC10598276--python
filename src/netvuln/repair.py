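"""Attack-and-reconstruction experiments with indicator-guided link repair.

Each round removes the ``k_remove`` highest edge-weight links (endpoint
centrality products recomputed on the current graph — the repair loop is
adaptive, unlike the static trajectory stage) and then greedily restores
``k_restore`` absent links, one at a time, re-scoring candidates after every
restoration.  Restoration scenarios:

* ``assort_to_zero``    — maximise ``1 / max(|r(G+e)|, eps)``, pushing the
  degree assortativity toward 0,
* ``assort_minimize``   — minimise ``r(G+e)`` (score ``-r``), making the
  network disassortative,
* ``combo_high_r_low_M`` / ``combo_low_r_high_M`` — min-max-normalised
  assortativity and modularity of ``G+e`` over the candidate set, combined as
  ``r_norm / M_norm`` (resp. ``M_norm / r_norm``) with an epsilon guard,
* ``random``            — seeded uniform restoration (baseline).

The log records, per round, the edges remaining plus the two fragmentation
events: edges remaining when the component count first exceeds 1, and when
the LCC first drops to half the original node count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Optional

import networkx as nx
import numpy as np

from .attacks import ranked_edges, score_edges
from .graphcore import check_graph, community_modularity, largest_connected_component

__all__ = [
    "SCENARIOS",
    "EPSILON",
    "ReconstructionLog",
    "repair_score",
    "score_candidates",
    "attack_repair_experiment",
]

SCENARIOS = (
    "assort_to_zero",
    "assort_minimize",
    "combo_high_r_low_M",
    "combo_low_r_high_M",
    "random",
)

EPSILON = 1e-9


class _AssortStats:
    """Sufficient statistics of the degree-degree Pearson correlation,
    supporting O(deg) evaluation of r(G + e) for a candidate edge.

    Over the 2m directed edge stubs: sum of endpoint degrees is
    ``s2 = sum_i k_i^2``, of squared endpoint degrees ``s3 = sum_i k_i^3``,
    and of degree products ``2 * se`` with ``se = sum_{(u,v) in E} k_u k_v``.
    """

    def __init__(self, g: nx.Graph):
        self.deg = dict(g.degree())
        self.m = g.number_of_edges()
        self.s2 = sum(d * d for d in self.deg.values())
        self.s3 = sum(d ** 3 for d in self.deg.values())
        self.se = sum(self.deg[u] * self.deg[v] for u, v in g.edges())

    def r_with_edge(self, g: nx.Graph, x: Hashable, y: Hashable) -> Optional[float]:
        kx, ky = self.deg[x], self.deg[y]
        s2 = self.s2 + (2 * kx + 1) + (2 * ky + 1)
        s3 = self.s3 + (3 * kx * kx + 3 * kx + 1) + (3 * ky * ky + 3 * ky + 1)
        se = (
            self.se
            + sum(self.deg[w] for w in g.neighbors(x))
            + sum(self.deg[w] for w in g.neighbors(y))
            + (kx + 1) * (ky + 1)
        )
        n_stubs = 2.0 * (self.m + 1)
        mean = s2 / n_stubs
        var = s3 / n_stubs - mean * mean
        if var <= 0:
            return None  # regular graph: r undefined
        return (2.0 * se / n_stubs - mean * mean) / var


def _candidates(g: nx.Graph) -> list[tuple]:
    from .attacks import _edge_key

    nodes = sorted(g.nodes(), key=str)
    out = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if not g.has_edge(u, v):
                out.append(_edge_key((u, v)))
    return out


def _minmax(vals: dict) -> dict:
    arr = np.array(list(vals.values()), dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi - lo <= 0:
        return {k: 0.0 for k in vals}
    return {k: (v - lo) / (hi - lo) for k, v in vals.items()}


def score_candidates(
    g: nx.Graph,
    scenario: str,
    rng: np.random.Generator | None = None,
    candidates: list[tuple] | None = None,
) -> dict:
    """Score every absent node pair for restoration under one scenario.

    Candidates whose post-addition assortativity is undefined are skipped.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown repair scenario: {scenario!r}")
    if candidates is None:
        candidates = _candidates(g)
    if not candidates:
        raise ValueError("no candidate links to restore")
    if scenario == "random":
        if rng is None:
            rng = np.random.default_rng(0)
        return {e: float(s) for e, s in zip(candidates, rng.random(len(candidates)))}
    stats = _AssortStats(g)
    r_vals = {}
    for u, v in candidates:
        r = stats.r_with_edge(g, u, v)
        if r is not None:
            r_vals[(u, v)] = r
    if not r_vals:
        raise ValueError("assortativity undefined for every candidate")
    if scenario == "assort_to_zero":
        return {e: 1.0 / max(abs(r), EPSILON) for e, r in r_vals.items()}
    if scenario == "assort_minimize":
        return {e: -r for e, r in r_vals.items()}
    # combined assortativity/modularity scenarios
    m_vals = {}
    for e in r_vals:
        h = g.copy()
        h.add_edge(*e)
        _, mod = community_modularity(h)
        m_vals[e] = mod
    rn = _minmax(r_vals)
    mn = _minmax(m_vals)
    if scenario == "combo_high_r_low_M":
        return {e: rn[e] / max(mn[e], EPSILON) for e in r_vals}
    return {e: mn[e] / max(rn[e], EPSILON) for e in r_vals}


def repair_score(g: nx.Graph, candidate: tuple, scenario: str) -> float:
    """Score one absent node pair (delegates to :func:`score_candidates` so
    the combined scenarios see the full candidate set for normalisation)."""
    from .attacks import _edge_key

    u, v = candidate
    if g.has_edge(u, v):
        raise ValueError("candidate edge is already present")
    scores = score_candidates(g, scenario, rng=np.random.default_rng(0))
    key = _edge_key((u, v))
    if key not in scores:
        raise ValueError("candidate score undefined (assortativity has no value)")
    return scores[key]


@dataclass(frozen=True)
class ReconstructionLog:
    """Round-by-round record of an attack/repair run and its two
    fragmentation events (``None`` while an event has not occurred)."""

    rounds: tuple[dict, ...]
    edges_at_fragmentation: Optional[int]
    edges_at_half_lcc: Optional[int]
    flags: tuple[str, ...] = ()

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(list(self.rounds))


def attack_repair_experiment(
    g0: nx.Graph,
    attack_criterion: str,
    scenario: str,
    k_remove: int = 10,
    k_restore: int = 5,
    seed: int = 0,
    one_shot: bool = False,
) -> ReconstructionLog:
    """Iterate remove-``k_remove``/restore-``k_restore`` rounds until both
    fragmentation events have occurred or the edges are exhausted.

    Attack edges are the top endpoint-centrality products recomputed on the
    current graph each round; restorations are greedy per
    :func:`score_candidates`, re-scored after every added link.  With
    ``one_shot=True`` a single round is performed.
    """
    check_graph(g0)
    if k_restore >= k_remove:
        raise ValueError("k_restore must be smaller than k_remove")
    if g0.number_of_edges() < k_remove:
        raise ValueError("graph has fewer edges than k_remove")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown repair scenario: {scenario!r}")

    rng = np.random.default_rng(seed)
    g = g0.copy()
    _, n0 = largest_connected_component(g0)
    half = n0 / 2.0
    frag_edges: Optional[int] = None
    half_edges: Optional[int] = None
    rounds = []

    def check_events() -> None:
        # Events are observed at the end of a full remove/restore round: a
        # fragmentation that the same round's repairs heal does not count.
        nonlocal frag_edges, half_edges
        ncomp = nx.number_connected_components(g)
        lcc = max((len(c) for c in nx.connected_components(g)), default=0)
        if frag_edges is None and ncomp > 1:
            frag_edges = g.number_of_edges()
        if half_edges is None and lcc <= half:
            half_edges = g.number_of_edges()

    t = 0
    while True:
        t += 1
        n_remove = min(k_remove, g.number_of_edges())
        if n_remove == 0:
            break
        scores = score_edges(g, attack_criterion, seed=int(rng.integers(2 ** 31)))
        g.remove_edges_from(ranked_edges(scores)[:n_remove])
        restored = 0
        if g.number_of_edges() > 0:
            for _ in range(k_restore):
                try:
                    cand_scores = score_candidates(g, scenario, rng=rng)
                except ValueError:
                    break
                best = min(cand_scores, key=lambda e: (-cand_scores[e], str(e[0]), str(e[1])))
                g.add_edge(*best)
                restored += 1
        check_events()
        comps = nx.number_connected_components(g)
        lcc = max((len(c) for c in nx.connected_components(g)), default=0)
        rounds.append(
            {
                "round": t,
                "edges_remaining": g.number_of_edges(),
                "removed": n_remove,
                "restored": restored,
                "lcc_size": lcc,
                "n_components": comps,
            }
        )
        if one_shot or (frag_edges is not None and half_edges is not None):
            break
        if g.number_of_edges() == 0:
            break

    flags = []
    if frag_edges is None:
        flags.append("fragmentation_not_reached")
    if half_edges is None:
        flags.append("half_lcc_not_reached")
    return ReconstructionLog(
        rounds=tuple(rounds),
        edges_at_fragmentation=frag_edges,
        edges_at_half_lcc=half_edges,
        flags=tuple(flags),
    )
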