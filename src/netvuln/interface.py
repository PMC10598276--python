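"""Edge-list I/O and run manifests.

Node identifiers are opaque strings: numeric labels are never coerced, which
avoids silent 0/1-based confusion between datasets.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import networkx as nx

logger = logging.getLogger("netvuln")

__all__ = ["read_edge_list", "write_edge_list", "read_graph", "karate_graph", "write_manifest"]


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected simple graph from a whitespace-separated edge list.

    Lines hold exactly two node tokens; ``#`` lines are comments.  Self-loops
    and duplicate edges are dropped, with counts logged.  Malformed lines and
    empty files raise with the offending line number.
    """
    path = Path(path)
    g = nx.Graph()
    self_loops = duplicates = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two node tokens, got {len(tokens)}"
                )
            u, v = tokens
            if u == v:
                self_loops += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                duplicates += 1
                continue
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: no nodes found")
    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)
    if duplicates:
        logger.info("%s: dropped %d duplicate edge(s)", path, duplicates)
    return g


def read_graph(path: str | Path, fmt: str = "edgelist") -> nx.Graph:
    """Read a graph as an edge list (default) or GML file; directed input is
    symmetrised and self-loops are dropped."""
    if fmt == "edgelist":
        return read_edge_list(path)
    if fmt == "gml":
        g = nx.read_gml(path)
        if g.is_directed():
            g = g.to_undirected()
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g
    raise ValueError(f"unknown graph format: {fmt!r}")


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write the edge set, one ``u v`` pair per line, in deterministic
    lexicographic order."""
    path = Path(path)
    with open(path, "w") as fh:
        for u, v in sorted(
            (tuple(sorted((str(u), str(v)))) for u, v in g.edges())
        ):
            fh.write(f"{u} {v}\n")


def karate_graph() -> nx.Graph:
    """The bundled Zachary karate club network (34 nodes, 78 edges)."""
    ref = resources.files("netvuln").joinpath("data/karate.edgelist")
    with resources.as_file(ref) as p:
        return read_edge_list(p)


def write_manifest(path: str | Path, config: dict) -> None:
    """Write the run manifest (config echo, seeds, tool version) as JSON."""
    from . import __version__

    payload = {"tool": "netvuln", "version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
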