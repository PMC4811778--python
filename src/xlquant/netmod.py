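"""Protein-protein interaction networks from inter-protein cross-links.

Each inter-protein (or ambiguous) cross-linked site pair contributes to an
edge between its two proteins; edge weight is the summed spectral count of
the supporting site pairs and an ambiguity flag marks edges supported only
by multi-mapped peptides (rendered grey in the conventional display).
Dense-module extraction follows the classic MCODE procedure: vertices are
weighted by the density of the highest k-core of their closed
neighborhood times its core number, and the module grows greedily from the
top-weighted seed.  Spectral-count weights affect rendering output only,
never module scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

from .linkio import LinkPair

__all__ = [
    "build_network",
    "ModuleResult",
    "extract_top_module",
    "mcode_vertex_weights",
    "write_edge_list",
    "write_graphml",
]

PathLike = Union[str, Path]


def build_network(pairs: Iterable[LinkPair]) -> nx.Graph:
    """Build the PPI graph from classified inter/ambiguous site pairs.

    One edge per protein pair; weight sums spectral counts across the
    supporting site pairs; ``ambiguous`` is true if any supporting pair is
    ambiguous.  Intra-protein pairs and self-edges are excluded.
    """
    g = nx.Graph()
    for p in pairs:
        if p.classification not in ("inter", "ambiguous"):
            continue
        u, v = p.site_1[0], p.site_2[0]
        if u == v:
            continue
        if g.has_edge(u, v):
            g[u][v]["weight"] += p.spectral_count
            g[u][v]["ambiguous"] |= p.classification == "ambiguous"
            g[u][v]["n_site_pairs"] += 1
        else:
            g.add_edge(u, v, weight=p.spectral_count,
                       ambiguous=p.classification == "ambiguous",
                       n_site_pairs=1)
    for node in g:
        g.nodes[node]["degree"] = g.degree(node)
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def mcode_vertex_weights(g: nx.Graph) -> dict:
    """MCODE vertex weighting: density of the highest k-core of the closed
    neighborhood, times that core number."""
    weights = {}
    for v in g:
        neighborhood = g.subgraph(set(g[v]) | {v})
        core = nx.core_number(neighborhood)
        k = max(core.values())
        kcore = neighborhood.subgraph([u for u, c in core.items() if c >= k])
        weights[v] = k * _density(kcore)
    return weights


@dataclass(frozen=True)
class ModuleResult:
    members: tuple[str, ...]
    score: float            # density x size
    seed: str


def _grow_module(g: nx.Graph, seed: str, weights: dict,
                 node_weight_pct: float) -> set:
    threshold = weights[seed] * (1.0 - node_weight_pct)
    members = {seed}
    frontier = [seed]
    while frontier:
        nxt = []
        for v in frontier:
            for u in sorted(g[v], key=str):
                if u not in members and weights[u] > threshold:
                    members.add(u)
                    nxt.append(u)
        frontier = nxt
    return members


def _haircut(g: nx.Graph, members: set, seed: str) -> set:
    while True:
        sub = g.subgraph(members)
        trim = {v for v in members if sub.degree(v) < 2 and v != seed}
        if not trim or len(members) - len(trim) < 2:
            return members
        members = members - trim


def extract_top_module(
    g: nx.Graph,
    node_weight_pct: float = 0.2,
    haircut: bool = True,
) -> ModuleResult:
    """Extract the most highly connected module.

    Seeds are tried in descending vertex-weight order; from each unvisited
    seed the module grows to neighbors whose weight is within
    ``node_weight_pct`` of the seed's, optionally trimmed of
    singly-connected vertices (haircut).  The highest density-times-size
    module wins; membership is independent of input order.
    """
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    weights = mcode_vertex_weights(g)
    visited: set = set()
    best: Optional[ModuleResult] = None
    for seed in sorted(g, key=lambda v: (-weights[v], str(v))):
        if seed in visited:
            continue
        members = _grow_module(g, seed, weights, node_weight_pct)
        visited |= members
        if haircut:
            members = _haircut(g, members, seed)
        if len(members) < 2:
            continue
        sub = g.subgraph(members)
        score = _density(sub) * len(members)
        if best is None or score > best.score:
            best = ModuleResult(members=tuple(sorted(members, key=str)),
                                score=score, seed=seed)
    if best is None:
        raise ValueError("no module of size >= 2 found")
    return best


def write_edge_list(g: nx.Graph, path: PathLike) -> None:
    """TSV edge list with weight and ambiguity attributes."""
    with open(path, "w") as fh:
        fh.write("protein_1\tprotein_2\tweight\tambiguous\tn_site_pairs\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(
                f"{u}\t{v}\t{data.get('weight', 1)}\t"
                f"{str(data.get('ambiguous', False)).lower()}\t"
                f"{data.get('n_site_pairs', 1)}\n"
            )


def write_graphml(g: nx.Graph, path: PathLike) -> None:
    nx.write_graphml(g, str(path))
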