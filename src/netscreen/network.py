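"""Interaction-network handling and dense-module (MCODE) detection.

MCODE finds densely connected regions of a protein-protein interaction graph
in three stages:

1. *Vertex weighting.*  For each vertex v, take the subgraph induced by v and
   its neighbors, find its highest k-core (the maximal subgraph of minimum
   degree k for the largest attainable k), and set
   ``weight(v) = k * density(highest k-core)``.
2. *Complex prediction.*  Seeds are taken in order of decreasing weight; from
   each unvisited seed, neighbors are added (breadth-first) whenever their
   weight is at least ``seed_weight * (1 - vwp)``.  A vertex assigned to a
   complex is never re-seeded or assigned to another complex.
3. *Post-processing.*  ``haircut`` trims members with a single connection
   inside the complex (the complex's 2-core); ``fluff`` optionally adds
   boundary neighbors whose own neighborhood density exceeds
   ``fluff_density`` (fluffed members may overlap complexes).

Complexes of fewer than two members are discarded and output is sorted by
descending score, where ``score = density * size`` of the induced subgraph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .types import GeneSet, as_gene_set

logger = logging.getLogger(__name__)

__all__ = [
    "load_network",
    "write_network",
    "intersect_sets",
    "prune_low_degree",
    "mcode_vertex_weight",
    "mcode_find_complexes",
    "score_complex",
    "MCODEComplex",
]


def load_network(path, score_threshold: float = 0.4) -> nx.Graph:
    """Read an undirected edge list (TSV/SIF style) with optional scores.

    Lines hold two node columns and an optional confidence score.  Scores on
    a 0-1000 scale are auto-detected (any score > 1 switches the dialect, and
    a threshold given on the 0-1 scale is rescaled, so the default 0.4 means
    400).  Edges with score <= threshold, self loops and duplicate edges are
    dropped (with logged counts).
    """
    records: list[tuple[str, str, float | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns, got {len(parts)}")
            if lineno == 1 and parts[0].lower() in (
                "node_a", "source", "protein1", "node1", "from", "gene_a"
            ):
                continue  # header row
            a, b = parts[0], parts[1]
            score: float | None = None
            if len(parts) >= 3:
                try:
                    score = float(parts[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable score {parts[2]!r}") from exc
            records.append((a, b, score))

    scores = [s for _, _, s in records if s is not None]
    threshold = score_threshold
    if scores and max(scores) > 1 and score_threshold <= 1:
        threshold = score_threshold * 1000
        logger.info("load_network: 0-1000 score dialect detected, threshold -> %g", threshold)

    G = nx.Graph()
    n_self = n_dup = n_low = 0
    for a, b, score in records:
        if a == b:
            n_self += 1
            continue
        if score is not None and score <= threshold:
            n_low += 1
            continue
        if G.has_edge(a, b):
            n_dup += 1
            continue
        if score is None:
            G.add_edge(a, b)
        else:
            G.add_edge(a, b, score=score)
    logger.info(
        "load_network: %d nodes, %d edges (dropped %d low-score, %d duplicate, %d self)",
        G.number_of_nodes(), G.number_of_edges(), n_low, n_dup, n_self,
    )
    return G


def write_network(G: nx.Graph, path) -> None:
    """Write a three-column edge list: node_a, node_b, score."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tscore\n")
        for a, b, data in sorted(G.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 1.0):.6g}\n")


def intersect_sets(sets: list[GeneSet]) -> GeneSet:
    """Genes present in every input set; requires at least two sets."""
    if len(sets) < 2:
        raise ValueError("intersect_sets requires >= 2 gene sets")
    genes = frozenset.intersection(*(s.genes for s in sets))
    if not genes:
        logger.warning("intersect_sets: empty intersection of %s", [s.name for s in sets])
    return GeneSet("&".join(s.name for s in sets), genes)


def prune_low_degree(
    G: nx.Graph,
    gene_subset: GeneSet,
    min_degree: int = 1,
    iterate: bool = False,
) -> nx.Graph:
    """Induced subgraph on ``gene_subset`` with low-degree nodes removed.

    By default a single pass removes nodes whose degree in the induced
    subgraph is below ``min_degree`` (so isolated genes are dropped).  With
    ``iterate=True`` removal repeats to a fixed point (k-core-style peeling).
    """
    subset = set(as_gene_set(gene_subset).genes) & set(G.nodes)
    H = G.subgraph(subset).copy()
    while True:
        low = [n for n, d in H.degree() if d < min_degree]
        H.remove_nodes_from(low)
        if not low or not iterate:
            break
    if H.number_of_nodes() == 0:
        logger.warning("prune_low_degree: no nodes left after pruning")
    return H


def _highest_k_core(G: nx.Graph) -> tuple[int, nx.Graph]:
    """(k, subgraph) of the highest k-core of G (k = max core number)."""
    core = nx.core_number(G)
    k = max(core.values())
    nodes = [n for n, c in core.items() if c >= k]
    return k, G.subgraph(nodes)


def _density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def mcode_vertex_weight(G: nx.Graph, v) -> float:
    """MCODE stage-1 weight: k * density of the highest k-core of N[v]."""
    neighbors = list(G[v])
    if not neighbors:
        return 0.0
    Gv = G.subgraph([v, *neighbors])
    if Gv.number_of_edges() == 0:
        return 0.0
    k, core = _highest_k_core(Gv)
    return k * _density(core)


@dataclass(frozen=True)
class MCODEComplex:
    """A dense subnetwork: its members, originating seed, and score."""

    members: frozenset
    seed: str
    score: float


def score_complex(G: nx.Graph, members) -> float:
    """Complex ranking score: density of the induced subgraph times its size."""
    members = set(members)
    if len(members) < 2:
        raise ValueError("a complex needs at least 2 members")
    return _density(G.subgraph(members)) * len(members)


def _haircut(G: nx.Graph, members: set, seed) -> set:
    """2-core of the complex; keep the component containing the seed."""
    H = G.subgraph(members).copy()
    while True:
        low = [n for n, d in H.degree() if d < 2]
        if not low:
            break
        H.remove_nodes_from(low)
    if H.number_of_nodes() == 0:
        return set()
    if seed in H:
        return set(nx.node_connected_component(H, seed))
    return set(max(nx.connected_components(H), key=len))


def _neighborhood_density(G: nx.Graph, v) -> float:
    nbrs = list(G[v])
    if not nbrs:
        return 0.0
    return _density(G.subgraph([v, *nbrs]))


def mcode_find_complexes(
    G: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.5,
) -> list[MCODEComplex]:
    """Run all three MCODE stages and return complexes sorted by score.

    Ties in seed weight are broken lexicographically by node id so runs are
    deterministic.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    weights = {v: mcode_vertex_weight(G, v) for v in G.nodes}
    order = sorted(G.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    complexes: list[MCODEComplex] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for w in G[u]:
                    if w in visited or w in members:
                        continue
                    if weights[w] >= threshold:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        visited |= members
        if haircut:
            members = _haircut(G, members, seed)
        if fluff:
            boundary = {
                w
                for u in members
                for w in G[u]
                if w not in members and _neighborhood_density(G, w) > fluff_density
            }
            members = members | boundary
        if len(members) < 2:
            continue
        complexes.append(
            MCODEComplex(frozenset(members), seed, score_complex(G, members))
        )

    complexes.sort(key=lambda c: (-c.score, -len(c.members), str(c.seed)))
    return complexes
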