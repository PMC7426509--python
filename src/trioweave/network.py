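"""Seed-gene network reconstruction and minimalist condensation.

The stage takes a merged interactome (protein-protein, transcription-factor
and pathway edges, treated as an undirected multigraph with provenance
collapsed onto single edges), a set of seed genes nominated by the upstream
omics stages, and produces a condensed disease network: every retained seed,
its direct seed-seed edges, and a near-minimal set of "connector" genes
linking seed pairs that sit at distance exactly 2.  Connector choice is a
greedy weighted set cover over the distance-2 seed pairs — the systematic
counterpart of a manual "keep as few neighbours as possible" curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .enrich import AnnotationMap, ease_enrich

PROVENANCES = ("PPI", "TF", "PATHWAY")


class NetworkError(ValueError):
    """Raised on invalid interactome assembly or queries."""


@dataclass
class MinimalNetwork:
    """Condensed output network: seeds + connectors + their edges."""

    graph: nx.Graph
    seeds: set
    connectors: list
    decorations: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def to_json_dict(self) -> dict:
        return {
            "nodes": [
                {
                    "id": n,
                    "role": "seed" if n in self.seeds else "connector",
                    **self.decorations.get(n, {}),
                }
                for n in sorted(self.graph.nodes)
            ],
            "edges": [
                {"source": u, "target": v, "provenance": sorted(d.get("provenance", set()))}
                for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[1]))
            ],
        }


def assemble_interactome(ppi_edges=(), tf_edges=(), pathway_edges=()) -> nx.Graph:
    """Merge provenance-labelled edge lists into one undirected graph.

    Duplicate pairs are collapsed with the union of their provenances;
    self-loops are dropped (count kept in ``graph.graph['self_loops_dropped']``).
    TF edges lose their direction here: neighbour queries are topological.
    """
    g = nx.Graph()
    dropped = 0
    for provenance, edges in zip(PROVENANCES, (ppi_edges, tf_edges, pathway_edges)):
        for u, v in edges:
            if u == v:
                dropped += 1
                continue
            if g.has_edge(u, v):
                g[u][v]["provenance"].add(provenance)
            else:
                g.add_edge(u, v, provenance={provenance})
    if g.number_of_edges() == 0:
        raise NetworkError("interactome assembly produced no edges")
    g.graph["self_loops_dropped"] = dropped
    return g


def neighbors_within(net: nx.Graph, seeds, k: int = 2) -> set:
    """All nodes at unweighted distance <= k from any seed (seeds included).

    Seeds absent from the graph are reported via the returned set's
    exclusion, not an error.
    """
    if k not in (1, 2):
        raise NetworkError("k must be 1 or 2")
    present = [s for s in seeds if s in net]
    out = set(present)
    frontier = set(present)
    for _ in range(k):
        frontier = {v for u in frontier for v in net.neighbors(u)}
        out |= frontier
    return out


def select_interconnected_seeds(net: nx.Graph, seeds) -> tuple[set, pd.DataFrame]:
    """Retain seeds within graph distance 2 of at least one other seed.

    Returns (retained, dropped_report); the report lists each dropped seed
    with its distance to the nearest other seed (inf if disconnected or
    absent from the interactome).
    """
    seeds = sorted(set(seeds))
    present = [s for s in seeds if s in net]
    retained = set()
    nearest = {}
    neigh1 = {s: set(net.neighbors(s)) for s in present}
    for s in present:
        ball1 = neigh1[s]
        ball2 = ball1 | {v for u in ball1 for v in net.neighbors(u)}
        others = [t for t in present if t != s]
        if any(t in ball1 for t in others):
            nearest[s] = 1
        elif any(t in ball2 for t in others):
            nearest[s] = 2
        if s in nearest:
            retained.add(s)
    dropped = [s for s in seeds if s not in retained]
    report = pd.DataFrame(
        {
            "seed": dropped,
            "nearest_seed_distance": [
                _nearest_seed_distance(net, s, [t for t in present if t != s]) for s in dropped
            ],
        }
    )
    return retained, report


def _nearest_seed_distance(net: nx.Graph, seed, others) -> float:
    if seed not in net or not others:
        return float("inf")
    lengths = nx.single_source_shortest_path_length(net, seed)
    dists = [lengths[t] for t in others if t in lengths]
    return float(min(dists)) if dists else float("inf")


def condense_minimal(
    net: nx.Graph,
    retained_seeds,
    max_intermediates: int = 1,
    decorations: dict | None = None,
) -> MinimalNetwork:
    """Condense to seeds plus a near-minimal connector set.

    (1) keep all retained seeds and every direct seed-seed edge;
    (2) enumerate non-adjacent seed pairs at distance exactly 2;
    (3) greedy weighted set cover over candidate connectors (non-seed
        nodes adjacent to >= 2 seeds): repeatedly add the connector
        covering the most uncovered pairs, ties broken by lexicographic
        node id; (4) include connector-seed edges only.

    ``max_intermediates`` > 1 additionally admits longer seed-seed chains
    by iterating the cover over intermediate layers (2 allowed, mirroring
    occasional second-neighbour exceptions in manual curation); pairs
    farther apart than 1 + max_intermediates stay unconnected by design.
    """
    seeds = sorted(set(retained_seeds))
    seed_set = set(seeds)
    out = nx.Graph()
    out.add_nodes_from(seeds)
    for u, v in combinations(seeds, 2):
        if net.has_edge(u, v):
            out.add_edge(u, v, provenance=set(net[u][v]["provenance"]))

    # candidate connectors: non-seed nodes adjacent to >= 2 retained seeds
    adjacency = {}
    for s in seeds:
        if s not in net:
            continue
        for v in net.neighbors(s):
            if v not in seed_set:
                adjacency.setdefault(v, set()).add(s)
    candidates = {v: adj for v, adj in adjacency.items() if len(adj) >= 2}

    pairs_to_cover = set()
    for u, v in combinations(seeds, 2):
        if out.has_edge(u, v):
            continue
        if any(u in adj and v in adj for adj in candidates.values()):
            pairs_to_cover.add((u, v))

    covered: set = set()
    connectors: list = []
    cover_map: dict = {}
    remaining = dict(candidates)
    while covered != pairs_to_cover:
        best, best_cover = None, set()
        for node in sorted(remaining):
            adj = remaining[node]
            cover = {
                p for p in pairs_to_cover - covered if p[0] in adj and p[1] in adj
            }
            if len(cover) > len(best_cover):
                best, best_cover = node, cover
        if best is None:
            break
        connectors.append(best)
        cover_map[best] = {
            p for p in pairs_to_cover if p[0] in candidates[best] and p[1] in candidates[best]
        }
        covered |= best_cover
        del remaining[best]

    # prune redundant connectors (greedy cover is not always irredundant):
    # drop, in reverse selection order, any connector whose pairs are all
    # covered by the others that remain
    for conn in list(reversed(connectors)):
        others = set().union(*(cover_map[c] for c in connectors if c != conn)) if len(connectors) > 1 else set()
        if cover_map[conn] <= others:
            connectors.remove(conn)

    for conn in connectors:
        for s in (set(net.neighbors(conn)) & seed_set):
            out.add_edge(conn, s, provenance=set(net[conn][s]["provenance"]))

    if max_intermediates >= 2:
        _attach_second_layer(net, out, seed_set)

    decorations = decorations or {}
    return MinimalNetwork(
        graph=out,
        seeds=seed_set,
        connectors=connectors,
        decorations={n: decorations.get(n, {}) for n in out.nodes},
    )


def _attach_second_layer(net: nx.Graph, out: nx.Graph, seed_set: set) -> None:
    """Bridge seed pairs at distance 3 with a lexicographically-first
    two-intermediate chain (the occasional curation exception)."""
    for u, v in combinations(sorted(seed_set), 2):
        if u in out and v in out and nx.has_path(out, u, v):
            if nx.shortest_path_length(out, u, v) <= 3:
                continue
        if u not in net or v not in net:
            continue
        try:
            path = nx.shortest_path(net, u, v)
        except nx.NetworkXNoPath:
            continue
        if len(path) - 1 == 3:
            for a, b in zip(path, path[1:]):
                out.add_edge(a, b, provenance=set(net[a][b]["provenance"]))


def common_tf_report(minimal: MinimalNetwork, tf_annot: AnnotationMap) -> pd.DataFrame:
    """EASE enrichment of the condensed network's genes against TF targets."""
    if not minimal.nodes:
        raise NetworkError("empty minimal network")
    return ease_enrich(minimal.nodes, tf_annot)
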