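"""PPI direct/bridged pair extraction, node topology metrics, and the
crosstalk-gene–pathway–neuropeptide tripartite network.

Node roles: ``crosstalk`` (DE in both diseases), ``neuropeptide`` (curated
panel) and ``other``.  A bridge triple is an indirect interaction path
crosstalk–other–neuropeptide of length two; the bridged subnetwork is the
union of those paths' edges.  Topology metrics follow the Cytoscape
conventions used for interactome analysis: per-node degree, average shortest
path length over reachable nodes, normalized shortest-path betweenness,
closeness = 1 / average distance to reachable nodes, and the topological
coefficient measuring shared-neighbour density.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

ROLE_CROSSTALK = "crosstalk"
ROLE_NEUROPEPTIDE = "neuropeptide"
ROLE_OTHER = "other"


def assign_roles(graph: nx.Graph, crosstalk, neuropeptides) -> dict[str, str]:
    """Label every node of the graph; overlap between the two input lists is
    rejected (the crosstalk set and the panel are disjoint by construction)."""
    crosstalk, neuropeptides = set(crosstalk), set(neuropeptides)
    overlap = crosstalk & neuropeptides
    if overlap:
        raise ValueError(f"genes labelled both crosstalk and neuropeptide: {sorted(overlap)[:5]}")
    roles = {}
    for node in graph.nodes:
        if node in crosstalk:
            roles[node] = ROLE_CROSSTALK
        elif node in neuropeptides:
            roles[node] = ROLE_NEUROPEPTIDE
        else:
            roles[node] = ROLE_OTHER
    return roles


def direct_pairs(graph: nx.Graph, crosstalk, neuropeptides) -> list[tuple[str, str]]:
    """Edges with one crosstalk and one neuropeptide endpoint, as sorted
    (crosstalk, neuropeptide) tuples."""
    crosstalk, neuropeptides = set(crosstalk), set(neuropeptides)
    pairs = set()
    for a, b in graph.edges:
        if a in crosstalk and b in neuropeptides:
            pairs.add((a, b))
        elif b in crosstalk and a in neuropeptides:
            pairs.add((b, a))
    return sorted(pairs)


def bridge_pairs(
    graph: nx.Graph, crosstalk, neuropeptides
) -> tuple[list[tuple[str, str, str]], nx.Graph]:
    """All triples (c, b, n) with edges c–b and b–n and b of role 'other'.

    Returns the sorted triple list and the induced subnetwork (union of the
    triples' edges, with node ``role`` attributes).
    """
    crosstalk, neuropeptides = set(crosstalk), set(neuropeptides)
    roles = assign_roles(graph, crosstalk, neuropeptides)
    triples = set()
    for bridge, role in roles.items():
        if role != ROLE_OTHER:
            continue
        neigh = set(graph.neighbors(bridge))
        cs = sorted(neigh & crosstalk)
        ns = sorted(neigh & neuropeptides)
        for c in cs:
            for n in ns:
                triples.add((c, bridge, n))
    triples = sorted(triples)
    sub = nx.Graph()
    for c, b, n in triples:
        sub.add_edge(c, b)
        sub.add_edge(b, n)
    nx.set_node_attributes(sub, {v: roles[v] for v in sub.nodes}, "role")
    return triples, sub


def topological_coefficient(graph: nx.Graph, node) -> float:
    """Cytoscape topological coefficient: TC(n) = avg over nodes m sharing at
    least one neighbour with n of J(n,m)/k(n), where J(n,m) = number of shared
    neighbours of n and m, plus one if m is adjacent to n.  Nodes with no such
    partner (or degree 0) get 0."""
    neigh = set(graph.neighbors(node))
    k = len(neigh)
    if k == 0:
        return 0.0
    partners = set()
    for u in neigh:
        partners.update(graph.neighbors(u))
    partners.discard(node)
    scores = []
    for m in partners:
        shared = len(neigh & set(graph.neighbors(m)))
        if shared == 0:
            continue
        scores.append((shared + (1 if m in neigh else 0)) / k)
    return sum(scores) / len(scores) if scores else 0.0


def topology_metrics(
    graph: nx.Graph, roles: dict[str, str] | None = None, top: int | None = None
) -> pd.DataFrame:
    """Per-node topology table sorted by degree descending (ties by name).

    Columns: role, degree, avg_shortest_path, betweenness, closeness,
    topological_coefficient.  Path-based metrics average over reachable nodes
    only (unreachable pairs excluded); an isolated node gets 0 for all of
    them.  Betweenness is normalized by 2/((N−1)(N−2)).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    betweenness = nx.betweenness_centrality(graph, normalized=True)
    rows = []
    for node in graph.nodes:
        lengths = nx.single_source_shortest_path_length(graph, node)
        lengths.pop(node, None)
        if lengths:
            aspl = sum(lengths.values()) / len(lengths)
            closeness = 1.0 / aspl
        else:
            aspl = 0.0
            closeness = 0.0
        rows.append(
            (
                node,
                (roles or {}).get(node, ""),
                graph.degree(node),
                aspl,
                betweenness[node],
                closeness,
                topological_coefficient(graph, node),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "node", "role", "degree", "avg_shortest_path", "betweenness",
            "closeness", "topological_coefficient",
        ],
    )
    table = table.sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(top) if top else table


def shared_pathway_network(
    crosstalk, neuropeptides, pathways: dict[str, list[str]]
) -> list[tuple[str, str, str]]:
    """Tripartite edge list linking crosstalk genes and neuropeptides through
    pathways containing at least one member of each role.

    Returns sorted (source, edge_type, target) tuples with edge types
    ``crosstalk-pathway`` and ``pathway-neuropeptide``.
    """
    crosstalk, neuropeptides = set(crosstalk), set(neuropeptides)
    edges = []
    for name in sorted(pathways):
        members = set(pathways[name])
        cs = sorted(members & crosstalk)
        ns = sorted(members & neuropeptides)
        if not cs or not ns:
            continue
        edges.extend((c, "crosstalk-pathway", name) for c in cs)
        edges.extend((name, "pathway-neuropeptide", n) for n in ns)
    return edges
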