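"""Brute-force graph-metric oracles, independent of networkx's algorithms:
BFS distance fields, explicit shortest-path enumeration for betweenness, and
adjacency-matrix arithmetic for the topological coefficient."""

import networkx as nx
import numpy as np


def bf_distances(graph):
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}
    out = {}
    for s in graph.nodes:
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        nxt.append(w)
            frontier = nxt
        out[s] = dist
    return out


def bf_betweenness(graph):
    """Normalized betweenness by enumerating every shortest path."""
    nodes = list(graph.nodes)
    n = len(nodes)
    dist = bf_distances(graph)
    adj = {v: set(graph.neighbors(v)) for v in nodes}
    score = {v: 0.0 for v in nodes}

    def shortest_paths(s, t):
        d_t = dist[t]
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in adj[u]:
                if w in d_t and d_t[w] == d_t[u] - 1:
                    extend(path + [w])

        if t in dist[s]:
            extend([s])
        return paths

    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = shortest_paths(s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                score[v] += through / len(paths)
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return {v: score[v] * norm for v in nodes}


def bf_topological_coefficient(graph):
    nodes = list(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes)
    A2 = A @ A
    out = {}
    for i, v in enumerate(nodes):
        k = A[i].sum()
        if k == 0:
            out[v] = 0.0
            continue
        scores = [
            (A2[i, j] + A[i, j]) / k
            for j in range(len(nodes))
            if j != i and A2[i, j] > 0
        ]
        out[v] = float(np.mean(scores)) if scores else 0.0
    return out
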