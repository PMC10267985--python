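"""Brute-force helpers for the acceptance script.

Path-enumeration centralities and a small random connected graph
generator, independent of the library's own code paths.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


def random_connected_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    nodes = [f"N{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(1, n):
        g.add_edge(nodes[i], nodes[int(rng.integers(0, i))])
    for _ in range(int(rng.integers(0, n))):
        u, v = rng.choice(n, size=2, replace=False)
        g.add_edge(nodes[u], nodes[v])
    return g


def _all_simple_paths(adj: dict, s, t) -> list[list]:
    out: list[list] = []

    def walk(node, visited, path):
        if node == t:
            out.append(path[:])
            return
        for nbr in adj[node]:
            if nbr not in visited:
                visited.add(nbr)
                path.append(nbr)
                walk(nbr, visited, path)
                path.pop()
                visited.remove(nbr)

    walk(s, {s}, [s])
    return out


def brute_force_centralities(g: nx.Graph) -> pd.DataFrame:
    nodes = sorted(g.nodes())
    adj = {u: sorted(g.neighbors(u)) for u in nodes}
    n = len(nodes)
    dist = {u: {} for u in nodes}
    bc = {u: 0.0 for u in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_simple_paths(adj, s, t)
        lengths = [len(p) - 1 for p in paths]
        d = min(lengths)
        shortest = [p for p, ln in zip(paths, lengths) if ln == d]
        dist[s][t] = dist[t][s] = d
        sigma = len(shortest)
        for v in nodes:
            if v in (s, t):
                continue
            bc[v] += sum(1 for p in shortest if v in p) / sigma
    denom = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    rows = {
        u: {
            "dc": g.degree(u),
            "bc": bc[u] / denom,
            "cc": (n - 1) / sum(dist[u][v] for v in nodes if v != u),
        }
        for u in nodes
    }
    return pd.DataFrame.from_dict(rows, orient="index").loc[nodes]
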