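"""Independent brute-force oracles used by the test suite.

Each oracle computes a quantity from first principles — exhaustive path
enumeration, exhaustive subset enumeration, direct observed-minus-
expected accumulation — without touching the code paths it checks.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


def _all_simple_paths(adj: dict, s, t) -> list[list]:
    """Every simple path s→t by depth-first enumeration."""
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
    """DC/BC/CC on a small connected graph by exhaustive path enumeration.

    Betweenness sums sigma_st(v)/sigma_st over unordered pairs s<t with
    v not an endpoint, normalised by (n-1)(n-2)/2; closeness is (n-1)
    over the sum of shortest-path lengths found among enumerated paths.
    """
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
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / sigma
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


def brute_force_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    term = set(range(K))
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(term.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_table(N: int, n: int) -> np.ndarray:
    """tail[K, k] = P(overlap >= k) for all K in 0..N, k in 0..n, by enumeration."""
    draws = np.array(list(combinations(range(N), n)))  # C x n
    tail = np.empty((N + 1, n + 1))
    for K in range(N + 1):
        overlap = (draws < K).sum(axis=1)
        for k in range(n + 1):
            tail[K, k] = (overlap >= k).mean()
    return tail


def logrank_oe(df: pd.DataFrame, group_col: str = "arm") -> float:
    """Two-group log-rank chi-square by direct O−E accumulation."""
    arms = sorted(df[group_col].unique())
    assert len(arms) == 2
    O = E = V = 0.0
    for t in sorted(df.loc[df["event"] == 1, "time_days"].unique()):
        at_risk = df[df["time_days"] >= t]
        nj = len(at_risk)
        n1 = (at_risk[group_col] == arms[0]).sum()
        dying = (df["time_days"] == t) & (df["event"] == 1)
        dj = dying.sum()
        d1 = (dying & (df[group_col] == arms[0])).sum()
        O += d1
        E += dj * n1 / nj
        if nj > 1:
            V += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    return (O - E) ** 2 / V


def km_product_limit(times: list[float], events: list[int]) -> list[tuple[float, float]]:
    """(time, S(t)) pairs at each distinct event time, by the product formula."""
    order = np.argsort(times)
    times = np.asarray(times, dtype=float)[order]
    events = np.asarray(events, dtype=int)[order]
    s = 1.0
    curve = []
    for t in np.unique(times[events == 1]):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        curve.append((float(t), s))
    return curve
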