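"""Centrality computation and the two-stage median-adaptive screening cascade.

The cascade extracts a "core" subnetwork from the merged drug/disease
interactome in two passes, each with thresholds derived from the current
network's own medians rather than fixed numbers:

stage 1
    restrict to the largest connected component, keep nodes whose raw
    degree strictly exceeds **twice the median degree**, re-induce the
    subgraph and re-restrict to its largest component;
stage 2
    recompute degree, betweenness and closeness centrality on the
    stage-1 network and keep nodes strictly above **all three medians**.

Median-adaptive cuts make the screen scale-free: on a heavy-tailed
interactome they carve out the hub backbone regardless of absolute size.
Conventions: degree centrality is the raw degree (integer); betweenness
is Brandes' algorithm normalised by (n−1)(n−2)/2; closeness is
(n−1)/Σ shortest-path distances, well defined because each pass runs on
a connected graph.  Strict ``>`` everywhere — ties are excluded.  If a
stage would empty the network the stage returns its input unchanged with
a ``fallback_triggered`` flag, so degenerate inputs (regular graphs,
single nodes) never silently produce an empty core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["CentralityTable", "ScreenReport", "centralities", "screen_stage", "screen_core"]


@dataclass
class CentralityTable:
    """Per-node degree/betweenness/closeness with the table's medians."""

    table: pd.DataFrame  # index node; columns dc (int), bc, cc
    med_dc: float
    med_bc: float
    med_cc: float


@dataclass
class ScreenReport:
    """Everything the cascade did: per-stage nodes, thresholds, fallbacks."""

    input_nodes: int
    input_edges: int
    stage1_nodes: set[str] = field(default_factory=set)
    stage2_nodes: set[str] = field(default_factory=set)
    stage1_edges: int = 0
    stage2_edges: int = 0
    stage1_thresholds: dict[str, float] = field(default_factory=dict)
    stage2_thresholds: dict[str, float] = field(default_factory=dict)
    fallback_triggered: bool = False
    core: nx.Graph | None = None

    def to_dict(self) -> dict:
        return {
            "input": {"nodes": self.input_nodes, "edges": self.input_edges},
            "stage1": {
                "nodes": len(self.stage1_nodes),
                "edges": self.stage1_edges,
                "thresholds": self.stage1_thresholds,
            },
            "stage2": {
                "nodes": len(self.stage2_nodes),
                "edges": self.stage2_edges,
                "thresholds": self.stage2_thresholds,
            },
            "fallback_triggered": self.fallback_triggered,
        }


def _require_connected(g: nx.Graph) -> None:
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected; restrict to a connected component first "
            "(closeness centrality is undefined across components)"
        )


def centralities(g: nx.Graph) -> CentralityTable:
    """Exact DC/BC/CC for every node of a connected graph.

    DC is the raw degree; BC uses Brandes' exact algorithm with the
    undirected normalisation 2/((n−1)(n−2)); CC is (n−1) divided by the
    sum of shortest-path distances to all other nodes.  Medians use the
    average-of-middle-two convention for even n.
    """
    _require_connected(g)
    dc = dict(g.degree())
    bc = nx.betweenness_centrality(g, normalized=True)
    cc = nx.closeness_centrality(g)
    nodes = sorted(g.nodes())
    table = pd.DataFrame(
        {
            "dc": [dc[n] for n in nodes],
            "bc": [bc[n] for n in nodes],
            "cc": [cc[n] for n in nodes],
        },
        index=nodes,
    )
    return CentralityTable(
        table=table,
        med_dc=float(median(table["dc"])),
        med_bc=float(median(table["bc"])),
        med_cc=float(median(table["cc"])),
    )


def screen_stage(
    g: nx.Graph, metric_thresholds: dict[str, float], strict: bool = True
) -> tuple[nx.Graph, bool]:
    """Induce the subgraph of nodes strictly exceeding every threshold.

    ``metric_thresholds`` maps metric names (``dc``, ``bc``, ``cc``) to
    cut values.  Returns ``(subgraph, fallback_triggered)``; when the
    filter would retain nothing, the input graph is returned unchanged
    and the flag is set.
    """
    _require_connected(g)
    unknown = set(metric_thresholds) - {"dc", "bc", "cc"}
    if unknown:
        raise ValueError(f"unknown centrality metric(s): {sorted(unknown)}")
    need_full = bool({"bc", "cc"} & set(metric_thresholds))
    if need_full:
        tab = centralities(g).table
    else:
        tab = pd.DataFrame({"dc": dict(g.degree())})
    keep = pd.Series(True, index=tab.index)
    for metric, thr in metric_thresholds.items():
        keep &= (tab[metric] > thr) if strict else (tab[metric] >= thr)
    kept = set(tab.index[keep])
    if not kept:
        log.warning("screen stage retained no node at %s; falling back to input", metric_thresholds)
        return g.copy(), True
    return g.subgraph(kept).copy(), False


def _largest_component(g: nx.Graph) -> nx.Graph:
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if nx.is_connected(g):
        return g
    comp = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)[0]))
    log.info("restricting to largest component: %d of %d nodes", len(comp), g.number_of_nodes())
    return g.subgraph(comp).copy()


def screen_core(g: nx.Graph) -> ScreenReport:
    """Run the full two-stage cascade and return the core network report.

    The returned report's ``core`` attribute holds the final graph
    (stage-2 survivors, or the stage-1 network when the strict filter
    would empty it).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot screen an empty graph")
    g0 = _largest_component(g)
    report = ScreenReport(input_nodes=g.number_of_nodes(), input_edges=g.number_of_edges())

    # stage 1: degree only, cut at twice the median degree
    med_dc = float(median(d for _, d in g0.degree()))
    thr1 = {"dc": 2.0 * med_dc}
    g1, fb1 = screen_stage(g0, thr1)
    g1 = _largest_component(g1)
    report.stage1_thresholds = thr1
    report.stage1_nodes = set(g1.nodes())
    report.stage1_edges = g1.number_of_edges()

    # stage 2: all three centralities above their stage-1 medians
    if g1.number_of_nodes() < 3:
        # BC/CC are degenerate below 3 nodes; strict median filters empty
        log.warning("stage-1 network has <3 nodes; stage 2 falls back")
        g2, fb2 = g1.copy(), True
        report.stage2_thresholds = {}
    else:
        ct = centralities(g1)
        thr2 = {"dc": ct.med_dc, "bc": ct.med_bc, "cc": ct.med_cc}
        g2, fb2 = screen_stage(g1, thr2)
        g2 = _largest_component(g2)
        report.stage2_thresholds = thr2
    report.stage2_nodes = set(g2.nodes())
    report.stage2_edges = g2.number_of_edges()
    report.fallback_triggered = fb1 or fb2
    report.core = g2
    return report
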