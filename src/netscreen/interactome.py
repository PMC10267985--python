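"""Background interactome model, seed expansion and network merging.

The interactome is an undirected simple graph whose nodes are gene
symbols.  It serves three roles: the universe against which drug and
disease target sets are expanded to their first protein-interaction
neighbourhoods, the carrier of the merged drug/disease network, and the
input to the topological screening cascade.

Graphs are plain :class:`networkx.Graph` objects throughout; this module
adds the domain operations and the two-column TSV edge-list format used
for every graph artifact on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .targets import TargetSet

log = logging.getLogger(__name__)

__all__ = [
    "ExpandedNetwork",
    "EmptyResultError",
    "read_edgelist",
    "write_edgelist",
    "as_simple_graph",
    "expand_seeds",
    "merge_networks",
]


class EmptyResultError(ValueError):
    """An operation produced an empty network where the pipeline needs one."""


@dataclass
class ExpandedNetwork:
    """A seed set together with its first-neighbour subnetwork.

    ``graph`` is the background subgraph induced on the seeds present in
    the background plus all of their direct interactors.  ``missing``
    records seeds absent from the background; they are reported, never
    fatal, because curated target lists routinely contain symbols outside
    any given interactome build.
    """

    graph: nx.Graph
    seeds: TargetSet
    label: str  # "drug" or "disease"
    missing: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def as_simple_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    """Build an undirected simple graph, dropping self-loops and duplicates."""
    g = nx.Graph()
    n_self = 0
    for u, v in edges:
        if u == v:
            n_self += 1
            continue
        g.add_edge(u, v)
    if n_self:
        log.info("dropped %d self-loop(s)", n_self)
    return g


def read_edgelist(path: str | Path) -> nx.Graph:
    """Read a two-column TSV edge list.

    Lines starting with ``#`` are comments; an optional header line is
    tolerated (detected as the literal pair ``source``/``target``).
    Self-loops and parallel edges are silently collapsed with a logged
    count, matching how public interactome dumps are usually cleaned.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            u, v = parts[0].strip(), parts[1].strip()
            if lineno == 1 and u.lower() in {"source", "node1", "gene1"}:
                continue
            edges.append((u, v))
    return as_simple_graph(edges)


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u}\t{v}\n")


def expand_seeds(
    background: nx.Graph, seeds: TargetSet, depth: int = 1, label: str | None = None
) -> ExpandedNetwork:
    """Expand a seed target set to its interaction neighbourhood.

    The result's node set is the seeds found in the background plus every
    node within ``depth`` edges of a seed (default 1: direct interactors
    only); its edge set is all background edges induced on those nodes.
    This mirrors how PPI construction tools grow a network around a
    query list before any topological filtering.

    Raises :class:`EmptyResultError` if no seed is present in the
    background, with a diagnostic listing a sample of the missing symbols.
    """
    if background.number_of_nodes() == 0:
        raise ValueError("background interactome is empty")
    if depth < 1:
        raise ValueError(f"expansion depth must be >= 1, got {depth}")
    present = {s for s in seeds.genes if s in background}
    missing = frozenset(seeds.genes - present)
    if not present:
        sample = ", ".join(sorted(missing)[:5])
        raise EmptyResultError(
            f"none of the {len(seeds.genes)} seeds of {seeds.name!r} occur in the "
            f"background interactome (e.g. {sample})"
        )
    if missing:
        log.info("%d/%d seeds absent from background", len(missing), len(seeds.genes))
    nodes = set(present)
    frontier = set(present)
    for _ in range(depth):
        frontier = {nbr for u in frontier for nbr in background[u]} - nodes
        nodes |= frontier
    sub = background.subgraph(nodes).copy()
    return ExpandedNetwork(
        graph=sub,
        seeds=seeds,
        label=label or seeds.provenance,
        missing=missing,
    )


def merge_networks(a: ExpandedNetwork | nx.Graph, b: ExpandedNetwork | nx.Graph) -> nx.Graph:
    """Merge two expanded networks into the integrative network.

    Node set is the *intersection* of the two node sets; edge set is the
    union of both edge sets induced on the shared nodes.  Intersection
    semantics keep only proteins reachable from both the drug and the
    disease side, which is what makes the merged network smaller than
    either input.  Commutative and idempotent.
    """
    ga = a.graph if isinstance(a, ExpandedNetwork) else a
    gb = b.graph if isinstance(b, ExpandedNetwork) else b
    if ga.number_of_nodes() == 0 or gb.number_of_nodes() == 0:
        raise ValueError("cannot merge an empty network")
    shared = set(ga.nodes()) & set(gb.nodes())
    if not shared:
        raise EmptyResultError("drug and disease networks share no nodes")
    merged = nx.Graph()
    merged.add_nodes_from(shared)
    for g in (ga, gb):
        for u, v in g.edges():
            if u in shared and v in shared:
                merged.add_edge(u, v)
    return merged
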