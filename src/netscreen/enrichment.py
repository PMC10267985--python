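"""Over-representation analysis of a target set against gene-set collections.

Given a query set of genes (the core targets) and a GMT collection
(GO-BP- or KEGG-like), each term is scored with the hypergeometric
upper tail: drawing ``n`` query genes from a universe of ``N``, the
probability of seeing at least the observed overlap ``k`` with a term of
size ``K``.  Benjamini–Hochberg FDR is reported alongside; the default
significance column is the raw p at alpha, which is how most annotation
servers report their term lists, with FDR available for stricter use.

The background universe defaults to the union of all genes occurring in
the collection; any query gene outside the universe is dropped before
testing (it carries no information about the annotation space).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .targets import TargetSet

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "hypergeom_sf", "enrich"]


@dataclass
class GeneSetCollection:
    """term_id -> (description, member genes), with a background universe."""

    terms: dict[str, tuple[str, set[str]]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*(g for _, g in self.terms.values())) if self.terms else set()
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid} has no genes")
            extra = genes - self.universe
            if extra:
                raise ValueError(f"term {tid} contains genes outside the universe: {sorted(extra)[:3]}")

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a standard GMT file: term <tab> description <tab> gene..."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if not line.strip():
                    continue
                raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
            terms[parts[0]] = (parts[1], {g.upper() for g in parts[2:] if g})
    return GeneSetCollection(terms=terms, universe=universe or set())


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, genes) in coll.terms.items():
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the over-representation tail."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query: TargetSet, coll: GeneSetCollection, alpha: float = 0.05) -> pd.DataFrame:
    """Score every term; rows sorted by p ascending.

    Columns: term_id, description, k (overlap), K (term size), n
    (effective query size), N (universe size), p, fdr, significant
    (raw p < alpha), overlap_genes.  Raises on an empty effective query.
    """
    q = query.genes & coll.universe
    if not q:
        raise ValueError(
            f"query {query.name!r} shares no genes with the collection universe"
        )
    N, n = len(coll.universe), len(q)
    rows = []
    for tid, (desc, genes) in coll.terms.items():
        overlap = q & genes
        k, K = len(overlap), len(genes)
        rows.append(
            {
                "term_id": tid,
                "description": desc,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_sf(k, N, K, n),
                "overlap_genes": ",".join(sorted(overlap)),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["p"] < alpha
    df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return df[
        ["term_id", "description", "k", "K", "n", "N", "p", "fdr", "significant", "overlap_genes"]
    ]
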