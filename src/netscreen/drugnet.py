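"""Herb → ingredient → target tables: pooling and the bipartite drug network.

A prescription of several herbs yields, per herb, a list of candidate
active ingredients, each with predicted protein targets.  The screening
pipeline only needs the pooled, deduplicated union of those targets, but
the ingredient→target bipartite structure is kept because shared targets
across ingredients are the usual first hint of synergy in a multi-herb
formula.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .targets import TargetSet

COLUMNS = ["herb", "ingredient", "target"]


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a (herb, ingredient, target) TSV; duplicates allowed on input."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"drug table {path} lacks column(s) {missing}")
    return validate_drug_table(df)


def validate_drug_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df[COLUMNS].copy()
    if df.empty:
        raise ValueError("drug table is empty")
    if df.isna().any().any() or (df.map(lambda x: str(x).strip() == "")).any().any():
        raise ValueError("drug table contains blank fields")
    df["target"] = df["target"].str.upper()
    return df


def pool_targets(table: pd.DataFrame, name: str = "drug_targets") -> TargetSet:
    """Pool and deduplicate all targets across herbs and ingredients.

    The returned set is the union over every row; per-gene support lists
    each distinct ingredient that nominates the gene, so targets hit by
    two or more ingredients (the candidate synergy core) can be counted
    with :meth:`TargetSet.multi_supported`.
    """
    table = validate_drug_table(table)
    support: dict[str, list[str]] = {}
    for _, row in table.drop_duplicates(["ingredient", "target"]).iterrows():
        support.setdefault(row["target"], []).append(row["ingredient"])
    return TargetSet(
        name=name,
        genes=set(support),
        provenance="drug",
        support=support,
    )


def build_bipartite(table: pd.DataFrame) -> nx.Graph:
    """Ingredient–target bipartite network (Figure-2-style drug network).

    Nodes carry a ``kind`` attribute ("ingredient" or "target"); edges are
    exactly the distinct (ingredient, target) pairs.
    """
    table = validate_drug_table(table)
    g = nx.Graph()
    for _, row in table.drop_duplicates(["ingredient", "target"]).iterrows():
        g.add_node(row["ingredient"], kind="ingredient", herb=row["herb"])
        g.add_node(row["target"], kind="target")
        g.add_edge(row["ingredient"], row["target"])
    return g


def overlap_stats(pooled: TargetSet) -> dict[str, int]:
    """Simple pooling summary: total targets and those shared by >=2 ingredients."""
    return {
        "n_targets": len(pooled),
        "n_shared_by_2plus_ingredients": len(pooled.multi_supported(2)),
    }
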