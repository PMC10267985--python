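"""Synthetic inputs for the whole screening pipeline, with ground truth.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so recovery of planted
signal is testable end to end:

* a scale-free background interactome grown by preferential attachment
  (the screening cascade is only meaningful on heavy-tailed graphs);
* per-study tumour/normal log2 expression matrices with a planted,
  sign-consistent core of differentially expressed genes shared across
  studies (so the multi-study intersection is non-degenerate);
* herb→ingredient→target tables whose targets can be biased toward
  interactome hubs (``hub_bias``), giving a known set of hub targets the
  cascade should recover;
* gene-set collections with terms deliberately over-sampling a
  core-like set, giving known enriched terms;
* two-arm exponential survival data at a specified hazard ratio.

All generators are driven by one integer seed in :class:`SimConfig`;
child seeds are derived per generator with fixed offsets, so the same
config is byte-identical across runs while the sub-streams stay
independent.  Gene symbols are synthetic uppercase tokens (``G000123``);
the gene universe is the expression gene list, and interactome nodes
are a seeded subset of it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import ExpressionStudy
from .enrichment import GeneSetCollection, write_gmt
from .interactome import write_edgelist
from .targets import TargetSet

__all__ = ["SimConfig", "GroundTruth", "gen_interactome", "gen_expression",
           "gen_drug_tables", "gen_genesets", "gen_survival", "simulate_all"]

# fixed child-seed offsets per generator stream
_OFF_UNIVERSE, _OFF_GRAPH, _OFF_DE, _OFF_EXPR, _OFF_DRUG, _OFF_GSET, _OFF_SURV = range(7)


def _child_seed(seed: int, offset: int) -> int:
    return (seed * 1_000_003 + offset) % (2**31 - 1)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulation, with the study-scale defaults.

    Defaults emulate the scale of the motivating screen: a six-herb
    prescription with ~4 ingredients per herb, three expression studies
    of 10 tumour vs 10 normal samples, a 1,500-node heavy-tailed
    interactome, and a ~50-patients-per-arm two-arm cohort.
    """

    seed: int = 0
    n_genes: int = 5000
    n_interactome_nodes: int = 4000
    attachment_edges: int = 7
    n_tumor: int = 10
    n_normal: int = 10
    n_studies: int = 3
    de_fraction: float = 0.02
    de_log2fc: float = 3.0
    noise_sd: float = 0.3
    n_herbs: int = 6
    ingredients_per_herb: int = 4
    targets_per_ingredient: int = 25
    n_distinct_drug_targets: int = 120
    hub_bias: float = 0.5
    n_genesets: int = 50
    geneset_size: int = 30
    n_planted_enriched: int = 5
    surv_n_per_arm: int = 50
    surv_hazard_ratio: float = 0.62
    surv_median_control_days: float = 246.0
    surv_censor_upper_days: float | None = None  # Uniform(0, c) censoring if set

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_interactome_nodes": self.n_interactome_nodes,
            "attachment_edges": self.attachment_edges,
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_studies": self.n_studies,
            "n_herbs": self.n_herbs,
            "ingredients_per_herb": self.ingredients_per_herb,
            "targets_per_ingredient": self.targets_per_ingredient,
            "surv_n_per_arm": self.surv_n_per_arm,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0,1]")
        if not 0 <= self.hub_bias <= 1:
            raise ValueError("hub_bias must be in [0,1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.surv_hazard_ratio <= 0:
            raise ValueError("surv_hazard_ratio must be > 0")
        if self.n_interactome_nodes > self.n_genes:
            raise ValueError("n_interactome_nodes cannot exceed n_genes")
        if self.n_planted_enriched > self.n_genesets:
            raise ValueError("n_planted_enriched cannot exceed n_genesets")

    def gene_universe(self) -> list[str]:
        return [f"G{i:06d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """What was planted, keyed so recovery tests can score it."""

    de_genes: dict[str, set[str]] = field(default_factory=dict)  # study_id -> planted DE
    de_signs: dict[str, int] = field(default_factory=dict)  # gene -> ±1, shared across studies
    hub_targets: set[str] = field(default_factory=set)
    planted_enriched_terms: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": {k: sorted(v) for k, v in self.de_genes.items()},
            "de_signs": self.de_signs,
            "hub_targets": sorted(self.hub_targets),
            "planted_enriched_terms": sorted(self.planted_enriched_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _interactome_symbols(cfg: SimConfig) -> list[str]:
    rng = np.random.default_rng(_child_seed(cfg.seed, _OFF_UNIVERSE))
    return [
        str(s)
        for s in rng.choice(cfg.gene_universe(), size=cfg.n_interactome_nodes, replace=False)
    ]


def gen_interactome(cfg: SimConfig) -> nx.Graph:
    """Scale-free background PPI graph via Barabási–Albert growth.

    ``attachment_edges`` (m) edges are added per incoming node, attached
    preferentially to high-degree nodes; the result is a connected
    simple graph with a heavy-tailed degree distribution, relabelled to
    gene symbols from the universe.
    """
    n, m = cfg.n_interactome_nodes, cfg.attachment_edges
    if not (n > m >= 1):
        raise ValueError(f"need n_interactome_nodes > attachment_edges >= 1, got n={n}, m={m}")
    g = nx.barabasi_albert_graph(n, m, seed=_child_seed(cfg.seed, _OFF_GRAPH))
    symbols = _interactome_symbols(cfg)
    return nx.relabel_nodes(g, {i: symbols[i] for i in range(n)})


def _planted_de(cfg: SimConfig) -> tuple[list[str], dict[str, int]]:
    # one shared planted core, sign fixed per gene across all studies
    rng = np.random.default_rng(_child_seed(cfg.seed, _OFF_DE))
    k = int(round(cfg.de_fraction * cfg.n_genes))
    genes = [str(s) for s in rng.choice(cfg.gene_universe(), size=k, replace=False)]
    signs = {g: int(s) for g, s in zip(genes, rng.choice([-1, 1], size=k))}
    return genes, signs


def gen_expression(cfg: SimConfig, study_index: int) -> tuple[ExpressionStudy, GroundTruth]:
    """One tumour/normal study with the shared planted DE core.

    Non-DE genes share a gene-specific baseline in both groups; planted
    genes get their tumour mean shifted by ``±de_log2fc`` with the sign
    fixed per gene across studies, emulating consistent tumour biology
    across series.  Noise is i.i.d. N(0, noise_sd²) on the log2 scale.
    """
    if cfg.n_tumor < 2 or cfg.n_normal < 2:
        raise ValueError("need at least 2 samples per group")
    study_id = f"study{study_index + 1}"
    de_genes, de_signs = _planted_de(cfg)
    universe = cfg.gene_universe()

    rng = np.random.default_rng(_child_seed(cfg.seed, _OFF_EXPR) + study_index)
    baseline = rng.uniform(4.0, 12.0, size=cfg.n_genes)
    shift = np.zeros(cfg.n_genes)
    idx = {g: i for i, g in enumerate(universe)}
    for g in de_genes:
        shift[idx[g]] = de_signs[g] * cfg.de_log2fc

    n_samp = cfg.n_tumor + cfg.n_normal
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samp))
    mat = baseline[:, None] + noise
    mat[:, : cfg.n_tumor] += shift[:, None]

    samples = [f"{study_id}_T{i+1}" for i in range(cfg.n_tumor)] + [
        f"{study_id}_N{i+1}" for i in range(cfg.n_normal)
    ]
    groups = pd.Series(
        ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal, index=samples, name="group"
    )
    study = ExpressionStudy(study_id, pd.DataFrame(mat, index=universe, columns=samples), groups)
    truth = GroundTruth(de_genes={study_id: set(de_genes)}, de_signs=de_signs)
    return study, truth


def gen_drug_tables(cfg: SimConfig, interactome: nx.Graph) -> tuple[pd.DataFrame, GroundTruth]:
    """Herb→ingredient→target rows with hub-biased, heavily overlapping targets.

    Target prediction for a multi-herb prescription yields a *shared*
    candidate pool far smaller than the interactome, with each
    ingredient's list drawn largely from that pool — which is why pooled
    counts grow slowly with ingredient number and overlap is the rule.
    The generator mirrors that: a prescription-level pool of
    ``n_distinct_drug_targets`` nodes is drawn first (a ``hub_bias``
    fraction from the top-degree decile of the interactome — the planted
    hubs the screen should recover — the remainder uniform over all
    nodes), then every ingredient samples its ``targets_per_ingredient``
    targets from that pool.  ``GroundTruth.hub_targets`` is the set of
    decile-drawn pool members that actually appear in the table.
    """
    if interactome.number_of_nodes() == 0:
        raise ValueError("interactome is empty")
    rng = np.random.default_rng(_child_seed(cfg.seed, _OFF_DRUG))
    nodes = sorted(interactome.nodes())
    deg = dict(interactome.degree())
    by_deg = sorted(nodes, key=lambda x: (-deg[x], x))
    hub_pool = by_deg[: max(1, len(nodes) // 10)]

    pool_size = min(cfg.n_distinct_drug_targets, len(nodes))
    n_hub = int(round(cfg.hub_bias * pool_size))
    hub_part = [str(s) for s in rng.choice(hub_pool, size=min(n_hub, len(hub_pool)), replace=False)]
    uniform_part: list[str] = []
    hub_set = set(hub_part)
    remaining = [n for n in nodes if n not in hub_set]
    if pool_size - len(hub_part) > 0:
        uniform_part = [
            str(s) for s in rng.choice(remaining, size=pool_size - len(hub_part), replace=False)
        ]
    pool = hub_part + uniform_part

    rows = []
    drawn: set[str] = set()
    for h in range(cfg.n_herbs):
        for i in range(cfg.ingredients_per_herb):
            ingredient = f"H{h+1}_I{i+1}"
            k = min(cfg.targets_per_ingredient, len(pool))
            for t in rng.choice(pool, size=k, replace=False):
                t = str(t)
                drawn.add(t)
                rows.append({"herb": f"HERB{h+1}", "ingredient": ingredient, "target": t})
    table = pd.DataFrame(rows, columns=["herb", "ingredient", "target"])
    return table, GroundTruth(hub_targets=set(hub_part) & drawn)


def gen_genesets(cfg: SimConfig, core_like: TargetSet) -> tuple[GeneSetCollection, GroundTruth]:
    """A GMT-style collection with ``n_planted_enriched`` enriched terms.

    Planted terms draw at least half their members from ``core_like``;
    all other members, and all members of background terms, are sampled
    uniformly from the gene universe.
    """
    universe = cfg.gene_universe()
    if cfg.geneset_size > len(universe):
        raise ValueError("geneset_size exceeds the gene universe")
    core = sorted(core_like.genes & set(universe))
    if cfg.n_planted_enriched > 0 and not core:
        raise ValueError("cannot plant enriched terms: core set empty in universe")
    rng = np.random.default_rng(_child_seed(cfg.seed, _OFF_GSET))

    terms: dict[str, tuple[str, set[str]]] = {}
    planted: set[str] = set()
    for j in range(cfg.n_genesets):
        tid = f"TERM{j+1:04d}"
        if j < cfg.n_planted_enriched:
            n_core = min(len(core), (cfg.geneset_size + 1) // 2)
            members = set(str(s) for s in rng.choice(core, size=n_core, replace=False))
            planted.add(tid)
        else:
            members = set()
        while len(members) < cfg.geneset_size:
            members.add(str(universe[rng.integers(len(universe))]))
        desc = "planted enriched term" if tid in planted else "background term"
        terms[tid] = (desc, members)
    coll = GeneSetCollection(terms=terms, universe=set(universe))
    return coll, GroundTruth(planted_enriched_terms=planted)


def gen_survival(cfg: SimConfig) -> pd.DataFrame:
    """Two-arm exponential survival at the configured hazard ratio.

    The control (nonexposure) arm has median ``surv_median_control_days``
    (rate λ = ln2/median); the exposure arm's rate is λ·HR, so HR < 1
    means longer survival under exposure.  Optional Uniform(0, c)
    censoring when ``surv_censor_upper_days`` is set.
    """
    rng = np.random.default_rng(_child_seed(cfg.seed, _OFF_SURV))
    lam = np.log(2) / cfg.surv_median_control_days
    n = cfg.surv_n_per_arm
    t_exp = rng.exponential(1.0 / (lam * cfg.surv_hazard_ratio), size=n)
    t_non = rng.exponential(1.0 / lam, size=n)
    times = np.concatenate([t_exp, t_non])
    events = np.ones(2 * n, dtype=int)
    if cfg.surv_censor_upper_days is not None:
        cens = rng.uniform(0, cfg.surv_censor_upper_days, size=2 * n)
        events = (times <= cens).astype(int)
        times = np.minimum(times, cens)
    return pd.DataFrame(
        {
            "id": [f"P{i+1:03d}" for i in range(2 * n)],
            "time_days": times,
            "event": events,
            "arm": ["exposure"] * n + ["nonexposure"] * n,
        }
    )


def simulate_all(cfg: SimConfig, outdir: str | Path) -> GroundTruth:
    """Write every pipeline input to ``outdir`` and return merged truth.

    Files: ``interactome.tsv``, ``expr{N}.tsv`` + ``expr{N}.groups.tsv``
    per study, ``drug_targets.tsv``, ``genesets.gmt``, ``survival.tsv``,
    ``truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = GroundTruth()

    g = gen_interactome(cfg)
    write_edgelist(g, outdir / "interactome.tsv")

    for s in range(cfg.n_studies):
        study, t = gen_expression(cfg, s)
        study.values.round(4).to_csv(outdir / f"expr{s+1}.tsv", sep="\t")
        study.groups.rename("group").to_csv(outdir / f"expr{s+1}.groups.tsv", sep="\t")
        truth.de_genes.update(t.de_genes)
        truth.de_signs = t.de_signs

    drug_table, t = gen_drug_tables(cfg, g)
    drug_table.to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)
    truth.hub_targets = t.hub_targets

    # gene sets planted around what the screen *should* find: the hub targets
    core_like = TargetSet("planted_core", set(truth.hub_targets) or set(g.nodes()))
    coll, t = gen_genesets(cfg, core_like)
    write_gmt(coll, outdir / "genesets.gmt")
    truth.planted_enriched_terms = t.planted_enriched_terms

    gen_survival(cfg).round(2).to_csv(outdir / "survival.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    (outdir / "simconfig.json").write_text(json.dumps(asdict(cfg), indent=1))
    return truth
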