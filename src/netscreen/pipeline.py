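"""End-to-end orchestration: simulate/load → targets → networks → core → enrichment.

One :class:`RunConfig` drives the whole screen.  Inputs either come from
files (drug table, expression studies, background edge list, GMT) or are
generated in place from an embedded :class:`~netscreen.synthetic.SimConfig`.
The stages run in a fixed order; any stage that would produce an empty
result aborts with a stage-named diagnostic, and a machine-readable
:class:`RunReport` mirrors the chain of counts the screen produces
(drug targets → disease targets → two expanded networks → merged →
stage-1 "key" network → stage-2 core → significant terms).
"""

from __future__ import annotations

import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .diffexpr import DEConfig, ExpressionStudy, de_summary_table, de_test, intersect_targets
from .drugnet import build_bipartite, overlap_stats, pool_targets, read_drug_table
from .enrichment import enrich, read_gmt
from .interactome import expand_seeds, merge_networks, read_edgelist, write_edgelist
from .synthetic import SimConfig, simulate_all
from .targets import TargetSet
from .topo import screen_core

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_all"]


@dataclass
class RunConfig:
    outdir: Path
    # either simulate from this config ...
    sim: SimConfig | None = None
    # ... or read these inputs (paths relative to cwd)
    drug_table: Path | None = None
    expression: list[tuple[Path, Path]] = field(default_factory=list)  # (expr, groups)
    background: Path | None = None
    gmt: Path | None = None
    de: DEConfig = field(default_factory=DEConfig)
    expansion_depth: int = 1
    enrich_alpha: float = 0.05

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        kw: dict = {"outdir": Path(raw.get("outdir", "netscreen_out"))}
        if "sim" in raw:
            kw["sim"] = SimConfig(**raw["sim"])
        inputs = raw.get("inputs", {})
        if "drug_table" in inputs:
            kw["drug_table"] = Path(inputs["drug_table"])
        if "background" in inputs:
            kw["background"] = Path(inputs["background"])
        if "gmt" in inputs:
            kw["gmt"] = Path(inputs["gmt"])
        kw["expression"] = [
            (Path(e["values"]), Path(e["groups"])) for e in inputs.get("expression", [])
        ]
        if "de" in raw:
            kw["de"] = DEConfig(**raw["de"])
        for key in ("expansion_depth", "enrich_alpha"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


@dataclass
class RunReport:
    n_drug_targets: int = 0
    n_disease_targets: int = 0
    drug_net: tuple[int, int] = (0, 0)  # (nodes, edges)
    disease_net: tuple[int, int] = (0, 0)
    merged: tuple[int, int] = (0, 0)
    key_net: tuple[int, int] = (0, 0)  # stage-1 survivors
    core: tuple[int, int] = (0, 0)  # stage-2 survivors
    screen: dict = field(default_factory=dict)
    n_terms_tested: int = 0
    n_terms_significant: int = 0
    fallback_triggered: bool = False
    stage_seconds: dict[str, float] = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    version: str = __version__

    def chain(self) -> dict[str, int]:
        """The node-count chain the screen narrows through."""
        return {
            "drug_net_nodes": self.drug_net[0],
            "disease_net_nodes": self.disease_net[0],
            "merged_nodes": self.merged[0],
            "key_nodes": self.key_net[0],
            "core_nodes": self.core[0],
        }

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.__dict__.items() if k != "stage_seconds"}
        payload["chain"] = self.chain()
        payload["stage_seconds"] = {k: round(v, 3) for k, v in self.stage_seconds.items()}
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


class _Timer:
    def __init__(self, report: RunReport):
        self.report = report

    def __call__(self, stage: str):
        return _StageTimer(self.report, stage)


class _StageTimer:
    def __init__(self, report: RunReport, stage: str):
        self.report, self.stage = report, stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s ...", self.stage)

    def __exit__(self, exc_type, exc, tb):
        self.report.stage_seconds[self.stage] = time.perf_counter() - self.t0
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.stage!r} failed: {exc}") from exc


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the full screen; artifacts and ``report.json`` in ``outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    timer = _Timer(report)

    with timer("simulate"):
        if cfg.sim is not None:
            simulate_all(cfg.sim, outdir / "inputs")
            indir = outdir / "inputs"
            drug_path = indir / "drug_targets.tsv"
            bg_path = indir / "interactome.tsv"
            gmt_path = indir / "genesets.gmt"
            expr_paths = [
                (indir / f"expr{i+1}.tsv", indir / f"expr{i+1}.groups.tsv")
                for i in range(cfg.sim.n_studies)
            ]
            report.config_echo["sim"] = json.loads(json.dumps(cfg.sim.__dict__, default=str))
        else:
            if not (cfg.drug_table and cfg.background and cfg.expression):
                raise ValueError("RunConfig needs either sim= or all input paths")
            drug_path, bg_path, gmt_path = cfg.drug_table, cfg.background, cfg.gmt
            expr_paths = cfg.expression
    report.config_echo["de"] = cfg.de.__dict__.copy()
    report.config_echo["expansion_depth"] = cfg.expansion_depth

    with timer("drug_targets"):
        table = read_drug_table(drug_path)
        drug = pool_targets(table)
        drug.to_tsv(outdir / "drug_targets_pooled.tsv")
        write_edgelist(build_bipartite(table), outdir / "drugnet_edges.tsv")
        report.n_drug_targets = len(drug)
        report.config_echo["drug_overlap"] = overlap_stats(drug)
        if len(drug) == 0:
            raise ValueError("no drug targets after pooling")

    with timer("disease_targets"):
        results = [
            de_test(ExpressionStudy.from_tsv(v, g), cfg.de) for v, g in expr_paths
        ]
        disease = intersect_targets(results)
        disease.to_tsv(outdir / "disease_targets.tsv")
        de_summary_table(results).round(4).to_csv(outdir / "de_summary.tsv", sep="\t")
        report.n_disease_targets = len(disease)
        if len(disease) == 0:
            raise ValueError("no disease targets pass the DE screen in all studies")

    with timer("expand"):
        background = read_edgelist(bg_path)
        drug_net = expand_seeds(background, drug, depth=cfg.expansion_depth, label="drug")
        disease_net = expand_seeds(background, disease, depth=cfg.expansion_depth, label="disease")
        write_edgelist(drug_net.graph, outdir / "drug_ppi.tsv")
        write_edgelist(disease_net.graph, outdir / "disease_ppi.tsv")
        report.drug_net = (drug_net.n_nodes, drug_net.n_edges)
        report.disease_net = (disease_net.n_nodes, disease_net.n_edges)

    with timer("merge"):
        merged = merge_networks(drug_net, disease_net)
        write_edgelist(merged, outdir / "merged_ppi.tsv")
        report.merged = (merged.number_of_nodes(), merged.number_of_edges())

    with timer("screen"):
        sr = screen_core(merged)
        assert sr.core is not None
        write_edgelist(sr.core, outdir / "core_ppi.tsv")
        core_set = TargetSet("core_targets", set(sr.core.nodes()), provenance="drug")
        core_set.to_tsv(outdir / "core_targets.tsv")
        report.key_net = (len(sr.stage1_nodes), sr.stage1_edges)
        report.core = (len(sr.stage2_nodes), sr.stage2_edges)
        report.screen = sr.to_dict()
        report.fallback_triggered = sr.fallback_triggered

    if gmt_path is not None:
        with timer("enrich"):
            coll = read_gmt(gmt_path)
            enr = enrich(core_set, coll, alpha=cfg.enrich_alpha)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report.n_terms_tested = len(enr)
            report.n_terms_significant = int(enr["significant"].sum())

    report.to_json(outdir / "report.json")
    return report
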