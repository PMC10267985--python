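"""Generators: determinism, planted structure, conservation of symbols."""

import filecmp

import networkx as nx
import numpy as np
import pytest

from netscreen import (
    SimConfig,
    gen_drug_tables,
    gen_expression,
    gen_genesets,
    gen_interactome,
    gen_survival,
    km_curve,
    simulate_all,
)
from netscreen.targets import TargetSet


class TestSimConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_genes": 0},
            {"noise_sd": 0.0},
            {"noise_sd": -1.0},
            {"de_fraction": 1.5},
            {"hub_bias": -0.1},
            {"surv_hazard_ratio": 0.0},
            {"n_interactome_nodes": 10_000, "n_genes": 100},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimConfig(**kw)


class TestInteractome:
    def test_m1_preferential_attachment_gives_tree(self):
        cfg = SimConfig(seed=7, n_genes=20, n_interactome_nodes=10, attachment_edges=1)
        g = gen_interactome(cfg)
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 9
        assert nx.is_connected(g)

    def test_seeded_determinism(self):
        cfg = SimConfig(seed=7, n_genes=20, n_interactome_nodes=10, attachment_edges=1)
        g1, g2 = gen_interactome(cfg), gen_interactome(cfg)
        assert sorted(g1.edges()) == sorted(g2.edges())

    def test_heavy_tail_max_degree_far_above_median(self):
        cfg = SimConfig(seed=1, n_genes=600, n_interactome_nodes=500, attachment_edges=3)
        g = gen_interactome(cfg)
        degs = sorted(d for _, d in g.degree())
        assert degs[-1] >= 5 * degs[len(degs) // 2]

    def test_simple_connected_no_self_loops(self, small_cfg):
        g = gen_interactome(small_cfg)
        assert nx.is_connected(g)
        assert nx.number_of_selfloops(g) == 0

    def test_degenerate_sizes_rejected(self):
        cfg = SimConfig(seed=0, n_genes=10, n_interactome_nodes=3, attachment_edges=5)
        with pytest.raises(ValueError):
            gen_interactome(cfg)


class TestExpression:
    def test_no_de_fraction_means_empty_truth(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "de_fraction": 0.0})
        study, truth = gen_expression(cfg, 0)
        assert truth.de_genes[study.study_id] == set()

    def test_planted_signs_fixed_across_studies(self, small_cfg):
        _, t0 = gen_expression(small_cfg, 0)
        _, t1 = gen_expression(small_cfg, 1)
        assert t0.de_signs == t1.de_signs
        assert t0.de_genes["study1"] == t1.de_genes["study2"]

    def test_planted_shift_visible_in_group_means(self, small_cfg):
        study, truth = gen_expression(small_cfg, 0)
        de = sorted(truth.de_genes[study.study_id])
        tum = study.values.loc[de, study.groups == "tumor"].mean(axis=1)
        nor = study.values.loc[de, study.groups == "normal"].mean(axis=1)
        observed = tum - nor
        expected = np.array([truth.de_signs[g] * small_cfg.de_log2fc for g in de])
        assert np.allclose(observed, expected, atol=0.5)

    def test_too_few_samples_rejected(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "n_tumor": 1})
        with pytest.raises(ValueError):
            gen_expression(cfg, 0)


class TestDrugTables:
    def test_row_and_ingredient_counts(self, small_cfg):
        g = gen_interactome(small_cfg)
        table, _ = gen_drug_tables(small_cfg, g)
        n_ing = small_cfg.n_herbs * small_cfg.ingredients_per_herb
        assert table["ingredient"].nunique() == n_ing
        assert len(table) == n_ing * small_cfg.targets_per_ingredient

    def test_targets_live_in_interactome(self, small_cfg):
        g = gen_interactome(small_cfg)
        table, truth = gen_drug_tables(small_cfg, g)
        assert set(table["target"]) <= set(g.nodes())
        assert truth.hub_targets <= set(table["target"])

    def test_zero_hub_bias_plants_no_hubs(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "hub_bias": 0.0})
        g = gen_interactome(cfg)
        _, truth = gen_drug_tables(cfg, g)
        assert truth.hub_targets == set()

    def test_full_hub_bias_draws_only_top_decile(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "hub_bias": 1.0})
        g = gen_interactome(cfg)
        table, truth = gen_drug_tables(cfg, g)
        deg = dict(g.degree())
        decile = sorted(g.nodes(), key=lambda x: (-deg[x], x))[: len(deg) // 10]
        assert set(table["target"]) <= set(decile)
        assert truth.hub_targets == set(table["target"])

    def test_distinct_targets_bounded_by_draws(self, small_cfg):
        g = gen_interactome(small_cfg)
        table, _ = gen_drug_tables(small_cfg, g)
        n_draws = len(table)
        assert table["target"].nunique() <= min(n_draws, small_cfg.n_distinct_drug_targets)


class TestGenesets:
    def test_oversized_sets_rejected(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "geneset_size": 10_000})
        core = TargetSet("c", {"G000001"})
        with pytest.raises(ValueError):
            gen_genesets(cfg, core)

    def test_planted_terms_oversample_core(self, small_cfg):
        core = TargetSet("c", {f"G{i:06d}" for i in range(40)})
        coll, truth = gen_genesets(small_cfg, core)
        assert len(truth.planted_enriched_terms) == small_cfg.n_planted_enriched
        for tid in truth.planted_enriched_terms:
            _, genes = coll.terms[tid]
            assert len(genes & core.genes) >= small_cfg.geneset_size // 2

    def test_collection_sizes(self, small_cfg):
        core = TargetSet("c", {f"G{i:06d}" for i in range(40)})
        coll, _ = gen_genesets(small_cfg, core)
        assert len(coll) == small_cfg.n_genesets
        assert all(len(g) == small_cfg.geneset_size for _, g in coll.terms.values())


class TestSurvival:
    def test_arms_and_schema(self, small_cfg):
        t = gen_survival(small_cfg)
        assert len(t) == 2 * small_cfg.surv_n_per_arm
        assert set(t["arm"]) == {"exposure", "nonexposure"}
        assert (t["time_days"] >= 0).all()

    def test_hazard_ratio_shifts_exposure_times_up(self):
        cfg = SimConfig(seed=3, surv_n_per_arm=500, surv_hazard_ratio=0.5)
        t = gen_survival(cfg)
        assert (
            t.loc[t.arm == "exposure", "time_days"].median()
            > t.loc[t.arm == "nonexposure", "time_days"].median()
        )

    def test_all_censored_handled_km_median_undefined(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "surv_censor_upper_days": 1e-6})
        t = gen_survival(cfg)
        assert (t["event"] == 0).all()
        km = km_curve(t, "exposure")
        assert not km.median_defined


class TestSimulateAll:
    def test_byte_identical_outputs_and_symbol_conservation(self, small_cfg, tmp_path):
        truth = simulate_all(small_cfg, tmp_path / "a")
        simulate_all(small_cfg, tmp_path / "b")
        names = [
            "interactome.tsv", "expr1.tsv", "expr1.groups.tsv",
            "drug_targets.tsv", "genesets.gmt", "survival.tsv", "truth.json",
        ]
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert mismatch == [] and errors == []
        universe = set(small_cfg.gene_universe())
        for study_genes in truth.de_genes.values():
            assert study_genes <= universe
        assert truth.hub_targets <= universe
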