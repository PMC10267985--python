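"""Hypergeometric over-representation of a core set in a GMT collection."""

from netscreen import SimConfig, TargetSet, enrich, gen_genesets

cfg = SimConfig(seed=1)
core = TargetSet("core", set(cfg.gene_universe()[:100]))
coll, truth = gen_genesets(cfg, core)

rows = enrich(core, coll, alpha=0.05)
print(rows.head(7)[["term_id", "k", "K", "p", "fdr", "significant"]].to_string(index=False))
top = set(rows.head(cfg.n_planted_enriched)["term_id"])
print(f"planted terms in top {cfg.n_planted_enriched} by p: "
      f"{len(top & truth.planted_enriched_terms)}/{len(truth.planted_enriched_terms)}")
# k of K term genes overlap the n-gene query in an N-gene universe;
# p is the upper-tail hypergeometric probability of that overlap.
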