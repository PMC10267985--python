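"""Generate every synthetic input the screen consumes, with ground truth.

The generator plants recoverable structure: a heavy-tailed interactome,
a shared core of differentially expressed genes, hub-biased drug
targets, enriched gene-set terms and a two-arm survival difference.
"""

from netscreen import SimConfig, simulate_all

cfg = SimConfig(seed=1)
truth = simulate_all(cfg, "scratch/example_inputs")

print(f"interactome: {cfg.n_interactome_nodes} nodes (preferential attachment, m={cfg.attachment_edges})")
print(f"expression: {cfg.n_studies} studies, {cfg.n_tumor} tumour vs {cfg.n_normal} normal")
print(f"planted DE genes per study: {len(truth.de_signs)} (sign fixed across studies)")
print(f"drug table: {cfg.n_herbs} herbs x {cfg.ingredients_per_herb} ingredients, "
      f"{len(truth.hub_targets)} planted hub targets")
print(f"gene sets: {cfg.n_genesets} terms, {len(truth.planted_enriched_terms)} planted enriched")
print("files written to scratch/example_inputs/ (TSV/GMT/JSON)")
# The planted labels in truth.json are what recovery tests score against.
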