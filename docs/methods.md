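# Methods

## The screening model

`netscreen` treats core-target discovery as a graph-restriction
problem. Two seed sets — pooled drug targets and multi-study disease
targets — are each expanded to their first-neighbour subnetwork of a
background protein–protein interactome, the expansions are merged, and
the merged network is reduced by a two-stage, median-adaptive
centrality cascade. The surviving nodes ("core targets") are scored
for gene-set over-representation. The method's central assumption is
that the background interactome is heavy-tailed: median-relative
thresholds carve out the hub backbone only when a hub backbone exists.
On a degree-regular graph the cascade would retain everything (see
*Degenerate inputs*).

### Differential-expression screen

Each study is a genes × samples log2 matrix with tumour/normal labels.
Per gene we use a two-sided Welch two-sample *t*-test (unequal
variances) and Benjamini–Hochberg adjustment across all tested genes.
A gene passes at |log2FC| ≥ log2(`fc_threshold`) and (adjusted or raw)
*p* < `alpha`; defaults are fold change 2 with adjusted *p* < 0.05, and
a stricter raw *p* < 0.01 preset (`PRESET_RAW_P01`) is provided because
both rules are in common use with two-fold screens. The fold-change cut
is symmetric: up- and down-regulation both count. Duplicate gene rows
(multiple probes) are collapsed to the row with maximal |log2FC| before
testing — deterministic and signal-preserving. Genes with zero variance
in both groups are untestable and get *p* = 1 with a flag. Web tools
for this screen typically use a moderated (empirical-Bayes) *t*;
Welch's test is the dependency-free desk equivalent, and the test
choice is configurable by design so a moderated variant can be added
without touching the intersection logic. Disease targets are the genes
passing in *every* study, an intersection that is order-invariant and
idempotent.

### Expansion and merge

Expansion depth is fixed at 1 by default (seeds plus direct
interactors, a config knob): first-neighbour growth is the standard
behaviour of interactome-construction tools, and deeper expansion
rapidly swallows the whole graph. Seeds absent from the background are
reported, not fatal. **Merge semantics**: node set = intersection of
the two node sets, edge set = union of both edge sets induced on the
shared nodes. Intersection (rather than graph union) is what makes the
merged network smaller than either input and is the reading consistent
with published size chains in this kind of screen, where the merged
"integrative" network is reported smaller than both inputs; it is an
inference, stated prominently because the literature rarely spells the
rule out. Merging is commutative and idempotent.

### Centrality cascade

Conventions, chosen from the magnitudes such screens print:

* **DC** — raw integer degree (printed cuts in this literature are
  integers);
* **BC** — Brandes' exact betweenness, normalised by (n−1)(n−2)/2
  (printed cuts ≪ 1 imply the normalised form);
* **CC** — classic closeness, (n−1)/Σ of shortest-path distances,
  well defined because every pass restricts to a connected component
  first.

Stage 1 keeps nodes with DC **strictly** greater than twice the median
degree, re-induces, and re-restricts to the largest component; stage 2
recomputes all three centralities on the stage-1 network and keeps
nodes strictly above all three medians. "Strictly" means ties are
excluded. Medians use the average-of-middle-two convention for even n.
Thresholds are always derived from the current network's medians, never
hard-coded, so the cascade is scale-adaptive. If a stage would retain
nothing (a regular graph, a single node), it returns its input
unchanged with `fallback_triggered` set: degenerate inputs must flag,
not crash or silently empty a pipeline.

### Enrichment

Per term, the upper-tail hypergeometric probability P(X ≥ k) of
observing overlap k between an n-gene query and a K-gene term in an
N-gene universe; BH-FDR across all terms tested. The default universe
is the union of the collection's genes — the usual behaviour of
annotation servers when no background is supplied — and is
configurable. Significance defaults to raw *p* < 0.05 (how these term
lists are typically reported) with FDR always present in the output.
The jackknifed "EASE-score" variant (k−1 in the numerator) is *not*
used; this is plain one-sided Fisher/hypergeometric.

### Cohort statistics

Kaplan–Meier product-limit curves per arm with the median defined as
the smallest observed time with S(t) ≤ 0.5 (flagged undefined when the
curve never reaches 0.5); the standard two-group log-rank chi-square
(1 df); Pearson chi-square on 2×2 event-by-arm tables with Yates
continuity correction on by default (the variant used by any given
published table is usually unstated; both variants are exposed, and the
printed p-values of such tables are therefore not treated as exact
references); incidence percentages rounded half-up to integers, the
display convention of clinical tables. Two plain-text fixtures
transcribed from published summary tables ship with the package: nine
stage-D survival times (5 exposure / 4 nonexposure) and a ten-row
adverse-event count table for 50 vs 47 patients. All nine survival
times are treated as events; one case carries a lost-to-follow-up
footnote in the source, and re-coding it censored changes the
nonexposure median from 64 to 67 days — a one-cell edit in the fixture
if that reading is preferred. Cox regression is deliberately out of
scope: published hazard ratios require patient-level data that summary
tables do not contain, so they are documented references, not
reproducible quantities.

## The synthetic-data generator

One integer seed drives everything; per-generator child seeds are
derived as `seed·1000003 + offset (mod 2³¹−1)`, so outputs are
byte-identical across runs and sub-streams are independent. Gene
symbols are synthetic tokens (`G000123`); the universe is the
expression gene list and interactome nodes are a seeded subset of it,
which removes any identifier-mapping concern.

What it emulates, and the defaults (the study conditions):

* **Interactome** — Barabási–Albert preferential attachment,
  4,000 nodes, m = 7 edges per new node. Growth by preferential
  attachment gives the heavy-tailed degree structure real interactomes
  have, which the cascade needs. Real curated interactomes are larger
  (~17k nodes) and denser; 4,000/m=7 is a quarter-scale stand-in that
  keeps exact Brandes betweenness affordable across many seeded runs.
* **Expression** — 3 studies, 10 tumour vs 10 normal each; 2% of the
  5,000-gene universe planted as differentially expressed at ±3 log2
  units with N(0, 0.3²) noise on gene-specific baselines. The planted
  fraction mirrors the few-hundred-of-twenty-thousand scale of real
  tumour/normal intersections; the sign is fixed per gene across
  studies (consistent tumour biology), which is what makes the
  three-study intersection non-degenerate.
* **Drug tables** — 6 herbs × 4 ingredients × 25 targets per
  ingredient, drawn from a prescription-level candidate pool of 120
  distinct targets (3% of the interactome, matching the proportion of
  pooled predicted targets to interactome size in real screens). A
  `hub_bias` fraction of the pool comes from the top-degree decile —
  the planted hubs. Sampling every ingredient from one shared pool
  produces the heavy ingredient-overlap real target predictions show;
  independent per-ingredient sampling does not.
* **Gene sets** — 50 terms of 30 genes; 5 planted terms draw at least
  half their members from a supplied core-like set, the rest uniform.
* **Survival** — exponential event times, control median 246 days,
  exposure rate multiplied by a hazard ratio of 0.62, 50 patients per
  arm (the scale of a small two-arm cohort); optional Uniform(0, c)
  censoring.

What it does **not** emulate: probe-level microarray structure,
normalisation artefacts, batch effects, correlated noise between genes,
interaction-evidence quality, or annotation redundancy between terms.
Passing recovery tests therefore show the pipeline's logic is sound
under its own assumptions, not that real data meet those assumptions.

## Numerical and design choices

* Medians: average-of-middle-two for even n, everywhere.
* Strict inequalities in both cascade stages; ties drop.
* Disconnected graphs are restricted to the largest connected
  component (deterministic tie-break by size, then lexicographically
  smallest member) before any centrality pass, with a log line.
* Self-loops and duplicate edges in input edge lists are silently
  collapsed with a logged count.
* Chi-square on a 2×2 with a zero margin raises (the approximation is
  meaningless there) with a pointer to the exact test.
* Empty-result stages raise stage-named errors in the pipeline rather
  than propagating empty sets.
* Problem sizes in the test suite and acceptance script (graphs of
  ≤ 8 nodes for brute-force oracle comparisons, 100 random instances,
  20 seeds × 2,000 genes for null calibration, 10 seeds for
  pipeline-level recovery) are chosen so exhaustive enumeration stays
  exact and the whole suite runs in well under a minute of simulation
  per property.

## Known limitations

* The cascade's selectivity (top few percent of nodes by centrality)
  is much sharper than the top-degree *decile* used to define planted
  hubs, so whole-decile-scale planted sets can never be fully
  recovered in the core — the recovered core is hub-*pure* rather than
  hub-*complete*. Tests assert the directional property (the core is
  strongly hub-enriched) and measure the absolute recovery fraction.
* Welch *t* is slightly conservative relative to moderated tests at
  n = 10 per group; published target counts obtained with moderated
  tests will not be matched exactly by design.
* The merge rule is an inference from printed size chains (see above).
* Betweenness is exact, not approximated; very large merged networks
  (≫10⁴ nodes) would need an approximate BC backend that this package
  intentionally does not include.
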