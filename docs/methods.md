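# Methods

`netpharm` implements a network-pharmacology workflow for a multi-compound
herbal formula acting on a disease gene set: pharmacokinetic triage of
candidate compounds, construction of four typed interaction networks,
detection of densely connected modules, over-representation analysis (ORA)
of module gene sets, and partition of the drug–disease overlap of enriched
biological processes by disease etiology. This note records the models, the
parameters that matter, the numerical conventions, and what the synthetic
benchmarks do and do not establish.

## ADME triage

Each compound carries three precomputed properties: oral bioavailability
(OB, percent), Caco-2 monolayer permeability (dimensionless in-silico
score), and drug-likeness (DL). DL is the Tanimoto similarity between a
compound's molecular-descriptor vector x and an average-drug reference
vector y:

    f(x, y) = x·y / (|x|² + |y|² − x·y)

For non-negative vectors the score is symmetric and bounded in [0, 1]
(Cauchy–Schwarz). The composition of the descriptor vector is deliberately
opaque: the package treats it as a fixed-dimension non-negative vector, and
negative components are rejected at validation because the bound does not
hold for them. The reference vector is user-supplied; computing a real
drug-database average is out of scope.

The inclusion rule is `OB ≥ 30`, `Caco-2 > −0.4`, `DL ≥ 0.18` — note the
mixed boundary semantics: OB and DL inclusive, Caco-2 strict. The filter
reports, for every excluded compound, the first criterion it fails (checked
in the order OB, Caco-2, DL), never silently drops a record with missing
properties, and is idempotent.

## Typed networks

Nodes carry one of five roles: `compound`, `compound_target`,
`disease_target`, `shared_target` (a protein that is both a compound target
and a disease gene), `other_protein`. All graphs are simple and undirected.

1. **Disease network** — the induced subnetwork of the confidence-filtered
   PPI on the disease gene set; genes with no within-set interaction are
   dropped (this is why an input list of 131 genes can yield a 113-node
   network).
2. **Compound-target bipartite network** — one edge per distinct
   (compound, target) association; no target–target edges at this stage.
3. **Merged network** — exact node union of the two, plus every filtered
   PPI edge between protein-role nodes of the union; roles recomputed so
   dual-membership proteins become `shared_target`. The incremental
   node/edge report is emitted against *both* components, labeled, because
   either baseline can be the one a reader wants.
4. **Expanded network** — the merged core grown by the first PPI neighbors
   of its protein nodes; added nodes are `other_protein` unless they match
   a disease gene. All filtered PPI edges among the expanded node set are
   kept.

PPI confidences must lie in [0, 1]; an edge is admitted only when its
confidence is strictly greater than the threshold (default 0.4).
Undirected duplicates keep the maximum confidence; self-loops are dropped.
Identifiers are matched exactly and case-sensitively — symbol
normalization is a curation task, not a graph operation.

## Module detection

The detector is a from-scratch implementation of the three-stage
molecular-complex detection algorithm (k-core-based vertex weighting,
seeded greedy growth, post-processing). Defaults follow the widely used
plug-in: degree cutoff 2, node score cutoff 0.2, k-core filter 2, max
depth 100, haircut on, fluff off. Density is 2E/(n(n−1)) throughout;
cluster score is density × member count. All tie-breaks (seed choice,
equal weights, equal scores) are lexicographic on node identifier, making
runs fully deterministic. The k-core extraction inside stages 1 and 3 uses
`networkx.core_number` / `k_core`; the test suite checks stage-1 weights
against an independent exhaustive subset-enumeration oracle on all graphs
of ≤ 10 nodes in a generated corpus.

Two deliberate deviations from the original plug-in:

- **Fluff** only adds nodes not already assigned to another cluster, so
  clusters are always node-disjoint (the original allows overlap when
  fluffing). Fluff is off by default.
- Zero-weight vertices never seed a cluster; with a zero seed weight the
  growth threshold would be vacuous and a single complex would swallow an
  entire connected component.

**Known limitation — bridged equal-density modules merge.** Growth admits
any neighbor whose weight is at least `seed_weight × (1 − node_score_cutoff)`.
On planted-partition graphs whose modules are equally dense, a single
between-module edge ("bridge") lets the first complex absorb the
neighboring module, because every node in it also clears the threshold. At
3 modules × 10 nodes with p_in = 0.95 and p_out = 0.02 a graph carries ~6
bridges on average (the probability of none is ≈ 0.2 %), and measured mean
best-match Jaccard over 50 seeds is ≈ 0.49 at the default cutoff and
≤ 0.65 at any cutoff in [0, 0.2]. This is a property of the seed-relative
greedy rule, not of this implementation: recovery is exact (Jaccard 1.0)
on bridge-free fixtures (p_out = 0), which the unit suite verifies. On real
PPI networks the algorithm behaves as intended because vertex weights fall
off away from dense cores; on uniformly dense benchmarks it under-segments.

## Over-representation analysis

For a query of n genes (restricted to the annotation universe of N genes)
and a term with K annotated genes, the raw p-value of an observed overlap
k is the hypergeometric upper tail P(X ≥ k), evaluated with
`scipy.stats.hypergeom.sf`. The conservative EASE variant evaluates the
tail at k − 1 and is offered for comparability with annotation servers
that report it; tests verify both against exact enumeration for every
(k, K, n, N) with N ≤ 12.

The Bonferroni multiplier is the number of terms actually tested for the
query (terms with k ≥ 1) — common ORA practice; a term is significant when
the adjusted p falls below alpha (default 0.05). The universe defaults to
all annotated genes of the catalog; it is explicit and configurable
because background choice is the largest single lever in ORA. Monte-Carlo
checks: under a pure null (random 20-gene queries, 100-term catalog,
2000-gene universe, 1000 replicates) the family-wise error stays within
the Bonferroni guarantee (measured ≈ 0.03); a term planted at strength 10
(module genes 10× the background inclusion probability, i.e. 0.5 vs 0.05)
is detected in ≥ 95 % of 200 seeds.

## Drug–disease overlap and etiology partition

Each side's significant terms are unioned across its clusters; the overlap
is an exact set intersection. Overlapping terms are then assigned to named
disease-etiology categories. The packaged default mapping for
pregnancy-induced hypertension holds four categories (endothelial cell
activation and injury; placental or trophoblast cell ischemia; hypoxia and
oxidative stress; maternal–fetal immune tolerance disorders). The mapping
is editorial domain judgment and therefore ships as a versioned YAML data
file users can replace. A term may appear in at most one category —
duplicates are a load-time error — so counts always conserve cardinality.
One term (GO:0045766, positive regulation of angiogenesis) could plausibly
sit in two categories; the packaged file assigns it to the
placental/trophoblast ischemia category.

## Synthetic data

The generators emulate the five inputs with known ground truth. Defaults
mirror the scale of the published analysis: 77 compounds, a 0.52-dense
bipartite layer (⇒ ~17 k associations at 432 targets), 131 disease genes
with 0.5 expected overlap against compound targets, planted-partition PPI
(p_in = 0.9, p_out = 0.05), background term density 0.05. Each generator
draws from its own PCG64 stream derived from the single seed plus a fixed
per-generator stream id, so outputs are byte-identical for a fixed seed
regardless of call order. Failing compounds violate exactly one criterion,
chosen uniformly, so exclusion reporting is exercised on all three.

What the generators do *not* model: real chemistry (no structures), the
degree heterogeneity and clustering of real PPI networks (modules are
homogeneous planted blocks), the GO DAG (terms are flat, independent
sets), and real gene nomenclature. Passing benchmarks therefore establish
algorithmic correctness and calibration — not biological validity of any
particular network snapshot.

## Pipeline

Stages communicate only through files (TSV/SIF/GraphML/GMT/JSON) under the
run directory; the manifest records parameters and a SHA-256 checksum per
artifact, and a rerun from the same config is byte-identical. Any stage
failure aborts the run with the stage name. Compound-only clusters (no
annotated genes) are skipped at enrichment rather than treated as errors.
A run at the published network scale (77 × 432 bipartite layer, 131
disease genes, 800-gene universe in 8 planted modules) completes in well
under a minute on one CPU; benchmark sizes in the test suite were chosen
at desk scale for the same reason.

## Reproducibility caveat

The published headline numbers (network sizes, 5/14/38 cluster counts,
per-term Bonferroni values) derive from 2014–2017 snapshots of live
databases and a proprietary annotation background; they are not
recomputable from scratch. Where the package reports them, the network
cardinalities come from synthetic fixtures engineered to those printed
totals, and the step increments come from the printed component totals
through the same increment-report code the builders use. Cluster counts
are not treated as reproduction targets because the original clustering
parameters are unrecorded.
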