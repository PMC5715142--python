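# Full pipeline on seeded synthetic inputs at the published network scale:
# 77 compounds, 432 targets (0.52-dense bipartite layer), 131 disease genes,
# an 800-gene universe in 8 planted PPI modules, 3 planted enriched terms.
seed: 1
output_dir: runs/paper_scale
simulate:
  n_compounds: 77
  pass_fraction: 1.0
  n_modules: 8
  module_size: 100
  p_in: 0.9
  p_out: 0.01
  confidence_range: [0.0, 1.0]
  n_terms: 50
  planted_terms:
    - [GO:0002576, 0, 10]
    - [GO:0030168, 1, 10]
    - [GO:0045429, 2, 10]
  bipartite_density: 0.52
  disease_overlap_fraction: 0.5
  n_disease_genes: 131
  target_fraction: 0.54
thresholds: {ob_min: 30.0, caco2_min: -0.4, dl_min: 0.18}
min_confidence: 0.4
mcode: {degree_cutoff: 2, node_score_cutoff: 0.2, k_core_filter: 2, haircut: true, fluff: false}
enrichment: {method: hypergeom, alpha: 0.05}
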