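# netpharm

Network pharmacology of a multi-compound herbal formula against a disease
gene set, as a tested, reusable pipeline. The package is aimed at
computational systems-biology practitioners who have compound property
tables, predicted compound→target associations, a curated disease gene
list, confidence-scored protein–protein interactions (PPI), and a gene-set
annotation catalog — and want the full chain from compound triage to an
etiology-partitioned list of the biological processes a formula may
regulate directly.

The pipeline:

1. **ADME triage** — drug-likeness is the Tanimoto similarity between a
   compound's descriptor vector x and an average-drug reference y,
   `f(x,y) = x·y / (|x|² + |y|² − x·y)`; compounds are retained when
   `OB ≥ 30`, `Caco-2 > −0.4`, `DL ≥ 0.18`.
2. **Typed networks** — the disease network (induced PPI on the disease
   genes, isolated genes dropped), the compound-target bipartite network,
   their merge (plus PPI edges among all protein nodes, with proteins that
   are both compound targets and disease genes flagged `shared_target`),
   and the one-hop expansion into "other human proteins". PPI edges pass
   only with confidence strictly above 0.4.
3. **Module detection** — a from-scratch implementation of the
   three-stage molecular-complex detection algorithm (k-core vertex
   weighting, seeded greedy growth, haircut/fluff post-processing),
   deterministic via lexicographic tie-breaks.
4. **Enrichment** — hypergeometric over-representation P(X ≥ k) per
   annotation term (plain or EASE variant), Bonferroni-corrected over the
   terms tested; significant means adjusted p < 0.05.
5. **Overlap** — intersection of the drug-side and disease-side
   significant biological processes, partitioned by named disease-etiology
   categories (a packaged, editable YAML mapping for pregnancy-induced
   hypertension ships as the default).

A seeded synthetic-data module generates every input with known ground
truth (controllable ADME pass rate, planted PPI modules, bipartite density,
disease overlap, planted enriched terms), so the whole chain is testable
offline.

## Worked example

```python
import pandas as pd
from netpharm import dl_score, apply_adme_filter, EtiologyMapping, partition_by_etiology

dl_score([1, 2], [2, 1])
# 0.6666666666666666        (x·y = 4, |x|² = |y|² = 5 → 4 / (5 + 5 − 4))

table = pd.DataFrame({
    "compound_id": ["C1", "C2", "C3"],
    "name": ["quercetin-like", "weak-absorber", "non-druglike"],
    "herb": ["Astragalus", "Salvia", "Salvia"],
    "ob": [46.4, 12.1, 55.0], "caco2": [0.05, 0.3, -0.4], "dl": [0.28, 0.31, 0.18]})
retained, excluded = apply_adme_filter(table)
print(excluded[["compound_id", "failed_criterion"]])
#   compound_id failed_criterion
# 1          C2               ob      (12.1 < 30)
# 2          C3            caco2      (−0.4 is not > −0.4: the bound is strict)
```

Only C1 survives. Downstream, the ten biological processes shared between
the drug and disease sides partition under the packaged etiology mapping:

```python
ten = ["GO:0002576", "GO:0030168", "GO:0007596", "GO:0045429", "GO:0001525",
       "GO:0051000", "GO:0035924", "GO:0048010", "GO:0045766", "GO:0043066"]
report = partition_by_etiology(ten, ten, EtiologyMapping.default_pih())
print(report.per_category_counts)
# {'endothelial cell activation and injury': 3,
#  'placental or trophoblast cell ischemia': 7,
#  'hypoxia and oxidative stress': 0,
#  'maternal-fetal immune tolerance disorders': 0}
```

Three of the shared processes are platelet/coagulation biology
(endothelial activation and injury); seven concern nitric-oxide signaling,
angiogenesis and apoptosis (placental/trophoblast ischemia) — the
mechanisms through which the formula plausibly acts directly.

The full pipeline runs from one YAML config:

```
netpharm run --config examples/paper_scale.yaml
```

producing the four networks (GraphML/SIF), per-network cluster tables,
per-cluster enrichment tables, the overlap report, and a manifest with a
SHA-256 checksum per artifact; reruns from the same config are
byte-identical. Individual stages are also exposed (`netpharm simulate`,
`adme-filter`, `build`, `cluster`, `enrich`, `overlap`, `validate`).

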