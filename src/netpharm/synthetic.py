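"""Seeded generators for every input the pipeline consumes.

The live inputs of the original analysis (compound property tables from TCM
databases, pharmacophore-predicted targets, curated disease genes,
confidence-scored PPI) are not redistributable, so this module emulates
each of them with known ground truth:

- a compound table whose expected pass-rate at the ADME thresholds is
  controllable (``pass_fraction``);
- a PPI layer with planted dense modules (a planted-partition graph:
  within-module edge probability ``p_in``, between-module ``p_out``, edge
  confidences uniform on ``confidence_range``);
- a compound->target bipartite layer of controllable density;
- an annotation catalog with terms planted to be over-represented in chosen
  modules;
- a disease gene list with a controllable expected overlap against the
  compound targets.

Every generator draws from its own numpy PCG64 stream, derived from the
single config seed and a fixed per-generator stream id, so a fixed seed
yields byte-identical outputs regardless of which generators run or in
what order. Gene identifiers are synthetic symbols ("G0001", ...) with no
claim to real nomenclature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "gen_compound_table",
    "gen_planted_ppi",
    "gen_bipartite_targets",
    "gen_annotation",
    "gen_disease_genes",
    "gene_symbols",
]

# fixed stream ids: one documented pseudo-random stream per generator
_STREAMS = {"compounds": 1, "ppi": 2, "bipartite": 3, "annotation": 4, "disease": 5, "targets": 6}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all generators; invalid combinations raise at construction."""

    seed: int = 0
    n_compounds: int = 77
    pass_fraction: float = 0.3
    n_modules: int = 3
    module_size: int = 10
    p_in: float = 0.9
    p_out: float = 0.05
    confidence_range: tuple[float, float] = (0.0, 1.0)
    n_terms: int = 50
    planted_terms: tuple[tuple[str, int, float], ...] = ()
    bipartite_density: float = 0.52
    disease_overlap_fraction: float = 0.5
    term_density: float = 0.05
    n_disease_genes: int = 131

    def __post_init__(self):
        for name in ("pass_fraction", "bipartite_density", "disease_overlap_fraction", "term_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_out={self.p_out}, p_in={self.p_in}")
        lo, hi = self.confidence_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"confidence_range must be ordered within [0, 1], got {self.confidence_range}")

    def rng(self, generator: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[generator], self.seed])


def gene_symbols(n: int, prefix: str = "G") -> list[str]:
    """Synthetic gene symbols G0001..Gnnnn (width grows as needed)."""
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


# -- compound table --------------------------------------------------------

_PASS_RANGES = {"ob": (30.0, 100.0), "caco2": (-0.35, 1.5), "dl": (0.18, 1.0)}
_FAIL_RANGES = {"ob": (0.0, 29.9), "caco2": (-2.0, -0.4), "dl": (0.0, 0.1799)}


def gen_compound_table(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Compound property table with known pass/fail ground truth.

    Each compound passes all three ADME thresholds with probability
    ``pass_fraction``; a failing compound violates exactly one criterion,
    chosen uniformly, so exclusion reporting is exercised on every
    criterion. Returns (table, boolean ground-truth labels indexed by
    compound_id).
    """
    if cfg.n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = cfg.rng("compounds")
    n = cfg.n_compounds
    passes = rng.random(n) < cfg.pass_fraction
    which_fail = rng.integers(0, 3, size=n)  # used only for failing rows
    cols = {}
    for j, prop in enumerate(("ob", "caco2", "dl")):
        lo_p, hi_p = _PASS_RANGES[prop]
        lo_f, hi_f = _FAIL_RANGES[prop]
        vals = rng.uniform(lo_p, hi_p, size=n)
        fail_here = (~passes) & (which_fail == j)
        vals[fail_here] = rng.uniform(lo_f, hi_f, size=int(fail_here.sum()))
        cols[prop] = np.round(vals, 4)
    ids = [f"C{i + 1:04d}" for i in range(n)]
    herbs = ["Astragalus" if i % 2 == 0 else "Salvia" for i in range(n)]
    table = pd.DataFrame(
        {
            "compound_id": ids,
            "name": [f"compound-{i + 1}" for i in range(n)],
            "herb": herbs,
            "ob": cols["ob"],
            "caco2": cols["caco2"],
            "dl": cols["dl"],
        }
    )
    labels = pd.Series(passes, index=pd.Index(ids, name="compound_id"), name="passes")
    return table, labels


# -- planted-partition PPI -------------------------------------------------

def gen_planted_ppi(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Planted-partition PPI edge list with per-edge confidences.

    Nodes are ``n_modules * module_size`` synthetic genes; within-module
    pairs are linked with probability ``p_in``, between-module pairs with
    ``p_out``; confidences are uniform on ``confidence_range``. Returns the
    canonical (node_a < node_b, sorted) edge list and the node -> module
    ground-truth labels.
    """
    if cfg.n_modules < 1 or cfg.module_size < 3:
        raise ValueError("need n_modules >= 1 and module_size >= 3")
    rng = cfg.rng("ppi")
    n = cfg.n_modules * cfg.module_size
    nodes = np.array(gene_symbols(n))
    module = np.arange(n) // cfg.module_size
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(module[iu] == module[ju], cfg.p_in, cfg.p_out)
    keep = rng.random(p.size) < p
    lo, hi = cfg.confidence_range
    conf = np.round(rng.uniform(lo, hi, size=int(keep.sum())), 4)
    edges = pd.DataFrame(
        {"node_a": nodes[iu[keep]], "node_b": nodes[ju[keep]], "confidence": conf}
    ).sort_values(["node_a", "node_b"], ignore_index=True)
    labels = {node: int(m) for node, m in zip(nodes, module)}
    return edges, labels


# -- bipartite compound->target layer --------------------------------------

def gen_bipartite_targets(compounds, genes, cfg: SimulationConfig) -> pd.DataFrame:
    """Compound->target association table: each pair linked with probability
    ``bipartite_density``; rows are unique and sorted."""
    compounds, genes = list(compounds), list(genes)
    if not compounds or not genes:
        raise ValueError("compound and gene sets must be non-empty")
    rng = cfg.rng("bipartite")
    mask = rng.random((len(compounds), len(genes))) < cfg.bipartite_density
    ci, gi = np.nonzero(mask)
    return pd.DataFrame(
        {
            "compound_id": np.array(compounds)[ci],
            "gene_id": np.array(genes)[gi],
        }
    ).sort_values(["compound_id", "gene_id"], ignore_index=True)


# -- annotation catalog ----------------------------------------------------

def gen_annotation(
    genes,
    cfg: SimulationConfig,
    module_labels: dict[str, int] | None = None,
) -> tuple[dict[str, tuple[str, frozenset[str]]], dict[str, int]]:
    """GMT-serializable annotation catalog with planted enriched terms.

    Background terms ("T0001", ...) include each universe gene independently
    with probability ``term_density``. Each planted term ``(term_id,
    module_id, strength)`` instead includes its target module's genes with
    probability ``min(1, strength * term_density)`` (all of them, and
    nothing else, when strength is infinite) and background genes with
    probability ``term_density``. Returns (terms, planted term -> module).
    """
    if cfg.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    genes = list(genes)
    gene_arr = np.array(genes)
    rng = cfg.rng("annotation")
    labels = module_labels or {}
    known_modules = set(labels.values())
    terms: dict[str, tuple[str, frozenset[str]]] = {}

    for i in range(cfg.n_terms):
        mask = rng.random(len(genes)) < cfg.term_density
        members = set(gene_arr[mask])
        if not members:  # keep the catalog free of empty terms
            members = {genes[int(rng.integers(len(genes)))]}
        tid = f"T{i + 1:04d}"
        terms[tid] = (f"background process {i + 1}", frozenset(members))

    truth: dict[str, int] = {}
    for term_id, module_id, strength in cfg.planted_terms:
        if module_id not in known_modules:
            raise ValueError(f"planted term {term_id} references unknown module {module_id}")
        in_module = np.array([labels.get(g) == module_id for g in genes])
        if math.isinf(strength):
            members = set(gene_arr[in_module])
        else:
            p_mod = min(1.0, strength * cfg.term_density)
            draw = rng.random(len(genes))
            mask = np.where(in_module, draw < p_mod, draw < cfg.term_density)
            members = set(gene_arr[mask])
        if not members:
            members = {genes[int(rng.integers(len(genes)))]}
        terms[term_id] = (f"planted process for module {module_id}", frozenset(members))
        truth[term_id] = module_id
    return terms, truth


# -- disease gene list -----------------------------------------------------

def gen_disease_genes(
    genes, compound_targets, cfg: SimulationConfig
) -> tuple[list[str], frozenset[str]]:
    """Disease gene list with controllable overlap against compound targets.

    Of the ``n_disease_genes`` genes, a Binomial(n, disease_overlap_fraction)
    number is drawn from the compound targets, the rest from the remaining
    universe. Returns (sorted gene list, ground-truth shared-target set).
    """
    genes = list(genes)
    targets = sorted(set(compound_targets) & set(genes))
    others = sorted(set(genes) - set(targets))
    n = cfg.n_disease_genes
    if n > len(genes):
        raise ValueError(f"requested {n} disease genes from a universe of {len(genes)}")
    rng = cfg.rng("disease")
    n_shared = int(rng.binomial(n, cfg.disease_overlap_fraction))
    n_shared = min(n_shared, len(targets))
    n_other = n - n_shared
    if n_other > len(others):
        raise ValueError(
            f"cannot draw {n_other} non-target disease genes from a pool of {len(others)}"
        )
    shared = list(rng.choice(targets, size=n_shared, replace=False)) if n_shared else []
    rest = list(rng.choice(others, size=n_other, replace=False)) if n_other else []
    disease = sorted(shared + rest)
    return disease, frozenset(shared)
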