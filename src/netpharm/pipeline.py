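"""End-to-end orchestration: simulate/ingest -> ADME filter -> networks ->
module detection -> enrichment -> etiology overlap.

Stages communicate only through files under the run's output directory, so
each stage is independently inspectable and a run is resumable by hand. A
run is fully determined by its YAML config (and the seed inside it); the
manifest records parameters and a SHA-256 checksum of every artifact, and a
rerun with the same config reproduces the artifacts byte for byte.

Layout of a run directory::

    inputs/      simulated (or copied-in) input tables + ground truth
    adme/        retained / excluded compound tables
    networks/    GraphML + SIF + summary JSON for the four networks
    clusters/    per-network cluster tables (rank, score, seed, members)
    enrichment/  per-cluster enrichment tables
    overlap/     drug-disease overlap report (JSON + TSV)
    manifest.json
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as npio
from .adme import FilterThresholds, apply_adme_filter
from .enrichment import AnnotationCatalog, enrich
from .mcode import McodeParams, find_clusters
from .netbuild import (
    TypedNetwork,
    build_bipartite_network,
    build_disease_network,
    expand_network,
    filter_ppi,
    merge_networks,
)
from .overlap import EtiologyMapping, collect_significant, partition_by_etiology
from .synthetic import (
    SimulationConfig,
    gen_annotation,
    gen_bipartite_targets,
    gen_compound_table,
    gen_disease_genes,
    gen_planted_ppi,
)

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "load_config", "run_pipeline"]

_SIM_KEYS = {
    "n_compounds", "pass_fraction", "n_modules", "module_size", "p_in", "p_out",
    "confidence_range", "n_terms", "planted_terms", "bipartite_density",
    "disease_overlap_fraction", "term_density", "n_disease_genes", "target_fraction",
}
_INPUT_KEYS = {"compounds", "associations", "ppi", "disease_genes", "annotations"}
_TOP_KEYS = {
    "seed", "output_dir", "simulate", "inputs", "thresholds", "min_confidence",
    "mcode", "enrichment", "etiology_mapping",
}


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name in the message."""


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: Path
    seed: int | None = None
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    min_confidence: float = 0.4
    mcode: McodeParams = field(default_factory=McodeParams)
    enrichment_method: str = "hypergeom"
    alpha: float = 0.05
    etiology_mapping: Path | None = None


def validate_config(path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and cross-validate a YAML pipeline config.

    Returns ``(config, errors)``; the error list is exhaustive rather than
    first-failure, and ``config`` is None whenever it is non-empty.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        return None, [f"unparseable YAML: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a YAML mapping"]

    errors: list[str] = []
    for key in sorted(set(raw) - _TOP_KEYS):
        errors.append(f"unknown key: {key}")
    if "output_dir" not in raw:
        errors.append("missing required key: output_dir")
    sim = raw.get("simulate")
    inputs = raw.get("inputs")
    if sim is None and inputs is None:
        errors.append("need either a simulate block or an inputs block")
    if sim is not None:
        if raw.get("seed") is None:
            errors.append("seed is mandatory when a simulate block is present")
        for key in sorted(set(sim) - _SIM_KEYS):
            errors.append(f"unknown simulate key: {key}")
    if inputs is not None:
        for key in sorted(set(inputs) - _INPUT_KEYS):
            errors.append(f"unknown inputs key: {key}")
        for key, p in sorted((inputs or {}).items()):
            if key in _INPUT_KEYS and not Path(p).exists():
                errors.append(f"inputs.{key}: file not found: {p}")
    mapping = raw.get("etiology_mapping")
    if mapping is not None and not Path(mapping).exists():
        errors.append(f"etiology_mapping: file not found: {mapping}")

    try:
        thresholds = FilterThresholds(**(raw.get("thresholds") or {}))
    except TypeError as exc:
        errors.append(f"thresholds: {exc}")
        thresholds = None
    try:
        mcode = McodeParams(**(raw.get("mcode") or {}))
    except (TypeError, ValueError) as exc:
        errors.append(f"mcode: {exc}")
        mcode = None
    enr = raw.get("enrichment") or {}
    method = enr.get("method", "hypergeom")
    if method not in ("hypergeom", "ease"):
        errors.append(f"enrichment.method must be hypergeom or ease, got {method!r}")
    if errors:
        return None, errors
    cfg = PipelineConfig(
        output_dir=Path(raw["output_dir"]),
        seed=raw.get("seed"),
        simulate=sim,
        inputs=inputs,
        thresholds=thresholds,
        min_confidence=float(raw.get("min_confidence", 0.4)),
        mcode=mcode,
        enrichment_method=method,
        alpha=float(enr.get("alpha", 0.05)),
        etiology_mapping=Path(mapping) if mapping else None,
    )
    return cfg, []


def load_config(path) -> PipelineConfig:
    cfg, errors = validate_config(path)
    if errors:
        raise PipelineError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_clusters(clusters, path: Path) -> None:
    rows = [
        (c.rank, round(c.score, 6), c.seed, ",".join(sorted(c.members)))
        for c in clusters
    ]
    pd.DataFrame(rows, columns=["rank", "score", "seed", "members"]).to_csv(
        path, sep="\t", index=False
    )


def _simulate_inputs(cfg: PipelineConfig, outdir: Path) -> dict:
    sim = dict(cfg.simulate or {})
    target_fraction = float(sim.pop("target_fraction", 0.5))
    planted = [tuple(t) for t in sim.pop("planted_terms", [])]
    simcfg = SimulationConfig(seed=cfg.seed, planted_terms=tuple(planted), **sim)

    compounds, pass_labels = gen_compound_table(simcfg)
    ppi_edges, module_labels = gen_planted_ppi(simcfg)
    universe = sorted(module_labels)
    rng = simcfg.rng("targets")
    n_targets = max(1, round(target_fraction * len(universe)))
    targets = sorted(rng.choice(universe, size=n_targets, replace=False))
    associations = gen_bipartite_targets(compounds["compound_id"], targets, simcfg)
    disease_genes, shared = gen_disease_genes(universe, targets, simcfg)
    terms, planted_truth = gen_annotation(universe, simcfg, module_labels)

    npio.write_compound_table(compounds, outdir / "compounds.tsv")
    npio.write_edge_list(ppi_edges, outdir / "ppi_edges.tsv")
    npio.write_associations(associations, outdir / "associations.tsv")
    npio.write_gene_list(disease_genes, outdir / "disease_genes.txt")
    npio.write_gmt(terms, outdir / "annotations.gmt")
    npio.write_json(
        {
            "pass_labels": {k: bool(v) for k, v in pass_labels.items()},
            "module_labels": module_labels,
            "shared_targets": sorted(shared),
            "planted_terms": planted_truth,
            "targets": list(targets),
        },
        outdir / "ground_truth.json",
    )
    return {
        "compounds": compounds,
        "ppi": ppi_edges,
        "associations": associations,
        "disease_genes": disease_genes,
        "annotations": terms,
        "universe": universe,
    }


def _load_inputs(cfg: PipelineConfig) -> dict:
    paths = cfg.inputs or {}
    terms = npio.read_gmt(paths["annotations"])
    universe = sorted(frozenset().union(*(g for _, g in terms.values())))
    return {
        "compounds": npio.read_compound_table(paths["compounds"]),
        "ppi": npio.read_edge_list(paths["ppi"]),
        "associations": npio.read_associations(paths["associations"]),
        "disease_genes": npio.read_gene_list(paths["disease_genes"]),
        "annotations": terms,
        "universe": universe,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage in order; returns (and writes) the run manifest.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(cfg.output_dir)
    stages: list[dict] = []
    artifacts: list[Path] = []

    def stage(name, subdir):
        d = out / subdir
        d.mkdir(parents=True, exist_ok=True)
        return d

    # -- inputs ------------------------------------------------------------
    try:
        d = stage("inputs", "inputs")
        data = _simulate_inputs(cfg, d) if cfg.simulate is not None else _load_inputs(cfg)
        artifacts += sorted(d.glob("*"))
        stages.append({"stage": "inputs", "compounds": int(len(data["compounds"]))})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage inputs failed: {exc}") from exc

    # -- ADME filter -------------------------------------------------------
    try:
        d = stage("adme", "adme")
        retained, excluded = apply_adme_filter(data["compounds"], cfg.thresholds)
        if retained.empty:
            raise PipelineError("stage adme failed: no compounds retained by the ADME filter")
        npio.write_compound_table(retained, d / "retained.tsv")
        npio.write_compound_table(excluded, d / "excluded.tsv")
        artifacts += [d / "retained.tsv", d / "excluded.tsv"]
        stages.append({"stage": "adme", "retained": int(len(retained)), "excluded": int(len(excluded))})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage adme failed: {exc}") from exc

    # -- networks ----------------------------------------------------------
    try:
        d = stage("networks", "networks")
        ppi = filter_ppi(data["ppi"], cfg.min_confidence)
        kept_compounds = set(retained["compound_id"])
        assoc = data["associations"]
        assoc = assoc[assoc["compound_id"].isin(kept_compounds)]
        disease_net = build_disease_network(data["disease_genes"], ppi)
        bipartite_net = build_bipartite_network(assoc)
        merged_net, merge_rep = merge_networks(bipartite_net, disease_net, ppi)
        expanded_net, expand_rep = expand_network(merged_net, ppi, data["disease_genes"])
        nets = {
            "disease": disease_net,
            "bipartite": bipartite_net,
            "merged": merged_net,
            "expanded": expanded_net,
        }
        for name, net in nets.items():
            net.to_graphml(d / f"{name}_network.graphml")
            net.to_sif(d / f"{name}_network.sif")
            artifacts += [d / f"{name}_network.graphml", d / f"{name}_network.sif"]
        summary = {name: net.summary() for name, net in nets.items()}
        summary["merge_report"] = merge_rep
        summary["expand_report"] = expand_rep
        npio.write_json(summary, d / "summaries.json")
        artifacts.append(d / "summaries.json")
        stages.append({"stage": "networks", **{k: v.summary() for k, v in nets.items()}})
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage networks failed: {exc}") from exc

    # -- clustering --------------------------------------------------------
    try:
        d = stage("clusters", "clusters")
        cluster_sets = {}
        for name in ("disease", "merged", "expanded"):
            clusters = find_clusters(nets[name], cfg.mcode)
            cluster_sets[name] = clusters
            _write_clusters(clusters, d / f"{name}_clusters.tsv")
            artifacts.append(d / f"{name}_clusters.tsv")
        stages.append(
            {"stage": "clusters", **{k: len(v) for k, v in cluster_sets.items()}}
        )
    except Exception as exc:
        raise PipelineError(f"stage clusters failed: {exc}") from exc

    # -- enrichment --------------------------------------------------------
    try:
        d = stage("enrichment", "enrichment")
        catalog = AnnotationCatalog.from_terms(data["annotations"])
        tables: dict[str, list[pd.DataFrame]] = {}
        n_sig = 0
        for name, clusters in cluster_sets.items():
            tables[name] = []
            for c in clusters:
                query = set(c.members) & set(catalog.universe)
                if not query:
                    continue  # compound-only or unannotated cluster
                res = enrich(query, catalog, cfg.enrichment_method, cfg.alpha)
                res.insert(0, "cluster_rank", c.rank)
                tables[name].append(res)
                p = d / f"{name}_cluster{c.rank:02d}.tsv"
                res.to_csv(p, sep="\t", index=False)
                artifacts.append(p)
                n_sig += int(res["significant"].sum())
        stages.append({"stage": "enrichment", "significant_rows": n_sig})
    except Exception as exc:
        raise PipelineError(f"stage enrichment failed: {exc}") from exc

    # -- overlap -----------------------------------------------------------
    try:
        d = stage("overlap", "overlap")
        mapping = (
            EtiologyMapping.from_yaml(cfg.etiology_mapping)
            if cfg.etiology_mapping
            else EtiologyMapping.default_pih()
        )
        drug_terms = collect_significant(tables["merged"] + tables["expanded"])
        disease_terms = collect_significant(tables["disease"])
        report = partition_by_etiology(drug_terms, disease_terms, mapping)
        npio.write_json(report.to_dict(), d / "report.json")
        report.to_frame().to_csv(d / "report.tsv", sep="\t", index=False)
        artifacts += [d / "report.json", d / "report.tsv"]
        stages.append(
            {
                "stage": "overlap",
                "overlap": len(report.overlap),
                "per_category": dict(report.per_category_counts),
            }
        )
    except Exception as exc:
        raise PipelineError(f"stage overlap failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "parameters": {
            "thresholds": asdict(cfg.thresholds),
            "min_confidence": cfg.min_confidence,
            "mcode": asdict(cfg.mcode),
            "enrichment": {"method": cfg.enrichment_method, "alpha": cfg.alpha},
            "simulate": cfg.simulate,
        },
        "stages": stages,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
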