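"""Readers and writers for the plain-text formats the pipeline exchanges.

Everything is line-oriented text: TSV tables, SIF edge files, GMT gene-set
catalogs, one-symbol-per-line gene lists, and JSON summaries. Graph
serialization (GraphML/SIF for typed networks) lives in :mod:`netpharm.netbuild`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_compound_table",
    "write_compound_table",
    "read_edge_list",
    "write_edge_list",
    "read_sif",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_associations",
    "write_associations",
    "write_json",
]


def read_compound_table(path) -> pd.DataFrame:
    """Read a compound property TSV (compound_id, name, herb, ob, caco2, dl)."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    return df


def write_compound_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> pd.DataFrame:
    """Read an edge-list TSV with header (node_a, node_b[, confidence])."""
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    if not {"node_a", "node_b"} <= set(df.columns):
        raise ValueError(f"{path}: edge list must have node_a and node_b columns")
    return df


def write_edge_list(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sif(path, interaction: str = "pp") -> pd.DataFrame:
    """Read a simple-interaction-format file into an edge-list frame.

    SIF rows are ``source<TAB>interaction<TAB>target[<TAB>target...]``;
    confidence is not representable in SIF, so the column is absent.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            continue  # isolated node line: "A"
        src = parts[0]
        for tgt in parts[2:]:
            rows.append((src, tgt))
    return pd.DataFrame(rows, columns=["node_a", "node_b"])


def read_gene_list(path) -> list[str]:
    """Read a gene list, one symbol per line, blank lines ignored."""
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT catalog: term_id -> (description, gene set).

    GMT is tab-separated: term, description, then one gene per field.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs >=3 fields): {ln[:80]!r}")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in terms:
            raise ValueError(f"duplicate term in GMT: {term}")
        terms[term] = (desc, frozenset(genes))
    return terms


def write_gmt(terms: dict[str, tuple[str, frozenset[str]]], path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            desc, genes = terms[term_id]
            fh.write("\t".join([term_id, desc, *sorted(genes)]) + "\n")


def read_associations(path) -> pd.DataFrame:
    """Read a compound->target association TSV (compound_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"compound_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: associations need compound_id and gene_id columns")
    return df


def write_associations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
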