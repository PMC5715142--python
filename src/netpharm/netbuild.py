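"""Construction of the four typed networks of the analysis.

The pipeline builds, in order:

1. the disease network — the induced protein-protein interaction (PPI)
   subnetwork on the disease gene set, isolated genes dropped;
2. the compound-target bipartite network — compounds linked to the proteins
   they are predicted to hit (no target-target edges at this stage);
3. the merged drug-disease network — the union of the two, plus
   confidence-filtered PPI edges among all protein nodes of the union;
4. the expanded network — the merged core grown by the first PPI neighbors
   of its protein nodes ("other human proteins") and all filtered PPI edges
   among the expanded node set.

Every node carries a role: ``compound``, ``compound_target``,
``disease_target``, ``shared_target`` (a protein that is both a compound
target and a disease gene) or ``other_protein``. PPI edges carry a
confidence in [0, 1] and are admitted only when strictly above the
threshold (default 0.4).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "ROLES",
    "PROTEIN_ROLES",
    "TypedNetwork",
    "filter_ppi",
    "build_disease_network",
    "build_bipartite_network",
    "merge_networks",
    "expand_network",
    "increment_report",
]

ROLES = ("compound", "compound_target", "disease_target", "shared_target", "other_protein")
PROTEIN_ROLES = frozenset(ROLES[1:])


class TypedNetwork:
    """An undirected simple graph whose nodes carry a role label.

    Thin wrapper over :class:`networkx.Graph`; node attribute ``role`` is one
    of :data:`ROLES`, edge attribute ``confidence`` is optional (bipartite
    compound->target edges have none).
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        for n, data in self.graph.nodes(data=True):
            if data.get("role") not in ROLES:
                raise ValueError(f"node {n!r} has invalid role {data.get('role')!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_with_role(self, *roles: str) -> set[str]:
        return {n for n, r in self.graph.nodes(data="role") if r in roles}

    @property
    def protein_nodes(self) -> set[str]:
        return self.nodes_with_role(*PROTEIN_ROLES)

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for _, r in self.graph.nodes(data="role"):
            counts[r] += 1
        return {r: c for r, c in counts.items() if c}

    def summary(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "roles": self.role_counts(),
        }

    # -- serialization -----------------------------------------------------
    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, role=d["role"])
        for u, v, d in self.graph.edges(data=True):
            conf = d.get("confidence")
            if conf is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, confidence=float(conf))
        nx.write_graphml(g, path)

    @classmethod
    def from_graphml(cls, path) -> "TypedNetwork":
        return cls(nx.read_graphml(path))

    def to_sif(self, path, interaction: str = "pp") -> None:
        with open(path, "w") as fh:
            for u, v in sorted(map(sorted, self.graph.edges())):
                fh.write(f"{u}\t{interaction}\t{v}\n")

    def node_table(self) -> pd.DataFrame:
        rows = sorted((n, d["role"]) for n, d in self.graph.nodes(data=True))
        return pd.DataFrame(rows, columns=["node", "role"])


def filter_ppi(edges: pd.DataFrame, min_confidence: float = 0.4) -> pd.DataFrame:
    """Confidence-filter and canonicalize a PPI edge list.

    Keeps exactly the edges with confidence strictly greater than
    ``min_confidence``, drops self-loops, and deduplicates undirected pairs
    keeping the maximum confidence. Output rows are canonical
    (node_a < node_b) and sorted.

    Raises
    ------
    ValueError
        If any confidence is missing, non-numeric, or outside [0, 1].
    """
    if "confidence" not in edges.columns:
        raise ValueError("PPI edge list requires a confidence column")
    conf = pd.to_numeric(edges["confidence"], errors="coerce")
    bad = conf.isna() | (conf < 0) | (conf > 1)
    if bad.any():
        rows = edges.index[bad].tolist()[:5]
        raise ValueError(f"malformed confidence values at rows {rows}")
    df = edges.assign(confidence=conf)
    df = df[df["node_a"] != df["node_b"]]
    df = df[df["confidence"] > min_confidence]
    a = df["node_a"].astype(str)
    b = df["node_b"].astype(str)
    swap = a > b
    lo, hi = a.where(~swap, b), b.where(~swap, a)
    df = pd.DataFrame({"node_a": lo, "node_b": hi, "confidence": df["confidence"]})
    df = (
        df.groupby(["node_a", "node_b"], as_index=False)["confidence"]
        .max()
        .sort_values(["node_a", "node_b"], ignore_index=True)
    )
    return df


def _ppi_graph(ppi_edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for row in ppi_edges.itertuples(index=False):
        g.add_edge(row.node_a, row.node_b, confidence=float(row.confidence))
    return g


def build_disease_network(disease_genes, ppi_edges: pd.DataFrame) -> TypedNetwork:
    """Induced PPI subnetwork on the disease gene set, isolated genes dropped.

    ``ppi_edges`` must already be confidence-filtered. All retained nodes get
    role ``disease_target``; genes with no within-set interaction do not
    appear (this is what shrinks an input gene list to a smaller network).
    """
    genes = set(disease_genes)
    if not genes:
        raise ValueError("disease gene list is empty")
    ppi = _ppi_graph(ppi_edges)
    sub = ppi.subgraph(genes & set(ppi.nodes))
    g = nx.Graph()
    for u, v, d in sub.edges(data=True):
        g.add_edge(u, v, confidence=d.get("confidence"))
    nx.set_node_attributes(g, "disease_target", "role")
    return TypedNetwork(g)


def build_bipartite_network(associations: pd.DataFrame) -> TypedNetwork:
    """Compound-target bipartite network from an association table.

    Compounds get role ``compound``, targets ``compound_target``; the edge
    count equals the number of distinct (compound, target) pairs. No
    target-target edges are added here — those enter at merge time from PPI.
    """
    if not {"compound_id", "gene_id"} <= set(associations.columns):
        raise ValueError("associations need compound_id and gene_id columns")
    pairs = associations[["compound_id", "gene_id"]].drop_duplicates()
    compounds = set(pairs["compound_id"])
    genes = set(pairs["gene_id"])
    collision = compounds & genes
    if collision:
        raise ValueError(f"identifiers used as both compound and gene: {sorted(collision)[:5]}")
    g = nx.Graph()
    g.add_nodes_from(compounds, role="compound")
    g.add_nodes_from(genes, role="compound_target")
    g.add_edges_from(pairs.itertuples(index=False, name=None))
    return TypedNetwork(g)


def increment_report(component: tuple[int, int], merged: tuple[int, int]) -> dict[str, int]:
    """Nodes/edges added by a construction step, from (nodes, edges) totals."""
    return {
        "nodes_added": merged[0] - component[0],
        "edges_added": merged[1] - component[1],
    }


def merge_networks(
    drug_net: TypedNetwork,
    disease_net: TypedNetwork,
    ppi_edges: pd.DataFrame,
) -> tuple[TypedNetwork, dict]:
    """Integrate the compound-target and disease networks into one.

    The node set is the exact union. Edges are the union of both input
    networks' edges plus every confidence-filtered PPI edge whose two
    endpoints are protein-role nodes of the merged set. Roles are
    recomputed: a protein that is both a compound target and a disease gene
    becomes ``shared_target``. Returns the merged network and a report with
    incremental node/edge counts against *each* input network.

    Raises
    ------
    ValueError
        If an identifier is a compound in one input and a protein in the
        other (role contradiction).
    """
    compounds = drug_net.nodes_with_role("compound")
    drug_targets = drug_net.protein_nodes
    disease_genes = disease_net.protein_nodes
    contradiction = compounds & (disease_genes | drug_targets)
    if contradiction:
        raise ValueError(f"nodes both compound and protein: {sorted(contradiction)[:5]}")

    g = nx.Graph()
    for node in compounds:
        g.add_node(node, role="compound")
    for node in drug_targets | disease_genes:
        if node in drug_targets and node in disease_genes:
            role = "shared_target"
        elif node in drug_targets:
            role = "compound_target"
        else:
            role = "disease_target"
        g.add_node(node, role=role)

    for net in (drug_net, disease_net):
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, **{k: val for k, val in d.items() if val is not None})
    proteins = drug_targets | disease_genes
    for row in ppi_edges.itertuples(index=False):
        if row.node_a in proteins and row.node_b in proteins:
            g.add_edge(row.node_a, row.node_b, confidence=float(row.confidence))

    merged = TypedNetwork(g)
    totals = (merged.n_nodes, merged.n_edges)
    report = {
        "merged": {"nodes": totals[0], "edges": totals[1]},
        "vs_compound_target_network": increment_report(
            (drug_net.n_nodes, drug_net.n_edges), totals
        ),
        "vs_disease_network": increment_report(
            (disease_net.n_nodes, disease_net.n_edges), totals
        ),
    }
    return merged, report


def expand_network(
    core_net: TypedNetwork,
    ppi_edges: pd.DataFrame,
    disease_genes=(),
) -> tuple[TypedNetwork, dict]:
    """Grow the core by the first PPI neighbors of its protein nodes.

    Added nodes get role ``other_protein`` unless they belong to
    ``disease_genes`` (then ``disease_target`` — disease genes do turn up
    among the "other human proteins"). All filtered PPI edges among the
    expanded node set are included. Returns the expanded network and the
    incremental report against the core.
    """
    disease_genes = set(disease_genes)
    core_proteins = core_net.protein_nodes
    ppi = _ppi_graph(ppi_edges)

    neighbors: set[str] = set()
    for node in core_proteins & set(ppi.nodes):
        neighbors.update(ppi.neighbors(node))
    new_nodes = neighbors - set(core_net.graph.nodes)

    g = core_net.graph.copy()
    for node in new_nodes:
        role = "disease_target" if node in disease_genes else "other_protein"
        g.add_node(node, role=role)
    expanded_proteins = core_proteins | new_nodes
    for u, v, d in ppi.edges(data=True):
        if u in expanded_proteins and v in expanded_proteins:
            g.add_edge(u, v, confidence=d.get("confidence"))

    expanded = TypedNetwork(g)
    report = {
        "expanded": {"nodes": expanded.n_nodes, "edges": expanded.n_edges},
        "vs_core_network": increment_report(
            (core_net.n_nodes, core_net.n_edges),
            (expanded.n_nodes, expanded.n_edges),
        ),
    }
    return expanded, report
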