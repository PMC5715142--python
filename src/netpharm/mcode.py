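"""MCODE molecular-complex detection, implemented from scratch.

The algorithm finds densely connected regions of a simple undirected graph
in three stages:

1. **Vertex weighting.** For each vertex v, take the subgraph induced by its
   closed neighborhood (v plus its neighbors), find the highest k-core of
   that subgraph, and set
   ``weight(v) = k_max * density(highest k-core)`` with
   ``density = 2E / (n (n - 1))``. Vertices with degree below
   ``degree_cutoff`` are weighted 0.
2. **Complex prediction.** Seed at the highest-weight unassigned vertex and
   grow outward breadth-first, admitting vertices whose weight is at least
   ``seed_weight * (1 - node_score_cutoff)``, to at most ``max_depth`` hops
   from the seed. Assigned vertices never join a second complex.
3. **Post-processing.** Complexes that do not contain a
   ``k_core_filter``-core are discarded. With ``haircut`` the complex is
   trimmed to its 2-core (iteratively sheds singly-connected members). With
   ``fluff`` unassigned neighbors whose closed-neighborhood density exceeds
   ``fluff_density_cutoff`` are pulled in.

A complex's score is its density times its member count; complexes are
ranked by score descending. All ties (seed choice, equal weights, equal
scores) break lexicographically on node identifier so a run is fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["McodeParams", "Cluster", "vertex_weights", "find_clusters", "recover_planted"]


@dataclass(frozen=True)
class McodeParams:
    """Tuning parameters, defaulting to the values of the original plug-in."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if min(self.degree_cutoff, self.k_core_filter, self.max_depth) < 0:
            raise ValueError("cutoffs must be non-negative")


@dataclass(frozen=True)
class Cluster:
    """One detected complex: members, the seed it grew from, score and rank."""

    members: frozenset[str]
    seed: str
    score: float
    rank: int

    def __len__(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _as_graph(net) -> nx.Graph:
    """Accept a TypedNetwork or a bare networkx graph; roles are ignored."""
    g = net if isinstance(net, nx.Graph) else getattr(net, "graph", net)
    if not isinstance(g, nx.Graph) or g.is_directed():
        raise TypeError("expected an undirected graph")
    return g


def vertex_weights(net, params: McodeParams | None = None) -> dict[str, float]:
    """Stage-1 weights: k_max times the density of the highest k-core of the
    closed neighborhood, 0 for vertices below the degree cutoff."""
    g = _as_graph(net)
    params = params or McodeParams()
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph([v, *g.neighbors(v)])
        core_num = nx.core_number(closed)
        k_max = max(core_num.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        top_core = closed.subgraph([u for u, k in core_num.items() if k >= k_max])
        weights[v] = k_max * _density(top_core)
    return weights


def _grow_complex(
    g: nx.Graph, weights: dict[str, float], seed: str, assigned: set[str], params: McodeParams
) -> set[str]:
    threshold = weights[seed] * (1.0 - params.node_score_cutoff)
    members = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < params.max_depth:
        nxt = []
        for v in frontier:
            for u in sorted(g.neighbors(v)):
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    nxt.append(u)
        frontier = nxt
        depth += 1
    return members


def find_clusters(net, params: McodeParams | None = None) -> list[Cluster]:
    """Stages 2-3: grow complexes from high-weight seeds and post-process.

    Returns node-disjoint clusters ranked by score descending (ties by seed
    identifier). A cluster records the seed it grew from even if the haircut
    later removed it. An empty list is a valid result (e.g. any tree, where
    no complex contains a 2-core).
    """
    g = _as_graph(net)
    params = params or McodeParams()
    weights = vertex_weights(net, params)

    # seeds in descending weight, lexicographic on ties; zero weight never seeds
    order = sorted(weights, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        members = _grow_complex(g, weights, seed, assigned, params)
        assigned |= members
        raw.append((seed, members))

    clusters: list[Cluster] = []
    for seed, members in raw:
        sub = g.subgraph(members)
        if params.k_core_filter > 0:
            core = nx.k_core(sub, params.k_core_filter)
            if core.number_of_nodes() == 0:
                continue
        kept = set(members)
        if params.haircut:
            kept = set(nx.k_core(sub, 2).nodes)
            if not kept:
                continue
        if params.fluff:
            extra = set()
            for v in sorted(kept):
                for u in sorted(g.neighbors(v)):
                    if u in kept or u in assigned or u in extra:
                        continue
                    closed = g.subgraph([u, *g.neighbors(u)])
                    if _density(closed) > params.fluff_density_cutoff:
                        extra.add(u)
            kept |= extra
            assigned |= extra
        if len(kept) < 2:
            continue
        final = g.subgraph(kept)
        score = _density(final) * final.number_of_nodes()
        clusters.append(Cluster(frozenset(kept), seed, score, rank=0))

    clusters.sort(key=lambda c: (-c.score, c.seed))
    return [Cluster(c.members, c.seed, c.score, i + 1) for i, c in enumerate(clusters)]


def recover_planted(clusters: list[Cluster], truth_labels: dict[str, int]) -> dict:
    """Score detected clusters against planted modules by best Jaccard match.

    ``truth_labels`` maps every node to its planted module id. For each
    planted module the best Jaccard overlap over all clusters is taken; the
    report carries per-module matches and their mean (0.0 when no clusters
    were found).
    """
    modules: dict[int, set[str]] = {}
    for node, label in truth_labels.items():
        modules.setdefault(label, set()).add(node)
    per_module = {}
    for label, members in sorted(modules.items()):
        best, best_rank = 0.0, None
        for c in clusters:
            inter = len(members & c.members)
            union = len(members | c.members)
            j = inter / union if union else 0.0
            if j > best:
                best, best_rank = j, c.rank
        per_module[label] = {"jaccard": best, "cluster_rank": best_rank}
    mean = (
        sum(m["jaccard"] for m in per_module.values()) / len(per_module)
        if per_module
        else 0.0
    )
    return {"per_module": per_module, "mean_jaccard": mean}
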