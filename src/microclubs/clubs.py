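"""Co-occurrence networks, Markov clustering, social and rival clubs.

The network keeps every taxon pair whose correlation passed the significance
filter; positive edges mark taxa that co-occur (candidate "social clubs"),
negative edges taxa that co-avoid.  Markov clustering (MCL) — alternating
expansion (matrix powers) and inflation (element-wise powers) of a column-
stochastic flow matrix until the flow freezes onto attractors — runs on the
positive-edge subgraph only, since the flow matrix must stay non-negative;
negative edges are reserved for detecting rivalries *between* the resulting
clubs.  Club tightness is the mean +/- sd of the intra-club edge
correlations; a pair of clubs is rival when enough significant negative
edges connect them and their mean correlation is low enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import OtuTable
from .sparcc import CorrelationEstimate

__all__ = [
    "Clustering",
    "ClubReport",
    "build_network",
    "mcl_cluster",
    "club_statistics",
    "rival_clubs",
    "heatmap_order",
]


@dataclass
class Clustering:
    assignment: dict[str, int]
    converged: bool = True
    n_iterations: int = 0

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, cid: int) -> list[str]:
        return sorted(n for n, c in self.assignment.items() if c == cid)


@dataclass
class ClubReport:
    social: list[dict] = field(default_factory=list)   # club_id, members, size, tightness_mean/sd
    rivals: list[dict] = field(default_factory=list)   # club_a, club_b, mean_correlation, n_edges


def build_network(est: CorrelationEstimate, rel_abund: OtuTable,
                  alpha: float = 0.05, min_abs_r: float = 0.0) -> nx.Graph:
    """Significance-filtered co-occurrence graph over the taxa.

    Edge (i, j) is kept iff p_ij < alpha and \\|rho_ij\\| >= min_abs_r; node
    attribute ``relative_abundance`` is the taxon's mean proportion across
    samples, edge attributes are ``correlation`` and ``p_value``.
    """
    if est.pvals is None:
        raise ValueError("correlation estimate carries no p-values")
    if set(est.taxon_ids) != set(rel_abund.taxon_ids):
        raise ValueError("taxa of correlation estimate and abundance table differ")
    if rel_abund.kind != "relative":
        raise ValueError("node sizes need a relative-abundance table")
    mean_abund = dict(zip(rel_abund.taxon_ids, rel_abund.values.mean(axis=0)))
    g = nx.Graph()
    for t in est.taxon_ids:
        g.add_node(t, relative_abundance=float(mean_abund[t]))
    d = len(est.taxon_ids)
    for i in range(d):
        for j in range(i + 1, d):
            p, r = est.pvals[i, j], est.rho[i, j]
            if p < alpha and abs(r) >= min_abs_r:
                g.add_edge(est.taxon_ids[i], est.taxon_ids[j],
                           correlation=float(r), p_value=float(p))
    return g


def mcl_cluster(network: nx.Graph, inflation: float = 2.0, expansion: int = 2,
                prune: float = 1e-5, tol: float = 1e-8, max_iter: int = 100,
                min_weight: float = 0.0) -> Clustering:
    """Markov clustering of the positive-edge subgraph.

    Positive edges with correlation >= ``min_weight`` form the flow graph
    (weight = correlation); unit self-loops are added; the column-stochastic
    matrix is alternately raised to the ``expansion`` matrix power and the
    ``inflation`` element-wise power, renormalized and pruned, until the
    maximum column change falls below ``tol``.  Clusters are read off the
    attractor rows; a node drawn by several attractor systems joins the one
    receiving its largest flow mass (ties -> smallest cluster id); isolated
    nodes become singletons.  Fully deterministic.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    d = len(nodes)
    m = np.zeros((d, d))
    for u, v, data in network.edges(data=True):
        w = data.get("correlation", data.get("weight", 1.0))
        if w > 0 and w >= min_weight:
            m[index[u], index[v]] = m[index[v], index[u]] = w
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new = np.linalg.matrix_power(m, expansion)
        new = new ** inflation
        new[new < prune] = 0.0
        colsums = new.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        new /= colsums
        if np.abs(new - m).max() < tol:
            m = new
            converged = True
            break
        m = new

    # attractors: nodes keeping flow on their own diagonal
    attractors = np.flatnonzero(np.diag(m) > prune)
    if attractors.size == 0:  # degenerate (should not happen with self-loops)
        attractors = np.arange(d)
    # attractor systems: connected components of the attractor-attractor flow
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(int(a) for a in attractors)
    for a in attractors:
        for b in attractors:
            if a < b and (m[a, b] > prune or m[b, a] > prune):
                sys_graph.add_edge(int(a), int(b))
    systems = sorted((sorted(c) for c in nx.connected_components(sys_graph)),
                     key=lambda c: c[0])
    assignment: dict[str, int] = {}
    for j in range(d):
        mass = np.array([m[list(c), j].sum() for c in systems])
        if mass.max() <= 0:
            continue  # no attractor claims this node yet
        assignment[nodes[j]] = int(np.argmax(mass))  # argmax -> smallest id on ties
    next_id = len(systems)
    for j in range(d):  # unclaimed nodes (isolated or starved) -> singletons
        if nodes[j] not in assignment:
            assignment[nodes[j]] = next_id
            next_id += 1
    # renumber densely by first appearance in sorted node order
    remap: dict[int, int] = {}
    for n in nodes:
        remap.setdefault(assignment[n], len(remap))
    assignment = {n: remap[assignment[n]] for n in nodes}
    return Clustering(assignment, converged=converged, n_iterations=iterations)


def club_statistics(network: nx.Graph, clustering: Clustering,
                    min_club_size: int = 3) -> ClubReport:
    """Social clubs (clusters of size >= ``min_club_size``) with tightness.

    Tightness is the mean and sd (population sd, 0 for a single edge) of the
    correlations on the intra-club edges present in the network.
    """
    missing = [n for n in network.nodes if n not in clustering.assignment]
    if missing:
        raise ValueError(f"clustering does not cover nodes: {missing[:5]}")
    report = ClubReport()
    for cid in sorted(set(clustering.assignment.values())):
        members = clustering.members(cid)
        if len(members) < min_club_size:
            continue
        mset = set(members)
        weights = [data["correlation"] for u, v, data in network.edges(data=True)
                   if u in mset and v in mset]
        report.social.append({
            "club_id": cid,
            "members": members,
            "size": len(members),
            "n_edges": len(weights),
            "tightness_mean": float(np.mean(weights)) if weights else float("nan"),
            "tightness_sd": float(np.std(weights)) if weights else float("nan"),
        })
    return report


def rival_clubs(network: nx.Graph, clustering: Clustering,
                report: ClubReport | None = None,
                min_club_size: int = 3, rival_threshold: float = -0.4,
                min_rival_edges: int = 3) -> ClubReport:
    """Add rival pairs to the social-club report.

    For each unordered pair of social clubs, the significant negative edges
    between them are collected; the pair is rival iff there are at least
    ``min_rival_edges`` of them and their mean correlation is <=
    ``rival_threshold``.
    """
    if report is None:
        report = club_statistics(network, clustering, min_club_size)
    clubs = {c["club_id"]: set(c["members"]) for c in report.social}
    ids = sorted(clubs)
    report.rivals = []
    for x, a in enumerate(ids):
        for b in ids[x + 1:]:
            weights = [data["correlation"] for u, v, data in network.edges(data=True)
                       if data["correlation"] < 0
                       and ((u in clubs[a] and v in clubs[b])
                            or (u in clubs[b] and v in clubs[a]))]
            if len(weights) >= min_rival_edges and np.mean(weights) <= rival_threshold:
                report.rivals.append({
                    "club_a": a, "club_b": b,
                    "mean_correlation": float(np.mean(weights)),
                    "n_edges": len(weights),
                })
    return report


def heatmap_order(est: CorrelationEstimate, clustering: Clustering) -> list[str]:
    """Taxon permutation placing same-cluster taxa contiguously.

    Clusters are ordered by decreasing size (ties by smallest member label);
    within a cluster taxa are ordered by decreasing mean intra-cluster
    correlation (ties by label).  Applying the permutation to rows and
    columns of rho restores block-diagonal structure for heatmap export.
    """
    taxa = est.taxon_ids
    idx = {t: i for i, t in enumerate(taxa)}
    missing = [t for t in taxa if t not in clustering.assignment]
    if missing:
        raise ValueError(f"clustering does not cover taxa: {missing[:5]}")
    clusters: dict[int, list[str]] = {}
    for t in taxa:
        clusters.setdefault(clustering.assignment[t], []).append(t)
    ordered_clusters = sorted(clusters.values(),
                              key=lambda ms: (-len(ms), min(ms)))
    order: list[str] = []
    for members in ordered_clusters:
        if len(members) == 1:
            order.extend(members)
            continue
        rows = np.array([idx[t] for t in members])
        sub = est.rho[np.ix_(rows, rows)]
        mean_r = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
        order.extend(t for _, t in sorted(zip(-mean_r, members)))
    return order
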