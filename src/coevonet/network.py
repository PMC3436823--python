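"""Co-evolutionary network: construction, summary statistics, clustering.

The network has one node per analyzed gene (isolates included) and an
undirected edge for every significantly co-evolving pair.  Degree summaries,
the Watts-Strogatz clustering coefficient, a log-log power-law regression of
the degree distribution and a chi-square goodness-of-fit test against a
Poisson degree distribution characterize its topology.  Modules are extracted
by a deterministic greedy cluster-editing heuristic: the objective is the
usual transitivity-clustering one — the minimum number of edge insertions
plus deletions turning the graph into disjoint cliques.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .phylo import EdgeList

__all__ = [
    "build_network",
    "degree_summary",
    "clustering_coefficient",
    "powerlaw_loglog_fit",
    "poisson_gof",
    "editing_cost",
    "transitivity_cluster",
    "Clustering",
    "network_summary",
]


def build_network(edges: EdgeList, nodes=None) -> nx.Graph:
    """Graph over ``nodes`` (default: edge endpoints) with the given edges."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def degree_summary(net: nx.Graph) -> dict:
    """Average/median degree, connected fraction and degree histogram.

    The average runs over *all* nodes, isolates included: with N nodes and E
    edges it equals 2E/N.
    """
    n = net.number_of_nodes()
    if n == 0:
        return {
            "n_nodes": 0,
            "n_edges": 0,
            "average_degree": 0.0,
            "median_degree": 0.0,
            "n_connected": 0,
            "fraction_connected": 0.0,
            "histogram": {},
        }
    degrees = np.array([d for _, d in net.degree()])
    vals, counts = np.unique(degrees, return_counts=True)
    return {
        "n_nodes": n,
        "n_edges": net.number_of_edges(),
        "average_degree": float(degrees.mean()),
        "median_degree": float(np.median(degrees)),
        "n_connected": int((degrees > 0).sum()),
        "fraction_connected": float((degrees > 0).mean()),
        "histogram": {int(v): int(c) for v, c in zip(vals, counts)},
    }


def clustering_coefficient(net: nx.Graph, include_isolates: bool = False) -> float:
    """Watts-Strogatz clustering coefficient.

    Mean over nodes of local transitivity (triangles through the node over
    wedges through it).  Nodes of degree < 2 contribute 0.  By default the
    mean runs over non-isolated nodes only; ``include_isolates=True`` averages
    over every node instead — the choice changes the statistic, so it is an
    explicit flag.
    """
    if include_isolates:
        nodes = list(net.nodes)
    else:
        nodes = [v for v, d in net.degree() if d > 0]
    if not nodes:
        return 0.0
    local = nx.clustering(net, nodes)
    return float(np.mean(list(local.values())))


def powerlaw_loglog_fit(histogram: dict) -> dict:
    """OLS of log10(count) on log10(degree) over degrees >= 1.

    Returns slope, intercept and R^2; fewer than 3 distinct positive degrees
    makes the regression meaningless and sets ``reliable`` to False.
    """
    pts = [(k, c) for k, c in histogram.items() if k >= 1 and c >= 1]
    if len(pts) < 3:
        return {"slope": np.nan, "intercept": np.nan, "r_squared": np.nan, "reliable": False}
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "reliable": True,
    }


def poisson_gof(histogram: dict) -> float:
    """Chi-square goodness of fit of the degree histogram to a Poisson law.

    The Poisson mean is the average degree implied by the histogram.  Cells
    are pooled from the upper tail (and merged upward from low degrees)
    until every expected count is at least 5; one degree of freedom is spent
    on the estimated mean.
    """
    total = sum(histogram.values())
    if total == 0:
        raise ValidationError("empty histogram")
    lam = sum(k * c for k, c in histogram.items()) / total
    kmax = max(histogram)
    ks = np.arange(kmax + 1)
    expected = total * stats.poisson.pmf(ks, lam)
    tail = total * stats.poisson.sf(kmax, lam)
    observed = np.array([histogram.get(int(k), 0) for k in ks], dtype=float)
    expected = np.append(expected, tail)
    observed = np.append(observed, 0.0)
    # pool adjacent cells until every expected count >= 5
    obs_pooled, exp_pooled = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5.0:
            obs_pooled.append(o_acc)
            exp_pooled.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 or o_acc > 0:
        if exp_pooled:
            obs_pooled[-1] += o_acc
            exp_pooled[-1] += e_acc
        else:
            obs_pooled, exp_pooled = [o_acc], [e_acc]
    if len(exp_pooled) < 2:
        raise ValidationError("too few pooled cells for a goodness-of-fit test")
    obs_pooled = np.asarray(obs_pooled)
    exp_pooled = np.asarray(exp_pooled)
    # renormalize pooled expectations to the observed total (guards rounding)
    exp_pooled *= obs_pooled.sum() / exp_pooled.sum()
    chi2 = float(((obs_pooled - exp_pooled) ** 2 / exp_pooled).sum())
    dof = len(exp_pooled) - 1 - 1  # one parameter (the mean) estimated
    dof = max(dof, 1)
    return float(stats.chi2.sf(chi2, dof))


# ---------------------------------------------------------------------------
# Cluster editing (transitivity clustering)
# ---------------------------------------------------------------------------


@dataclass
class Clustering:
    """Partition of the node set into disjoint clusters."""

    clusters: list  # list of sorted node lists, deterministic order

    def __post_init__(self):
        flat = [v for c in self.clusters for v in c]
        if len(flat) != len(set(flat)):
            raise ValidationError("clusters must be disjoint")

    @property
    def sizes(self) -> list:
        return [len(c) for c in self.clusters]

    def membership(self) -> dict:
        return {v: i for i, c in enumerate(self.clusters) for v in c}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": i, "gene": v, "size": len(c)}
            for i, c in enumerate(self.clusters)
            for v in c
        ]
        return pd.DataFrame(rows, columns=["cluster", "gene", "size"])


def editing_cost(net: nx.Graph, clusters) -> int:
    """Edge deletions + insertions needed to turn ``net`` into these cliques."""
    member = {v: i for i, c in enumerate(clusters) for v in c}
    inter = sum(1 for a, b in net.edges if member[a] != member[b])
    intra_edges = net.number_of_edges() - inter
    possible_intra = sum(len(c) * (len(c) - 1) // 2 for c in clusters)
    return inter + (possible_intra - intra_edges)


def _greedy_component(net: nx.Graph, comp: list) -> list:
    """Greedy agglomeration + node-move refinement on one component.

    Nodes are seeded in order of decreasing degree (ties by node id); each
    node joins the existing cluster minimizing the marginal editing cost
    ``|C| - 2k`` (k = neighbors already in C), with ties broken toward
    merging.  Refinement passes then let every node move to the cluster (or
    a fresh singleton) that lowers the cost most, repeated until no move
    improves (each pass strictly lowers the cost, so this terminates).
    """
    order = sorted(comp, key=lambda v: (-net.degree(v), v))
    clusters: list[set] = []
    for v in order:
        nbrs = set(net[v])
        best, best_delta = None, None
        for c in clusters:
            k = len(nbrs & c)
            delta = len(c) - 2 * k  # insertions needed minus deletions saved
            if best_delta is None or delta < best_delta:
                best, best_delta = c, delta
        if best is not None and best_delta <= 0:  # "<= 0": merge-preferring tie-break
            best.add(v)
        else:
            clusters.append({v})
    # node-move refinement in canonical node order, repeated to a fixed point
    for _ in range(len(comp)):
        moved = False
        for v in sorted(comp):
            home = next(c for c in clusters if v in c)
            nbrs = set(net[v])
            k_home = len(nbrs & home)
            # editing cost attributable to v inside its current cluster,
            # relative to v as a singleton: missing edges minus covered edges
            leave_gain = (len(home) - 1 - k_home) - k_home
            best_c, best_delta = home, 0
            for c in clusters:
                if c is home:
                    continue
                k = len(nbrs & c)
                delta = (len(c) - 2 * k) - leave_gain
                if delta < best_delta:
                    best_c, best_delta = c, delta
            if -leave_gain < best_delta:
                best_c = None  # best move is out into a fresh singleton
            if best_c is not home:
                home.discard(v)
                if best_c is None:
                    clusters.append({v})
                else:
                    best_c.add(v)
                moved = True
        clusters = [c for c in clusters if c]
        if not moved:
            break
    return [sorted(c) for c in clusters]


def transitivity_cluster(net: nx.Graph) -> Clustering:
    """Deterministic greedy cluster editing of the whole network.

    Connected components are clustered independently (edits never pay off
    across components); isolates become singletons.  Output order is by
    decreasing cluster size, then lexicographic first member.
    """
    clusters = []
    for comp in nx.connected_components(net):
        comp = sorted(comp)
        if len(comp) == 1:
            clusters.append(comp)
        else:
            clusters.extend(_greedy_component(net, comp))
    clusters.sort(key=lambda c: (-len(c), c))
    return Clustering(clusters=clusters)


def network_summary(net: nx.Graph) -> dict:
    """All topology statistics in one JSON-serializable dictionary."""
    deg = degree_summary(net)
    out = dict(deg)
    out["clustering_coefficient"] = clustering_coefficient(net)
    out["powerlaw_fit"] = powerlaw_loglog_fit(deg["histogram"])
    try:
        out["poisson_gof_pvalue"] = poisson_gof(deg["histogram"])
    except ValidationError:
        out["poisson_gof_pvalue"] = None
    return out
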