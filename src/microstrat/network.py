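"""Thresholded Spearman co-occurrence networks and Zi-Pi topological roles.

A co-occurrence network joins two taxa when the Spearman correlation of
their abundances across samples is strong (|rho| above a kingdom-specific
threshold, conventionally 0.7 for bacteria and 0.5 for fungi) and
significant after multiple-testing correction. Nodes are then placed in
the Zi-Pi plane — within-module degree z-score against among-module
participation coefficient — and non-peripheral nodes (module hubs,
connectors, network hubs) are reported as keystone taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .core_io import validate_feature_table

__all__ = [
    "prevalence_filter",
    "spearman_matrix",
    "build_network",
    "detect_modules",
    "zi_pi",
    "classify_roles",
    "NetworkSummary",
    "network_summary",
    "bipartite_function_host",
    "SpearmanCooccurrence",
    "write_edge_list",
]


def prevalence_filter(table: pd.DataFrame, min_prevalence: float = 0.2) -> pd.DataFrame:
    """Keep taxa present (count > 0) in at least ``min_prevalence`` of samples."""
    if not 0 <= min_prevalence <= 1:
        raise ValueError("min_prevalence must be in [0, 1]")
    validate_feature_table(table)
    prevalence = (table > 0).mean(axis=0)
    kept = table.loc[:, prevalence >= min_prevalence]
    if kept.shape[1] == 0:
        raise ValueError(
            f"prevalence filter at {min_prevalence} removed all {table.shape[1]} taxa"
        )
    return kept


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and p-values between taxa (columns).

    Rho uses average ranks for ties; p comes from the standard
    t-distribution approximation. Pairs involving a constant taxon are
    NaN (undefined) and are excluded from edges downstream.
    """
    validate_feature_table(table)
    if table.shape[0] < 4:
        raise ValueError("need >= 4 samples for meaningful correlation p-values")
    X = table.to_numpy(dtype=float)
    constant = table.columns[np.ptp(X, axis=0) == 0].tolist()
    if constant:
        warnings.warn(f"constant taxa give undefined correlations: {constant}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        res = stats.spearmanr(X)
    stat = np.asarray(res.statistic)
    if stat.ndim == 0:  # scipy collapses the 2-taxon case to a scalar
        r, pv = float(stat), float(np.asarray(res.pvalue))
        rho = np.array([[1.0, r], [r, 1.0]])
        pval = np.array([[0.0, pv], [pv, 0.0]])
    else:
        rho, pval = stat, np.asarray(res.pvalue)
    np.fill_diagonal(rho, 1.0)
    cols = table.columns
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )


def _edge_candidates(rho: pd.DataFrame, pairs=None):
    """Upper-triangle (i, j, rho, p-index) candidates with finite rho."""
    taxa = rho.index
    if pairs is None:
        iu, ju = np.triu_indices(len(taxa), k=1)
        pairs = list(zip(iu, ju))
    vals = rho.to_numpy()
    return [(i, j) for i, j in pairs if np.isfinite(vals[i, j])]


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    r_threshold: float = 0.7,
    alpha: float | None = 0.05,
    correction: str = "bh",
    _pairs=None,
    _node_kind=None,
) -> nx.Graph:
    """Threshold a correlation matrix into a signed co-occurrence graph.

    An edge joins i and j iff |rho_ij| > ``r_threshold`` and (when
    ``alpha`` is not None) the corrected p-value is < alpha; correction
    is Benjamini-Hochberg over all candidate pairs ("bh") or none.
    Isolated nodes are dropped; an empty result is a valid empty graph.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    if correction not in ("bh", "none"):
        raise ValueError(f"unknown correction: {correction!r}")
    taxa = rho.index
    rv = rho.to_numpy()
    pv = p.to_numpy()
    cand = _edge_candidates(rho, _pairs)
    off_diag = rv.astype(float).copy()
    np.fill_diagonal(off_diag, 1.0)
    undefined = sorted(taxa[~np.isfinite(off_diag).all(axis=1)].tolist())

    graph = nx.Graph(
        r_threshold=r_threshold, alpha=alpha, correction=correction,
        undefined_taxa=undefined,
    )
    if not cand:
        return graph
    raw_p = np.array([pv[i, j] for i, j in cand])
    if alpha is None:
        adj_p = raw_p
        keep_p = np.ones(len(cand), dtype=bool)
    else:
        adj_p = multipletests(raw_p, method="fdr_bh")[1] if correction == "bh" else raw_p
        keep_p = adj_p < alpha
    for (i, j), pr, pa, ok in zip(cand, raw_p, adj_p, keep_p):
        r = rv[i, j]
        if ok and abs(r) > r_threshold:
            graph.add_edge(
                taxa[i], taxa[j], rho=float(r), sign=1 if r > 0 else -1,
                p=float(pr), p_adj=float(pa),
            )
    if _node_kind:
        nx.set_node_attributes(graph, {n: _node_kind[n] for n in graph.nodes}, "kind")
    return graph


def detect_modules(graph: nx.Graph, seed: int = 0) -> dict:
    """Greedy Newman-modularity module assignment, node -> module id.

    Uses greedy agglomerative modularity maximisation over a graph
    rebuilt with lexicographically sorted nodes, which makes the result
    deterministic; ``seed`` is accepted for interface stability and
    recorded, but the algorithm itself draws no random numbers.
    Singleton components end up as their own modules.
    """
    if graph.number_of_nodes() == 0:
        return {}
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes, key=str))
    ordered.add_edges_from(sorted((min(u, v, key=str), max(u, v, key=str)) for u, v in graph.edges))
    if ordered.number_of_edges() == 0:
        communities = [{n} for n in ordered.nodes]
    else:
        communities = nx.community.greedy_modularity_communities(ordered)
    assignment = {}
    for module_id, members in enumerate(sorted((sorted(c, key=str) for c in communities), key=lambda m: m[0])):
        for node in members:
            assignment[node] = module_id
    return assignment


def zi_pi(graph: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    For node i in module s with k_{i,t} edges into module t and total
    degree k_i: Zi = (k_{i,s} - mean_s) / sd_s with mean/sd taken over
    the within-module degrees of s's members (population sd; Zi = 0 when
    sd is 0), and Pi = 1 - sum_t (k_{i,t}/k_i)^2. Isolated nodes are
    excluded with a warning.
    """
    missing = [n for n in graph.nodes if n not in modules]
    if missing:
        raise ValueError(f"modules do not cover nodes: {missing}")
    isolated = [n for n in graph.nodes if graph.degree(n) == 0]
    if isolated:
        warnings.warn(f"isolated nodes excluded from Zi-Pi: {isolated}")
    nodes = [n for n in graph.nodes if graph.degree(n) > 0]
    # edges from each node into each module
    k_to_module = {n: {} for n in nodes}
    for n in nodes:
        for nbr in graph.neighbors(n):
            m = modules[nbr]
            k_to_module[n][m] = k_to_module[n].get(m, 0) + 1
    within = {n: k_to_module[n].get(modules[n], 0) for n in nodes}
    rows = {}
    for n in nodes:
        s = modules[n]
        member_degrees = np.array([within[m] for m in nodes if modules[m] == s], dtype=float)
        sd = member_degrees.std()  # population sd
        zi = 0.0 if sd == 0 else (within[n] - member_degrees.mean()) / sd
        k = graph.degree(n)
        pi = 1.0 - sum((kt / k) ** 2 for kt in k_to_module[n].values())
        rows[n] = {"module": s, "degree": k, "within_degree": within[n], "Zi": zi, "Pi": pi}
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("taxon_id")
    return out


def classify_roles(
    topology: pd.DataFrame, zi_threshold: float = 2.5, pi_threshold: float = 0.62
) -> pd.DataFrame:
    """Assign Zi-Pi plane roles; non-peripheral nodes are keystones.

    Module hub: Zi > zi_threshold and Pi <= pi_threshold; connector:
    Pi > pi_threshold and Zi <= zi_threshold; network hub: both
    exceeded; peripheral otherwise (strict inequalities, so boundary
    values are peripheral).
    """
    if not np.isfinite(topology[["Zi", "Pi"]].to_numpy()).all():
        raise ValueError("non-finite Zi or Pi values")
    out = topology.copy()
    high_z = out["Zi"] > zi_threshold
    high_p = out["Pi"] > pi_threshold
    role = np.where(
        high_z & high_p, "network hub",
        np.where(high_z, "module hub", np.where(high_p, "connector", "peripheral")),
    )
    out["role"] = role
    out["keystone"] = out["role"] != "peripheral"
    return out


@dataclass
class NetworkSummary:
    """Node/edge counts and composition shares of a co-occurrence graph."""

    n_nodes: int
    n_edges: int
    positive_edge_fraction: float
    abundance_counts: dict = field(default_factory=dict)
    abundance_fractions: dict = field(default_factory=dict)
    module_sizes: dict = field(default_factory=dict)


def network_summary(
    graph: nx.Graph,
    classification: pd.Series | pd.DataFrame | None = None,
    modules: dict | None = None,
) -> NetworkSummary:
    """Count nodes, edges, positive-edge share and abundance-class shares.

    ``classification`` may be the label Series (or the classify_abundance
    frame) from the partition module; nodes it does not cover count as
    "unclassified". An empty graph yields zeros without division errors.
    """
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    if n_edges:
        positive = sum(1 for _, _, d in graph.edges(data=True) if d.get("sign", 1) > 0)
        pos_frac = positive / n_edges
    else:
        pos_frac = 0.0
    counts: dict = {}
    fractions: dict = {}
    if classification is not None:
        labels = classification["label"] if isinstance(classification, pd.DataFrame) else classification
        for node in graph.nodes:
            label = labels.get(node, "unclassified")
            counts[label] = counts.get(label, 0) + 1
        fractions = {k: v / n_nodes for k, v in counts.items()} if n_nodes else {}
    sizes: dict = {}
    if modules is not None:
        for node in graph.nodes:
            m = modules[node]
            sizes[m] = sizes.get(m, 0) + 1
    return NetworkSummary(n_nodes, n_edges, pos_frac, counts, fractions, sizes)


def bipartite_function_host(
    taxa_table: pd.DataFrame,
    function_table: pd.DataFrame,
    r_threshold: float = 0.7,
    alpha: float | None = 0.05,
    correction: str = "bh",
) -> nx.Graph:
    """Bipartite taxon-function network over shared samples.

    Spearman + threshold + significance exactly as :func:`build_network`,
    but only taxon-function pairs are candidates (BH corrects over those
    pairs alone). Node attribute ``kind`` is "taxon" or "function".
    """
    validate_feature_table(taxa_table)
    validate_feature_table(function_table)
    if set(taxa_table.index) != set(function_table.index):
        raise ValueError("taxa and function tables cover different samples")
    function_table = function_table.loc[taxa_table.index]
    overlap = set(taxa_table.columns) & set(function_table.columns)
    if overlap:
        raise ValueError(f"taxon and function ids overlap: {sorted(overlap)}")
    combined = pd.concat([taxa_table, function_table], axis=1)
    rho, p = spearman_matrix(combined)
    n_taxa = taxa_table.shape[1]
    pairs = [
        (i, n_taxa + j)
        for i in range(n_taxa)
        for j in range(function_table.shape[1])
    ]
    kinds = {c: "taxon" for c in taxa_table.columns}
    kinds.update({c: "function" for c in function_table.columns})
    graph = build_network(
        rho, p, r_threshold=r_threshold, alpha=alpha, correction=correction,
        _pairs=pairs, _node_kind=kinds,
    )
    graph.graph["n_connected_taxa"] = sum(1 for n in graph if kinds[n] == "taxon")
    graph.graph["n_connected_functions"] = sum(1 for n in graph if kinds[n] == "function")
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write the edge list as TSV (source, target, rho, sign, p_adj)."""
    rows = [
        {"source": u, "target": v, "rho": d.get("rho"), "sign": d.get("sign"),
         "p_adj": d.get("p_adj")}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "sign", "p_adj"]).to_csv(
        path, sep="\t", index=False
    )


class SpearmanCooccurrence(BaseEstimator):
    """End-to-end co-occurrence network estimator.

    fit(X) on a samples x taxa count table: prevalence-filters, computes
    the Spearman matrix, thresholds it into a graph, detects modules,
    computes Zi-Pi and classifies roles.

    Parameters mirror the individual steps; see :func:`build_network`,
    :func:`detect_modules` and :func:`classify_roles`.

    Attributes
    ----------
    graph_ : nx.Graph
        The signed co-occurrence graph (node attributes: module, Zi, Pi,
        role, and abundance class when a classification is passed to fit).
    rho_, p_ : pd.DataFrame
        Full correlation and p-value matrices after filtering.
    modules_ : dict
        node -> module id.
    topology_ : pd.DataFrame
        Zi, Pi, role and keystone flag per connected node.
    keystones_ : list
        Non-peripheral node ids.
    """

    def __init__(
        self,
        r_threshold: float = 0.7,
        alpha: float | None = 0.05,
        correction: str = "bh",
        min_prevalence: float = 0.2,
        zi_threshold: float = 2.5,
        pi_threshold: float = 0.62,
        seed: int = 0,
    ):
        self.r_threshold = r_threshold
        self.alpha = alpha
        self.correction = correction
        self.min_prevalence = min_prevalence
        self.zi_threshold = zi_threshold
        self.pi_threshold = pi_threshold
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None, classification: pd.Series | pd.DataFrame | None = None):
        filtered = prevalence_filter(X, self.min_prevalence)
        self.rho_, self.p_ = spearman_matrix(filtered)
        self.graph_ = build_network(
            self.rho_, self.p_, self.r_threshold, self.alpha, self.correction
        )
        self.modules_ = detect_modules(self.graph_, seed=self.seed)
        if self.graph_.number_of_nodes():
            topo = zi_pi(self.graph_, self.modules_)
            self.topology_ = classify_roles(topo, self.zi_threshold, self.pi_threshold)
        else:
            self.topology_ = pd.DataFrame(
                columns=["module", "degree", "within_degree", "Zi", "Pi", "role", "keystone"]
            )
        self.keystones_ = self.topology_.index[self.topology_["keystone"]].tolist()
        nx.set_node_attributes(self.graph_, self.modules_, "module")
        for col in ("Zi", "Pi", "role"):
            if col in self.topology_:
                nx.set_node_attributes(self.graph_, self.topology_[col].to_dict(), col)
        self._classification = classification
        if classification is not None:
            labels = (
                classification["label"]
                if isinstance(classification, pd.DataFrame)
                else classification
            )
            nx.set_node_attributes(
                self.graph_,
                {n: labels.get(n, "unclassified") for n in self.graph_.nodes},
                "abundance_class",
            )
        return self

    def summary(self) -> NetworkSummary:
        return network_summary(self.graph_, self._classification, self.modules_)
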