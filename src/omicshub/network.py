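"""DEG PPI networks, seed-plus-neighbor subnetworks, centralities, hubs.

The DEG network is the subgraph of a scored protein-protein interaction
edge list induced on differentially expressed genes, keeping edges with
score >= 0.4 (the usual medium-confidence cutoff). For each candidate
set, the subnetwork is the induced graph on the seeds plus their first
interacting neighbors. Topology is summarised per node by degree,
betweenness (unordered source-target pairs, endpoints excluded,
unnormalised) and closeness ((n_c - 1) / sum of distances within the
node's connected component) — the conventions of Cytoscape's
NetworkAnalyzer. Hubs are candidate genes ranking in the top k (dense
ranks, ties included) of at least two of the three metrics; candidates
in the degree top k of at least two subnetworks are additionally called
key genes (the cross-network degree rule).
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

METRICS = ("degree", "betweenness", "closeness")


def build_deg_network(edges: pd.DataFrame, degs: set, score_min: float = 0.4) -> nx.Graph:
    """Induced DEG graph from a scored edge list.

    Keeps edges with score >= score_min whose both endpoints are DEGs.
    Self-loops and duplicate edges are dropped (logged); isolated DEGs do
    not appear (the graph is built from surviving edges only).
    """
    g = nx.Graph()
    n_self = n_dup = 0
    for a, b, score in edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
        if a == b:
            n_self += 1
            continue
        if score < score_min or a not in degs or b not in degs:
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b, score=float(score))
    if n_self or n_dup:
        logger.info("dropped %d self-loops and %d duplicate edges", n_self, n_dup)
    return g


def extract_subnetwork(graph: nx.Graph, seeds: set) -> nx.Graph:
    """Induced subgraph on (seeds present in graph) plus their neighbors."""
    present = set(seeds) & set(graph.nodes)
    if not present:
        logger.warning("no seed gene present in the network; empty subnetwork")
        return nx.Graph()
    nodes = set(present)
    for s in present:
        nodes.update(graph.neighbors(s))
    return graph.subgraph(nodes).copy()


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness per node, with dense ranks.

    Betweenness counts, for each node v, the fraction of shortest paths
    through v summed over unordered pairs {s, t} excluding v, on the
    unweighted graph (edge scores are a filter, not a distance).
    Closeness is computed within each connected component; isolated
    nodes get 0. Ranks are dense (1 = highest; ties share a rank).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("centralities of an empty graph are undefined")
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=False)
    clo = nx.closeness_centrality(graph, wf_improved=False)
    table = pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "betweenness": pd.Series(btw, dtype=float),
            "closeness": pd.Series(clo, dtype=float),
        }
    )
    table.index.name = "gene_id"
    for m in METRICS:
        table[f"{m}_rank"] = table[m].rank(method="dense", ascending=False).astype(int)
    return table.sort_index()


def top_k_set(table: pd.DataFrame, metric: str, k: int = 10) -> set:
    """Nodes with dense rank <= k for one metric (ties at rank k included)."""
    return set(table.index[table[f"{metric}_rank"] <= k])


def hub_call(table: pd.DataFrame, candidates: set, k: int = 10, restrict: bool = True) -> pd.DataFrame:
    """Hub genes: top-k in at least two of the three metrics.

    With ``restrict`` (default) only candidate (seed) genes are eligible;
    set it False to rank every node for inspection. Returns a DataFrame
    with gene_id index, the per-metric membership flags and the list of
    qualifying metrics.
    """
    tops = {m: top_k_set(table, m, k) for m in METRICS}
    eligible = set(table.index) & set(candidates) if restrict else set(table.index)
    rows = []
    for gene in sorted(eligible):
        metrics_in = [m for m in METRICS if gene in tops[m]]
        if len(metrics_in) >= 2:
            rows.append((gene, ",".join(metrics_in), len(metrics_in)))
    return pd.DataFrame(rows, columns=["gene_id", "top_metrics", "n_top_metrics"]).set_index("gene_id")


def cross_network_degree_rule(
    tables: dict[str, pd.DataFrame], candidates: set, k: int = 10, exclude: set = frozenset()
) -> pd.DataFrame:
    """Candidates in the degree top-k of >= 2 networks, minus known hubs.

    ``tables`` maps network name -> centrality table. Returns gene_id
    index with the comma-joined networks in which the gene made the
    degree top-k.
    """
    if len(tables) < 2:
        raise ValueError("cross-network rule needs at least two networks")
    membership: dict[str, list[str]] = {}
    for name, table in tables.items():
        for gene in top_k_set(table, "degree", k) & set(candidates):
            membership.setdefault(gene, []).append(name)
    rows = [
        (g, ",".join(sorted(nets)), len(nets))
        for g, nets in sorted(membership.items())
        if len(nets) >= 2 and g not in exclude
    ]
    return pd.DataFrame(rows, columns=["gene_id", "networks", "n_networks"]).set_index("gene_id")


def hub_report(
    hubs_by_network: dict[str, pd.DataFrame],
    cross_degree: pd.DataFrame,
    candidate_sets,
    gene_de: pd.DataFrame,
) -> pd.DataFrame:
    """Per-key-gene summary table (expression direction + regulatory notes).

    Mirrors the classic key-gene table: one row per hub or cross-network
    key gene with its expression direction, the number of regulatory
    miRNAs, the methylation direction and the copy-number state, plus the
    networks in which it qualified.
    """
    def _indexed(ann: pd.DataFrame | None) -> pd.DataFrame:
        if ann is None or not len(ann):
            return pd.DataFrame()
        return ann.set_index("gene_id")

    ann_mirna = _indexed(candidate_sets.mirna_annotations)
    ann_meth = _indexed(candidate_sets.meth_annotations)
    ann_cna = _indexed(candidate_sets.cna_annotations)

    entries: dict[str, dict] = {}
    for net, hubs in hubs_by_network.items():
        for gene in hubs.index:
            entry = entries.setdefault(gene, {"networks": [], "rule": "two_metrics"})
            entry["networks"].append(net)
    for gene in cross_degree.index:
        entry = entries.setdefault(gene, {"networks": [], "rule": "cross_network_degree"})
        entry["networks"].extend(cross_degree.loc[gene, "networks"].split(","))

    rows = []
    for gene in sorted(entries):
        status = gene_de.loc[gene, "status"] if gene in gene_de.index else "ns"
        n_mirnas = int(ann_mirna.loc[gene, "n_mirnas"]) if gene in getattr(ann_mirna, "index", []) else 0
        meth = ann_meth.loc[gene, "methylation"] if gene in getattr(ann_meth, "index", []) else ""
        cna_state = ann_cna.loc[gene, "cna"] if gene in getattr(ann_cna, "index", []) else ""
        rows.append(
            (gene, status, n_mirnas, meth, cna_state,
             ",".join(sorted(set(entries[gene]["networks"]))), entries[gene]["rule"])
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "expression", "n_mirnas", "methylation", "cna", "networks", "rule"],
    ).set_index("gene_id")


def export_subnetwork(graph: nx.Graph, table: pd.DataFrame, edge_path, node_path, node_attrs: pd.DataFrame | None = None) -> None:
    """Write a subnetwork as an edge-list TSV plus a node-attribute TSV."""
    edges = pd.DataFrame(
        [(a, b, d.get("score", np.nan)) for a, b, d in graph.edges(data=True)],
        columns=["gene_a", "gene_b", "score"],
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = table.copy()
    if node_attrs is not None:
        nodes = nodes.join(node_attrs, how="left")
    nodes.to_csv(node_path, sep="\t")
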