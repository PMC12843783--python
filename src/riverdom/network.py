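"""Co-occurrence networks linking OTUs and DOM fluorescent components.

Edges are pairwise correlations passing both a magnitude threshold
(|r| > 0.5 by default) and a raw significance threshold (p < 0.05),
following common practice for microbial co-occurrence analysis.
Keystone taxa are operationalised as hub nodes: high degree combined
with low betweenness centrality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


class NetworkError(ValueError):
    pass


@dataclass
class CorrelationNetwork:
    """Thresholded correlation graph over OTUs and DOM components."""

    graph: nx.Graph
    r_min: float
    p_max: float
    method: str = "spearman"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [{"node1": u, "node2": v, **d}
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["node1", "node2", "rho", "p",
                                           "sign"])


def build_network(features: pd.DataFrame, r_min: float = 0.5,
                  p_max: float = 0.05, scope: str = "all",
                  component_labels: set[str] | None = None,
                  node_meta: dict[str, dict] | None = None,
                  method: str = "spearman",
                  bh_adjust: bool = False) -> CorrelationNetwork:
    """Build a co-occurrence network from a sample x feature table.

    ``component_labels`` names the columns that are DOM components (the
    rest are OTUs).  ``scope`` is ``"all"`` (OTU-OTU and OTU-component
    pairs) or ``"otu-component"`` (bipartite only).  Edges must satisfy
    ``|rho| > r_min`` and ``p < p_max``; isolated features are dropped.
    ``node_meta`` attaches attributes (e.g. phylum) per node.
    """
    if features.shape[0] < 4:
        raise NetworkError(f"need >=4 samples, got {features.shape[0]}")
    component_labels = set(component_labels or ())
    cols = list(features.columns)
    for col in cols:
        if features[col].nunique() <= 1:
            raise NetworkError(f"feature {col!r} is constant")
    results = []
    for f1, f2 in combinations(cols, 2):
        both_comp = f1 in component_labels and f2 in component_labels
        both_otu = f1 not in component_labels and f2 not in component_labels
        if scope == "otu-component" and (both_comp or both_otu):
            continue
        x = features[f1].to_numpy(dtype=float)
        y = features[f2].to_numpy(dtype=float)
        if method == "spearman":
            rho, p = stats.spearmanr(x, y)
        elif method == "pearson":
            rho, p = stats.pearsonr(x, y)
        else:
            raise NetworkError(f"unknown method {method!r}")
        results.append((f1, f2, float(rho), float(p)))
    if bh_adjust and results:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([r[3] for r in results], method="fdr_bh")[1]
        results = [(f1, f2, rho, float(q))
                   for (f1, f2, rho, _), q in zip(results, adj)]
    g = nx.Graph()
    for f1, f2, rho, p in results:
        if abs(rho) > r_min and p < p_max:
            g.add_edge(f1, f2, rho=rho, p=p,
                       sign="positive" if rho > 0 else "negative")
    for node in g.nodes:
        g.nodes[node]["kind"] = ("component" if node in component_labels
                                 else "OTU")
        if node_meta and node in node_meta:
            g.nodes[node].update(node_meta[node])
    return CorrelationNetwork(graph=g, r_min=r_min, p_max=p_max,
                              method=method)


def percent_negative(n_negative: int, n_edges: int) -> float:
    """Share of negative edges, in percent rounded to 1 decimal."""
    if n_edges == 0:
        return float("nan")
    return round(100.0 * n_negative / n_edges, 1)


def phylum_share(counts: dict[str, int], total: int) -> dict[str, float]:
    """Per-phylum share of nodes, in percent rounded to 2 decimals."""
    if total == 0:
        return {}
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


def combined_share(shares: dict[str, float], names: list[str]) -> float:
    """Combined percent share of a named set of phyla (2 decimals)."""
    return round(sum(shares.get(n, 0.0) for n in names), 2)


def network_summary(net: CorrelationNetwork,
                    phylum_set: list[str] | None = None) -> dict:
    """Node/edge counts, percent negative edges and per-phylum node shares.

    ``phylum_set`` optionally names phyla whose combined node share is
    reported, mirroring how dominant phyla are summarised in
    seasonal network comparisons.
    """
    g = net.graph
    n_neg = sum(1 for _, _, d in g.edges(data=True)
                if d.get("sign") == "negative")
    otu_nodes = [n for n, d in g.nodes(data=True) if d.get("kind") == "OTU"]
    counts: dict[str, int] = {}
    for n in otu_nodes:
        ph = g.nodes[n].get("phylum", "unclassified")
        counts[ph] = counts.get(ph, 0) + 1
    shares = phylum_share(counts, len(otu_nodes))
    summary = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "percent_negative": percent_negative(n_neg, net.n_edges),
        "phylum_shares": shares,
    }
    if phylum_set:
        summary["combined_share"] = combined_share(shares, phylum_set)
    return summary


def compare_networks(nodes_a: int, edges_a: int,
                     nodes_b: int, edges_b: int) -> dict:
    """Absolute and percent change in node and edge counts, a -> b.

    Percent change is ``100 (b - a) / a`` rounded to the nearest
    integer; undefined (None) when the baseline is zero.
    """
    def pct(a: int, b: int):
        if a == 0:
            return None
        return int(round(100.0 * (b - a) / a))

    return {
        "node_change": nodes_b - nodes_a,
        "edge_change": edges_b - edges_a,
        "node_percent_change": pct(nodes_a, nodes_b),
        "edge_percent_change": pct(edges_a, edges_b),
    }


def keystone_taxa(net: CorrelationNetwork, degree_quantile: float = 0.8,
                  betweenness_quantile: float = 0.2) -> pd.DataFrame:
    """Keystone detection: high degree, low betweenness.

    A node qualifies when its degree is at or above the
    ``degree_quantile`` of the degree distribution AND its betweenness
    centrality is at or below the ``betweenness_quantile`` of the
    betweenness distribution.  Both metrics are reported for every node.
    """
    g = net.graph
    if g.number_of_nodes() < 3:
        raise NetworkError("keystone detection needs at least 3 nodes")
    degree = dict(g.degree())
    btw = nx.betweenness_centrality(g)
    deg_cut = float(np.quantile(list(degree.values()), degree_quantile))
    btw_cut = float(np.quantile(list(btw.values()), betweenness_quantile))
    rows = []
    for node in g.nodes:
        rows.append({
            "node": node,
            "kind": g.nodes[node].get("kind", "OTU"),
            "degree": degree[node],
            "betweenness": btw[node],
            "keystone": bool(degree[node] >= deg_cut
                             and btw[node] <= btw_cut),
        })
    return pd.DataFrame(rows).set_index("node")


def export_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


def export_edge_list(net: CorrelationNetwork, path) -> None:
    net.edge_table().to_csv(path, index=False)
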