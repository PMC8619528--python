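"""Node-level network topology metrics and between-network comparisons.

Metrics follow the Cytoscape NetworkAnalyzer conventions: degree (DG) is the
number of incident edges regardless of correlation sign; neighborhood
connectivity (NC) is the mean degree of a node's neighbors; closeness
centrality (CC) is the reciprocal of the mean shortest-path length to the
nodes reachable from the node (computed per connected component, not
normalised by network size).  Degree-0 nodes take NC = CC = 0 by convention.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .conetwork import TaxonNetwork

__all__ = [
    "degree",
    "neighborhood_connectivity",
    "closeness_centrality",
    "topology_table",
    "compare_networks",
]


def _graph_of(network) -> nx.Graph:
    return network.graph if isinstance(network, TaxonNetwork) else network


def _check_node(g: nx.Graph, node) -> None:
    if node not in g:
        raise KeyError(f"node {node!r} not in network")


def degree(network, node) -> int:
    g = _graph_of(network)
    _check_node(g, node)
    return int(g.degree(node))


def neighborhood_connectivity(network, node) -> float:
    """Mean degree of the node's neighbors; 0 for an isolated node."""
    g = _graph_of(network)
    _check_node(g, node)
    neighbors = list(g.neighbors(node))
    if not neighbors:
        return 0.0
    return float(np.mean([g.degree(v) for v in neighbors]))


def closeness_centrality(network, node) -> float:
    """1 / mean(shortest-path length to reachable nodes); 0 if isolated."""
    g = _graph_of(network)
    _check_node(g, node)
    if g.degree(node) == 0:
        return 0.0
    # networkx with wf_improved=False: (r-1)/sum(d) over the node's
    # component, i.e. exactly 1/mean(d) — the NetworkAnalyzer convention.
    return float(nx.closeness_centrality(g, u=node, wf_improved=False))


def topology_table(network: TaxonNetwork) -> pd.DataFrame:
    """One row per node: condition, genus, degree, NC, CC."""
    rows = []
    for node in sorted(network.graph.nodes):
        rows.append(
            {
                "section": network.section,
                "dose_ppb": network.dose_ppb,
                "genus": node,
                "degree": degree(network, node),
                "neighborhood_connectivity": neighborhood_connectivity(network, node),
                "closeness_centrality": closeness_centrality(network, node),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["section", "dose_ppb", "genus", "degree",
                 "neighborhood_connectivity", "closeness_centrality"],
    )


def compare_networks(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    metric: str,
    min_nodes: int = 3,
) -> dict[str, float]:
    """Two-sided Mann–Whitney U between two networks' per-node metric
    distributions (normal approximation with tie correction).

    Returns ``{"u_stat", "p", "median_a", "median_b", "median_diff"}`` with
    direction reported as median_a − median_b.
    """
    a = rows_a[metric].to_numpy(dtype=float)
    b = rows_b[metric].to_numpy(dtype=float)
    if a.size < min_nodes or b.size < min_nodes:
        raise ValueError(
            f"compare_networks needs ≥ {min_nodes} nodes per network "
            f"(got {a.size} and {b.size})"
        )
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        u, p = a.size * b.size / 2.0, 1.0
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic")
    return {
        "u_stat": float(u),
        "p": float(p),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "median_diff": float(np.median(a) - np.median(b)),
    }


def compare_condition_grid(
    topo: pd.DataFrame, metrics: tuple[str, ...] = (
        "degree", "neighborhood_connectivity", "closeness_centrality",
    ),
) -> pd.DataFrame:
    """All within-section pairwise dose comparisons for each metric.

    Mirrors the exposed-vs-control and exposed-vs-exposed comparison grid;
    no multiplicity correction is applied across the grid by default.
    """
    rows = []
    for section, sub in topo.groupby("section"):
        doses = sorted(sub["dose_ppb"].unique())
        for i, da in enumerate(doses):
            for db in doses[i + 1:]:
                ra = sub[sub["dose_ppb"] == da]
                rb = sub[sub["dose_ppb"] == db]
                for metric in metrics:
                    res = compare_networks(ra, rb, metric)
                    rows.append(
                        {
                            "section": section,
                            "dose_a_ppb": da,
                            "dose_b_ppb": db,
                            "metric": metric,
                            **res,
                        }
                    )
    return pd.DataFrame(rows)
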