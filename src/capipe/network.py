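"""Functional connectivity networks from dF/F traces.

Edges are pairwise Spearman correlations that survive Bonferroni correction
over all n(n-1)/2 pairs at adjusted p < 0.001 and are positive; the edge
weight is the correlation coefficient.  Per-node centralities: degree
normalised by network size, the Barrat weighted clustering coefficient, and
closeness with edge length 1/r computed within connected components.
Session-level means are expressed as a percentage of the habituation value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import NetworkConfig, TraceMatrix, ValidationError


@dataclass
class FunctionalNetwork:
    graph: nx.Graph  # nodes = cell ids, edge attr "weight" = Spearman r
    edge_table: pd.DataFrame  # cell_i, cell_j, r, p_adjusted for kept edges

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(traces: TraceMatrix, config: NetworkConfig | None = None) -> FunctionalNetwork:
    """All-pairs Spearman network with Bonferroni-thresholded positive edges.

    With ``config.correction="none"`` the raw p-values are thresholded
    instead (the looser reading of the edge rule).
    """
    config = config or NetworkConfig()
    n = traces.n_cells
    if n < 2:
        raise ValidationError("need at least 2 cells to build a network")
    values = traces.values
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant trace(s): nodes kept, edges undefined"
        )
    ok = np.flatnonzero(~constant)
    rho = np.full((n, n), np.nan)
    pval = np.full((n, n), np.nan)
    if len(ok) >= 2:
        sub_r, sub_p = stats.spearmanr(values[ok], axis=1)
        if np.ndim(sub_r) == 0:  # scipy collapses the 2-variable case to scalars
            sub_r = np.array([[1.0, sub_r], [sub_r, 1.0]])
            sub_p = np.array([[0.0, sub_p], [sub_p, 0.0]])
        rho[np.ix_(ok, ok)] = sub_r
        pval[np.ix_(ok, ok)] = sub_p
    m = n * (n - 1) // 2
    graph = nx.Graph()
    graph.add_nodes_from(traces.cell_ids)
    rows = []
    iu, ju = np.triu_indices(n, k=1)
    r_u, p_u = rho[iu, ju], pval[iu, ju]
    if config.correction == "bonferroni":
        p_adj = np.minimum(p_u * m, 1.0)
    elif config.correction == "none":
        p_adj = p_u
    else:
        raise ValidationError(f"unknown correction {config.correction!r}")
    keep = np.isfinite(p_adj) & (p_adj < config.edge_alpha)
    if config.positive_only:
        keep &= r_u > 0
    for i, j, r, p in zip(iu[keep], ju[keep], r_u[keep], p_adj[keep]):
        a, b = traces.cell_ids[i], traces.cell_ids[j]
        graph.add_edge(a, b, weight=float(r))
        rows.append({"cell_i": a, "cell_j": b, "r": float(r), "p_adjusted": float(p)})
    edge_table = pd.DataFrame(rows, columns=["cell_i", "cell_j", "r", "p_adjusted"])
    return FunctionalNetwork(graph, edge_table)


def degree_centrality(net: FunctionalNetwork) -> dict[str, float]:
    """Edge count per node divided by network size minus one."""
    n = net.n_nodes
    if n < 2:
        raise ValidationError("degree undefined for fewer than 2 nodes")
    return {node: net.graph.degree(node) / (n - 1) for node in net.graph.nodes}


def clustering_coefficient(net: FunctionalNetwork) -> dict[str, float]:
    """Barrat weighted local clustering.

    C_i = 1 / (s_i (k_i - 1)) * sum over triangle-closing neighbour pairs
    (j, h) of (w_ij + w_ih) / 2; nodes of degree < 2 score 0.
    """
    g = net.graph
    out: dict[str, float] = {}
    for i in g.nodes:
        neigh = list(g[i])
        k = len(neigh)
        if k < 2:
            out[i] = 0.0
            continue
        s = sum(g[i][j]["weight"] for j in neigh)
        acc = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = neigh[a], neigh[b]
                if g.has_edge(j, h):
                    acc += (g[i][j]["weight"] + g[i][h]["weight"]) / 2
        out[i] = (2 * acc) / (s * (k - 1)) if s > 0 else 0.0
    return out


def closeness_centrality(net: FunctionalNetwork, config: NetworkConfig | None = None) -> dict[str, float]:
    """Inverse mean shortest-path distance, with edge length 1/weight.

    Distances are computed within each connected component (stronger
    correlation = shorter edge); isolated nodes score 0.  With
    ``config.distance = "one_minus_r"`` edge length is 1 - r instead.
    """
    config = config or NetworkConfig()
    if net.n_nodes < 2:
        raise ValidationError("closeness undefined for fewer than 2 nodes")
    g = net.graph.copy()
    for u, v, d in g.edges(data=True):
        if config.distance == "inverse":
            d["length"] = 1.0 / d["weight"]
        elif config.distance == "one_minus_r":
            d["length"] = 1.0 - d["weight"]
        else:
            raise ValidationError(f"unknown distance rule {config.distance!r}")
    # wf_improved=False gives (n_reachable - 1) / sum(distances): the plain
    # inverse-average-distance within the node's component
    return nx.closeness_centrality(g, distance="length", wf_improved=False)


def node_table(net: FunctionalNetwork, config: NetworkConfig | None = None) -> pd.DataFrame:
    deg = degree_centrality(net)
    clu = clustering_coefficient(net)
    clo = closeness_centrality(net, config)
    return pd.DataFrame(
        {
            "cell": list(net.graph.nodes),
            "degree": [deg[c] for c in net.graph.nodes],
            "clustering": [clu[c] for c in net.graph.nodes],
            "closeness": [clo[c] for c in net.graph.nodes],
        }
    )


def session_summary(net: FunctionalNetwork, config: NetworkConfig | None = None) -> dict[str, float]:
    """Network-level means of the three centralities."""
    table = node_table(net, config)
    return {
        "mean_degree": float(table["degree"].mean()),
        "mean_clustering": float(table["clustering"].mean()),
        "mean_closeness": float(table["closeness"].mean()),
        "n_edges": float(net.n_edges),
    }


def normalize_to_habituation(summaries: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Express each session's centrality means as a percentage of HA's.

    ``summaries`` maps session label -> session_summary output; HA required.
    """
    if "HA" not in summaries:
        raise ValidationError("habituation summary required for normalisation")
    baseline = summaries["HA"]
    metrics = ("mean_degree", "mean_clustering", "mean_closeness")
    if all(baseline[m] == 0 or not np.isfinite(baseline[m]) for m in metrics):
        raise ValidationError("all habituation centrality means are zero; cannot normalise")
    rows = []
    for session, summary in summaries.items():
        for metric in metrics:
            base = baseline[metric]
            if base == 0 or not np.isfinite(base):
                warnings.warn(f"habituation {metric} is zero; percent_of_HA undefined")
                rows.append(
                    {"session": session, "metric": metric,
                     "value": summary[metric], "percent_of_HA": np.nan}
                )
                continue
            rows.append(
                {
                    "session": session,
                    "metric": metric,
                    "value": summary[metric],
                    "percent_of_HA": 100.0 * summary[metric] / base,
                }
            )
    return pd.DataFrame(rows)
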