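"""Per-arm Spearman correlation networks and differential-network statistics.

Within one phase/arm cell a feature-by-feature Spearman matrix (average
ranks for ties, Pearson on ranks, two-sided p from the t approximation with
n - 2 df) is thresholded into an undirected simple graph: an edge requires
|r| strictly above ``r_threshold`` (default 0.6) and p strictly below
``p_threshold`` (default 0.05). Betweenness centrality uses Brandes'
algorithm with unnormalized pair counts. Arm-wise comparison produces
elementwise correlation differences (polyphenol minus placebo), betweenness
differences on the placebo-minus-polyphenol convention (positive = more
central under placebo), per-node changes in the count of strong
(|r| > 0.7) partners, and pathway-pair mean correlation differences.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


class NetworkError(ValueError):
    pass


def spearman_pair(x, y) -> tuple[float, float]:
    """Spearman r and two-sided p for one pair of vectors."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_matrix(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-by-feature Spearman r and p matrices.

    Requires n >= 4 samples. Constant features produce NaN r/p against
    every partner (flagged by NaN — they can never form an edge); the
    diagonal is fixed to r = 1, p = 0.
    """
    n = X.shape[0]
    if n < 4:
        raise NetworkError(f"need >= 4 samples for correlation, got {n}")
    cols = X.columns
    arr = X.to_numpy(dtype=float)
    ranks = np.apply_along_axis(stats.rankdata, 0, arr)  # average ranks
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks, rowvar=False)  # Pearson on ranks; NaN if constant
        r = np.clip(r, -1.0, 1.0, out=r)
        # two-sided p from the t approximation with n - 2 df
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.abs(r) == 1.0] = 0.0
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


@dataclasses.dataclass
class GroupNetwork:
    """Thresholded correlation network for one arm."""

    nodes: list
    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    edges: list[tuple]            # (i, j, r, p)
    betweenness: pd.Series
    pathways: dict = dataclasses.field(default_factory=dict)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            [(i, j, r) for i, j, r, _ in self.edges], weight="spearman_r")
        return g


def build_network(r_matrix: pd.DataFrame, p_matrix: pd.DataFrame,
                  r_threshold: float = 0.6, p_threshold: float = 0.05,
                  pathways: dict | None = None) -> GroupNetwork:
    """Edge iff |r| > r_threshold (strict) and p < p_threshold (strict);
    isolated nodes are retained. NaN correlations never form edges."""
    nodes = list(r_matrix.index)
    edges = []
    for a_idx, i in enumerate(nodes):
        for j in nodes[a_idx + 1:]:
            r = r_matrix.loc[i, j]
            p = p_matrix.loc[i, j]
            if np.isfinite(r) and np.isfinite(p) and abs(r) > r_threshold and p < p_threshold:
                edges.append((i, j, float(r), float(p)))
    net = GroupNetwork(nodes=nodes, r_matrix=r_matrix, p_matrix=p_matrix,
                       edges=edges, betweenness=pd.Series(dtype=float),
                       pathways=dict(pathways or {}))
    net.betweenness = betweenness(net)
    return net


def betweenness(network: GroupNetwork) -> pd.Series:
    """Unnormalized shortest-path betweenness (Brandes); each unordered pair
    of other nodes contributes 1 split evenly over tied shortest paths."""
    values = nx.betweenness_centrality(network.graph, normalized=False)
    return pd.Series(values, name="betweenness").reindex(network.nodes)


@dataclasses.dataclass
class DifferentialNetwork:
    """Arm-wise network differences (recovery-phase rewiring statistics)."""

    delta_r: pd.DataFrame              # r_polyphenol - r_placebo
    delta_betweenness: pd.Series       # b_placebo - b_polyphenol
    strong_edge_delta: pd.Series       # strong-partner count, poly - placebo
    abs_r: dict[str, np.ndarray]       # off-diagonal |r| distribution per arm
    pathway_pair_mean_delta: pd.DataFrame
    strong_threshold: float


def _strong_counts(r: pd.DataFrame, threshold: float) -> pd.Series:
    a = r.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    with np.errstate(invalid="ignore"):
        counts = np.nansum(np.abs(a) > threshold, axis=1)
    return pd.Series(counts.astype(int), index=r.index)


def _offdiag_abs(r: pd.DataFrame) -> np.ndarray:
    a = r.to_numpy(dtype=float)
    iu = np.triu_indices_from(a, k=1)
    vals = np.abs(a[iu])
    return vals[np.isfinite(vals)]


def differential_network(net_placebo: GroupNetwork, net_polyphenol: GroupNetwork,
                         pathways: pd.Series | dict | None = None,
                         strong_threshold: float = 0.7) -> DifferentialNetwork:
    """Differential statistics between the two arm networks.

    The strong-partner rule |r| > ``strong_threshold`` is applied to the raw
    correlation matrices, independent of the edge rule. ``pathways`` maps
    feature -> pathway label for the pathway-pair means; when omitted the
    networks' own labels are used.
    """
    if list(net_placebo.nodes) != list(net_polyphenol.nodes):
        raise NetworkError("node sets differ between arm networks")
    r_pla = net_placebo.r_matrix
    r_pol = net_polyphenol.r_matrix
    delta_r = r_pol - r_pla
    delta_b = (net_placebo.betweenness - net_polyphenol.betweenness)
    strong = (_strong_counts(r_pol, strong_threshold)
              - _strong_counts(r_pla, strong_threshold))

    if pathways is None:
        pathways = {**net_polyphenol.pathways, **net_placebo.pathways}
    pathways = pd.Series(dict(pathways)).reindex(net_placebo.nodes).fillna("other")

    labels = sorted(pathways.unique())
    rows = []
    nodes = list(net_placebo.nodes)
    dvals = delta_r.to_numpy(dtype=float)
    for ai, pa in enumerate(labels):
        idx_a = [k for k, n in enumerate(nodes) if pathways[n] == pa]
        for pb in labels[ai:]:
            idx_b = [k for k, n in enumerate(nodes) if pathways[n] == pb]
            pair_vals = []
            if pa == pb:
                for u in range(len(idx_a)):
                    for v in range(u + 1, len(idx_a)):
                        pair_vals.append(dvals[idx_a[u], idx_a[v]])
            else:
                for u in idx_a:
                    for v in idx_b:
                        pair_vals.append(dvals[u, v])
            pair_vals = np.asarray(pair_vals, dtype=float)
            pair_vals = pair_vals[np.isfinite(pair_vals)]
            if pair_vals.size:
                rows.append({"pathway_a": pa, "pathway_b": pb,
                             "mean_delta_r": float(pair_vals.mean()),
                             "n_pairs": int(pair_vals.size)})
    return DifferentialNetwork(
        delta_r=delta_r,
        delta_betweenness=delta_b,
        strong_edge_delta=strong,
        abs_r={"placebo": _offdiag_abs(r_pla), "polyphenol": _offdiag_abs(r_pol)},
        pathway_pair_mean_delta=pd.DataFrame(rows),
        strong_threshold=strong_threshold,
    )


def pvalue_ecdf(p_values, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Right-continuous ECDF of p-values evaluated on a fixed grid
    (default 0, 0.01, ..., 1) for serialization."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise NetworkError("empty p-value input")
    if np.any((p < 0) | (p > 1)):
        raise NetworkError("p-values must lie in [0, 1]")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    sorted_p = np.sort(p)
    values = np.searchsorted(sorted_p, grid, side="right") / p.size
    return pd.DataFrame({"p": grid, "ecdf": values})
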