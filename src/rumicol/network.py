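"""Time-stratified co-occurrence network inference and complexity metrics.

Genera passing a prevalence filter within a stratum are correlated
pairwise (Spearman, on log relative abundances — a no-op safeguard since
ranks are invariant to monotone transforms).  Pairs with |rho| above a
threshold and BH-adjusted p below alpha become signed edges.  Communities
come from Girvan-Newman edge-betweenness removal with the partition
chosen at maximum modularity; complexity is summarised as node count,
signed edge counts, mean degree, and the share of the community's total
abundance covered by the network's genera.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import girvan_newman, modularity
from scipy import stats

from .community import CountTable, adjust_bh

__all__ = [
    "CoNetwork",
    "filter_prevalence",
    "infer_edges",
    "build_network",
    "detect_communities",
    "network_metrics",
    "network_trajectory",
    "spearman_exact_null",
]

logger = logging.getLogger(__name__)

LOG_PSEUDOCOUNT = 1e-6
EXACT_P_MAX_N = 10
MIN_SAMPLES = 5


@dataclass
class CoNetwork:
    """Signed co-occurrence graph for one (group x time) stratum."""

    stratum: str
    graph: nx.Graph
    nodes: pd.DataFrame        # index genus; mean_rel_abundance
    edges: pd.DataFrame        # a, b, rho, p, q, sign
    communities: dict[str, int] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)


def filter_prevalence(table: CountTable, stratum_samples=None,
                      min_prevalence: float = 0.75) -> CountTable:
    """Keep genera present (count > 0) in strictly more than
    ``min_prevalence`` of the stratum's samples."""
    if not 0 < min_prevalence < 1:
        raise ValueError("min_prevalence must be in (0, 1)")
    sub = table if stratum_samples is None else table.subset(samples=stratum_samples)
    if len(sub.samples) == 0:
        raise ValueError("stratum is empty")
    prev = (sub.counts > 0).mean(axis=0)
    keep = prev > min_prevalence
    if not keep.any():
        warnings.warn("prevalence filter removed every genus")
    return sub.subset(taxa=[t for t, k in zip(sub.taxa, keep) if k])


@lru_cache(maxsize=None)
def _exact_null_s(n: int) -> np.ndarray:
    """Sorted sum-of-squared-rank-differences over all n! permutations.

    rho = 1 - 6 S / (n (n^2 - 1)), so the distribution of integer S gives
    the exact tie-free Spearman null.
    """
    base = np.arange(1, n + 1)
    vals = np.fromiter(
        (int(((np.array(p) - base) ** 2).sum()) for p in permutations(base)),
        dtype=np.int64, count=math.factorial(n))
    vals.sort()
    return vals


def spearman_exact_null(n: int) -> np.ndarray:
    """Exact null distribution of Spearman rho for sample size n (no ties)."""
    s = _exact_null_s(n)
    return 1.0 - 6.0 * s / (n * (n * n - 1))


def _exact_p_two_sided(rho: float, n: int) -> float:
    s = _exact_null_s(n)
    denom = n * (n * n - 1) / 6.0
    # |rho| >= |rho_obs|  <=>  S <= s_lo or S >= s_hi
    s_obs = (1.0 - abs(rho)) * denom
    s_hi = (1.0 + abs(rho)) * denom
    lo = int(np.searchsorted(s, s_obs + 1e-9, side="right"))
    hi = len(s) - int(np.searchsorted(s, s_hi - 1e-9, side="left"))
    # the two tails can share the central atom when rho ~ 0
    return min((lo + hi) / len(s), 1.0)


def _spearman_p(rho: float, n: int, has_ties: bool) -> float:
    if n <= EXACT_P_MAX_N and not has_ties:
        return _exact_p_two_sided(rho, n)
    if abs(rho) >= 1.0:
        return 2.0 / math.factorial(n) if n <= 20 else 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def infer_edges(table: CountTable, rho_threshold: float = 0.7,
                alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Spearman edges surviving |rho| > threshold and BH q < alpha.

    The table should already be stratum-filtered; counts are transformed
    to log10(relative abundance + pseudocount) before ranking (ranks make
    the result invariant to this monotone transform).  p-values are exact
    (full rank-permutation enumeration) for n <= 10 without ties, else
    from the t approximation; BH is applied across all tested pairs of
    the stratum.  Constant genera are skipped and logged.
    """
    n = len(table.samples)
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {n}")
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    logged = np.log10(rel + LOG_PSEUDOCOUNT)
    taxa = table.taxa

    const = np.ptp(logged, axis=0) == 0
    if const.any():
        skipped = [t for t, c in zip(taxa, const) if c]
        logger.warning("skipping %d constant genera: %s", len(skipped), skipped[:5])

    ranks = np.apply_along_axis(stats.rankdata, 0, logged)
    ties = np.array([len(np.unique(ranks[:, j])) < n for j in range(len(taxa))])
    centred = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centred ** 2).sum(axis=0))

    rows = []
    for i, j in combinations(range(len(taxa)), 2):
        if const[i] or const[j]:
            continue
        rho = float(centred[:, i] @ centred[:, j] / (norms[i] * norms[j]))
        p = _spearman_p(rho, n, bool(ties[i] or ties[j]))
        rows.append((taxa[i], taxa[j], rho, p))
    if not rows:
        return pd.DataFrame(columns=["a", "b", "rho", "p", "q", "sign"])
    df = pd.DataFrame(rows, columns=["a", "b", "rho", "p"])
    df["q"] = adjust_bh(df["p"].values)
    keep = (df["rho"].abs() > rho_threshold) & (df["q"] < alpha)
    df = df[keep].reset_index(drop=True)
    df["sign"] = np.sign(df["rho"]).astype(int)
    return df


def detect_communities(graph: nx.Graph) -> dict[str, int]:
    """Girvan-Newman partition at maximum modularity.

    Edges are removed by highest betweenness (ties broken by
    lexicographic edge order, so the result is deterministic); candidate
    partitions are the initial connected components plus every partition
    along the removal sequence, scored by modularity.  Graphs with no
    edges yield singleton communities.
    """
    if graph.number_of_nodes() == 0:
        return {}
    if graph.number_of_edges() == 0:
        return {node: i for i, node in enumerate(sorted(graph.nodes()))}

    def most_valuable(g: nx.Graph):
        bet = nx.edge_betweenness_centrality(g)
        best = max(bet.values())
        cands = [tuple(sorted(e)) for e, v in bet.items() if v >= best - 1e-12]
        return min(cands)

    candidates = [tuple(nx.connected_components(graph))]
    candidates.extend(girvan_newman(graph, most_valuable_edge=most_valuable))
    best_part, best_q = None, -np.inf
    for part in candidates:
        part = [set(c) for c in part]
        q = modularity(graph, part)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    out: dict[str, int] = {}
    for cid, comm in enumerate(sorted(best_part, key=lambda c: min(map(str, c)))):
        for node in comm:
            out[node] = cid
    return out


def network_metrics(network: CoNetwork, table: CountTable) -> dict[str, float]:
    """Complexity metrics of one stratum network.

    ``community_coverage_pct`` is 100 x the summed mean relative
    abundance (over the stratum's samples) of the genera in the network,
    relative to the whole community.
    """
    g = network.graph
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    if n_edges:
        n_neg = int((network.edges["sign"] < 0).sum())
    else:
        n_neg = 0
    n_pos = n_edges - n_neg
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    mean_rel = pd.Series(rel.mean(axis=0), index=table.taxa)
    coverage = 100.0 * float(mean_rel.reindex(list(g.nodes()), fill_value=0.0).sum())
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "n_positive_edges": n_pos,
        "n_negative_edges": n_neg,
        "pct_negative_edges": 100.0 * n_neg / n_edges if n_edges else 0.0,
        "avg_neighbors": 2.0 * n_edges / n_nodes if n_nodes else 0.0,
        "community_coverage_pct": coverage,
        "n_communities": len(set(network.communities.values())),
    }


def build_network(table: CountTable, stratum_samples=None, stratum: str = "",
                  min_prevalence: float = 0.75, rho_threshold: float = 0.7,
                  alpha: float = 0.05) -> CoNetwork:
    """Prevalence filter -> Spearman edges -> communities -> metrics."""
    sub_all = table if stratum_samples is None else table.subset(samples=stratum_samples)
    filt = filter_prevalence(table, stratum_samples, min_prevalence)
    edges = (infer_edges(filt, rho_threshold, alpha)
             if len(filt.taxa) >= 2 else
             pd.DataFrame(columns=["a", "b", "rho", "p", "q", "sign"]))
    g = nx.Graph()
    g.add_nodes_from(filt.taxa)
    for _, e in edges.iterrows():
        g.add_edge(e["a"], e["b"], rho=e["rho"], q=e["q"], sign=int(e["sign"]))
    rel = sub_all.counts / sub_all.counts.sum(axis=1, keepdims=True)
    mean_rel = pd.Series(rel.mean(axis=0), index=sub_all.taxa)
    nodes = pd.DataFrame({"mean_rel_abundance":
                          mean_rel.reindex(filt.taxa, fill_value=0.0)})
    net = CoNetwork(stratum=stratum, graph=g, nodes=nodes, edges=edges)
    net.communities = detect_communities(g)
    net.metrics = network_metrics(net, sub_all)
    return net


def network_trajectory(table: CountTable, metadata: pd.DataFrame,
                       group_by: str = "forage", time_col: str = "time_h",
                       min_prevalence: float = 0.75,
                       rho_threshold: float = 0.7, alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, dict[str, CoNetwork]]:
    """One network per (group x time) with metrics in a tidy long table.

    The default stratification groups by forage at each time point,
    pooling the other factors (n = 8 per stratum in the reference
    design).  Strata with too few samples are skipped with a warning.
    """
    meta = metadata.loc[table.samples]
    rows = []
    networks: dict[str, CoNetwork] = {}
    for group in sorted(meta[group_by].astype(str).unique()):
        for t in sorted(meta[time_col].unique()):
            mask = (meta[group_by].astype(str) == group) & (meta[time_col] == t)
            ids = list(meta.index[mask])
            label = f"{group}@{t:g}h"
            if len(ids) < MIN_SAMPLES:
                warnings.warn(f"stratum {label}: only {len(ids)} samples, skipped")
                continue
            net = build_network(table, ids, stratum=label,
                                min_prevalence=min_prevalence,
                                rho_threshold=rho_threshold, alpha=alpha)
            networks[label] = net
            rows.append({group_by: group, time_col: t, "n_samples": len(ids),
                         **net.metrics})
    return pd.DataFrame(rows), networks


def export_graphml(network: CoNetwork, path) -> None:
    g = network.graph.copy()
    for node, cid in network.communities.items():
        g.nodes[node]["community"] = cid
    for node in g.nodes():
        if node in network.nodes.index:
            g.nodes[node]["mean_rel_abundance"] = \
                float(network.nodes.loc[node, "mean_rel_abundance"])
    nx.write_graphml(g, path)
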