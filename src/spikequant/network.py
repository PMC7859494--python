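"""Signed Spearman co-occurrence networks and their attribute block.

Edges connect abundant OTUs whose pairwise Spearman correlation passes
|r| >= r_cutoff with a BH-adjusted p < alpha.  Attributes follow the
usual graph summaries: average degree 2E/N, mean local clustering
(degree < 2 contributes 0), mean shortest-path length over connected
pairs only, and Newman modularity of a seeded Louvain partition on the
unweighted, sign-ignored graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class NetworkAttributes:
    node_count: int
    edge_count: int
    positive_edges: int
    negative_edges: int
    average_degree: float
    average_clustering_coefficient: float
    average_path_length: float | None
    modularity: float | None
    n_components: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def _spearman_matrix(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman r and p as full matrices (scipy collapses the
    2-column case to scalars)."""
    rho, pval = stats.spearmanr(arr)
    if np.ndim(rho) == 0:
        rho = np.array([[1.0, rho], [rho, 1.0]])
        pval = np.array([[0.0, pval], [pval, 0.0]])
    return np.asarray(rho), np.asarray(pval)


def filter_abundant(
    table, threshold: float = 0.001, per_sample_mean: bool = False
) -> list:
    """OTUs whose overall proportion strictly exceeds ``threshold``.

    Default interpretation: summed abundance across all samples relative to
    the grand total.  ``per_sample_mean=True`` instead thresholds the mean
    of per-sample proportions.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0,1)")
    df = table.data if hasattr(table, "data") else pd.DataFrame(table)
    if per_sample_mean:
        totals = df.sum(axis=1).to_numpy(dtype=float)
        props = df.to_numpy(dtype=float) / totals[:, None]
        overall = pd.Series(props.mean(axis=0), index=df.columns)
    else:
        overall = df.sum(axis=0) / df.to_numpy().sum()
    subset = list(overall.index[overall > threshold])
    if not subset:
        raise ValueError(
            f"no OTUs exceed abundance threshold {threshold}; lower the threshold"
        )
    return subset


def build_network(
    table, r_cutoff: float = 0.6, alpha: float = 0.05, otu_subset=None
) -> nx.Graph:
    """All-pairs Spearman graph with BH-FDR edge selection.

    Keeps edges with adjusted p < alpha and |r| >= r_cutoff; edge
    attributes are ``r``, ``q`` and ``sign``.
    """
    df = table.data if hasattr(table, "data") else pd.DataFrame(table)
    if otu_subset is not None:
        df = df[list(otu_subset)]
    if df.shape[0] < 5:
        raise ValueError("need >= 5 samples to build a co-occurrence network")
    constant = [o for o in df.columns if df[o].nunique() == 1]
    if constant:
        warnings.warn(f"constant OTUs excluded from network: {constant}", stacklevel=2)
        df = df.drop(columns=constant)
    if df.shape[1] < 2:
        raise ValueError("need >= 2 non-constant OTUs")
    otus = list(df.columns)
    rho, pval = _spearman_matrix(df.to_numpy())
    iu = np.triu_indices(len(otus), k=1)
    qvals = multipletests(pval[iu], method="fdr_bh")[1]
    g = nx.Graph()
    g.add_nodes_from(otus)
    for (i, j), q in zip(zip(*iu), qvals):
        r = rho[i, j]
        if q < alpha and abs(r) >= r_cutoff:
            g.add_edge(
                otus[i], otus[j], r=float(r), q=float(q), sign=1 if r > 0 else -1
            )
    return g


def _mean_path_length_connected_pairs(g: nx.Graph) -> float | None:
    total, pairs = 0.0, 0
    for source, lengths in nx.all_pairs_shortest_path_length(g):
        for target, dist in lengths.items():
            if target != source:
                total += dist
                pairs += 1
    if pairs == 0:
        return None
    return total / pairs


def network_attributes(g: nx.Graph, seed: int = 0) -> NetworkAttributes:
    """Attribute block of a co-occurrence network (see module docstring)."""
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("network must have at least one node")
    e = g.number_of_edges()
    signs = nx.get_edge_attributes(g, "sign")
    pos = sum(1 for s in signs.values() if s > 0)
    neg = sum(1 for s in signs.values() if s < 0)
    if not signs:  # unsigned graph: count every edge as positive
        pos, neg = e, 0
    apl = _mean_path_length_connected_pairs(g)
    if apl is None:
        warnings.warn("edgeless graph: average path length undefined", stacklevel=2)
    if e > 0:
        communities = nx.community.louvain_communities(g, weight=None, seed=seed)
        q = nx.community.modularity(g, communities, weight=None)
    else:
        q = None
    return NetworkAttributes(
        node_count=n,
        edge_count=e,
        positive_edges=pos,
        negative_edges=neg,
        average_degree=2.0 * e / n,
        average_clustering_coefficient=float(nx.average_clustering(g)) if n else 0.0,
        average_path_length=apl,
        modularity=None if q is None else float(q),
        n_components=nx.number_connected_components(g),
    )


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, str(path))
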