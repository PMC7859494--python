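"""Alpha diversity of the relative-abundance branch.

Richness, bias-corrected Chao 1, Shannon (log base configurable,
default 2) and Faith's phylogenetic diversity, plus seeded rarefaction
curves.  Faith's PD includes the path from the observed tips to the
tree root by default (the historical behavior of the widely used
alpha-diversity scripts); pass ``include_root=False`` for the minimal
spanning subtree of the observed tips only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio

from .io import CountTable


def richness(sample_counts) -> int:
    """Number of OTUs with count > 0."""
    arr = np.asarray(sample_counts)
    return int(np.count_nonzero(arr > 0))


def chao1(sample_counts, bias_corrected: bool = True) -> float:
    """Chao 1 richness estimator.

    Bias-corrected form (default): S_obs + F1*(F1-1) / (2*(F2+1)).
    Classic form: S_obs + F1^2 / (2*F2) (undefined without doubletons,
    in which case the bias-corrected value is returned).
    """
    arr = np.asarray(sample_counts)
    s_obs = np.count_nonzero(arr > 0)
    f1 = int(np.count_nonzero(arr == 1))
    f2 = int(np.count_nonzero(arr == 2))
    if bias_corrected or f2 == 0:
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    return float(s_obs + f1 * f1 / (2.0 * f2))


def shannon(sample_counts, base: float = 2.0) -> float:
    """Shannon entropy of the positive proportions."""
    arr = np.asarray(sample_counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("shannon undefined for an all-zero vector")
    p = arr[arr > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(
    sample_counts, otu_ids, tree: skbio.TreeNode, include_root: bool = True
) -> float:
    """Faith's phylogenetic diversity of the observed OTUs.

    Sums the branch lengths of the subtree spanned by the observed tips,
    connected to the root when ``include_root`` (default).
    """
    arr = np.asarray(sample_counts)
    observed = [o for o, c in zip(otu_ids, arr) if c > 0]
    if not observed:
        return 0.0
    tip_index = {t.name: t for t in tree.tips()}
    missing = [o for o in observed if o not in tip_index]
    if missing:
        raise ValueError(f"observed OTUs missing from tree: {missing}")
    marked: set[int] = set()
    nodes: dict[int, skbio.TreeNode] = {}
    for name in observed:
        node = tip_index[name]
        while node is not None and id(node) not in marked:
            marked.add(id(node))
            nodes[id(node)] = node
            node = node.parent
    root = tree
    pd_total = sum(
        (n.length or 0.0) for n in nodes.values() if n is not root
    )
    if include_root:
        return float(pd_total)
    # subtract the chain from the root down to the LCA of the observed tips
    lca = tree.lca([tip_index[o] for o in observed]) if len(observed) > 1 else tip_index[observed[0]]
    node = lca
    off = 0.0
    while node is not None and node is not root:
        off += node.length or 0.0
        node = node.parent
    return float(pd_total - off)


def alpha_diversity(
    counts: CountTable,
    tree: skbio.TreeNode | None = None,
    shannon_base: float = 2.0,
    chao1_bias_corrected: bool = True,
    pd_include_root: bool = True,
) -> pd.DataFrame:
    """Per-sample index table (richness, chao1, shannon, faith_pd)."""
    rows = {}
    otus = counts.otu_ids
    for sid in counts.sample_ids:
        vec = counts.data.loc[sid].to_numpy()
        row = {
            "richness": richness(vec),
            "chao1": chao1(vec, bias_corrected=chao1_bias_corrected),
            "shannon": shannon(vec, base=shannon_base),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(vec, otus, tree, include_root=pd_include_root)
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def rarefaction_curve(
    sample_counts, depths, n_reps: int, seed: int
) -> pd.Series:
    """Mean observed richness at each subsampling depth."""
    arr = np.asarray(sample_counts, dtype=np.int64)
    total = int(arr.sum())
    depths = [int(d) for d in depths]
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds sample total {total}")
    if any(d < 1 for d in depths):
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(seed)
    means = {}
    for d in depths:
        vals = [
            richness(rng.multivariate_hypergeometric(arr, d)) for _ in range(n_reps)
        ]
        means[d] = float(np.mean(vals))
    return pd.Series(means, name="mean_richness")
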