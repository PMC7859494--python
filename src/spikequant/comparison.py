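"""Whole-community comparison of the relative and quantitative branches.

Bray-Curtis distances, classical PCoA, symmetric Procrustes with a
Monte-Carlo (row permutation) significance test, per-OTU Spearman
concordance with BH adjustment, and taxonomy-level aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from statsmodels.stats.multitest import multipletests

from .io import TaxonomyTable


@dataclass
class DistanceMatrix:
    sample_ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.d = d

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class Ordination:
    sample_ids: list
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # non-increasing, positive


@dataclass
class ProcrustesResult:
    m_squared: float
    p_value: float
    n_permutations: int
    seed: int


def bray_curtis(table) -> DistanceMatrix:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min)/sum(sums)."""
    df = table.data if hasattr(table, "data") else pd.DataFrame(table)
    arr = df.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        bad = list(df.index[arr.sum(axis=1) == 0])
        raise ValueError(f"all-zero samples have undefined Bray-Curtis: {bad}")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(sample_ids=list(df.index), d=d)


def pcoa(dist: DistanceMatrix, eig_tol: float = 1e-9) -> Ordination:
    """Classical (Torgerson) scaling of a distance matrix.

    Axes with non-positive eigenvalues are dropped (with a warning when
    meaningfully negative eigenvalues are present).
    """
    d = dist.d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    if eigvals[-1] < -1e-6 * scale:
        warnings.warn(
            f"dropping negative-eigenvalue axes (min eigenvalue {eigvals[-1]:.3g})",
            stacklevel=2,
        )
    keep = eigvals > eig_tol * scale
    eigvals = eigvals[keep]
    coords = eigvecs[:, keep] * np.sqrt(eigvals)
    return Ordination(
        sample_ids=list(dist.sample_ids), coordinates=coords, eigenvalues=eigvals
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    norm = np.sqrt((x**2).sum())
    if norm == 0:
        raise ValueError("degenerate configuration (all points identical)")
    return x / norm


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric Procrustes residual after centering, unit-scaling, rotation."""
    xs, ys = _standardize(x), _standardize(y)
    s = np.linalg.svd(xs.T @ ys, compute_uv=False).sum()
    return float(max(1.0 - s**2, 0.0))


def procrustes_test(
    ord_a: Ordination,
    ord_b: Ordination,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes M^2 with a PROTEST-style permutation p-value.

    Rows of the second configuration are permuted; the observed statistic
    is included in the null set (add-one convention), so p > 0 always.
    """
    if list(ord_a.sample_ids) != list(ord_b.sample_ids):
        raise ValueError("ordinations must share the same samples in the same order")
    k = min(ord_a.coordinates.shape[1], ord_b.coordinates.shape[1])
    if n_axes is not None:
        k = min(k, int(n_axes))
    if k < 1:
        raise ValueError("no shared positive-eigenvalue axes")
    x = ord_a.coordinates[:, :k]
    y = ord_b.coordinates[:, :k]
    m2 = _procrustes_m2(x, y)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _procrustes_m2(x, y[perm]) <= m2:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ProcrustesResult(
        m_squared=m2, p_value=float(p), n_permutations=n_perm, seed=seed
    )


def per_otu_concordance(
    rel, quant, r_threshold: float = 0.8, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Spearman concordance of relative vs quantitative abundance per OTU.

    Only OTUs recovered (count > 0) in every sample of both tables qualify;
    OTUs with tied (constant) values in either branch are excluded with a
    warning.  Returns the per-OTU table and a summary with the fraction of
    coefficients below ``r_threshold`` and the fraction with BH-adjusted
    q >= alpha.
    """
    rel_df = rel.data if hasattr(rel, "data") else pd.DataFrame(rel)
    quant_df = quant.data if hasattr(quant, "data") else pd.DataFrame(quant)
    if rel_df.shape[0] < 5:
        raise ValueError("need >= 5 samples for per-OTU concordance")
    common_samples = [s for s in rel_df.index if s in quant_df.index]
    rel_df = rel_df.loc[common_samples]
    quant_df = quant_df.loc[common_samples]
    shared = [o for o in rel_df.columns if o in quant_df.columns]
    ubiquitous = [
        o
        for o in shared
        if (rel_df[o] > 0).all() and (quant_df[o] > 0).all()
    ]
    rows, skipped = [], []
    for o in ubiquitous:
        x, y = rel_df[o].to_numpy(), quant_df[o].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            skipped.append(o)
            continue
        r, p = stats.spearmanr(x, y)
        rows.append((o, float(r), float(p)))
    if skipped:
        warnings.warn(f"constant OTUs excluded from concordance: {skipped}", stacklevel=2)
    if not rows:
        raise ValueError("no OTUs qualify for concordance analysis")
    df = pd.DataFrame(rows, columns=["otu_id", "spearman_r", "p_value"]).set_index(
        "otu_id"
    )
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    summary = {
        "n_otus": len(df),
        "fraction_r_below_threshold": float((df["spearman_r"] < r_threshold).mean()),
        "fraction_not_significant": float((df["q_value"] >= alpha).mean()),
    }
    return df, summary


def aggregate_taxonomy(
    table, taxonomy: TaxonomyTable, rank: str, top_n: int | None = None
) -> pd.DataFrame:
    """Sum columns by lineage label at ``rank`` (phylum/class/order).

    OTUs without a label at that rank are pooled into ``"Others"``.  With
    ``top_n``, only the ``top_n`` groups by overall abundance are kept and
    the remainder pooled into ``"Others"``.
    """
    if rank not in {"phylum", "class", "order"}:
        raise ValueError(f"unsupported rank {rank!r}")
    df = table.data if hasattr(table, "data") else pd.DataFrame(table)
    labels = {o: taxonomy.rank_label(o, rank) for o in df.columns}
    agg = df.T.groupby(df.columns.map(labels)).sum().T
    if top_n is not None and agg.shape[1] > top_n:
        totals = agg.sum(axis=0).sort_values(ascending=False)
        top = [g for g in totals.index[:top_n] if g != "Others"]
        others = agg.drop(columns=top).sum(axis=1)
        agg = agg[top]
        agg["Others"] = others
    return agg
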