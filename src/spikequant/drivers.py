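"""Environmental and spatial driver attribution.

Mantel tests between community and predictor distance matrices,
RDA-based variation partitioning with the Ezekiel adjusted R^2, sparse
PLS subgroup-variable selection, plus the supporting correlation matrix
and geographic/environmental distances.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .comparison import DistanceMatrix
from .io import ENV_VARS, SampleMetadata

EARTH_RADIUS_KM = 6371.0


@dataclass
class MantelResult:
    r: float
    p: float
    method: str
    n_permutations: int
    seed: int | None
    exact: bool = False


@dataclass
class VPAResult:
    """Adjusted-R^2 variation fractions: pure env (a), shared (b),
    pure space (c), unexplained (d)."""

    frac_pure_env: float
    frac_shared: float
    frac_pure_space: float
    frac_unexplained: float
    raw_pure_env: float
    raw_shared: float
    raw_pure_space: float
    raw_unexplained: float
    p_pure_env: float | None = None
    p_pure_space: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SPLSResult:
    x_loadings: pd.DataFrame  # columns comp1..compK
    y_loadings: pd.DataFrame
    selected_subgroups: list  # list of lists, one per component
    heatmap_r: pd.DataFrame  # subgroups x variables Spearman r
    heatmap_flags: pd.DataFrame  # |r| > 0.5


def variable_correlation_matrix(
    variables: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman r with BH-adjusted p and a masked view.

    Returns (r, q, masked_r) where masked_r hides cells with q >= alpha
    (diagonal kept).  Constant variables are excluded with a warning.
    """
    if variables.shape[0] < 5:
        raise ValueError("need >= 5 samples")
    constant = [c for c in variables.columns if variables[c].nunique() == 1]
    if constant:
        warnings.warn(f"constant variables excluded: {constant}", stacklevel=2)
        variables = variables.drop(columns=constant)
    if variables.shape[1] < 2:
        raise ValueError("need >= 2 non-constant variables")
    cols = list(variables.columns)
    from .network import _spearman_matrix

    rho, pval = _spearman_matrix(variables.to_numpy())
    iu = np.triu_indices(len(cols), k=1)
    q = np.ones_like(pval)
    q[iu] = multipletests(pval[iu], method="fdr_bh")[1]
    q[(iu[1], iu[0])] = q[iu]
    np.fill_diagonal(q, 0.0)
    r_df = pd.DataFrame(rho, index=cols, columns=cols)
    q_df = pd.DataFrame(q, index=cols, columns=cols)
    masked = r_df.where(q_df < alpha)
    return r_df, q_df, masked


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km (antimeridian-safe)."""
    lam1, phi1, lam2, phi2 = map(math.radians, (lon1, lat1, lon2, lat2))
    h = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_distance(metadata: SampleMetadata) -> DistanceMatrix:
    df = metadata.data
    ids = list(df.index)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(
                df.iloc[i]["longitude"],
                df.iloc[i]["latitude"],
                df.iloc[j]["longitude"],
                df.iloc[j]["latitude"],
            )
    return DistanceMatrix(sample_ids=ids, d=d)


def environmental_distance(
    metadata: SampleMetadata | pd.DataFrame, variables=ENV_VARS
) -> DistanceMatrix:
    """Euclidean distance on z-scored variables (sample sd, ddof=1)."""
    df = metadata.data if isinstance(metadata, SampleMetadata) else metadata
    sub = df[list(variables)].astype(float)
    sd = sub.std(ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"zero-variance variables excluded: {dropped}", stacklevel=2)
        sub = sub.drop(columns=dropped)
    if sub.shape[1] == 0:
        raise ValueError("no variables with variance remain")
    z = (sub - sub.mean()) / sub.std(ddof=1)
    arr = z.to_numpy()
    diff = arr[:, None, :] - arr[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(sample_ids=list(df.index), d=d)


def variable_distance(metadata: SampleMetadata | pd.DataFrame, variable: str) -> DistanceMatrix:
    """Per-variable Euclidean distance on the z-scored variable."""
    return environmental_distance(metadata, variables=[variable])


def _unfold(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown mantel method {method!r}")


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation with permutation p (one-sided, positive).

    Rows/columns of the second matrix are permuted jointly.  For n <= 5
    all n! permutations are enumerated exactly; otherwise ``n_perm``
    random permutations with the add-one convention.
    """
    if list(d1.sample_ids) != list(d2.sample_ids):
        raise ValueError("distance matrices must share sample order")
    n = d1.d.shape[0]
    if n < 4:
        raise ValueError("mantel needs >= 4 samples")
    x = _unfold(d1.d)
    if method == "spearman":
        x = stats.rankdata(x)
    r_obs_raw = _corr(_unfold(d1.d), _unfold(d2.d), method)

    def perm_r(perm):
        y = _unfold(d2.d[np.ix_(perm, perm)])
        if method == "spearman":
            y = stats.rankdata(y)
        return float(np.corrcoef(x, y)[0, 1])

    if n <= 5:
        rs = [perm_r(list(p)) for p in itertools.permutations(range(n))]
        p_val = sum(1 for r in rs if r >= r_obs_raw - 1e-12) / len(rs)
        return MantelResult(
            r=r_obs_raw, p=p_val, method=method, n_permutations=len(rs),
            seed=None, exact=True,
        )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if perm_r(rng.permutation(n)) >= r_obs_raw - 1e-12:
            hits += 1
    p_val = (1 + hits) / (n_perm + 1)
    return MantelResult(
        r=r_obs_raw, p=p_val, method=method, n_permutations=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# variation partitioning (RDA)


def hellinger(abund: np.ndarray) -> np.ndarray:
    totals = abund.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("all-zero samples cannot be Hellinger-transformed")
    return np.sqrt(abund / totals)


def _design(x: np.ndarray) -> np.ndarray:
    """Column-center a predictor block, dropping collinear columns."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = x - x.mean(axis=0)
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        warnings.warn("collinear predictors rank-reduced", stacklevel=3)
    return x[:, keep]


def _rda_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    """R^2 of the multivariate regression of centered y on centered x."""
    yc = y - y.mean(axis=0)
    tss = (yc**2).sum()
    if tss == 0:
        raise ValueError("community matrix has zero variance")
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    fitted = x @ beta
    return float((fitted**2).sum() / tss), x.shape[1]


def _adj_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel adjustment."""
    if n - p - 1 <= 0:
        raise ValueError("too few samples for the requested predictor count")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def vpa(
    community,
    env_vars: pd.DataFrame,
    spatial_vars: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    transform: str = "hellinger",
    adjusted: bool = True,
) -> VPAResult:
    """Partition community variation into pure env / shared / pure space /
    unexplained fractions via (partial) RDA.

    Raw fractions sum to 1 exactly; adjusted fractions use the Ezekiel
    correction per block and may be slightly negative.  Permutation
    p-values test the two pure fractions via partial-model pseudo-F with
    reduced-model residual permutation.
    """
    df = community.data if hasattr(community, "data") else pd.DataFrame(community)
    y = df.to_numpy(dtype=float)
    if transform == "hellinger":
        y = hellinger(y)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    y = y - y.mean(axis=0)
    xe = _design(env_vars.to_numpy())
    xs = _design(spatial_vars.to_numpy())
    n = y.shape[0]
    p_e, p_s = xe.shape[1], xs.shape[1]
    if n <= p_e + p_s + 1:
        raise ValueError("need n_samples > rank(env) + rank(space) + 1")
    r2_e, _ = _rda_r2(y, xe)
    r2_s, _ = _rda_r2(y, xs)
    r2_es, _ = _rda_r2(y, np.hstack([xe, xs]))
    raw = dict(
        raw_pure_env=r2_es - r2_s,
        raw_shared=r2_e + r2_s - r2_es,
        raw_pure_space=r2_es - r2_e,
        raw_unexplained=1.0 - r2_es,
    )
    if adjusted:
        a_e = _adj_r2(r2_e, n, p_e)
        a_s = _adj_r2(r2_s, n, p_s)
        a_es = _adj_r2(r2_es, n, p_e + p_s)
    else:
        a_e, a_s, a_es = r2_e, r2_s, r2_es
    fracs = dict(
        frac_pure_env=a_es - a_s,
        frac_shared=a_e + a_s - a_es,
        frac_pure_space=a_es - a_e,
        frac_unexplained=1.0 - a_es,
    )
    rng = np.random.default_rng(seed)
    p_env = _partial_rda_perm_test(y, xe, xs, n_perm, rng)
    p_space = _partial_rda_perm_test(y, xs, xe, n_perm, rng)
    return VPAResult(**fracs, **raw, p_pure_env=p_env, p_pure_space=p_space)


def _partial_rda_perm_test(
    y: np.ndarray, x_test: np.ndarray, x_cond: np.ndarray, n_perm: int, rng
) -> float:
    """Pseudo-F test of x_test given x_cond, permuting reduced-model residuals."""
    n = y.shape[0]
    p_t, p_c = x_test.shape[1], x_cond.shape[1]

    def pseudo_f(yy):
        r2_c, _ = _rda_r2(yy, x_cond)
        r2_f, _ = _rda_r2(yy, np.hstack([x_test, x_cond]))
        df_res = n - p_t - p_c - 1
        return ((r2_f - r2_c) / p_t) / ((1.0 - r2_f) / df_res)

    f_obs = pseudo_f(y)
    beta, *_ = np.linalg.lstsq(x_cond, y, rcond=None)
    fitted = x_cond @ beta
    resid = y - fitted
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if pseudo_f(fitted + resid[perm]) >= f_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


# ---------------------------------------------------------------------------
# sparse PLS


def _scale_block(df: pd.DataFrame, name: str) -> np.ndarray:
    sd = df.std(ddof=1)
    zero = list(sd.index[sd == 0])
    if zero:
        raise ValueError(f"zero-variance column(s) in {name}: {zero}")
    return ((df - df.mean()) / sd).to_numpy()


def _soft_threshold_keep(u: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so exactly ``keep`` entries stay nonzero; renormalize."""
    if keep >= len(u):
        return u / np.linalg.norm(u)
    mags = np.sort(np.abs(u))[::-1]
    delta = mags[keep]  # (keep+1)-th largest magnitude
    thresholded = np.sign(u) * np.maximum(np.abs(u) - delta, 0.0)
    norm = np.linalg.norm(thresholded)
    if norm == 0:
        raise ValueError("soft threshold removed all loadings")
    return thresholded / norm


def spls_select(
    x: pd.DataFrame,
    y: pd.DataFrame,
    ncomp: int = 2,
    keepx: int = 5,
    flag_threshold: float = 0.5,
) -> SPLSResult:
    """Sparse PLS (regression mode) selecting ``keepx`` X columns per component.

    Each component takes the dominant singular-vector pair of the X-Y
    cross-covariance, soft-thresholds the X loading to exactly ``keepx``
    nonzeros, then deflates both blocks by regression on the X score.
    Loadings are unit-norm with the largest-magnitude entry positive.
    The accompanying heatmap reports the Spearman correlation of every X
    column with every Y column, flagged where |r| > ``flag_threshold``.
    """
    if keepx < 1 or keepx > x.shape[1]:
        raise ValueError("keepx must be in [1, n_x_columns]")
    if ncomp < 1 or ncomp > min(x.shape[0] - 1, x.shape[1], y.shape[1]):
        raise ValueError("ncomp exceeds the data dimensions")
    xs = _scale_block(x, "X")
    ys = _scale_block(y, "Y")
    x_load = np.zeros((x.shape[1], ncomp))
    y_load = np.zeros((y.shape[1], ncomp))
    selected = []
    xd, yd = xs.copy(), ys.copy()
    for k in range(ncomp):
        m = xd.T @ yd
        u_full, _, vt = np.linalg.svd(m, full_matrices=False)
        u = _soft_threshold_keep(u_full[:, 0], keepx)
        v = m.T @ u
        vn = np.linalg.norm(v)
        if vn == 0:
            raise ValueError("degenerate cross-covariance (no remaining signal)")
        v = v / vn
        # fix signs: largest-|.| entry of the X loading positive
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        xi = xd @ u
        x_load[:, k], y_load[:, k] = u, v
        selected.append([c for c, w in zip(x.columns, u) if w != 0])
        denom = float(xi @ xi)
        if denom > 0:
            xd = xd - np.outer(xi, (xi @ xd) / denom)
            yd = yd - np.outer(xi, (xi @ yd) / denom)
    comps = [f"comp{k + 1}" for k in range(ncomp)]
    heat = np.zeros((x.shape[1], y.shape[1]))
    for i, cx in enumerate(x.columns):
        for j, cy in enumerate(y.columns):
            heat[i, j] = stats.spearmanr(x[cx], y[cy]).statistic
    heat_df = pd.DataFrame(heat, index=x.columns, columns=y.columns)
    return SPLSResult(
        x_loadings=pd.DataFrame(x_load, index=x.columns, columns=comps),
        y_loadings=pd.DataFrame(y_load, index=y.columns, columns=comps),
        selected_subgroups=selected,
        heatmap_r=heat_df,
        heatmap_flags=heat_df.abs() > flag_threshold,
    )
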