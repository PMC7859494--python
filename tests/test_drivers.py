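import itertools
import math

import numpy as np
import pandas as pd
import pytest

import spikequant.drivers as dr
from spikequant.comparison import DistanceMatrix

from conftest import make_metadata


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def unfold(d):
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def random_dm(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(list(range(n)), squareform(pdist(pts)))


class TestVariableCorrelationMatrix:
    def _frame(self, n=20, seed=0, k=4):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, k)), columns=[f"v{i}" for i in range(k)]
        )

    def test_diagonal_is_one(self):
        r, q, masked = dr.variable_correlation_matrix(self._frame())
        assert np.allclose(np.diag(r), 1.0)

    def test_perfect_negative(self):
        df = self._frame()
        df["neg"] = -df["v0"]
        r, q, _ = dr.variable_correlation_matrix(df)
        assert r.loc["v0", "neg"] == pytest.approx(-1.0)
        assert q.loc["v0", "neg"] < 0.05

    def test_null_variables_mostly_masked(self):
        masked_frac = []
        for seed in range(20):
            df = self._frame(seed=seed, k=5)
            _, _, masked = dr.variable_correlation_matrix(df)
            off = ~np.eye(5, dtype=bool)
            masked_frac.append(masked.isna().to_numpy()[off].mean())
        assert np.mean(masked_frac) >= 0.9

    def test_constant_excluded(self):
        df = self._frame()
        df["const"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            r, _, _ = dr.variable_correlation_matrix(df)
        assert "const" not in r.columns


class TestGeographicDistance:
    def test_identical_points(self):
        meta = make_metadata(["S1", "S2"])
        df = meta.data.copy()
        df["longitude"] = [10.0, 10.0]
        df["latitude"] = [5.0, 5.0]
        dm = dr.geographic_distance(type(meta)(df))
        assert dm.d[0, 1] == pytest.approx(0.0)

    def test_antipodal_on_equator(self):
        assert dr.haversine_km(0, 0, 180, 0) == pytest.approx(
            math.pi * 6371.0, rel=1e-9
        )

    def test_antimeridian_wraparound(self):
        # 1 degree apart across the dateline, not 359 degrees
        d = dr.haversine_km(179.5, 0, -179.5, 0)
        assert d == pytest.approx(2 * math.pi * 6371.0 / 360.0, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        lons = rng.uniform(-180, 180, 3)
        lats = rng.uniform(-90, 90, 3)
        d01 = dr.haversine_km(lons[0], lats[0], lons[1], lats[1])
        d12 = dr.haversine_km(lons[1], lats[1], lons[2], lats[2])
        d02 = dr.haversine_km(lons[0], lats[0], lons[2], lats[2])
        assert d02 <= d01 + d12 + 1e-9


class TestEnvironmentalDistance:
    def test_identical_samples(self):
        meta = make_metadata(["S1", "S2", "S3"])
        df = meta.data.copy()
        for v in ["temperature", "salinity"]:
            df[v] = [1.0, 1.0, 2.0]
        dm = dr.environmental_distance(
            type(meta)(df), variables=["temperature", "salinity"]
        )
        assert dm.d[0, 1] == pytest.approx(0.0)

    def test_single_variable_hand_oracle(self):
        # values 0 and 1, sd(ddof=1) = 1/sqrt(2) -> z = +-1/sqrt(2) -> dist sqrt(2)
        df = pd.DataFrame({"x": [0.0, 1.0]}, index=["a", "b"])
        dm = dr.environmental_distance(df, variables=["x"])
        assert dm.d[0, 1] == pytest.approx(math.sqrt(2.0), abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(6, 2)), columns=["x", "y"])
        d1 = dr.environmental_distance(df, variables=["x", "y"]).d
        df2 = df.copy()
        df2["y"] *= 1000.0
        d2 = dr.environmental_distance(df2, variables=["x", "y"]).d
        assert np.allclose(d1, d2, atol=1e-10)

    def test_zero_variance_excluded(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "c": 5.0})
        with pytest.warns(UserWarning, match="zero-variance"):
            dm = dr.environmental_distance(df, variables=["x", "c"])
        assert dm.d[0, 2] > 0


class TestMantel:
    def test_monotone_transform_r_one(self):
        d1 = random_dm(8, 0)
        d2 = DistanceMatrix(d1.sample_ids, 2.0 * d1.d)
        for method in ("spearman", "pearson"):
            res = dr.mantel(d1, d2, method=method, n_perm=99, seed=0)
            assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_matches_brute_force(self):
        """n=4: p equals the fraction over all 24 permutations computed by an
        independent enumeration."""
        d1, d2 = random_dm(4, 1), random_dm(4, 2)
        res = dr.mantel(d1, d2, method="pearson")
        assert res.exact and res.n_permutations == 24
        r_obs = pearson_oracle(unfold(d1.d), unfold(d2.d))
        hits = 0
        for perm in itertools.permutations(range(4)):
            perm = list(perm)
            r_p = pearson_oracle(unfold(d1.d), unfold(d2.d[np.ix_(perm, perm)]))
            if r_p >= r_obs - 1e-12:
                hits += 1
        assert res.p == pytest.approx(hits / 24)

    def test_pearson_matches_textbook_formula(self):
        d1, d2 = random_dm(7, 3), random_dm(7, 4)
        res = dr.mantel(d1, d2, method="pearson", n_perm=9, seed=0)
        assert res.r == pytest.approx(
            pearson_oracle(unfold(d1.d), unfold(d2.d)), abs=1e-12
        )

    def test_null_calibration(self):
        rejections = 0
        for seed in range(100):
            d1 = random_dm(15, seed * 2 + 1000)
            d2 = random_dm(15, seed * 2 + 2001)
            res = dr.mantel(d1, d2, n_perm=99, seed=seed)
            if res.p <= 0.05:
                rejections += 1
        assert rejections <= 12

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            dr.mantel(random_dm(5, 0), random_dm(6, 1))


class TestVPA:
    def _oracle_r2(self, y, x):
        """Explicit normal-equations R^2 for centered y on centered x."""
        y = y - y.mean(axis=0)
        x = x - x.mean(axis=0)
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        fitted = x @ beta
        return (fitted**2).sum() / (y**2).sum()

    def test_raw_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        comm = pd.DataFrame(rng.uniform(1, 10, size=(15, 5)))
        env = pd.DataFrame(rng.normal(size=(15, 2)), columns=["e1", "e2"])
        space = pd.DataFrame(rng.normal(size=(15, 2)), columns=["x", "y"])
        res = dr.vpa(comm, env, space, n_perm=49, seed=0)
        total = (
            res.raw_pure_env + res.raw_shared + res.raw_pure_space + res.raw_unexplained
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_adjustment_disabled_reproduces_raw(self):
        rng = np.random.default_rng(1)
        comm = pd.DataFrame(rng.uniform(1, 10, size=(15, 5)))
        env = pd.DataFrame(rng.normal(size=(15, 2)), columns=["e1", "e2"])
        space = pd.DataFrame(rng.normal(size=(15, 2)), columns=["x", "y"])
        res = dr.vpa(comm, env, space, n_perm=49, seed=0, adjusted=False)
        assert res.frac_pure_env == pytest.approx(res.raw_pure_env, abs=1e-12)
        assert res.frac_unexplained == pytest.approx(res.raw_unexplained, abs=1e-12)

    def test_toy_against_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        comm = pd.DataFrame(rng.uniform(1, 5, size=(10, 3)))
        env = pd.DataFrame({"e": rng.normal(size=10)})
        space = pd.DataFrame({"s": rng.normal(size=10)})
        res = dr.vpa(comm, env, space, n_perm=49, seed=0, transform="hellinger")
        y = dr.hellinger(comm.to_numpy())
        r2_e = self._oracle_r2(y, env.to_numpy())
        r2_s = self._oracle_r2(y, space.to_numpy())
        r2_es = self._oracle_r2(y, np.hstack([env.to_numpy(), space.to_numpy()]))
        assert res.raw_pure_env == pytest.approx(r2_es - r2_s, abs=1e-10)
        assert res.raw_shared == pytest.approx(r2_e + r2_s - r2_es, abs=1e-10)
        assert res.raw_unexplained == pytest.approx(1 - r2_es, abs=1e-10)

    def test_env_constructed_community(self):
        """Community built from env alone: pure-space fraction ~ 0 and
        pure-env fraction significant."""
        ok_c, ok_p = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 20
            env = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])
            space = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x", "y"])
            b = rng.normal(size=(2, 6))
            comm = pd.DataFrame(
                env.to_numpy() @ b + rng.normal(0, 0.05, size=(n, 6))
            )
            res = dr.vpa(comm, env, space, n_perm=199, seed=seed, transform="raw")
            if abs(res.frac_pure_space) < 0.05:
                ok_c += 1
            if res.p_pure_env <= 0.05:
                ok_p += 1
        assert ok_c >= 9
        assert ok_p >= 9

    def test_too_few_samples(self):
        rng = np.random.default_rng(3)
        comm = pd.DataFrame(rng.uniform(1, 2, size=(5, 3)))
        env = pd.DataFrame(rng.normal(size=(5, 2)))
        space = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="n_samples"):
            dr.vpa(comm, env, space, n_perm=9, seed=0)


class TestSPLS:
    def _blocks(self, n=20, p=8, q=3, seed=0):
        rng = np.random.default_rng(seed)
        x = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"g{i}" for i in range(p)])
        return rng, x

    def test_noiseless_copy_selected(self):
        rng, x = self._blocks()
        y = pd.DataFrame({"y0": x["g3"], "y1": rng.normal(size=20)})
        res = dr.spls_select(x, y, ncomp=1, keepx=1)
        assert res.selected_subgroups[0] == ["g3"]

    def test_loadings_unit_norm_and_sign_fixed(self):
        rng, x = self._blocks(seed=1)
        y = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        res = dr.spls_select(x, y, ncomp=2, keepx=4)
        for comp in res.x_loadings.columns:
            u = res.x_loadings[comp].to_numpy()
            assert np.linalg.norm(u) == pytest.approx(1.0)
            assert u[np.argmax(np.abs(u))] > 0
            assert (u != 0).sum() == 4

    def test_keepx_all_reproduces_svd_pair(self):
        """No-sparsity limit: leading singular-vector pair of X^T Y."""
        rng, x = self._blocks(seed=2)
        y = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        res = dr.spls_select(x, y, ncomp=1, keepx=x.shape[1])
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        u_ref, _, vt_ref = np.linalg.svd(xs.to_numpy().T @ ys.to_numpy())
        u_ref = u_ref[:, 0]
        if u_ref[np.argmax(np.abs(u_ref))] < 0:
            u_ref = -u_ref
        assert np.allclose(res.x_loadings["comp1"], u_ref, atol=1e-10)

    def test_heatmap_flags(self):
        rng, x = self._blocks(seed=3)
        y = pd.DataFrame({"y0": x["g0"] + rng.normal(0, 0.1, 20)})
        res = dr.spls_select(x, y, ncomp=1, keepx=2)
        assert bool(res.heatmap_flags.loc["g0", "y0"])
        assert abs(res.heatmap_r.loc["g0", "y0"]) > 0.5

    def test_zero_variance_column_named(self):
        rng, x = self._blocks(seed=4)
        x["g2"] = 1.0
        y = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="g2"):
            dr.spls_select(x, y, ncomp=1, keepx=2)

    def test_ncomp_too_large(self):
        rng, x = self._blocks(seed=5)
        y = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="ncomp"):
            dr.spls_select(x, y, ncomp=5, keepx=2)

    def test_recovery_of_associated_subgroups(self):
        """2 associated subgroups among 20 recovered at keepx=2."""
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(
                rng.normal(size=(20, 20)), columns=[f"g{i}" for i in range(20)]
            )
            y = pd.DataFrame(
                {
                    "y0": x["g3"] + rng.normal(0, 0.3, 20),
                    "y1": x["g7"] + rng.normal(0, 0.3, 20),
                }
            )
            res = dr.spls_select(x, y, ncomp=2, keepx=2)
            selected = set().union(*res.selected_subgroups)
            if {"g3", "g7"} <= selected:
                hits += 1
        assert hits >= 0.8 * n_runs
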