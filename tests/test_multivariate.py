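import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes

from rumicol.community import CountTable, DistanceMatrix
from rumicol.config import FactorEffect, SimulationConfig
from rumicol.multivariate import (DesignMatrix, cca, env_significance,
                                  gower_center, pcoa, permanova,
                                  stratum_effect)
from rumicol.simulate import simulate_counts


def euclid_dm(y: np.ndarray, ids=None) -> DistanceMatrix:
    y = np.atleast_2d(y.T).T if y.ndim == 1 else y
    if y.ndim == 1:
        y = y[:, None]
    d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0)
    ids = ids or [f"s{i}" for i in range(len(y))]
    return DistanceMatrix(ids, (d + d.T) / 2, metric="euclidean")


def one_factor(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return DesignMatrix(pd.DataFrame({"g": labels}, index=ids), terms=["g"])


class TestPermanovaOracle:
    def test_closed_form_anova_example(self):
        d = euclid_dm(np.array([1.0, 2, 3, 4, 5, 6])[:, None])
        res = permanova(d, one_factor(list("aaabbb")), n_perm=99, seed=0)
        assert res.table.loc["g", "pseudo_F"] == pytest.approx(13.5, abs=1e-10)
        assert res.table.loc["g", "df"] == 1

    def test_equals_classical_f_on_random_data(self, rng):
        # 100 random univariate datasets, 2-4 groups
        for _ in range(100):
            k = int(rng.integers(2, 5))
            sizes = rng.integers(3, 6, size=k)
            y = rng.standard_normal(int(sizes.sum()))
            labels = np.repeat([f"g{i}" for i in range(k)], sizes)
            d = euclid_dm(y[:, None])
            res = permanova(d, one_factor(list(labels)), n_perm=99, seed=1)
            groups = [y[labels == f"g{i}"] for i in range(k)]
            f_oracle = stats.f_oneway(*groups).statistic
            assert res.table.loc["g", "pseudo_F"] == \
                pytest.approx(f_oracle, abs=1e-8)

    def test_ss_additivity(self, rng):
        y = rng.standard_normal((16, 4))
        ids = [f"s{i}" for i in range(16)]
        meta = pd.DataFrame({
            "a": list("xxyy") * 4,
            "b": ["p"] * 8 + ["q"] * 8,
        }, index=ids)
        d = euclid_dm(y, ids)
        design = DesignMatrix(meta, terms=["a", "b", "a:b"])
        res = permanova(d, design, n_perm=99, seed=0)
        tbl = res.table
        terms_ss = tbl.drop(["Residual", "Total"])["SS"].sum()
        assert terms_ss + tbl.loc["Residual", "SS"] == \
            pytest.approx(tbl.loc["Total", "SS"], abs=1e-9)

    def test_degenerate_all_identical(self):
        d = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)))
        res = permanova(d, one_factor(list("xxyy"), ["a", "b", "c", "d"]),
                        n_perm=99, seed=0)
        assert res.degenerate

    def test_aliased_design_rejected(self):
        ids = [f"s{i}" for i in range(6)]
        meta = pd.DataFrame({"a": list("xxxyyy"), "b": list("xxxyyy")},
                            index=ids)
        d = euclid_dm(np.arange(6.0)[:, None], ids)
        with pytest.raises(ValueError, match="aliased"):
            permanova(d, DesignMatrix(meta, terms=["a", "b"]), n_perm=99, seed=0)

    def test_misaligned_samples_rejected(self):
        d = euclid_dm(np.arange(4.0)[:, None], ["a", "b", "c", "d"])
        design = one_factor(list("xxyy"), ["d", "c", "b", "a"])
        with pytest.raises(ValueError, match="aligned"):
            permanova(d, design, n_perm=99, seed=0)


class TestPermanovaPermutation:
    def test_enumeration_matches_sampled_p(self, rng):
        for rep in range(5):
            y = rng.standard_normal(6)
            d = euclid_dm(y[:, None])
            design = one_factor(list("aaabbb"))
            p_en = permanova(d, design, enumerate_all=True) \
                .table.loc["g", "p_perm"]
            p_mc = permanova(d, design, n_perm=999, seed=rep) \
                .table.loc["g", "p_perm"]
            tol = 4 * np.sqrt(p_en * (1 - p_en) / 1000) + 2e-3
            assert abs(p_en - p_mc) < tol

    def test_type_one_error_calibrated(self, rng):
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.standard_normal((12, 3))
            d = euclid_dm(y)
            res = permanova(d, one_factor(list("aaaaaabbbbbb")),
                            n_perm=99, seed=int(rng.integers(2**31)))
            rej += res.table.loc["g", "p_perm"] <= 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_p_value_floor(self, rng):
        # strong separation: p bottoms out at 1/(n_perm+1)
        y = np.concatenate([rng.normal(0, 0.01, 6),
                            rng.normal(50, 0.01, 6)])
        d = euclid_dm(y[:, None])
        res = permanova(d, one_factor(list("aaaaaabbbbbb")), n_perm=99, seed=0)
        assert res.table.loc["g", "p_perm"] == pytest.approx(1 / 100)

    def test_restricted_permutation_runs(self, rng):
        ids = [f"s{i}" for i in range(16)]
        meta = pd.DataFrame({"g": list("ab") * 8,
                             "donor": np.repeat(list("wxyz"), 4)}, index=ids)
        d = euclid_dm(rng.standard_normal((16, 3)), ids)
        res = permanova(d, DesignMatrix(meta, terms=["g"]), n_perm=99, seed=0,
                        permute_within=meta["donor"])
        assert 0 < res.table.loc["g", "p_perm"] <= 1


class TestStratumEffect:
    def test_whole_dataset_equals_one_factor(self, rng):
        ids = [f"s{i}" for i in range(12)]
        meta = pd.DataFrame({"g": list("ab") * 6}, index=ids)
        d = euclid_dm(rng.standard_normal((12, 2)), ids)
        full = permanova(d, DesignMatrix(meta, terms=["g"]), n_perm=199, seed=3)
        strat = stratum_effect(d, meta, "g", None, n_perm=199, seed=3)
        assert strat.table.loc["g", "pseudo_F"] == \
            pytest.approx(full.table.loc["g", "pseudo_F"])
        assert strat.table.loc["g", "p_perm"] == full.table.loc["g", "p_perm"]

    def test_power_null_split_by_time(self):
        # forage effect planted only at 2 h: detected there, absent at 48 h
        cfg = SimulationConfig(
            n_taxa=30, n_replicates=4, time_points_h=(2.0, 48.0),
            fractions=("SAB",), depth_range=(3000, 4000), noise_sd=0.4,
            effect_sizes=tuple(
                FactorEffect("forage", "HAY", (k,), 2.5, times=(2.0,))
                for k in range(6)),
            seed=17)
        table, meta, _ = simulate_counts(cfg)
        from rumicol.community import bray_curtis
        d = bray_curtis(table, normalize=True)
        p2 = stratum_effect(d, meta, "forage", {"time_h": 2.0},
                            n_perm=999, seed=1).table.loc["forage", "p_perm"]
        p48 = stratum_effect(d, meta, "forage", {"time_h": 48.0},
                             n_perm=999, seed=1).table.loc["forage", "p_perm"]
        assert p2 < 0.05
        assert p48 > 0.05

    def test_single_level_stratum_rejected(self, rng):
        ids = [f"s{i}" for i in range(8)]
        meta = pd.DataFrame({"g": list("aaaabbbb"), "t": [1] * 4 + [2] * 4},
                            index=ids)
        d = euclid_dm(rng.standard_normal((8, 2)), ids)
        with pytest.raises(ValueError, match="levels"):
            stratum_effect(d, meta, "g", {"t": 1})


class TestCca:
    def test_site_basis_recovers_ca_inertia(self, rng):
        # environment spanning the site space: constrained == CA total
        cnt = rng.integers(1, 50, size=(6, 9))
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(6)],
            columns=[f"t{j}" for j in range(9)]))
        env = pd.DataFrame(np.eye(6)[:, :5], index=tab.samples,
                           columns=list("ABCDE"))
        res = cca(tab, env)
        assert res.constrained_inertia == pytest.approx(res.total_inertia,
                                                        rel=1e-9)

    def test_constrained_never_exceeds_total(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            cnt = r.integers(1, 40, size=(8, 10))
            tab = CountTable(pd.DataFrame(
                cnt, index=[f"s{i}" for i in range(8)],
                columns=[f"t{j}" for j in range(10)]))
            env = pd.DataFrame(r.standard_normal((8, 2)),
                               index=tab.samples, columns=["x", "y"])
            res = cca(tab, env)
            assert res.constrained_inertia <= res.total_inertia + 1e-9
            assert np.all(np.diff(res.eigenvalues) <= 1e-10)

    def test_duplicate_env_column_rejected(self, rng):
        cnt = rng.integers(1, 40, size=(6, 8))
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(6)],
            columns=[f"t{j}" for j in range(8)]))
        x = rng.standard_normal(6)
        env = pd.DataFrame({"x": x, "y": x}, index=tab.samples)
        with pytest.raises(ValueError, match="collinear"):
            cca(tab, env)

    def test_constant_env_rejected(self, rng):
        cnt = rng.integers(1, 40, size=(6, 8))
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(6)],
            columns=[f"t{j}" for j in range(8)]))
        env = pd.DataFrame({"x": np.ones(6)}, index=tab.samples)
        with pytest.raises(ValueError, match="constant"):
            cca(tab, env)

    def test_too_many_env_columns_rejected(self, rng):
        cnt = rng.integers(1, 40, size=(4, 8))
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(4)],
            columns=[f"t{j}" for j in range(8)]))
        env = pd.DataFrame(rng.standard_normal((4, 4)), index=tab.samples,
                           columns=list("wxyz"))
        with pytest.raises(ValueError, match="environmental columns"):
            cca(tab, env)

    def test_site_scores_are_weighted_averages(self, rng):
        cnt = rng.integers(1, 50, size=(7, 9))
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(7)],
            columns=[f"t{j}" for j in range(9)]))
        env = pd.DataFrame(rng.standard_normal((7, 2)), index=tab.samples,
                           columns=["x", "y"])
        res = cca(tab, env)
        profiles = cnt / cnt.sum(axis=1, keepdims=True)
        expected = profiles @ res.taxon_scores.values
        assert np.allclose(res.site_scores.values, expected, atol=1e-10)


class TestEnvSignificance:
    def test_gradient_variable_significant(self, rng):
        base = rng.integers(1, 30, size=(16, 10)).astype(float)
        grad = np.linspace(-1, 1, 16)
        cnt = (base * np.exp(np.outer(grad, np.linspace(-1, 1, 10) * 2))).astype(int) + 1
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(16)],
            columns=[f"t{j}" for j in range(10)]))
        env = pd.DataFrame({"grad": grad, "noise": rng.standard_normal(16)},
                           index=tab.samples)
        p = env_significance(tab, env, n_perm=999, seed=0)
        assert p["grad"] <= 0.01
        assert p["noise"] > 0.05

    def test_p_floor_at_99_perms(self, rng):
        base = rng.integers(1, 30, size=(12, 8)).astype(float)
        grad = np.linspace(-1, 1, 12)
        cnt = (base * np.exp(np.outer(grad, np.linspace(-1, 1, 8) * 3))).astype(int) + 1
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(12)],
            columns=[f"t{j}" for j in range(8)]))
        env = pd.DataFrame({"grad": grad}, index=tab.samples)
        p = env_significance(tab, env, n_perm=99, seed=0)
        assert p["grad"] >= 1 / 100

    def test_nperm_minimum_enforced(self, rng):
        cnt = rng.integers(1, 30, size=(6, 5))
        tab = CountTable(pd.DataFrame(
            cnt, index=[f"s{i}" for i in range(6)],
            columns=[f"t{j}" for j in range(5)]))
        env = pd.DataFrame({"x": rng.standard_normal(6)}, index=tab.samples)
        with pytest.raises(ValueError, match="n_perm"):
            env_significance(tab, env, n_perm=10)


class TestPcoa:
    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.standard_normal((10, 2))
        d = euclid_dm(pts)
        coords, eigvals = pcoa(d)
        _, _, disparity = procrustes(pts, coords.values[:, :2])
        assert disparity < 1e-8

    def test_equidistant_simplex(self):
        n = 5
        m = np.ones((n, n)) - np.eye(n)
        d = DistanceMatrix([f"s{i}" for i in range(n)], m)
        coords, eigvals = pcoa(d)
        pos = eigvals[eigvals > 1e-10]
        assert len(pos) == n - 1
        assert np.allclose(pos, pos[0], atol=1e-10)

    def test_duplicate_samples_coincide(self):
        pts = np.array([[0.0, 0], [0, 0], [3, 4], [6, 8]])
        d = euclid_dm(pts)
        coords, _ = pcoa(d)
        assert np.allclose(coords.values[0], coords.values[1], atol=1e-10)

    def test_negative_eigenvalues_reported(self, make_table):
        from rumicol.community import bray_curtis
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 40, size=(8, 6)))
        _, eigvals = pcoa(bray_curtis(t))
        # Bray-Curtis is non-Euclidean in general: negatives kept, not clipped
        assert len(eigvals) == 8

    def test_small_n_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError):
            pcoa(d)


def test_gower_center_trace_is_total_ss():
    y = np.array([1.0, 2, 3, 4])[:, None]
    d = euclid_dm(y)
    G = gower_center(d)
    assert np.trace(G) == pytest.approx(((y - y.mean()) ** 2).sum())
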