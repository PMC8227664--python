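import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from phytocommune import diversity as dv


class TestShannonEffective:
    def test_uniform_equals_richness(self):
        assert dv.shannon_effective([1, 1, 1, 1]) == pytest.approx(4.0, abs=1e-12)

    def test_single_peak(self):
        assert dv.shannon_effective([5, 0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_hand_oracle(self):
        # H = -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397207...
        expected = math.exp(-(0.5 * math.log(0.5) + 0.5 * math.log(0.25)))
        assert dv.shannon_effective([0.5, 0.25, 0.25]) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(2.8284271247461903, abs=1e-12)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            dv.shannon_effective([0, 0, 0])

    @given(st.lists(st.floats(min_value=0.01, max_value=100), min_size=1,
                    max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_hill_bounds(self, abund):
        eff = dv.shannon_effective(abund)
        assert 1 - 1e-9 <= eff <= len(abund) + 1e-9

    @given(st.lists(st.floats(min_value=0.01, max_value=100), min_size=2,
                    max_size=15), st.randoms())
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, abund, rnd):
        shuffled = abund.copy()
        rnd.shuffle(shuffled)
        assert dv.shannon_effective(abund) == pytest.approx(
            dv.shannon_effective(shuffled), rel=1e-12)


class TestDiversityByLevel:
    def _data(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, meta = {}, []
        for s in range(2):
            for b in range(3):
                for p in range(3):
                    for i in range(2):
                        sid = f"s{s}b{b}p{p}i{i}"
                        conc = 5.0 + (shift * b if s == 0 else 0)
                        rows[sid] = rng.dirichlet(np.full(30, conc)) * 1000
                        meta.append({"sample_id": sid, "site": f"site{s}",
                                     "subsite": f"site{s}_sub{b}",
                                     "plot": f"site{s}_sub{b}_p{p}",
                                     "individual": f"site{s}_sub{b}_p{p}_i{i}",
                                     "month": 1})
        table = pd.DataFrame(rows).T
        return table, pd.DataFrame(meta).set_index("sample_id")

    def test_identical_samples_zero_F(self):
        table, meta = self._data(seed=1)
        table.iloc[:, :] = np.tile(table.iloc[0].to_numpy(), (len(table), 1))
        d = dv.diversity_by_level(table, meta, "subsite")
        assert d.anova_F == pytest.approx(0.0, abs=1e-9)

    def test_planted_subsite_shift_detected(self):
        detections = 0
        for seed in range(10):
            table, meta = self._data(shift=40.0, seed=seed)
            d = dv.diversity_by_level(table, meta, "subsite")
            detections += d.anova_p < 0.01
        assert detections >= 9

    def test_aggregation_mean_matches_hand(self):
        table, meta = self._data(seed=2)
        d = dv.diversity_by_level(table, meta, "plot")
        per = d.per_sample
        plot0 = meta.index[meta["plot"] == "site0_sub0_p0"]
        assert d.groups.loc["site0_sub0_p0", "mean"] == pytest.approx(
            per[plot0].mean(), rel=1e-12)

    def test_single_group_skipped(self):
        table, meta = self._data(seed=3)
        sub = meta.index[meta["site"] == "site0"]
        d = dv.diversity_by_level(table.loc[sub], meta.loc[sub], "site")
        assert d.skipped is not None and d.anova_F is None

    def test_effective_bounds(self):
        table, meta = self._data(seed=4)
        d = dv.diversity_by_level(table, meta, "site")
        assert ((d.per_sample >= 1) & (d.per_sample <= table.shape[1])).all()


class TestDistances:
    def test_manhattan_identical_rows(self):
        t = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        d = dv.manhattan_distances(t)
        assert d.values[0, 1] == 0.0

    def test_manhattan_hand_sum(self):
        t = pd.DataFrame([[0.0, 0.0], [1.0, 2.0]], index=["a", "b"])
        assert dv.manhattan_distances(t).values[0, 1] == pytest.approx(3.0)

    def test_manhattan_triangle_inequality(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.uniform(0, 10, size=(50, 8)))
        D = dv.manhattan_distances(t).values
        for i, j, k in itertools.permutations(range(12), 3):
            assert D[i, k] <= D[i, j] + D[j, k] + 1e-9

    def test_missing_values_rejected(self):
        t = pd.DataFrame([[1.0, np.nan]])
        with pytest.raises(ValueError):
            dv.manhattan_distances(t)

    def test_jaccard_identical(self):
        t = pd.DataFrame([[3, 1, 0], [5, 2, 0]], index=["a", "b"])
        assert dv.jaccard_distances(t).values[0, 1] == 0.0

    def test_jaccard_disjoint(self):
        t = pd.DataFrame([[3, 0], [0, 2]], index=["a", "b"])
        assert dv.jaccard_distances(t).values[0, 1] == 1.0

    def test_jaccard_hand_count(self):
        # {a,b} vs {b,c}: 1 - 1/3
        t = pd.DataFrame([[1, 1, 0], [0, 1, 1]], index=["x", "y"])
        assert dv.jaccard_distances(t).values[0, 1] == pytest.approx(2 / 3)

    def test_jaccard_empty_pair_flagged(self):
        t = pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=["a", "b", "c"])
        d = dv.jaccard_distances(t)
        assert d.values[0, 1] == 0.0
        assert set(d.flagged_empty) == {"a", "b"}

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.uniform(0, 5, size=(10, 6)),
                         index=[f"s{i}" for i in range(10)])
        d1 = dv.manhattan_distances(t)
        perm = rng.permutation(10)
        d2 = dv.manhattan_distances(t.iloc[perm])
        f1, f2 = d1.to_frame(), d2.to_frame()
        assert np.allclose(f1.loc[f2.index, f2.columns].to_numpy(),
                           f2.to_numpy())


def _euclidean_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    D = squareform(pdist(np.asarray(points, dtype=float)))
    return dv.DistanceMatrix(ids=ids, values=D, metric="euclidean")


class TestDispersion:
    def test_identical_members_zero(self):
        d = _euclidean_dm([[1, 1], [1, 1], [5, 5], [5, 5]])
        res = dv.dispersion(d, ["g1", "g1", "g2", "g2"])
        assert np.allclose(res.distances.to_numpy(), 0.0, atol=1e-8)

    def test_two_point_toy_centroid(self):
        # oracle: centroid (1,0); both distances exactly 1
        d = _euclidean_dm([[0, 0], [2, 0]])
        res = dv.dispersion(d, ["g", "g"])
        assert np.allclose(res.distances.to_numpy(), [1.0, 1.0], atol=1e-8)

    def test_pcoa_equals_direct_euclidean(self):
        # equivalence oracle over 20 random datasets
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.normal(size=(12, 4))
            groups = ["a"] * 6 + ["b"] * 6
            res = dv.dispersion(_euclidean_dm(X), groups)
            direct = np.empty(12)
            for g, sl in (("a", slice(0, 6)), ("b", slice(6, 12))):
                cen = X[sl].mean(axis=0)
                direct[sl] = np.linalg.norm(X[sl] - cen, axis=1)
            assert np.allclose(res.distances.to_numpy(), direct, atol=1e-8)

    def test_singleton_group_zero_flagged(self):
        d = _euclidean_dm([[0, 0], [1, 0], [9, 9]])
        res = dv.dispersion(d, ["a", "a", "b"])
        assert "b" in res.flagged_singletons
        assert res.distances.iloc[2] == 0.0

    def test_df_accounting(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        res = dv.dispersion(_euclidean_dm(X), ["a"] * 5 + ["b"] * 5)
        assert res.df == (1, 8)

    def test_median_center_runs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 3))
        res = dv.dispersion(_euclidean_dm(X), ["a"] * 5 + ["b"] * 5,
                            center="median")
        assert (res.distances >= 0).all()


class TestPermanova:
    def test_identical_groups_F_zero_p_one(self):
        pts = [[0, 0], [1, 0], [0, 1]] * 2
        d = _euclidean_dm(pts)
        res = dv.permanova(d, ["a", "a", "a", "b", "b", "b"])
        assert res.complete_enumeration
        assert res.pseudo_F == pytest.approx(0.0, abs=1e-9)
        assert res.p == 1.0

    def test_separated_groups_minimum_p(self):
        # oracle: brute-force count of relabelings with F >= observed
        pts = [[0, 0], [0.1, 0], [0, 0.1], [50, 50], [50.1, 50], [50, 50.1]]
        labels = ["a", "a", "a", "b", "b", "b"]
        d = _euclidean_dm(pts)
        res = dv.permanova(d, labels)
        assert res.complete_enumeration
        n_distinct = math.comb(6, 3)
        # only the true split and its mirror reach the observed F
        assert res.p == pytest.approx(2 / 20)
        assert res.n_permutations == n_distinct

    def test_exact_p_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        d = _euclidean_dm(pts)
        res = dv.permanova(d, labels)

        # independent brute force over all distinct relabelings
        D2 = d.values ** 2
        def pseudo_f(lbl):
            n, g = 6, 2
            sst = D2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for grp in ("a", "b"):
                idx = np.where(lbl == grp)[0]
                sub = D2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            return ((sst - ssw) / (g - 1)) / (ssw / (n - g))

        obs = pseudo_f(labels)
        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            lbl = np.array(["b"] * 6)
            lbl[list(combo)] = "a"
            total += 1
            if pseudo_f(lbl) >= obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total)

    def test_single_group_error(self):
        d = _euclidean_dm([[0, 0], [1, 1]])
        with pytest.raises(ValueError):
            dv.permanova(d, ["a", "a"])

    def test_r2_in_unit_interval(self):
        rng = np.random.default_rng(6)
        d = _euclidean_dm(rng.normal(size=(8, 3)))
        res = dv.permanova(d, ["a"] * 4 + ["b"] * 4)
        assert 0 <= res.R2 <= 1

    def test_sampled_p_reproducible(self):
        rng = np.random.default_rng(8)
        d = _euclidean_dm(rng.normal(size=(30, 3)))
        labels = ["a"] * 15 + ["b"] * 15
        r1 = dv.permanova(d, labels, n_perm=199, seed=42, enumeration_limit=10)
        r2 = dv.permanova(d, labels, n_perm=199, seed=42, enumeration_limit=10)
        assert r1.p == r2.p and not r1.complete_enumeration


class TestGateAndModels:
    def test_gate(self):
        assert dv.dispersion_gate(0.50, 0.05)
        assert not dv.dispersion_gate(0.01, 0.05)
        assert dv.dispersion_gate(0.05, 0.05)  # boundary proceeds

    def test_exact_line(self):
        x = np.arange(10, dtype=float)
        res, _ = dv.fit_gradient_model(2 * x, pd.DataFrame({"x": x}))
        assert res["coefficients"]["x"] == pytest.approx(2.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_null_slope_within_2se(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        res, _ = dv.fit_gradient_model(y, pd.DataFrame({"x": x}))
        import statsmodels.api as sm
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(res["coefficients"]["x"]) < 2 * fit.bse[1]

    def test_normal_equation_oracle(self):
        # closed form (X'X)^-1 X'y on a 5-point toy
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 2.5, 3.8, 4.1, 5.3])
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res, _ = dv.fit_gradient_model(y, pd.DataFrame({"x": x}))
        assert res["coefficients"]["const"] == pytest.approx(beta[0], rel=1e-9)
        assert res["coefficients"]["x"] == pytest.approx(beta[1], rel=1e-9)

    def test_collinear_error(self):
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            dv.fit_gradient_model(x, pd.DataFrame({"a": x, "b": 2 * x}))

    def test_parasitoid_success(self):
        out = pd.DataFrame({
            "plot": ["p1"] * 15 + ["p2"] * 10 + ["p3"] * 2,
            "outcome": (["parasitoid"] * 3 + ["adult"] * 7 + ["died"] * 5
                        + ["parasitoid"] * 0 + ["adult"] * 10 + ["died"] * 2),
        })
        frac = dv.parasitoid_success(out)
        assert frac["p1"] == pytest.approx(0.30)
        assert frac["p2"] == pytest.approx(0.0)
        assert np.isnan(frac["p3"])  # all died

    def test_unknown_outcome_rejected(self):
        out = pd.DataFrame({"plot": ["p1"], "outcome": ["escaped"]})
        with pytest.raises(ValueError):
            dv.parasitoid_success(out)
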