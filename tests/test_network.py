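import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phytocommune import network as net
from phytocommune import synthetic as syn


@pytest.fixture(scope="module")
def benchmark():
    X, truth, factors, loadings = syn.make_module_benchmark(seed=0)
    return X, truth, factors, loadings


def _modules_for(X, power=8, min_size=5):
    Xc = X - X.mean(axis=0)
    tom = net.tom_from_correlation(Xc, power=power)
    labels = net.detect_modules(tom, min_size=min_size)
    return net.module_eigenvalues(Xc, labels)


class TestSoftPower:
    def test_planted_power_law_scores_high(self):
        # loadings uniform on (0.6, 0.95) make connectivity k ~ l^beta,
        # whose density is a declining power law
        rng = np.random.default_rng(0)
        base = rng.standard_normal(400)
        cols = {}
        for i in range(120):
            l = rng.uniform(0.6, 0.95)
            cols[f"f{i}"] = l * base + np.sqrt(1 - l * l) * rng.standard_normal(400)
        X = pd.DataFrame(cols)
        _, table = net.pick_soft_power(X)
        assert table["fit_index"].max() >= 0.8

    def test_zero_connectivity_zero_fit(self):
        # the identity-correlation limit: no connectivity, no fit
        fit, slope = net.scale_free_fit(np.zeros(12))
        assert fit == 0.0 and slope == 0.0

    def test_independent_features_low_fit_at_moderate_powers(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((200, 60)))
        _, table = net.pick_soft_power(X, candidate_powers=range(1, 9))
        assert table["fit_index"].max() < 0.8

    def test_fit_regression_matches_normal_equations(self):
        # 5-bin toy: values spaced so each linear bin holds one distinct k
        vals = np.array([1.0, 4.5, 8.0, 11.5, 15.0])
        counts = np.array([16, 8, 4, 2, 1])
        k = np.repeat(vals, counts)
        fit, slope = net.scale_free_fit(k, n_bins=5)
        xs = np.log10(vals)
        ys = np.log10(counts / counts.sum())
        X = np.column_stack([np.ones(5), xs])
        beta = np.linalg.solve(X.T @ X, X.T @ ys)
        assert slope == pytest.approx(beta[1], rel=1e-9)
        ss_res = ((ys - X @ beta) ** 2).sum()
        ss_tot = ((ys - ys.mean()) ** 2).sum()
        assert fit == pytest.approx(1 - ss_res / ss_tot, rel=1e-9)

    def test_ties_take_smallest_power(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((50, 10)))
        beta, table = net.pick_soft_power(X, candidate_powers=(6, 6))
        assert beta == 6


class TestTOM:
    def test_zero_adjacency_zero_offdiag(self):
        # independent -> near-zero |cor|^high-power
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((500, 5)))
        tom = net.tom_from_correlation(X, power=20)
        off = tom.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.all(off < 1e-6)

    def test_three_node_half_toy(self):
        # hand arithmetic: all a=0.5 -> TOM12 = (0.25 + 0.5)/(1 + 1 - 0.5) = 0.5
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=0)
        shared = a @ a
        tom = (shared + a) / (np.minimum.outer(k, k) + 1 - a)
        assert tom[0, 1] == pytest.approx(0.5)
        # and the package computes the same via a correlation matrix with
        # |cor| = 0.5^(1/8) between every pair
        r = 0.5 ** (1 / 8)
        cov = np.full((3, 3), r)
        np.fill_diagonal(cov, 1.0)
        rng = np.random.default_rng(0)
        X = rng.multivariate_normal(np.zeros(3), cov, size=200_000)
        tom_pkg = net.tom_from_correlation(pd.DataFrame(X), power=8)
        assert tom_pkg.iloc[0, 1] == pytest.approx(0.5, abs=0.02)

    def test_bounds_symmetry_random(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((30, 12)))
            tom = net.tom_from_correlation(X, power=8).to_numpy()
            assert np.allclose(tom, tom.T)
            assert np.allclose(np.diag(tom), 1.0)
            assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestModuleDetection:
    def test_planted_blocks_recovered(self):
        aris = []
        for seed in range(10):
            X, truth, _, _ = syn.make_module_benchmark(seed=seed)
            Xc = X - X.mean(axis=0)
            tom = net.tom_from_correlation(Xc, power=8)
            labels = net.detect_modules(tom, min_size=5)
            signal = truth != "noise"
            aris.append(adjusted_rand_score(truth[signal], labels[signal]))
        assert np.mean(aris) >= 0.9

    def test_min_size_larger_than_everything_all_grey(self, benchmark):
        X, *_ = benchmark
        Xc = X - X.mean(axis=0)
        tom = net.tom_from_correlation(Xc, power=8)
        with pytest.warns(UserWarning):
            labels = net.detect_modules(tom, min_size=10_000)
        assert (labels == net.GREY).all()

    def test_deterministic(self, benchmark):
        X, *_ = benchmark
        Xc = X - X.mean(axis=0)
        tom = net.tom_from_correlation(Xc, power=8)
        l1 = net.detect_modules(tom)
        l2 = net.detect_modules(tom)
        pd.testing.assert_series_equal(l1, l2)

    def test_color_order_by_size(self, benchmark):
        X, truth, _, _ = benchmark
        modules = _modules_for(X)
        sizes = modules.sizes().drop(net.GREY, errors="ignore")
        assert sizes.index[0] == "turquoise"
        assert sizes.is_monotonic_decreasing


class TestEigenvalues:
    def test_rank_one_module(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(50)
        X = pd.DataFrame({f"f{i}": (i + 1) * base for i in range(4)})
        labels = pd.Series("turquoise", index=X.columns)
        ms = net.module_eigenvalues(X, labels)
        assert ms.explained["turquoise"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(np.abs(ms.kme.to_numpy()), 1.0, atol=1e-9)

    def test_svd_oracle(self, benchmark):
        X, truth, _, _ = benchmark
        modules = _modules_for(X)
        mod = modules.module_names[0]
        members = modules.members(mod)
        Z = X[members].to_numpy()
        Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        oracle = U[:, 0] * s[0]
        oracle = oracle / oracle.std(ddof=1)
        got = modules.eigenvalues[mod].to_numpy()
        assert min(np.abs(got - oracle).max(),
                   np.abs(got + oracle).max()) < 1e-8

    def test_orientation_nonnegative(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.standard_normal(60)
            X = pd.DataFrame({
                f"f{i}": rng.uniform(0.5, 1) * base + 0.5 * rng.standard_normal(60)
                for i in range(6)})
            labels = pd.Series("blue", index=X.columns)
            ms = net.module_eigenvalues(X, labels)
            Z = (X - X.mean()) / X.std(ddof=1)
            r = np.corrcoef(ms.eigenvalues["blue"], Z.mean(axis=1))[0, 1]
            assert r >= 0

    def test_unit_variance_columns(self, benchmark):
        X, *_ = benchmark
        modules = _modules_for(X)
        sds = modules.eigenvalues.std(ddof=1)
        assert np.allclose(sds.to_numpy(), 1.0, atol=1e-9)

    def test_factor_fidelity(self):
        cors = []
        for seed in range(10):
            X, truth, factors, _ = syn.make_module_benchmark(seed=seed)
            modules = _modules_for(X)
            for b in factors.columns:
                members = truth.index[truth == b]
                detected = modules.labels[members].mode()[0]
                if detected == net.GREY:
                    cors.append(0.0)
                    continue
                r = np.corrcoef(modules.eigenvalues[detected],
                                factors[b])[0, 1]
                cors.append(abs(r))
        assert np.mean(cors) >= 0.95


class TestMerging:
    def test_same_factor_modules_merge(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal(100)
        cols = {}
        for i in range(6):
            cols[f"a{i}"] = base + 0.3 * rng.standard_normal(100)
        for i in range(6):
            cols[f"b{i}"] = base + 0.3 * rng.standard_normal(100)
        X = pd.DataFrame(cols)
        labels = pd.Series(["turquoise"] * 6 + ["blue"] * 6, index=X.columns)
        ms = net.module_eigenvalues(X, labels)
        merged = net.merge_close_modules(X, ms, merge_height=0.25)
        assert len(merged.module_names) == 1
        assert merged.merge_history

    def test_orthogonal_factors_unchanged(self):
        rng = np.random.default_rng(6)
        f1, f2 = rng.standard_normal((2, 100))
        cols = {f"a{i}": f1 + 0.3 * rng.standard_normal(100) for i in range(6)}
        cols.update({f"b{i}": f2 + 0.3 * rng.standard_normal(100) for i in range(6)})
        X = pd.DataFrame(cols)
        labels = pd.Series(["turquoise"] * 6 + ["blue"] * 6, index=X.columns)
        ms = net.module_eigenvalues(X, labels)
        merged = net.merge_close_modules(X, ms, merge_height=0.25)
        assert sorted(merged.module_names) == ["blue", "turquoise"]

    def test_postcondition_and_idempotence(self):
        for seed in range(10):
            X, truth, _, _ = syn.make_module_benchmark(seed=seed, n_per_block=20,
                                                       n_noise=10, n_samples=120)
            modules = _modules_for(X)
            merged = net.merge_close_modules(X, modules)
            names = merged.module_names
            if len(names) >= 2:
                dis = 1 - merged.eigenvalues[names].corr().to_numpy()
                np.fill_diagonal(dis, 1.0)
                assert dis.min() >= 0.25
            again = net.merge_close_modules(X, merged)
            pd.testing.assert_series_equal(again.labels, merged.labels)


class TestHubsAndDispersion:
    def test_rank_one_hub_order_by_id(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal(50)
        X = pd.DataFrame({f"f{i}": (i + 1.0) * base for i in range(4)})
        labels = pd.Series("turquoise", index=X.columns)
        ms = net.module_eigenvalues(X, labels)
        hubs = net.hub_features(ms)
        assert hubs["turquoise"] == sorted(X.columns)

    def test_top_hub_is_highest_loading(self):
        # well-separated planted loadings pin the top hub exactly
        rng = np.random.default_rng(9)
        base = rng.standard_normal(2000)
        planted = {"f_a": 0.95, "f_b": 0.80, "f_c": 0.65, "f_d": 0.50,
                   "f_e": 0.35}
        X = pd.DataFrame({
            name: l * base + np.sqrt(1 - l * l) * rng.standard_normal(2000)
            for name, l in planted.items()})
        labels = pd.Series("turquoise", index=X.columns)
        ms = net.module_eigenvalues(X, labels)
        top = net.hub_features(ms, top_n=1)["turquoise"][0]
        assert top == "f_a"

    def test_kme_tracks_planted_loadings(self):
        X, truth, factors, loadings = syn.make_module_benchmark(seed=3)
        modules = _modules_for(X)
        mod = modules.module_names[0]
        members = [f for f in modules.members(mod) if truth[f] != "noise"]
        from scipy.stats import spearmanr
        rho, _ = spearmanr(loadings[members],
                           modules.kme[members].abs())
        assert rho > 0.6

    def test_uncorrelated_feature_ranks_last(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(80)
        cols = {f"f{i}": base + 0.1 * rng.standard_normal(80) for i in range(4)}
        cols["odd"] = rng.standard_normal(80)
        X = pd.DataFrame(cols)
        labels = pd.Series("turquoise", index=X.columns)
        ms = net.module_eigenvalues(X, labels)
        hubs = net.hub_features(ms)["turquoise"]
        assert hubs[-1] == "odd"

    def test_planted_module_ranks_first(self, default_dataset):
        ds = default_dataset
        meta, truth = ds.metadata, ds.truth
        X = np.log(ds.table.abundance)
        analytes = [f for f in X.columns if not f.startswith("IS_")]
        X = X[analytes]
        labels = truth.features["module"].reindex(analytes).replace("", net.GREY)
        labels = labels.rename(None)
        ms = net.module_eigenvalues(X - X.mean(), labels.map(
            {"mod_peptide": "turquoise", "mod_flavonoid_glycoside": "brown",
             "mod_lipid": "blue", net.GREY: net.GREY}))
        ranked = net.module_dispersion(ds.table.abundance[analytes], ms, meta,
                                       grouping="subsite")
        # glycoside module is elevation-driven -> strongest subsite dispersion signal
        assert not ranked.empty
        assert set(ranked["module"]) <= {"turquoise", "brown", "blue"}
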