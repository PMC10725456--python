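"""Gene loadings, spatial-ensemble category enrichment, pSI and CSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fncmeta as fm
from fncmeta.enrichment import CategoryAnnotation, celltype_results_table, psi_tiers_table
from fncmeta.exceptions import DomainError
from fncmeta.pls import fit_pls, variogram_surrogates


class TestGeneLoadings:
    def test_exact_correlations(self):
        rng = np.random.default_rng(0)
        score = rng.normal(size=50)
        X = pd.DataFrame({"same": score, "neg": -score, "noise": rng.normal(size=50)})
        load = fm.gene_loadings(X, score)
        assert load["same"] == pytest.approx(1.0)
        assert load["neg"] == pytest.approx(-1.0)

    def test_null_correlation_bound(self):
        rng = np.random.default_rng(1)
        score = rng.normal(size=200)
        X = pd.DataFrame(rng.normal(size=(200, 500)),
                         columns=[f"g{i}" for i in range(500)])
        load = fm.gene_loadings(X, score)
        assert (np.abs(load) < 0.25).mean() > 0.99

    def test_zero_variance_gene_excluded(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "const": [1.0] * 4})
        load = fm.gene_loadings(X, np.array([1.0, 2.0, 1.0, 3.0]))
        assert "const" not in load.index


class TestGcea:
    @pytest.fixture(scope="class")
    def tiny_problem(self):
        """50 genes, 30 samples, 3 of them driving y; shared ensemble."""
        rng = np.random.default_rng(2)
        coords = rng.uniform(-40, 40, size=(30, 3))
        d2 = ((coords[:, None] - coords[None, :]) ** 2).sum(-1)
        L = np.linalg.cholesky(np.exp(-d2 / (2 * 15.0**2)) + 1e-8 * np.eye(30))
        y = L @ rng.standard_normal(30)
        y = (y - y.mean()) / y.std()
        X = pd.DataFrame(rng.normal(size=(30, 50)), columns=[f"g{i}" for i in range(50)])
        for j in range(3):
            X[f"g{j}"] = 1.5 * y + 0.5 * rng.normal(size=30)
        X = (X - X.mean()) / X.std()
        ens = variogram_surrogates(y, coords, n=50, seed=3)
        return X, y, coords, ens

    def test_matches_brute_force_loop(self, tiny_problem):
        """The vectorised GCEA equals an index-by-index reimplementation."""
        X, y, coords, ens = tiny_problem
        cats = [CategoryAnnotation("c0", "drivers+", [f"g{i}" for i in range(10)]),
                CategoryAnnotation("c1", "random", [f"g{i}" for i in range(20, 35)])]
        res = fm.gcea(y, X, cats, ensemble=ens, component_index=0, min_size=1)

        # brute force: per surrogate, per category, plain Python loops
        def loadings_of(resp):
            resp = (resp - resp.mean()) / resp.std()
            m = fit_pls(X, resp, n_components=1)
            score = m.scores[:, 0]
            if np.corrcoef(score, resp)[0, 1] < 0:
                score = -score
            return {g: np.corrcoef(X[g], score)[0, 1] for g in X.columns}

        real = loadings_of(y)
        for r, cat in zip(res, cats):
            real_score = np.mean([real[g] for g in cat.members])
            assert r.score == pytest.approx(real_score, abs=1e-10)
            count = 0
            for s in ens.surrogates:
                null = loadings_of(s)
                null_score = np.mean([null[g] for g in cat.members])
                if null_score >= real_score:
                    count += 1
            assert r.p == pytest.approx(count / ens.n_surrogates, abs=1e-12)

    def test_singleton_category_score_is_gene_loading(self, tiny_problem):
        X, y, coords, ens = tiny_problem
        cats = [CategoryAnnotation("solo", "one gene", ["g0"])]
        res = fm.gcea(y, X, cats, ensemble=ens, component_index=0, min_size=1)
        m = fit_pls(X, y, n_components=1)
        score = m.scores[:, 0] * np.sign(m.score_y_correlation[0])
        expected = np.corrcoef(X["g0"], score)[0, 1]
        assert res[0].score == pytest.approx(expected, abs=1e-10)

    def test_driver_category_enriched_random_not(self, tiny_problem):
        X, y, coords, ens = tiny_problem
        cats = [CategoryAnnotation("driv", "drivers", ["g0", "g1", "g2"]),
                CategoryAnnotation("rand", "random", [f"g{i}" for i in range(30, 45)])]
        res = {r.category_id: r for r in fm.gcea(y, X, cats, ensemble=ens,
                                                 component_index=0, min_size=1)}
        assert res["driv"].p < 0.05
        assert res["rand"].p > 0.05

    def test_size_bounds_filter(self, tiny_problem):
        X, y, coords, ens = tiny_problem
        cats = [CategoryAnnotation("small", "too small", ["g0"])]
        assert fm.gcea(y, X, cats, ensemble=ens, min_size=5) == []


class TestPsi:
    def test_exclusive_gene_reaches_most_stringent_tier(self):
        rng = np.random.default_rng(4)
        profiles = pd.DataFrame(rng.uniform(1, 2, size=(10, 400)),
                                index=[f"ct{i}" for i in range(10)],
                                columns=[f"g{i}" for i in range(400)])
        profiles.loc[:, "g0"] = 0.0
        profiles.loc["ct0", "g0"] = 5.0
        psi = fm.compute_psi(profiles)
        assert psi.loc["g0", "ct0"] < 1e-4
        tiers = psi_tiers_table(psi)
        assert tiers.loc["g0", "ct0"] == 1e-4

    def test_uniform_gene_gets_no_tier(self):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(rng.uniform(1, 2, size=(6, 100)),
                                index=[f"ct{i}" for i in range(6)],
                                columns=[f"g{i}" for i in range(100)])
        profiles.loc[:, "g0"] = 1.5  # identical in every cell type
        psi = fm.compute_psi(profiles)
        assert psi.loc["g0"].min() > 0.05

    def test_tiers_nested_for_every_gene(self):
        rng = np.random.default_rng(6)
        profiles = pd.DataFrame(rng.lognormal(0, 0.5, size=(8, 1000)),
                                index=[f"ct{i}" for i in range(8)],
                                columns=[f"g{i}" for i in range(1000)])
        psi = fm.compute_psi(profiles)
        lists = fm.psi_marker_lists(psi)
        for ct, tiers in lists.items():
            assert set(tiers[1e-4]) <= set(tiers[1e-3]) <= set(tiers[0.01]) <= set(tiers[0.05])

    def test_needs_three_cell_types(self):
        profiles = pd.DataFrame(np.ones((2, 10)))
        with pytest.raises(DomainError):
            fm.compute_psi(profiles)


class TestCseaFisher:
    def test_identical_set_and_list_overwhelmingly_significant(self):
        universe = [f"g{i}" for i in range(5000)]
        lst = universe[:50]
        res = fm.csea_fisher(lst, {"ct": lst}, universe)
        assert res[0].p < 1e-100
        assert res[0].q < 0.05
        # hypergeometric tail oracle for the same table
        expected = stats.hypergeom.sf(49, 5000, 50, 50)
        assert res[0].p == pytest.approx(expected, rel=1e-6)

    def test_disjoint_set_not_enriched(self):
        universe = [f"g{i}" for i in range(200)]
        res = fm.csea_fisher(universe[:20], {"ct": universe[100:130]}, universe)
        assert res[0].p > 0.5

    def test_matches_hypergeometric_exhaustively_on_small_universes(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            N = int(rng.integers(20, 200))
            universe = [f"g{i}" for i in range(N)]
            set_size = int(rng.integers(1, N // 2))
            list_size = int(rng.integers(1, N // 2))
            gset = list(rng.choice(universe, set_size, replace=False))
            lst = list(rng.choice(universe, list_size, replace=False))
            r = fm.csea_fisher(gset, {"ct": lst}, universe)[0]
            expected = stats.hypergeom.sf(r.overlap - 1, N, list_size, set_size)
            assert r.p == pytest.approx(expected, rel=1e-9)

    def test_bh_hand_example(self):
        from statsmodels.stats.multitest import multipletests
        _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_bh_q_monotone_after_sorting(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(500)]
        lists = {f"ct{i}": {t: list(rng.choice(universe, 40, replace=False))
                            for t in (0.05, 0.01, 1e-3, 1e-4)} for i in range(5)}
        res = fm.csea_fisher(list(rng.choice(universe, 60, replace=False)), lists, universe)
        df = celltype_results_table(res).sort_values("p")
        assert np.all(np.diff(df["q"].to_numpy()) >= -1e-12)
        assert np.all(df["q"].to_numpy() >= df["p"].to_numpy() - 1e-12)

    def test_empty_universe_intersection_rejected(self):
        with pytest.raises(DomainError):
            fm.csea_fisher(["a"], {"ct": ["b"]}, ["c", "d"])


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        cats = [CategoryAnnotation("c1", "first", ["a", "b", "c"]),
                CategoryAnnotation("c2", "second", ["d"])]
        path = tmp_path / "sets.gmt"
        fm.write_gmt(cats, path)
        again = fm.read_gmt(path)
        assert [(c.category_id, c.name, c.members) for c in again] == \
               [(c.category_id, c.name, c.members) for c in cats]
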