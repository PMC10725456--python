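"""PLS1 fitting, variogram surrogates, component significance, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import fncmeta as fm
from fncmeta.exceptions import DomainError
from fncmeta.pls import empirical_variogram


def _problem(seed=0, n=80, g=40):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, g))
    return rng, X


class TestFitPls:
    def test_single_driving_gene_dominates(self):
        # chance correlations of the noise genes dilute the first component
        # by roughly G/n, so purity needs samples >> genes
        rng, X = _problem(1, n=1500, g=10)
        y = X[:, 7].copy()
        X = (X - X.mean(0)) / X.std(0)
        y = (y - y.mean()) / y.std()
        model = fm.fit_pls(X, y, n_components=3)
        assert model.explained_variance[0] > 0.99
        assert np.argmax(np.abs(model.weights[:, 0])) == 7

    def test_orthogonal_response_explains_nothing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        # orthogonalise y against the column space of X exactly
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
        model = fm.fit_pls(X, y, n_components=3)
        assert np.all(model.explained_variance < 1e-20)

    def test_row_permutation_invariance(self):
        rng, X = _problem(3)
        y = X @ rng.normal(size=X.shape[1])
        perm = rng.permutation(len(y))
        m1 = fm.fit_pls(X, y, n_components=4)
        m2 = fm.fit_pls(X[perm], y[perm], n_components=4)
        assert np.allclose(m1.weights, m2.weights, atol=1e-8)

    def test_matches_sklearn_first_weights(self):
        from sklearn.cross_decomposition import PLSRegression
        rng, X = _problem(4)
        y = X @ rng.normal(size=X.shape[1]) + rng.normal(size=X.shape[0])
        Xz = (X - X.mean(0)) / X.std(0)
        yz = (y - y.mean()) / y.std()
        ours = fm.fit_pls(Xz, yz, n_components=3)
        sk = PLSRegression(n_components=3, scale=False).fit(Xz, yz)
        for c in range(3):
            w_sk = sk.x_weights_[:, c]
            w = ours.weights[:, c]
            sign = np.sign(w @ w_sk)
            assert np.allclose(w, sign * w_sk, atol=1e-6)

    def test_explained_variance_partitions_y(self):
        rng, X = _problem(5, n=25, g=10)
        y = X @ rng.normal(size=10) + 0.1 * rng.normal(size=25)
        model = fm.fit_pls(X, y, n_components=9)
        assert model.explained_variance.sum() <= 1 + 1e-9
        assert np.all(model.explained_variance >= -1e-12)

    def test_misaligned_rows_rejected(self):
        with pytest.raises(DomainError):
            fm.fit_pls(np.zeros((10, 4)), np.zeros(9))

    def test_too_many_components_rejected(self):
        with pytest.raises(DomainError):
            fm.fit_pls(np.random.default_rng(0).normal(size=(5, 3)), np.ones(5), n_components=5)


def _sa_fixture(seed=7, n=120):
    """Spatially structured response on random 3-D sample coordinates."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-60, 60, size=(n, 3))
    d2 = ((coords[:, None] - coords[None, :]) ** 2).sum(-1)
    C = np.exp(-d2 / (2 * 20.0**2)) + 1e-8 * np.eye(n)
    y = np.linalg.cholesky(C) @ rng.standard_normal(n)
    return y, coords


class TestVariogramSurrogates:
    def test_deterministic_under_seed(self):
        y, coords = _sa_fixture()
        e1 = fm.variogram_surrogates(y, coords, n=20, seed=5)
        e2 = fm.variogram_surrogates(y, coords, n=20, seed=5)
        assert np.array_equal(e1.surrogates, e2.surrogates)

    def test_surrogates_beat_plain_permutations_on_sa_fixture(self):
        y, coords = _sa_fixture()
        ens = fm.variogram_surrogates(y, coords, n=100, seed=5)
        wins = (ens.variogram_sse < ens.permutation_sse).mean()
        assert wins >= 0.95

    def test_iid_response_leaves_little_to_match(self):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(120)
        coords = rng.uniform(-60, 60, size=(120, 3))
        ens = fm.variogram_surrogates(y, coords, n=100, seed=5)
        # flat variogram: matched surrogates cannot beat permutations as often
        sa_wins = (ens.variogram_sse < ens.permutation_sse).mean()
        assert sa_wins < 0.95
        # and the achieved improvement is marginal
        assert np.median(ens.permutation_sse / np.maximum(ens.variogram_sse, 1e-12)) < 10

    def test_refuses_tiny_sample(self):
        with pytest.raises(DomainError):
            fm.variogram_surrogates(np.ones(5), np.zeros((5, 3)), n=10, seed=0)

    def test_variogram_shape_on_sa_data(self):
        y, coords = _sa_fixture()
        from scipy.spatial.distance import pdist
        dist = pdist(coords)
        bins = np.linspace(0, 0.5 * dist.max(), 26)[1:]
        centers, gamma, *_ = empirical_variogram(y, dist, bins)
        # SA: semivariance rises with lag distance
        assert gamma[:3].mean() < gamma[-3:].mean()


class TestComponentSignificance:
    def test_strong_signal_selected_with_extreme_p(self, expression_problem):
        X, y = expression_problem["X"], expression_problem["y"]
        coords = expression_problem["coords"]
        model = fm.fit_pls(X, y, n_components=3)
        ens = fm.variogram_surrogates(y, coords, n=50, seed=4)
        p = fm.component_significance(model, ens, X)
        assert model.selected_component is not None
        assert p[model.selected_component] < 0.05
        assert model.score_y_correlation[model.selected_component] > 0

    def test_all_null_components_unselected(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 30))
        y, coords = rng.standard_normal(60), rng.uniform(-50, 50, (60, 3))
        model = fm.fit_pls(X, y, n_components=2)
        ens = fm.variogram_surrogates(y, coords, n=60, seed=4)
        p = fm.component_significance(model, ens, X)
        if model.selected_component is None:
            assert np.all(p >= 0.05)


class TestBootstrapGeneWeights:
    def test_sign_antisymmetry_under_column_negation(self, expression_problem):
        X, y = expression_problem["X"].copy(), expression_problem["y"]
        gw1 = fm.bootstrap_gene_weights(X, y, 0, B=200, seed=6)
        gene = expression_problem["drivers"][0]
        X2 = X.copy()
        X2[gene] = -X2[gene]
        gw2 = fm.bootstrap_gene_weights(X2, y, 0, B=200, seed=6)
        z1 = gw1.table.set_index("gene").loc[gene, "z"]
        z2 = gw2.table.set_index("gene").loc[gene, "z"]
        assert np.sign(z1) == -np.sign(z2)
        assert abs(abs(z1) - abs(z2)) / abs(z1) < 0.25  # equal up to bootstrap noise

    def test_driver_recovery_with_correct_signs(self, expression_problem):
        X, y = expression_problem["X"], expression_problem["y"]
        drivers = expression_problem["drivers"]
        gw = fm.bootstrap_gene_weights(X, y, 0, B=300, seed=6)
        recovered = np.mean([d in gw.pls_plus for d in drivers])
        assert recovered >= 0.9
        assert not set(drivers) & set(gw.pls_minus)

    def test_null_fixture_controls_family_wise_error(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(80, 150)),
                         columns=[f"g{i}" for i in range(150)])
        y = rng.standard_normal(80)
        gw = fm.bootstrap_gene_weights(X, y, 0, B=200, seed=11)
        assert gw.table.significant.sum() <= 3

    def test_bonferroni_cutoff_definition(self, expression_problem):
        X, y = expression_problem["X"], expression_problem["y"]
        gw = fm.bootstrap_gene_weights(X, y, 0, B=200, seed=6)
        t = gw.table
        G = len(t)
        assert t.loc[t.significant, "p"].max() < 0.05 / G
        assert not (set(gw.pls_plus) & set(gw.pls_minus))
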