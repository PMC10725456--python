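"""Heterogeneity, publication bias, jackknife, subgroups, meta-regression."""

import numpy as np
import pytest
from scipy import stats

import fncmeta as fm
from fncmeta.exceptions import DomainError, StageRefusal
from fncmeta.grid import make_ellipsoid_grid
from fncmeta.meta import threshold_clusters
from fncmeta.robustness import cluster_effects
from fncmeta.study_io import PeakRecord, StudyDataset, StudyTable


class TestCochranQ:
    def test_identical_effects(self):
        Q, df, p = fm.cochran_q([0.4, 0.4, 0.4], [0.1, 0.1, 0.1])
        assert Q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_calculation(self):
        Q, df, p = fm.cochran_q([0.2, 0.6], [0.04, 0.04])
        assert Q == pytest.approx(2.0)
        assert df == 1
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_against_naive_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 15))
            g = rng.normal(0, 1, k)
            v = rng.uniform(0.01, 0.5, k)
            Q, df, p = fm.cochran_q(g, v)
            w = [1.0 / vi for vi in v]
            gbar = sum(wi * gi for wi, gi in zip(w, g)) / sum(w)
            Q_naive = sum(wi * (gi - gbar) ** 2 for wi, gi in zip(w, g))
            assert Q == pytest.approx(Q_naive, rel=1e-10)

    def test_homogeneous_null_is_chi_square(self):
        """Under homogeneity Q ~ chi-square(k-1)."""
        rng = np.random.default_rng(12)
        k = 10
        v = rng.uniform(0.05, 0.2, k)
        qs = []
        for _ in range(2000):
            g = rng.normal(0.3, np.sqrt(v))
            qs.append(fm.cochran_q(g, v)[0])
        ks = stats.kstest(qs, stats.chi2(k - 1).cdf)
        assert ks.pvalue > 0.01

    def test_needs_two_studies(self):
        with pytest.raises(DomainError):
            fm.cochran_q([0.5], [0.1])


class TestEgger:
    def test_needs_three_studies(self):
        with pytest.raises(DomainError):
            fm.egger_test([0.1, 0.2], [0.1, 0.1])

    def test_scale_invariance_of_intercept(self):
        rng = np.random.default_rng(3)
        g = rng.normal(0.4, 0.2, 20)
        se = rng.uniform(0.1, 0.4, 20)
        i1, p1, _ = fm.egger_test(g, se)
        i2, p2, _ = fm.egger_test(3.7 * g, 3.7 * se)
        assert i2 == pytest.approx(i1, rel=1e-9)
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_matches_linregress_oracle(self):
        rng = np.random.default_rng(4)
        g = rng.normal(0.4, 0.3, 15)
        se = rng.uniform(0.1, 0.5, 15)
        intercept, p, _ = fm.egger_test(g, se)
        lr = stats.linregress(1.0 / se, g / se)
        assert intercept == pytest.approx(lr.intercept, rel=1e-9)
        # two-sided p of the intercept t-test with k-2 df
        t = lr.intercept / lr.intercept_stderr
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 13), rel=1e-6)

    def test_unbiased_null_calibration(self):
        """No bias injected: the intercept test rejects at ~nominal rate."""
        rng = np.random.default_rng(5)
        rejections = 0
        reps = 200
        for _ in range(reps):
            se = rng.uniform(0.08, 0.5, 40)
            g = rng.normal(0.4, se)  # symmetric noise, no small-study effect
            _, p, _ = fm.egger_test(g, se)
            rejections += p < 0.05
        assert rejections / reps < 0.12

    def test_detects_small_study_suppression(self):
        """Dropping unfavourable small studies shifts the intercept positive."""
        rng = np.random.default_rng(6)
        detected = 0
        reps = 200
        for _ in range(reps):
            se = rng.uniform(0.08, 0.5, 120)
            g = rng.normal(0.2, se)
            keep = (se < 0.2) | (g > 0.2)  # suppress unfavourable small studies
            intercept, p, _ = fm.egger_test(g[keep], se[keep])
            detected += (intercept > 0) and (p < 0.05)
        assert detected / reps >= 0.8

    def test_funnel_points_returned(self):
        g = [0.1, 0.4, 0.3]
        se = [0.2, 0.1, 0.3]
        _, _, funnel = fm.egger_test(g, se)
        assert funnel == list(zip(g, se))


@pytest.fixture(scope="module")
def tiny_engine_problem():
    """Six studies all reporting the same blob peak on a small grid."""
    grid = make_ellipsoid_grid((14, 16, 14), 8.0)
    centre = grid.coords_mm[np.argmin(np.linalg.norm(grid.coords_mm - [10, -10, 10], axis=1))]
    rng = np.random.default_rng(21)
    datasets = []
    for i in range(6):
        t = float(rng.normal(4.5, 0.3))
        datasets.append(StudyDataset(
            study_id=f"t{i}", n_patients=40, n_controls=40,
            peaks=[PeakRecord(*centre, stat=t)]))
    return StudyTable(datasets=datasets), grid, centre


class TestJackknife:
    def test_unanimous_blob_is_fully_stable(self, tiny_engine_problem):
        table, grid, centre = tiny_engine_problem
        jk = fm.jackknife(table, grid, n_perm=30, seed=2)
        j = np.argmin(np.linalg.norm(grid.coords_mm - centre, axis=1))
        assert jk.probability_map[j] == 1.0
        assert jk.stable_mask[j]

    def test_probability_is_mean_of_iteration_masks(self, tiny_engine_problem):
        table, grid, _ = tiny_engine_problem
        jk = fm.jackknife(table, grid, n_perm=30, seed=2)
        assert np.array_equal(jk.probability_map, jk.per_iteration_masks.mean(axis=0))
        assert np.array_equal(jk.stable_mask, jk.probability_map >= 0.8)

    def test_single_study_effect_is_unstable(self, tiny_engine_problem):
        table, grid, centre = tiny_engine_problem
        # add a lone study reporting a second, distant peak
        other = grid.coords_mm[np.argmin(np.linalg.norm(grid.coords_mm - [-20, 20, -15], axis=1))]
        extra = StudyDataset(study_id="lone", n_patients=40, n_controls=40,
                             peaks=[PeakRecord(*other, stat=6.0)])
        table2 = StudyTable(datasets=list(table.datasets) + [extra])
        jk = fm.jackknife(table2, grid, n_perm=30, seed=2)
        j = np.argmin(np.linalg.norm(grid.coords_mm - other, axis=1))
        # the lone-study region cannot be stable across its own removal
        assert jk.probability_map[j] <= (len(table2) - 1) / len(table2)

    def test_needs_three_datasets(self):
        grid = make_ellipsoid_grid((8, 8, 8), 8.0)
        with pytest.raises(DomainError):
            fm.jackknife([], grid)


class TestSubgroup:
    def test_roster_gate_counts(self):
        roster = fm.load_reference_roster()
        grid = make_ellipsoid_grid((8, 8, 8), 8.0)
        # Philips scanner: 3 datasets -> refusal naming the count
        with pytest.raises(StageRefusal, match="3 datasets"):
            fm.subgroup_meta(roster, lambda d: d.scanner == "Philips", grid)
        # binary FNC: 11 datasets -> passes the > 10 gate (engine then requires
        # peaks, which the printed roster does not carry)
        assert sum(d.fnc_type == "binary" for d in roster) == 11

    def test_boundary_is_strict(self, tiny_engine_problem):
        table, grid, _ = tiny_engine_problem
        with pytest.raises(StageRefusal):
            fm.subgroup_meta(table, lambda d: True, grid, min_datasets=6)

    def test_always_true_predicate_matches_main_analysis(self, tiny_engine_problem):
        table, grid, _ = tiny_engine_problem
        main = fm.sdm_z_map(table, grid, n_perm=25, seed=9)
        sub = fm.subgroup_meta(table, lambda d: True, grid, min_datasets=2,
                               n_perm=25, seed=9)
        assert np.array_equal(main.sdm_z, sub.sdm_z)


class TestMetaRegression:
    @pytest.fixture(scope="class")
    def injected_problem(self):
        """Blob effect scales linearly with the PANSS covariate."""
        grid = make_ellipsoid_grid((14, 16, 14), 8.0)
        centre = grid.coords_mm[np.argmin(np.linalg.norm(grid.coords_mm - [10, -10, 10], axis=1))]
        rng = np.random.default_rng(31)
        datasets = []
        panss = np.linspace(60, 110, 12)
        for i, s in enumerate(panss):
            g = 0.3 + 0.02 * (s - panss.mean()) + rng.normal(0, 0.01)
            t = g / np.sqrt(2 / 40)
            datasets.append(StudyDataset(
                study_id=f"m{i}", n_patients=40, n_controls=40,
                panss_total=float(s), mean_age_pat=float(rng.normal(27, 3)),
                peaks=[PeakRecord(*centre, stat=float(t))]))
        table = StudyTable(datasets=datasets)
        result = fm.sdm_z_map(table, grid, n_perm=40, seed=5)
        clusters = threshold_clusters(result)
        assert clusters, "fixture must produce a main-analysis cluster"
        return table, result, clusters, centre

    def test_injected_signal_detected_with_positive_slope(self, injected_problem):
        table, result, clusters, centre = injected_problem
        mr = fm.meta_regression(result, table, "panss_total", clusters,
                                n_perm=5000, seed=1)
        assert mr.significant_clusters, "injected PANSS slope must be detected"
        grid = result.grid
        j = np.argmin(np.linalg.norm(grid.coords_mm - centre, axis=1))
        assert mr.slope_map[j] > 0

    def test_uncorrelated_covariate_not_significant(self, injected_problem):
        table, result, clusters, _ = injected_problem
        mr = fm.meta_regression(result, table, "mean_age_pat", clusters,
                                n_perm=5000, seed=1)
        assert mr.significant_clusters == []

    def test_restricted_to_main_clusters(self, injected_problem):
        table, result, clusters, _ = injected_problem
        mr = fm.meta_regression(result, table, "panss_total", clusters,
                                n_perm=200, p_thresh=0.05, seed=1)
        inside = np.unique(np.concatenate([c.member_voxels for c in clusters]))
        outside = np.setdiff1d(np.arange(result.grid.n_voxels), inside)
        assert np.all(np.isnan(mr.slope_map[outside]))

    def test_permutation_granularity_gates_significance(self, injected_problem):
        """With n_perm permutations the smallest attainable p is 1/(n_perm+1);
        below-threshold detection requires enough permutations."""
        table, result, clusters, _ = injected_problem
        coarse = fm.meta_regression(result, table, "panss_total", clusters,
                                    n_perm=1000, seed=1)  # min p ~ 1e-3 > 5e-4
        assert coarse.significant_clusters == []

    def test_constant_covariate_rejected(self, injected_problem):
        table, result, clusters, _ = injected_problem
        with pytest.raises(DomainError):
            fm.meta_regression(result, table, [1.0] * len(table.datasets), clusters)

    def test_missing_covariate_refusal(self, injected_problem):
        table, result, clusters, _ = injected_problem
        with pytest.raises(StageRefusal):
            fm.meta_regression(result, table, "illness_duration", clusters)

    def test_parametric_flag_agrees_on_sign(self, injected_problem):
        table, result, clusters, centre = injected_problem
        mr = fm.meta_regression(result, table, "panss_total", clusters,
                                method="parametric", seed=1)
        grid = result.grid
        j = np.argmin(np.linalg.norm(grid.coords_mm - centre, axis=1))
        assert mr.slope_map[j] > 0
        # the RE weights fold the covariate-driven heterogeneity into tau2,
        # so the parametric t-test is conservative relative to permutation
        assert mr.p_map[j] < 0.05


class TestClusterDiagnostics:
    def test_cluster_effects_mean_vs_peak(self, small_meta):
        result, _ = small_meta
        clusters = threshold_clusters(result)
        assert clusters
        g_mean, v_mean = cluster_effects(result, clusters[0], "mean")
        g_peak, v_peak = cluster_effects(result, clusters[0], "peak")
        assert g_mean.shape == g_peak.shape == (len(result.study_ids),)
        diag = fm.cluster_diagnostics(result, clusters[:2])
        for d in diag:
            assert d.Q >= 0
            assert 0 <= d.Q_p <= 1
            assert 0 <= d.egger_p <= 1
            assert len(d.funnel_points) == len(result.study_ids)
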