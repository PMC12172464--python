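import itertools

import numpy as np
import pandas as pd
import pytest

from microtensor import (
    FitConfig,
    ParafacModel,
    ProcessConfig,
    SimSpec,
    associate_loadings,
    build_cube,
    cluster_abundance_test,
    cluster_features,
    feature_fit_metrics,
    fit_parafac,
    multi_start_fit,
    process_data_cube,
    reconstruct,
    select_features,
    simulate_mock_counts,
    simulate_trilinear,
    transform_feature_loadings,
)
from microtensor.posthoc import FeatureFitMetrics, kmedoids


class TestFeatureFitMetrics:
    def test_perfectly_modelled_feature(self):
        cube, _ = simulate_trilinear(SimSpec(I=6, J=5, K=4, F=1,
                                             noise_sd=0.0, seed=1))
        model = fit_parafac(cube, 1, FitConfig(ctol=1e-12, maxit=2000, seed=2))
        t = feature_fit_metrics(model, cube).table
        assert np.allclose(t["variance_explained"], 100.0, atol=1e-5)
        assert np.allclose(t["congruence"].abs(), 1.0, atol=1e-8)

    def test_pure_noise_feature_falls_below_thresholds(self):
        cube, truth = simulate_trilinear(SimSpec(I=12, J=6, K=8, F=2,
                                                 noise_sd=0.05, seed=3))
        # overwrite one feature with pure noise
        rng = np.random.default_rng(4)
        cube.values[:, 2, :] = rng.standard_normal((12, 8))
        model = fit_parafac(cube, 2, FitConfig(ctol=1e-8, maxit=1000, seed=5))
        t = feature_fit_metrics(model, cube).table
        noise_row = t.iloc[2]
        others = t.drop(t.index[2])
        assert noise_row["variance_explained"] < t["variance_explained"].mean()
        assert noise_row["congruence"] < others["congruence"].min()

    def test_selection_rule_boundaries(self):
        t = pd.DataFrame(
            {"variance_explained": [50.0, 50.0, 50.0],
             "congruence": [0.39, 0.40, 0.41]},
            index=["x", "y", "z"])
        kept = select_features(FeatureFitMetrics(t), congruence_min=0.4)
        assert kept == ["y", "z"]  # boundary inclusive, mean rule vacuous

    def test_selection_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        t = pd.DataFrame({"variance_explained": rng.uniform(0, 100, 20),
                          "congruence": rng.uniform(-1, 1, 20)},
                         index=[f"f{i}" for i in range(20)])
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8):
            kept = set(select_features(FeatureFitMetrics(t), congruence_min=thr))
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestTransformLoadings:
    def test_inner_products_match_fitted_trajectories(self):
        cube, _ = simulate_trilinear(SimSpec(I=4, J=5, K=3, F=2,
                                             noise_sd=0.1, seed=7))
        model = fit_parafac(cube, 2, FitConfig(seed=8))
        Bt = transform_feature_loadings(model)
        rec = reconstruct(model)
        for j, jp in itertools.product(range(5), repeat=2):
            expected = np.sum(rec[:, j, :] * rec[:, jp, :])
            assert Bt[j] @ Bt[jp] == pytest.approx(expected, abs=1e-10)

    def test_orthonormal_modes_collapse_to_weighted_loadings(self):
        # orthonormal A and C make the Gram matrix the identity
        A, _ = np.linalg.qr(np.random.default_rng(1).standard_normal((6, 2)))
        C, _ = np.linalg.qr(np.random.default_rng(2).standard_normal((5, 2)))
        B = np.random.default_rng(3).standard_normal((4, 2))
        B /= np.linalg.norm(B, axis=0)
        model = ParafacModel(A=A, B=B, C=C, weights=np.array([3.0, 1.5]),
                             n_components=2)
        Bt = transform_feature_loadings(model)
        assert np.allclose(Bt, B * model.weights, atol=1e-10)

    def test_scalar_single_component_case(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(5); a /= np.linalg.norm(a)
        b = rng.standard_normal(4); b /= np.linalg.norm(b)
        c = rng.standard_normal(3); c /= np.linalg.norm(c)
        model = ParafacModel(A=a[:, None], B=b[:, None], C=c[:, None],
                             weights=np.array([2.5]), n_components=1)
        assert np.allclose(transform_feature_loadings(model).ravel(), 2.5 * b)

    def test_invariant_to_permutation_and_sign(self):
        cube, _ = simulate_trilinear(SimSpec(I=5, J=6, K=4, F=2,
                                             noise_sd=0.1, seed=9))
        model = fit_parafac(cube, 2, FitConfig(seed=10))
        perm, flip = [1, 0], np.array([-1.0, 1.0])
        twisted = ParafacModel(A=model.A[:, perm] * flip,
                               B=model.B[:, perm] * flip,
                               C=model.C[:, perm],
                               weights=model.weights[perm], n_components=2)
        g1 = transform_feature_loadings(model)
        g2 = transform_feature_loadings(twisted)
        assert np.allclose(g1 @ g1.T, g2 @ g2.T, atol=1e-10)


class TestKMedoids:
    def test_separable_clouds_found_with_silhouette_argmax(self):
        rng = np.random.default_rng(11)
        pts = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(5, 0.1, (8, 2))])
        result = cluster_features(pts, k_range=range(2, 5), n_starts=10,
                                  seed=1, n_gap_refs=5)
        assert result.chosen_k == 2
        labels = result.assignments.to_numpy()
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1

    def test_duplicate_points_give_zero_wss(self):
        pts = np.array([[0.0, 0.0]] * 4 + [[1.0, 1.0]] * 4)
        medoids, labels, obj = kmedoids(pts, 2, n_starts=10,
                                        rng=np.random.default_rng(0))
        assert obj == pytest.approx(0.0)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal([0, 0], 0.4, (4, 2)),
                         rng.normal([4, 0], 0.4, (4, 2)),
                         rng.normal([0, 4], 0.4, (4, 2))])
        _, _, obj = kmedoids(pts, 3, n_starts=50,
                             rng=np.random.default_rng(1))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        exhaustive = min(
            d[:, list(c)].min(axis=1).sum()
            for c in itertools.combinations(range(len(pts)), 3))
        assert obj == pytest.approx(exhaustive, abs=1e-9)

    def test_best_of_starts_never_worse_than_single_start(self):
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((15, 3))
        _, _, best50 = kmedoids(pts, 4, n_starts=50,
                                rng=np.random.default_rng(2))
        for s in range(5):
            _, _, one = kmedoids(pts, 4, n_starts=1,
                                 rng=np.random.default_rng(s))
            assert best50 <= one + 1e-12

    def test_medoids_are_members_and_assignment_total(self):
        rng = np.random.default_rng(14)
        pts = rng.standard_normal((12, 2))
        result = cluster_features(pts, k_range=[3], n_starts=10, seed=3,
                                  n_gap_refs=3)
        assert set(result.medoids) <= set(result.selected_features)
        assert len(result.assignments) == 12
        for m in result.medoids:
            assert result.assignments[m] == result.assignments[m]  # assigned


class TestClusterAbundanceTest:
    @staticmethod
    def _mock_setup(effect_size, seed, n=15, n_times=4):
        spec = SimSpec(n_cases=n, n_controls=n, n_times=n_times,
                       effect_size=effect_size, depth=2000, seed=seed)
        table = simulate_mock_counts(spec)
        cube = build_cube(table, list(range(1, n_times + 1)))
        assignments = pd.Series([1, 1, 2],
                                index=["Actinobacteria", "Bacteroidetes",
                                       "Proteobacteria"])
        return cube, assignments

    def test_identical_groups_give_p_one(self):
        cube, assignments = self._mock_setup(effect_size=0.0, seed=1)
        # make the two groups literally identical
        half = len(cube.subject_ids) // 2
        cube.raw_counts[half:] = cube.raw_counts[:half]
        cube.values[half:] = cube.values[:half]
        df = cluster_abundance_test(cube, assignments, "group", n_perm=99,
                                    seed=2)
        assert np.allclose(df["statistic"], 0.0)
        assert np.allclose(df["p_value"], 1.0)

    def test_null_labels_rarely_significant(self):
        mins = []
        for rep in range(15):
            cube, assignments = self._mock_setup(effect_size=0.0, seed=100 + rep)
            df = cluster_abundance_test(cube, assignments, "group",
                                        n_perm=199, seed=rep)
            mins.append(df["p_adjusted"].min())
        assert np.mean(np.array(mins) > 0.05) >= 0.8

    def test_real_effect_detected(self):
        cube, assignments = self._mock_setup(effect_size=2.0, seed=3, n_times=6)
        df = cluster_abundance_test(cube, assignments, "group", n_perm=199,
                                    seed=4)
        late = df[(df["cluster"] == 2) & (df["time"] == 6)]
        assert late["p_adjusted"].iloc[0] <= 0.05

    def test_adjusted_p_not_below_raw(self):
        cube, assignments = self._mock_setup(effect_size=1.0, seed=5)
        df = cluster_abundance_test(cube, assignments, "group", n_perm=99,
                                    seed=6)
        ok = df["testable"]
        assert (df.loc[ok, "p_adjusted"] >= df.loc[ok, "p_value"] - 1e-12).all()


class TestAssociateLoadings:
    def test_separated_groups_reach_rank_sum_floor(self):
        table = simulate_mock_counts(SimSpec(seed=7))
        cube = build_cube(table, list(range(1, 11)))
        proc = process_data_cube(cube, ProcessConfig())
        model, _ = multi_start_fit(proc, 2, FitConfig(n_starts=3, seed=8))
        df = associate_loadings(model, proc, {"group": "binary"})
        assert df["p_value"].min() < 1e-6  # strong group separation

    def test_continuous_variable_pearson(self):
        cube, truth = simulate_trilinear(SimSpec(I=30, J=8, K=5, F=2,
                                                 noise_sd=0.05, seed=9))
        model = fit_parafac(cube, 2, FitConfig(ctol=1e-8, maxit=500, seed=10))
        meta = pd.DataFrame({"covar": truth["A"][:, 0]},
                            index=cube.subject_ids)
        cube.subject_metadata = meta
        df = associate_loadings(model, cube, {"covar": "continuous"})
        assert df["p_value"].min() < 1e-6  # loading tracks its generator

    def test_single_level_variable_skipped(self, small_cube):
        cube, _ = simulate_trilinear(SimSpec(I=6, J=5, K=4, F=1,
                                             noise_sd=0.05, seed=11))
        cube.subject_metadata = pd.DataFrame({"const": ["x"] * 6},
                                             index=cube.subject_ids)
        model = fit_parafac(cube, 1, FitConfig(seed=12))
        df = associate_loadings(model, cube, {"const": "binary"})
        assert (df["note"] == "single level").all()
        assert df["p_value"].isna().all()

    def test_independent_label_rarely_significant(self):
        hits = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            cube, _ = simulate_trilinear(SimSpec(I=40, J=6, K=4, F=1,
                                                 noise_sd=0.1, seed=500 + rep))
            cube.subject_metadata = pd.DataFrame(
                {"label": rng.choice(["u", "v"], size=40)},
                index=cube.subject_ids)
            model = fit_parafac(cube, 1, FitConfig(seed=rep))
            df = associate_loadings(model, cube, {"label": "binary"})
            hits += (df["p_adjusted"] < 0.05).any()
        assert hits / reps <= 0.15
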