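import numpy as np
import pytest

from momcrad import (
    Beta,
    DegenerateFitError,
    IMIAConfig,
    ObjectiveTriple,
    Solution,
    dominates,
    evaluate_objectives,
    fit_base_classifiers,
    fuse_archive,
    hypervolume_3d,
    imia_optimize,
    pareto_front,
    predict_solution,
    solution_weights,
    train_modality,
)
from momcrad.momc import TrainedModalityModel, crowding_distance
from momcrad.tables import FeatureTable


class TestDominance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0.9, 0.8, 0.2), (0.8, 0.8, 0.2), True),
            ((0.8, 0.8, 0.2), (0.8, 0.8, 0.2), False),
            ((0.9, 0.7, 0.2), (0.7, 0.9, 0.2), False),
            ((0.7, 0.9, 0.2), (0.9, 0.7, 0.2), False),
            ((1.0, 1.0, 1.0), (0.0, 0.0, 0.0), True),
        ],
    )
    def test_examples(self, a, b, expected):
        assert dominates(a, b) is expected


def _sol(objectives, n_features=4, rng=None, f=None):
    rng = rng or np.random.default_rng(0)
    if f is None:
        f = np.zeros(n_features, dtype=bool)
        f[rng.integers(n_features)] = True
    s = Solution(f, Beta(), np.array([1.0, 0.0, 0.0]))
    s.objectives = ObjectiveTriple(*objectives)
    return s


class TestParetoFront:
    def test_incomparable_triples_all_kept(self):
        rng = np.random.default_rng(1)
        sols = [
            _sol(o, rng=rng, f=np.eye(4, dtype=bool)[i])
            for i, o in enumerate([(1, 0, 1), (0, 1, 1), (0.5, 0.5, 0.5)])
        ]
        assert len(pareto_front(sols)) == 3

    def test_dominated_point_removed(self):
        sols = [
            _sol((0.9, 0.9, 0.5), f=np.array([1, 0, 0, 0], dtype=bool)),
            _sol((0.5, 0.5, 0.2), f=np.array([0, 1, 0, 0], dtype=bool)),
        ]
        front = pareto_front(sols)
        assert len(front) == 1
        assert front[0].objectives == (0.9, 0.9, 0.5)

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            objs = rng.random((50, 3))
            sols = []
            for i in range(50):
                f = np.zeros(64, dtype=bool)
                f[i] = True
                sols.append(_sol(objs[i], f=f))
            front = {tuple(s.objectives) for s in pareto_front(sols)}
            brute = {
                tuple(objs[i])
                for i in range(50)
                if not any(dominates(objs[j], objs[i]) for j in range(50) if j != i)
            }
            assert front == brute


class TestHypervolume:
    def test_single_point_is_box_volume(self):
        assert hypervolume_3d([(0.5, 0.4, 0.2)]) == pytest.approx(0.04)

    def test_two_points_inclusion_exclusion(self):
        # boxes (0.6,0.5,0.5) and (0.3,0.8,0.8): union by hand =
        # 0.15 + 0.192 - 0.3*0.5*0.5 = 0.267
        pts = [(0.6, 0.5, 0.5), (0.3, 0.8, 0.8)]
        assert hypervolume_3d(pts) == pytest.approx(0.267)

    def test_dominated_point_adds_nothing(self):
        base = hypervolume_3d([(0.8, 0.8, 0.8)])
        assert hypervolume_3d([(0.8, 0.8, 0.8), (0.5, 0.5, 0.5)]) == pytest.approx(base)

    def test_crowding_boundary_points_largest(self):
        objs = np.array([[0.1, 0.9, 0.5], [0.5, 0.5, 0.5], [0.9, 0.1, 0.5]])
        d = crowding_distance(objs)
        assert d[0] == d.max() and d[2] == d.max()


class TestBaseClassifiers:
    def test_separable_blobs_all_fit_perfectly(self):
        # two well-separated 2-D Gaussian blobs, n = 40: every base
        # classifier must reach training accuracy 1.0
        rng = np.random.default_rng(0)
        y = np.array([0] * 20 + [1] * 20)
        X = rng.normal(0, 1, (40, 2))
        X[y == 1] += 6.0
        table = FeatureTable([f"p{i}" for i in range(40)], ["a", "b"], X, y)
        f = np.ones(2, dtype=bool)
        fitted = fit_base_classifiers(table, f, Beta(svm_gamma=0.5))
        from momcrad.classifiers import ZScaler

        Xs = ZScaler().fit(X).transform(X)
        for kind in ("lr", "da", "svm"):
            p = fitted[kind].predict_proba_pos(Xs)
            assert np.all((p >= 0) & (p <= 1))
            assert np.mean((p >= 0.5).astype(int) == y) == 1.0

    def test_constant_selected_feature_is_degenerate(self, toy_table):
        table = FeatureTable(
            toy_table.patient_ids,
            toy_table.feature_names,
            np.where(np.arange(10) == 0, 3.14, toy_table.values),
            toy_table.labels,
        )
        f = np.zeros(10, dtype=bool)
        f[0] = True
        with pytest.raises(DegenerateFitError):
            fit_base_classifiers(table, f, Beta())


class _StubClf:
    def __init__(self, p):
        self.p = p

    def predict_proba_pos(self, X):
        return np.full(np.atleast_2d(X).shape[0], self.p)


class TestPredictSolution:
    def test_degenerate_weight_returns_lr(self):
        fitted = {"lr": _StubClf(0.2), "da": _StubClf(0.6), "svm": _StubClf(1.0)}
        p = predict_solution(fitted, np.array([1.0, 0.0, 0.0]), np.zeros((3, 2)))
        np.testing.assert_allclose(p, 0.2)

    def test_uniform_weights_average(self):
        fitted = {"lr": _StubClf(0.2), "da": _StubClf(0.6), "svm": _StubClf(1.0)}
        p = predict_solution(fitted, np.full(3, 1 / 3), np.zeros((1, 2)))
        assert p[0] == pytest.approx(0.6)

    def test_monotone_in_each_component(self):
        omega = np.array([0.3, 0.3, 0.4])
        base = predict_solution(
            {"lr": _StubClf(0.2), "da": _StubClf(0.5), "svm": _StubClf(0.7)},
            omega, np.zeros((1, 1)))[0]
        raised = predict_solution(
            {"lr": _StubClf(0.4), "da": _StubClf(0.5), "svm": _StubClf(0.7)},
            omega, np.zeros((1, 1)))[0]
        assert raised > base


class TestObjectives:
    def test_sparsity_values(self, toy_table):
        for k, expected in ((5, 0.2), (1, 1.0)):
            f = np.zeros(10, dtype=bool)
            f[:k] = True
            s = Solution(f, Beta(), np.array([1.0, 0, 0]))
            s.train_probs = toy_table.labels.astype(float)  # perfect classifier
            obj = evaluate_objectives(s, toy_table)
            assert obj.sparsity == pytest.approx(expected)
            assert obj.sensitivity == 1.0 and obj.specificity == 1.0

    def test_always_positive_classifier(self, toy_table):
        f = np.ones(10, dtype=bool)
        s = Solution(f, Beta(), np.array([1.0, 0, 0]))
        s.train_probs = np.ones(toy_table.n_patients)
        obj = evaluate_objectives(s, toy_table)
        assert obj.sensitivity == 1.0 and obj.specificity == 0.0


class TestSolutionWeights:
    def test_balance_preferred(self):
        a = _sol((0.9, 0.9, 0.5), f=np.array([1, 0, 0, 0], dtype=bool))
        b = _sol((1.0, 0.5, 0.5), f=np.array([0, 1, 0, 0], dtype=bool))
        w = solution_weights([a, b])
        assert w[0] > w[1]
        assert w.sum() == pytest.approx(1.0)

    def test_single_solution_weight_one(self):
        assert solution_weights([_sol((0.8, 0.7, 0.5))])[0] == pytest.approx(1.0)

    def test_all_zero_raw_falls_back_to_uniform(self):
        sols = [
            _sol((0.0, 0.0, 0.0), f=np.eye(4, dtype=bool)[i]) for i in range(3)
        ]
        np.testing.assert_allclose(solution_weights(sols), 1 / 3)


class TestIMIA:
    CFG = dict(population_size=10, generations=5, objective_cv=1)

    def test_same_seed_identical_archive(self, toy_table):
        cfg = IMIAConfig(**self.CFG)
        a1 = imia_optimize(toy_table, cfg, seed=3)
        a2 = imia_optimize(toy_table, cfg, seed=3)
        assert [s.identity_key() for s in a1] == [s.identity_key() for s in a2]
        assert [s.objectives for s in a1] == [s.objectives for s in a2]

    def test_archive_invariants(self, toy_table):
        archive = imia_optimize(toy_table, IMIAConfig(**self.CFG), seed=1)
        objs = [s.objectives for s in archive]
        for i, s in enumerate(archive):
            assert s.n_selected >= 1
            assert s.objectives.sparsity == pytest.approx(1.0 / s.n_selected)
            assert not any(
                dominates(objs[j], objs[i]) for j in range(len(archive)) if j != i
            )

    def test_hypervolume_nondecreasing(self, toy_table):
        history: list = []
        imia_optimize(toy_table, IMIAConfig(**self.CFG), seed=2, history=history)
        assert all(b >= a - 1e-12 for a, b in zip(history, history[1:]))

    def test_generation_cap_respected(self, toy_table):
        history: list = []
        imia_optimize(
            toy_table,
            IMIAConfig(population_size=6, generations=50, patience=3,
                       hv_tol=1e-9, objective_cv=1),
            seed=4,
            history=history,
        )
        assert len(history) <= 51  # initial + at most 50 generations


class TestArchiveFusion:
    def test_fuse_single_solution_identity(self):
        s = _sol((0.8, 0.8, 0.5))
        p = fuse_archive([s], np.array([1.0]), np.array([[0.7, 0.2]]))
        np.testing.assert_allclose(p, [0.7, 0.2], atol=1e-12)

    def test_fused_monotone_in_solution_probs(self):
        rng = np.random.default_rng(0)
        sols = [_sol(rng.random(3), f=np.eye(4, dtype=bool)[i]) for i in range(3)]
        w = np.array([0.4, 0.35, 0.25])
        base = fuse_archive(sols, w, np.array([[0.3], [0.5], [0.6]]))[0]
        up = fuse_archive(sols, w, np.array([[0.4], [0.6], [0.7]]))[0]
        assert up >= base


class TestTrainModality:
    CFG = IMIAConfig(population_size=8, generations=4, objective_cv=1)

    def test_separable_cohort_high_training_auc(self, toy_table):
        model = train_modality(toy_table, self.CFG, seed=0)
        assert model.training_metrics["auc"] >= 0.95

    def test_clinical_table_trains_without_preselection(self, cohort):
        clin = cohort.tables["clinical"].subset_rows(cohort.train_idx)
        model = train_modality(clin, self.CFG, seed=1)
        assert model.modality == "clinical"
        assert 0.5 <= model.training_metrics["auc"] <= 1.0

    def test_serialization_round_trip_identical_predictions(self, toy_table):
        model = train_modality(toy_table, self.CFG, seed=2)
        reloaded = TrainedModalityModel.from_dict(model.to_dict())
        X = toy_table.values
        np.testing.assert_array_equal(
            model.predict_proba(X), reloaded.predict_proba(X)
        )

    def test_sparsity_objective_reduces_selected_features(self, toy_table):
        import dataclasses

        with_fs = train_modality(toy_table, self.CFG, seed=5)
        without = train_modality(
            toy_table, dataclasses.replace(self.CFG, include_sparsity=False), seed=5
        )
        med_w = np.median([s.n_selected for s in with_fs.archive])
        med_wo = np.median([s.n_selected for s in without.archive])
        assert med_w <= med_wo
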