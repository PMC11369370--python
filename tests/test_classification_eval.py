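"""Patient-wise splits, SVM training, ROC/AUC and the repeated pipeline."""

import numpy as np
import pandas as pd
import pytest

from drstissue import (
    FeatureTable,
    GeneratorConfig,
    evaluate,
    generate_dataset,
    patient_split,
    run_iteration,
    run_repeated,
    train_classifier,
)
from drstissue.classification_eval import (
    EvaluationError,
    LinearModel,
    SplitError,
    TrainingError,
)

from conftest import make_set


def auc_concordance_oracle(scores, y):
    """Pairwise-concordance AUC: over all (pos, neg) pairs count score_pos >
    score_neg as 1, ties as 1/2."""
    pos = [s for s, c in zip(scores, y) if c == 1]
    neg = [s for s, c in zip(scores, y) if c == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def table_from(X, y, patients=None):
    X = np.asarray(X, dtype=float)
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    frame = pd.DataFrame(X, columns=list(names))
    frame.insert(0, "label", ["tumor" if v else "healthy" for v in y])
    frame.insert(0, "patient_id", patients or [f"P{i}" for i in range(len(y))])
    return FeatureTable(frame=frame, feature_names=names)


def identity_model(n_features=1):
    """Decision value = first feature (for threshold/ROC arithmetic tests)."""
    return LinearModel(
        feature_names=tuple(f"f{i}" for i in range(n_features)),
        weights=np.eye(n_features)[0],
        bias=0.0,
        C=1.0,
        scaler_mean=np.zeros(n_features),
        scaler_scale=np.ones(n_features),
        cv_accuracy={},
    )


class TestPatientSplit:
    def test_ten_patients_ratio_70_gives_7_train(self):
        s = make_set({"tumor": 10, "healthy": 10}, n_patients=10)
        plan = patient_split(s, ratio=0.7, seed=0)
        assert len(plan.train_patients) == 7
        assert len(plan.test_patients) == 3

    def test_train_test_patient_sets_disjoint(self):
        s = make_set({"tumor": 30, "healthy": 30}, n_patients=12)
        for seed in range(5):
            plan = patient_split(s, seed=seed)
            assert not plan.train_patients & plan.test_patients
            assert plan.train_patients | plan.test_patients == set(s.patients())

    def test_hundred_patients_default_ratio_gives_70(self):
        s = make_set({"tumor": 150, "healthy": 150}, n_patients=100)
        plan = patient_split(s, seed=3)
        assert len(plan.train_patients) == 70

    def test_measurements_inherit_patient_side(self, default_cohort):
        spectra, _ = default_cohort
        labeled = spectra.labeled()
        plan = patient_split(labeled, seed=0)
        train = labeled.subset_patients(plan.train_patients)
        assert {m.patient_id for m in train} <= set(plan.train_patients)
        assert len(train) + len(labeled.subset_patients(plan.test_patients)) == len(labeled)

    def test_single_patient_raises(self):
        s = make_set({"tumor": 4, "healthy": 4}, n_patients=1)
        with pytest.raises(SplitError):
            patient_split(s, seed=0)


class TestTrainClassifier:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.array([0] * 20 + [1] * 20)
        X = np.column_stack([y * 4.0 + rng.normal(0, 0.2, n), rng.normal(0, 1, n)])
        model = train_classifier(table_from(X, y), seed=0)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_label_permutation_null_cv_accuracy(self):
        """Pure-noise features: mean selected-C CV accuracy over 20 seeds near chance."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, size=(40, 3))
            y = rng.permutation([0] * 20 + [1] * 20)
            model = train_classifier(table_from(X, y), seed=seed)
            accs.append(model.cv_accuracy[model.C])
        assert 0.3 <= np.mean(accs) <= 0.7

    def test_row_duplication_keeps_boundary_with_adjusted_C(self):
        # duplicating rows doubles the loss term; halving C compensates exactly
        rng = np.random.default_rng(1)
        y = np.array([0] * 10 + [1] * 10)
        X = np.column_stack([y + rng.normal(0, 0.4, 20), rng.normal(0, 1, 20)])
        base = train_classifier(table_from(X, y), C_grid=(1.0,), folds=2, seed=0)
        dup = train_classifier(
            table_from(np.vstack([X, X]), np.concatenate([y, y])),
            C_grid=(0.5,), folds=2, seed=0,
        )
        np.testing.assert_allclose(dup.weights, base.weights, atol=1e-6)
        assert dup.bias == pytest.approx(base.bias, abs=1e-6)

    def test_single_class_raises(self):
        X = np.random.default_rng(0).uniform(0, 1, (10, 2))
        with pytest.raises(TrainingError):
            train_classifier(table_from(X, [1] * 10))

    def test_constant_features_raise(self):
        with pytest.raises(TrainingError):
            train_classifier(table_from(np.ones((10, 2)), [0, 1] * 5))


class TestEvaluate:
    def test_confusion_arithmetic(self):
        # scores: 8 pos above 0, 2 pos below; 9 neg below, 1 neg above
        scores = [1.0] * 8 + [-1.0] * 2 + [-1.0] * 9 + [1.0]
        y = [1] * 10 + [0] * 10
        res = evaluate(identity_model(), table_from(np.array(scores)[:, None], y))
        assert res.confusion == {"TP": 8, "FN": 2, "TN": 9, "FP": 1}
        assert res.sensitivity == pytest.approx(0.8)
        assert res.specificity == pytest.approx(0.9)
        assert res.accuracy == pytest.approx(0.85)

    def test_perfect_separation_auc_one(self):
        scores = [2.0, 3.0, 4.0, -2.0, -3.0, -4.0]
        y = [1, 1, 1, 0, 0, 0]
        res = evaluate(identity_model(), table_from(np.array(scores)[:, None], y))
        assert res.auc == pytest.approx(1.0)

    def test_all_tied_scores_auc_half(self):
        scores = [1.0] * 6
        y = [1, 0, 1, 0, 1, 0]
        res = evaluate(identity_model(), table_from(np.array(scores)[:, None], y))
        assert res.auc == pytest.approx(0.5)

    def test_one_inversion_matches_concordance_oracle(self):
        scores = [3.0, 2.0, -0.5, 1.0, -1.0, -2.0]  # one pos below one neg
        y = [1, 1, 1, 0, 0, 0]
        res = evaluate(identity_model(), table_from(np.array(scores)[:, None], y))
        assert res.auc == pytest.approx(auc_concordance_oracle(scores, y))

    @pytest.mark.parametrize("seed", range(100))
    def test_trapezoidal_auc_equals_concordance_on_random_scores(self, seed):
        """Sweep-threshold trapezoidal AUC == exhaustive pairwise concordance
        (ties 1/2) on random score vectors of length <= 12, ties included."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        y = np.array([0, 1] + list(rng.integers(0, 2, n - 2)))
        scores = rng.choice([-1.5, -0.5, 0.0, 0.5, 1.5, 2.5], size=n)  # force ties
        res = evaluate(identity_model(), table_from(scores[:, None], y))
        assert res.auc == pytest.approx(auc_concordance_oracle(scores, y), abs=1e-12)

    def test_roc_is_monotone_nondecreasing(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 30)
        y = np.array([0, 1] * 15)
        res = evaluate(identity_model(), table_from(scores[:, None], y))
        fpr = [p[0] for p in res.roc]
        tpr = [p[1] for p in res.roc]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_cutoff_maximizes_youden_j(self):
        scores = np.array([3.0, 2.0, 1.0, -0.5, -1.0, -2.0])
        y = [1, 1, 1, 0, 0, 0]
        res = evaluate(identity_model(), table_from(scores[:, None], y))
        # any cutoff in (1.0, -0.5] separates perfectly; J at reported cutoff = 1
        sens = np.mean(scores[np.array(y) == 1] >= res.cutoff)
        spec = np.mean(scores[np.array(y) == 0] < res.cutoff)
        assert sens + spec - 1 == pytest.approx(1.0)

    def test_single_class_test_set_raises(self):
        with pytest.raises(EvaluationError):
            evaluate(identity_model(), table_from(np.ones((4, 1)), [1, 1, 1, 1]))


class TestRepeatedPipeline:
    def test_no_leakage_deleting_test_rows_changes_nothing(self, default_cohort):
        """Exact-equality leakage guard: the fitted model must be a function
        of the training patients only."""
        spectra, _ = default_cohort
        seed = 123
        _, artifacts = run_iteration(spectra, seed=seed, return_artifacts=True)
        plan = artifacts["plan"]

        from drstissue import (
            class_profiles,
            compute_features,
            relieff_rank,
            select_top_k,
            snv_normalize_set,
            train_classifier,
        )
        from drstissue.feature_extraction import build_feature_spec

        reduced = spectra.labeled().subset_patients(plan.train_patients)
        train_set = snv_normalize_set(reduced)
        spec = build_feature_spec(class_profiles(train_set))
        tbl = compute_features(train_set, spec)
        ranked = relieff_rank(tbl)
        selected = select_top_k(ranked, spec, k=min(20, len(spec)))
        model = train_classifier(compute_features(train_set, selected), seed=seed)

        np.testing.assert_array_equal(model.weights, artifacts["model"].weights)
        assert model.bias == artifacts["model"].bias
        assert model.feature_names == artifacts["model"].feature_names

    def test_single_iteration_report_degenerate_aggregation(self, default_cohort):
        spectra, _ = default_cohort
        rep = run_repeated(spectra, n_iter=1, base_seed=5)
        assert rep.mean("auc") == rep.iterations[0].auc
        assert rep.sd("auc") == 0.0

    def test_metric_means_within_iteration_range(self, default_cohort):
        spectra, _ = default_cohort
        rep = run_repeated(spectra, n_iter=3, base_seed=2)
        for metric in ("sensitivity", "specificity", "accuracy", "auc"):
            vals = [getattr(it, metric) for it in rep.iterations]
            assert min(vals) <= rep.mean(metric) <= max(vals)

    def test_easy_cohort_recovers_signal(self, default_cohort):
        """Default (well-separated) generator: mean AUC over 10 iterations >= 0.9."""
        spectra, _ = default_cohort
        rep = run_repeated(spectra, n_iter=10, base_seed=1)
        assert rep.mean("auc") >= 0.9
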