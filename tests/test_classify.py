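import numpy as np
import pytest

from ramangrade import (SCHEME_LMH, SCHEME_ZLMH, ConfusionMatrix, bin_grades,
                        classification_rate, coefficient_map, confusion_matrix,
                        cv_select_lambda, fit_multinomial_lasso, lambda_grid,
                        lambda_max, multinomial_deviance, predict_classes,
                        run_grading_experiment, split_train_test)
from ramangrade.classify import GradingModel, _fit_path, _ordered_classes
from ramangrade.reference import (fibrosis_binned_lmh, fibrosis_binned_zlmh,
                                  fibrosis_c57bl6)

from conftest import make_toy_dataset


def make_blobs(n_per_class=40, K=3, p=12, sep=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k in range(K):
        Xi = rng.normal(0, 1, (n_per_class, p))
        Xi[:, k] += sep * (k + 1)
        X.append(Xi)
        y.extend([float(k)] * n_per_class)
    return np.vstack(X), np.asarray(y)


class TestBinning:
    @pytest.mark.parametrize("grade, scheme, label", [
        (0.3, SCHEME_LMH, "Medium"),
        (0.3, SCHEME_ZLMH, "Low"),
        (0.0, SCHEME_ZLMH, "Zero"),
        (0.05, SCHEME_LMH, "Low"),
        (0.05, SCHEME_ZLMH, "Low"),
        (1.0, SCHEME_LMH, "High"),
    ])
    def test_scheme_assignments(self, grade, scheme, label):
        assert bin_grades([grade], scheme) == [label]

    def test_counts_preserved(self):
        grades = [0.0, 0.05, 0.1, 0.3, 0.5, 0.6, 0.9, 1.0] * 3
        assert len(bin_grades(grades, SCHEME_LMH)) == len(grades)

    def test_uncovered_grade_named_in_error(self):
        with pytest.raises(ValueError, match="0.2"):
            bin_grades([0.2], SCHEME_LMH)


class TestSplit:
    def test_study_sized_split(self):
        ds = make_toy_dataset(n_per_class=804, classes=(0.0, 0.5, 1.0), p=4)
        assert ds.n_spectra == 2412
        train, test = split_train_test(ds, 0.7, seed=1)
        assert test.n_spectra == 724
        assert train.n_spectra == 1688

    def test_even_split_and_disjointness(self):
        ds = make_toy_dataset(n_per_class=5, classes=(0.0, 1.0), p=4)
        train, test = split_train_test(ds, 0.5, seed=0)
        assert train.n_spectra == test.n_spectra == 5
        assert not set(train.metadata["spectrum_id"]) & set(test.metadata["spectrum_id"])

    def test_same_seed_same_split(self):
        ds = make_toy_dataset(n_per_class=10, p=4)
        a = split_train_test(ds, 0.7, seed=9)[0].metadata["spectrum_id"]
        b = split_train_test(ds, 0.7, seed=9)[0].metadata["spectrum_id"]
        assert a.equals(b)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_degenerate_fractions_rejected(self, frac):
        ds = make_toy_dataset(n_per_class=5, p=4)
        with pytest.raises(ValueError):
            split_train_test(ds, frac, seed=0)


class TestLassoFit:
    def test_total_shrinkage_above_lambda_max(self):
        X, y = make_blobs(seed=1)
        lam_max = lambda_max(X, y)
        model = fit_multinomial_lasso(X, y, 10 * lam_max)
        assert model.n_nonzero == 0
        freq = np.array([(y == c).mean() for c in model.classes])
        probs = np.exp(model.intercept) / np.exp(model.intercept).sum()
        assert np.allclose(probs, freq, atol=1e-9)

    def test_discriminative_channel_dominates(self):
        rng = np.random.default_rng(2)
        n, p = 60, 8
        X = rng.normal(0, 1, (n, p))
        y = (X[:, 3] > 0).astype(float)
        X[:, 3] += y * 2.0  # channel 3 carries the separation
        lam = 0.02 * lambda_max(X, y)
        model = fit_multinomial_lasso(X, y, lam)
        strength = np.abs(model.coef).max(axis=1)
        assert strength.argmax() == 3
        # higher class (1.0) gains likelihood when channel 3 increases
        assert model.coef[3, 1] > 0 > model.coef[3, 0]

    def test_local_optimality_probe(self):
        X, y = make_blobs(n_per_class=25, K=3, p=6, seed=3)
        lam = 0.1 * lambda_max(X, y)
        model = fit_multinomial_lasso(X, y, lam, tol=1e-10, max_iter=20000)
        from ramangrade.classify import _objective, _one_hot, _class_indices
        classes = model.classes
        Y = _one_hot(y, classes)
        yi = _class_indices(y, classes)
        base = _objective(X, Y, yi, model.coef, model.intercept, lam)
        rng = np.random.default_rng(0)
        for _ in range(100):
            dB = rng.normal(size=model.coef.shape)
            db = rng.normal(size=model.intercept.shape)
            perturbed = _objective(X, Y, yi, model.coef + 1e-3 * dB,
                                   model.intercept + 1e-3 * db, lam)
            assert perturbed >= base - 1e-9

    def test_objective_history_nonincreasing(self):
        X, y = make_blobs(n_per_class=20, seed=4)
        model = fit_multinomial_lasso(X, y, 0.05 * lambda_max(X, y))
        assert (np.diff(model.objective_history) <= 1e-12).all()

    def test_matches_sklearn_solution_quality(self):
        # independent solver cross-check: both minimize the same objective
        pytest.importorskip("sklearn")
        from sklearn.linear_model import LogisticRegression
        from ramangrade.classify import _objective, _one_hot, _class_indices
        X, y = make_blobs(n_per_class=20, K=3, p=6, sep=1.5, seed=5)
        n = X.shape[0]
        lam = 0.05 * lambda_max(X, y)
        mine = fit_multinomial_lasso(X, y, lam, tol=1e-10, max_iter=30000)
        sk = LogisticRegression(l1_ratio=1.0, solver="saga", C=1.0 / (lam * n),
                                tol=1e-8, max_iter=50000).fit(X, y)
        classes = mine.classes
        Y = _one_hot(y, classes)
        yi = _class_indices(y, classes)
        obj_mine = _objective(X, Y, yi, mine.coef, mine.intercept, lam)
        obj_sk = _objective(X, Y, yi, sk.coef_.T, sk.intercept_, lam)
        assert obj_mine <= obj_sk + 1e-4

    def test_single_class_rejected(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="2 classes"):
            fit_multinomial_lasso(X, np.zeros(10), 0.1)

    def test_shrinkage_monotone_along_path(self):
        # the L1 norm of the coefficient block is non-increasing in the
        # penalty (a theorem; the support size is not — variables can drop)
        X, y = make_blobs(n_per_class=30, K=3, p=10, seed=6)
        lambdas = lambda_grid(lambda_max(X, y), 30)
        models = _fit_path(X, y, _ordered_classes(y), lambdas, 1e-7, 2000)
        assert models[0].n_nonzero == 0
        l1 = np.array([np.abs(m.coef).sum() for m in models])
        assert (np.diff(l1) >= -1e-8 * np.maximum(1.0, l1[1:])).all()


class TestDeviance:
    def test_perfect_predictions_zero_deviance(self):
        model = GradingModel(classes=np.array([0.0, 1.0]),
                             coef=np.zeros((2, 2)), intercept=np.array([100.0, -100.0]),
                             lambda_=0.0)
        X = np.zeros((5, 2))
        assert multinomial_deviance(model, X, np.zeros(5)) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_predictions_closed_form(self):
        K, n = 4, 12
        model = GradingModel(classes=np.arange(K, dtype=float),
                             coef=np.zeros((3, K)), intercept=np.zeros(K), lambda_=0.0)
        X = np.zeros((n, 3))
        y = np.zeros(n)
        assert multinomial_deviance(model, X, y) == pytest.approx(2 * n * np.log(K))

    def test_deviance_nonnegative(self):
        X, y = make_blobs(n_per_class=10, seed=7)
        model = fit_multinomial_lasso(X, y, 0.1 * lambda_max(X, y))
        assert multinomial_deviance(model, X, y) >= 0


class TestCV:
    def test_single_lambda_grid(self):
        X, y = make_blobs(n_per_class=20, K=2, p=5, seed=8)
        res = cv_select_lambda(X, y, folds=4, seed=0, n_lambdas=1)
        assert res.lambda_1se == res.lambda_min == res.lambdas[0]

    def test_one_se_rule_definitional_invariants(self):
        X, y = make_blobs(n_per_class=25, K=3, p=8, seed=9)
        res = cv_select_lambda(X, y, folds=5, seed=1, n_lambdas=25)
        assert res.lambda_1se >= res.lambda_min
        i_min = int(np.argmin(res.mean_deviance))
        i_1se = int(np.argmin(np.abs(res.lambdas - res.lambda_1se)))
        assert res.mean_deviance[i_1se] <= res.mean_deviance[i_min] + res.se_deviance[i_min] + 1e-12

    def test_mean_equals_average_of_fold_deviances(self):
        X, y = make_blobs(n_per_class=20, K=3, p=6, seed=10)
        res = cv_select_lambda(X, y, folds=5, seed=2, n_lambdas=10)
        assert np.allclose(res.mean_deviance, res.fold_deviance.mean(axis=0))

    def test_rare_class_error_advises_binning(self):
        X, y = make_blobs(n_per_class=30, K=2, p=5, seed=11)
        y[:3] = 7.0  # a 3-member class cannot stratify into 10 folds
        with pytest.raises(ValueError, match="bin"):
            cv_select_lambda(X, y, folds=10, seed=0)

    def test_separable_classes_reach_high_holdout_rate(self):
        X, y = make_blobs(n_per_class=200, K=3, p=20, sep=1.2, seed=12)
        tr = np.arange(0, 600) % 2 == 0
        res = cv_select_lambda(X[tr], y[tr], folds=10, seed=3, n_lambdas=40)
        model = fit_multinomial_lasso(X[tr], y[tr], res.lambda_1se, raise_on_fail=False)
        cm = confusion_matrix(y[~tr], predict_classes(model, X[~tr]),
                              np.unique(y))
        assert classification_rate(cm) >= 0.9


class TestPrediction:
    def test_tie_breaks_toward_lower_grade(self):
        model = GradingModel(classes=np.array([0.0, 0.5, 1.0]),
                             coef=np.zeros((4, 3)), intercept=np.zeros(3), lambda_=1.0)
        preds = predict_classes(model, np.zeros((6, 4)))
        assert (preds == 0.0).all()

    def test_single_row(self):
        model = GradingModel(classes=np.array([0.0, 1.0]),
                             coef=np.zeros((2, 2)), intercept=np.array([0.0, 1.0]),
                             lambda_=0.0)
        assert predict_classes(model, np.zeros((1, 2))).shape == (1,)

    def test_dimension_mismatch_rejected(self):
        model = GradingModel(classes=np.array([0.0, 1.0]),
                             coef=np.zeros((3, 2)), intercept=np.zeros(2), lambda_=0.0)
        with pytest.raises(ValueError, match="columns"):
            predict_classes(model, np.zeros((2, 5)))

    def test_training_prototypes_predicted_correctly(self):
        X, y = make_blobs(n_per_class=30, K=3, p=6, sep=3.0, seed=13)
        model = fit_multinomial_lasso(X, y, 0.02 * lambda_max(X, y))
        protos = np.vstack([X[y == c].mean(axis=0) for c in model.classes])
        assert (predict_classes(model, protos) == model.classes).all()


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        y = np.array([0.0, 1.0, 1.0, 0.5])
        cm = confusion_matrix(y, y, [0.0, 0.5, 1.0])
        assert np.trace(cm.counts) == 4 and cm.counts.sum() == 4

    def test_swapping_two_predictions_moves_two_cells(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        p1 = y.copy()
        p2 = y.copy()
        p2[0], p2[1] = 1.0, 0.0
        c1 = confusion_matrix(y, p1, [0.0, 1.0]).counts
        c2 = confusion_matrix(y, p2, [0.0, 1.0]).counts
        diff = c2 - c1
        assert (np.sort(diff.flatten()) == [-1, -1, 1, 1]).all()

    def test_matches_sklearn_tally(self):
        pytest.importorskip("sklearn")
        from sklearn.metrics import confusion_matrix as sk_cm
        rng = np.random.default_rng(14)
        labels = ["Zero", "Low", "Medium", "High"]
        y_true = rng.choice(labels, 1000)
        y_pred = rng.choice(labels, 1000)
        ours = confusion_matrix(y_true, y_pred, labels).counts
        theirs = sk_cm(y_true, y_pred, labels=labels)
        assert np.array_equal(ours, theirs)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            confusion_matrix([0.0], [0.7], [0.0, 1.0])


class TestClassificationRate:
    def test_published_binned_lmh_rate(self):
        assert classification_rate(fibrosis_binned_lmh()) == pytest.approx(2363 / 2415)
        assert round(100 * classification_rate(fibrosis_binned_lmh()), 1) == 97.8

    def test_published_binned_zlmh_rate(self):
        assert round(100 * classification_rate(fibrosis_binned_zlmh()), 1) == 96.9

    def test_published_strain_specific_rate(self):
        assert round(100 * classification_rate(fibrosis_c57bl6()), 1) == 99.1

    def test_identity_and_zero_diagonal(self):
        eye = ConfusionMatrix(labels=(0.0, 1.0), counts=np.eye(2, dtype=int) * 5)
        assert classification_rate(eye) == 1.0
        off = ConfusionMatrix(labels=(0.0, 1.0), counts=np.array([[0, 5], [5, 0]]))
        assert classification_rate(off) == 0.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(labels=(0.0, 1.0), counts=np.zeros((2, 2), int))
        with pytest.raises(ValueError, match="empty"):
            classification_rate(cm)

    def test_rate_times_n_equals_trace_exactly(self):
        rng = np.random.default_rng(15)
        counts = rng.integers(0, 50, (4, 4))
        cm = ConfusionMatrix(labels=(0.0, 0.3, 0.6, 1.0), counts=counts)
        assert round(classification_rate(cm) * cm.n) == np.trace(counts)


class TestCoefficientMap:
    def test_zero_model_all_white(self):
        model = GradingModel(classes=np.array([0.0, 1.0]),
                             coef=np.zeros((5, 2)), intercept=np.zeros(2), lambda_=1.0)
        table = coefficient_map(model)
        assert (table["sign"] == "white").all()
        assert len(table[table["coefficient"] != 0]) == 0

    def test_discriminative_channel_dominates_table(self):
        rng = np.random.default_rng(16)
        X = rng.normal(0, 1, (80, 6))
        y = (X[:, 2] > 0).astype(float)
        X[:, 2] += 2 * y
        model = fit_multinomial_lasso(X, y, 0.05 * lambda_max(X, y))
        table = coefficient_map(model, axis=np.arange(6, dtype=float))
        nz = table[table["coefficient"] != 0]
        top = nz.loc[nz["coefficient"].abs().idxmax()]
        assert top["wavenumber"] == 2.0

    def test_sign_trichotomy_exhaustive(self):
        X, y = make_blobs(n_per_class=20, seed=17)
        model = fit_multinomial_lasso(X, y, 0.1 * lambda_max(X, y))
        table = coefficient_map(model)
        assert set(table["sign"]) <= {"red", "green", "white"}
        assert ((table["coefficient"] > 0) == (table["sign"] == "green")).all()
        assert ((table["coefficient"] < 0) == (table["sign"] == "red")).all()


class TestGradingExperiment:
    def test_self_prediction_at_least_as_good_as_holdout(self):
        # optimism is a property of the averages: individual seeds can tie
        # or flip when the CV re-selects a sparser penalty on the full data
        full_rates, split_rates = [], []
        for seed in range(1, 6):
            ds = make_toy_dataset(n_per_class=40, classes=(0.0, 0.5, 1.0),
                                  p=15, sep=0.8, seed=seed)
            full = run_grading_experiment(ds, train_frac=None, seed=seed,
                                          folds=5, n_lambdas=20)
            split = run_grading_experiment(ds, train_frac=0.7, seed=seed,
                                           folds=5, n_lambdas=20)
            assert full.evaluation == "train" and split.evaluation == "test"
            full_rates.append(full.rate)
            split_rates.append(split.rate)
        assert np.mean(full_rates) >= np.mean(split_rates) - 1e-12

    def test_binned_experiment_shape(self):
        ds = make_toy_dataset(n_per_class=30,
                              classes=(0.0, 0.05, 0.3, 0.6, 0.9), p=10, sep=2.0, seed=3)
        rep = run_grading_experiment(ds, scheme=SCHEME_LMH, train_frac=None,
                                     seed=0, folds=5, n_lambdas=15)
        assert rep.matrix.counts.shape == (3, 3)
        assert rep.matrix.labels == ("Low", "Medium", "High")

    def test_strain_filter_excluding_all_rejected(self):
        ds = make_toy_dataset(n_per_class=12, p=5)
        with pytest.raises(ValueError, match="strain"):
            run_grading_experiment(ds, strain="BALB/c", folds=3, n_lambdas=5)

    def test_pneumonitis_response_column_used(self):
        ds = make_toy_dataset(n_per_class=15, classes=(0.0, 0.5), p=8, sep=3.0, seed=4)
        ds.metadata["pneumonitis_grade"] = ds.metadata["fibrosis_grade"]
        rep = run_grading_experiment(ds, response="pneumonitis", train_frac=None,
                                     seed=0, folds=5, n_lambdas=10)
        assert rep.response == "pneumonitis"
        assert set(rep.matrix.labels) == {0.0, 0.5}
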