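import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from morphnet.classification import (
    BD_MDD_SUBMATRIX_REGIONS,
    AEReducer,
    DNNReducer,
    FeatureTable,
    GPConfoundResidualizer,
    _rates,
    apply_reducer,
    evaluate,
    fit_reducer,
    label_permutation_test,
    make_classifier,
    residualize_confound,
    run_grid,
    unvectorize,
    vectorize,
)
from morphnet.io_formats import aal90_labels
from morphnet.kls_network import SimilarityMatrix


def _random_matrices(n_subjects, seed=0):
    labels = aal90_labels()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        m = rng.uniform(0, 1, (90, 90))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        out.append(SimilarityMatrix(labels=labels, values=m))
    return out


def _separable_table(seed=0, n=120, p=12, k=8, shift=5.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, p))
    X[y == 1, :k] += shift
    return FeatureTable(subject_ids=[f"s{i}" for i in range(n)], labels=y, features=X)


class TestVectorize:
    def test_full_matrix_gives_4005_features(self):
        mats = _random_matrices(3)
        table = vectorize(mats, ["a", "b", "c"], np.array([0, 1, 0]))
        assert table.features.shape == (3, 4005)
        assert table.provenance == "full"

    def test_submatrix_gives_105_features(self):
        mats = _random_matrices(2)
        table = vectorize(
            mats, ["a", "b"], np.array([0, 1]), region_subset=BD_MDD_SUBMATRIX_REGIONS
        )
        assert table.features.shape == (2, 105)
        assert table.provenance == "submatrix"

    def test_submatrix_region_list_is_valid(self, aal):
        assert len(BD_MDD_SUBMATRIX_REGIONS) == 15
        assert len(set(BD_MDD_SUBMATRIX_REGIONS)) == 15
        assert set(BD_MDD_SUBMATRIX_REGIONS) <= set(aal)

    def test_round_trip_bit_exact(self):
        mats = _random_matrices(1, seed=3)
        table = vectorize(mats, ["a"], np.array([1]))
        rebuilt = unvectorize(table.features[0], 90)
        np.testing.assert_array_equal(rebuilt, mats[0].values)

    def test_unknown_region_rejected(self):
        mats = _random_matrices(1)
        with pytest.raises(ValueError, match="unknown region"):
            vectorize(mats, ["a"], np.array([1]), region_subset=["Nope_L"])

    def test_mismatched_labels_rejected(self):
        mats = _random_matrices(2)
        bad = SimilarityMatrix(labels=list(reversed(mats[0].labels)), values=mats[0].values)
        with pytest.raises(ValueError, match="share"):
            vectorize([mats[0], bad], ["a", "b"], np.array([0, 1]))


class TestResidualizeConfound:
    def test_linear_noise_free_removed(self):
        rng = np.random.default_rng(0)
        c = rng.integers(1, 4, 100).astype(float)
        X = np.column_stack([2.0 + 0.5 * c, -1.0 + 0.3 * c])
        resid = residualize_confound(X, c)
        assert np.abs(resid).max() < 1e-3

    def test_independent_feature_preserved(self):
        rng = np.random.default_rng(1)
        c = rng.integers(1, 4, 200).astype(float)
        X = rng.normal(0, 1, (200, 3))
        resid = residualize_confound(X, c)
        for j in range(3):
            assert np.corrcoef(resid[:, j], X[:, j])[0, 1] > 0.99

    def test_constant_confound_degenerates_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 1, (30, 4))
        with pytest.warns(UserWarning, match="constant confound"):
            resid = residualize_confound(X, np.ones(30))
        np.testing.assert_allclose(resid, X - X.mean(axis=0))

    def test_held_out_subjects_use_frozen_fit(self):
        rng = np.random.default_rng(3)
        c_train = rng.integers(1, 4, 120).astype(float)
        X_train = np.column_stack([1.0 + 0.8 * c_train + rng.normal(0, 0.05, 120)])
        c_test = np.array([1.0, 2.0, 3.0])
        X_test = np.column_stack([1.0 + 0.8 * c_test])
        _, test_resid = residualize_confound(X_train, c_train, apply_to=(X_test, c_test))
        assert np.abs(test_resid).max() < 0.2

    def test_fast_path_removes_strong_confound(self):
        # wide feature table exercises the vectorized marginal-likelihood path
        rng = np.random.default_rng(4)
        c = rng.integers(1, 4, 80).astype(float)
        X = rng.normal(0, 0.3, (80, 50))
        X += 1.5 * c[:, None]
        res = GPConfoundResidualizer(seed=0).fit(X, c)
        R = res.transform(X, c)
        corr = [abs(np.corrcoef(R[:, j], c)[0, 1]) for j in range(50)]
        assert np.mean(corr) < 0.1


class TestReducers:
    def test_ae_recovers_linear_manifold(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(0, 1, (300, 3))
        W = rng.normal(0, 1, (3, 20))
        X = latent @ W
        train, test = X[:200], X[200:]
        red = AEReducer(dim=3, seed=0, max_iter=800).fit(train)
        rec = red.reconstruct(test)
        assert ((rec - test) ** 2).mean() < 0.10 * test.var()

    def test_reducer_determinism(self):
        table = _separable_table(seed=1, n=60, p=10)
        for kind in ("ae", "dnn"):
            r1 = fit_reducer(kind, table.features, table.labels, dim=3, seed=7)
            r2 = fit_reducer(kind, table.features, table.labels, dim=3, seed=7)
            np.testing.assert_array_equal(
                apply_reducer(r1, table.features), apply_reducer(r2, table.features)
            )

    def test_dnn_preserves_separability(self):
        table = _separable_table(seed=2, n=100, p=20, k=10)
        rep = evaluate(table, "dnn", "svm", seed=0, dim=4)
        assert rep.balanced_accuracy >= 0.95

    def test_dim_too_large_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (40, 5))
        with pytest.raises(ValueError, match="dim"):
            AEReducer(dim=5, seed=0).fit(X)
        with pytest.raises(ValueError, match="dim"):
            DNNReducer(dim=7, seed=0).fit(X, np.repeat([0, 1], 20))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="reducer"):
            fit_reducer("pca", np.zeros((10, 4)), np.zeros(10), dim=2)


class TestEvaluate:
    def test_rate_arithmetic(self):
        bac, sens, spec = _rates(tp=9, fn=1, tn=7, fp=3)
        assert sens == pytest.approx(0.9)
        assert spec == pytest.approx(0.7)
        assert bac == pytest.approx(0.8)

    def test_constant_predictor_balanced_accuracy_half(self):
        # a predictor that always answers "positive"
        bac, _, _ = _rates(tp=10, fn=0, tn=0, fp=15)
        assert bac == 0.5

    def test_separable_task_high_accuracy(self):
        table = _separable_table(seed=0)
        for clf in ("svm", "rf", "xgb"):
            rep = evaluate(table, "none", clf, seed=0, n_trees=100)
            assert rep.balanced_accuracy >= 0.95, clf

    def test_scrambled_labels_chance_level(self):
        rng = np.random.default_rng(5)
        bacs = []
        for seed in range(10):
            table = _separable_table(seed=seed, n=40, p=10)
            scrambled = FeatureTable(
                subject_ids=table.subject_ids,
                labels=rng.permutation(table.labels),
                features=table.features,
            )
            bacs.append(evaluate(scrambled, "none", "svm", seed=seed).balanced_accuracy)
        assert 0.35 <= np.mean(bacs) <= 0.65

    def test_report_fields_consistent(self):
        table = _separable_table(seed=1, n=40, p=8)
        rep = evaluate(table, "none", "svm", seed=0)
        counts = rep.confusion
        assert counts["tp"] + counts["fn"] + counts["tn"] + counts["fp"] == 40
        sens = counts["tp"] / (counts["tp"] + counts["fn"])
        spec = counts["tn"] / (counts["tn"] + counts["fp"])
        assert rep.balanced_accuracy == pytest.approx((sens + spec) / 2)
        assert len(rep.fold_balanced_accuracies) == 5

    def test_non_binary_labels_rejected(self):
        rng = np.random.default_rng(6)
        table = FeatureTable(
            subject_ids=list("abcdef"),
            labels=np.array([0, 1, 2, 0, 1, 2]),
            features=rng.normal(0, 1, (6, 4)),
        )
        with pytest.raises(ValueError, match="binary"):
            evaluate(table, "none", "svm")

    def test_too_few_per_class_rejected(self):
        rng = np.random.default_rng(7)
        table = FeatureTable(
            subject_ids=list("abcdef"),
            labels=np.array([0, 0, 0, 0, 0, 1]),
            features=rng.normal(0, 1, (6, 4)),
        )
        with pytest.raises(ValueError, match="subjects per class"):
            evaluate(table, "none", "svm")


class TestNoLeakage:
    def test_every_fit_sees_only_training_rows(self, monkeypatch):
        """Wiring canary: spy on every fit-time entry point and assert none
        of them ever receives the full dataset (i.e. test rows).

        In k-fold CV every row serves as a test row somewhere, so a planted
        test-fold artifact cannot distinguish leaky from clean pipelines;
        instrumenting the fits can."""
        import morphnet.classification as mc

        n, k_folds = 60, 5
        train_size = n - n // k_folds
        fit_sizes = []

        orig_scaler_fit = mc.StandardScaler.fit
        orig_resid_fit = mc.GPConfoundResidualizer.fit
        orig_fit_reducer = mc.fit_reducer

        def spy_scaler_fit(self, X, *a, **k):
            fit_sizes.append(("scaler", np.asarray(X).shape[0]))
            return orig_scaler_fit(self, X, *a, **k)

        def spy_resid_fit(self, X, confound):
            fit_sizes.append(("residualizer", np.asarray(X).shape[0]))
            return orig_resid_fit(self, X, confound)

        def spy_fit_reducer(kind, X, y, **k):
            fit_sizes.append(("reducer", np.asarray(X).shape[0]))
            return orig_fit_reducer(kind, X, y, **k)

        monkeypatch.setattr(mc.StandardScaler, "fit", spy_scaler_fit)
        monkeypatch.setattr(mc.GPConfoundResidualizer, "fit", spy_resid_fit)
        monkeypatch.setattr(mc, "fit_reducer", spy_fit_reducer)

        table = _separable_table(seed=4, n=n, p=8, k=4, shift=3.0)
        rng = np.random.default_rng(0)
        confound = rng.integers(1, 4, n).astype(float)
        evaluate(table, "ae", "svm", confound=confound, k_folds=k_folds, seed=1, dim=3)

        assert len(fit_sizes) == 3 * k_folds  # residualizer, scaler, reducer per fold
        assert all(size == train_size for _, size in fit_sizes)

    def test_perturbing_test_rows_cannot_change_the_trained_model(self):
        """Replace one fold's test rows with garbage at transform time only:
        the fitted residualizer/scaler/reducer must be unchanged, so the
        transform of the untouched training rows is identical."""
        rng = np.random.default_rng(5)
        n = 40
        X = rng.normal(0, 1, (n, 12))
        c = rng.integers(1, 4, n).astype(float)
        train, test = np.arange(30), np.arange(30, 40)
        tr1, te1 = residualize_confound(X[train], c[train], apply_to=(X[test], c[test]))
        garbage = rng.normal(100, 50, (10, 12))
        tr2, _ = residualize_confound(X[train], c[train], apply_to=(garbage, c[test]))
        np.testing.assert_array_equal(tr1, tr2)


class TestPermutationValidation:
    def test_separable_task_small_p(self):
        table = _separable_table(seed=0, n=40, p=6, k=4)
        p = label_permutation_test(table, "none", "svm", n_perm=199, seed=0)
        assert p <= 0.01

    def test_observed_below_all_gives_one(self):
        table = _separable_table(seed=1, n=40, p=6, k=4)
        p = label_permutation_test(table, "none", "svm", n_perm=99, seed=0, observed=0.0)
        assert p == 1.0

    def test_min_permutations_enforced(self):
        table = _separable_table(seed=2, n=40, p=6)
        with pytest.raises(ValueError, match="n_perm"):
            label_permutation_test(table, n_perm=50)


class TestRunGrid:
    def test_full_grid_shape_and_consistency(self):
        table = _separable_table(seed=0, n=60, p=10, k=6)
        reports = run_grid(table, seed=0, n_trees=50, reducer_max_iter=200, dim=4)
        assert len(reports) == 9
        cells = {(r.reducer, r.classifier) for r in reports}
        assert len(cells) == 9
        # grid results match single-cell evaluation exactly
        single = evaluate(table, "ae", "rf", seed=0, n_trees=50, reducer_max_iter=200, dim=4)
        grid_cell = next(r for r in reports if (r.reducer, r.classifier) == ("ae", "rf"))
        assert grid_cell.balanced_accuracy == single.balanced_accuracy
        assert grid_cell.confusion == single.confusion


def test_make_classifier_kinds():
    assert make_classifier("svm").__class__.__name__ == "SVC"
    assert make_classifier("rf", n_trees=10).n_estimators == 10
    assert make_classifier("xgb") is not None
    with pytest.raises(ValueError):
        make_classifier("mlp")
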