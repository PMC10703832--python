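"""Classifier arm: features, scaling, resampling, models, metrics, protocol."""

import hashlib

import numpy as np
import pytest

import fotscreen.pattern_classifier as pc
from fotscreen.synthetic_cohort import default_spec, generate_cohort, generate_study_cohort
from fotscreen.fot_data import Cohort


@pytest.fixture(scope="module")
def tiny_cohort():
    males = generate_cohort(default_spec("male", "control", n=20), seed=1)
    females = generate_cohort(default_spec("female", "asthma", n=40), seed=2)
    return Cohort(records=males.records + females.records)


def xor_blobs(n_per_quadrant, seed, noise=0.35):
    """Balanced XOR pattern: four Gaussian blobs, diagonal pairs share a class."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cx, cy, lab in [(1, 1, 0), (-1, -1, 0), (1, -1, 1), (-1, 1, 1)]:
        X.append(
            np.column_stack(
                [rng.normal(cx, noise, n_per_quadrant), rng.normal(cy, noise, n_per_quadrant)]
            )
        )
        y.append(np.full(n_per_quadrant, lab))
    X, y = np.vstack(X), np.concatenate(y)
    perm = rng.permutation(y.size)
    return X[perm], y[perm]


class TestFeatures:
    def test_phase10_shape(self, tiny_cohort):
        X, y = pc.assemble_features(tiny_cohort, pc.FeatureSpec("phase10", include_sex=False))
        assert X.shape == (60, 10)
        assert y.sum() == 40  # asthma = 1

    def test_all24_age_sex_dimension(self, tiny_cohort):
        X, _ = pc.assemble_features(
            tiny_cohort, pc.FeatureSpec("all24", include_age=True, include_sex=True)
        )
        assert X.shape[1] == 26
        assert set(X[:, -1]) == {0.0, 1.0}  # sex column

    def test_deterministic(self, tiny_cohort):
        spec = pc.FeatureSpec("phase10")
        X1, y1 = pc.assemble_features(tiny_cohort, spec)
        X2, y2 = pc.assemble_features(tiny_cohort, spec)
        np.testing.assert_array_equal(X1, X2)
        np.testing.assert_array_equal(y1, y2)

    def test_missing_age_reported(self, tiny_cohort):
        tiny_cohort.records[0].age = None
        try:
            with pytest.raises(ValueError, match=tiny_cohort.records[0].subject_id):
                pc.assemble_features(tiny_cohort, pc.FeatureSpec("phase10", include_age=True))
        finally:
            tiny_cohort.records[0].age = 40.0

    def test_mixed_sex_without_sex_feature_warns(self, tiny_cohort):
        with pytest.warns(UserWarning, match="sex"):
            pc.assemble_features(tiny_cohort, pc.FeatureSpec("phase10", include_sex=False))


class TestScaler:
    def test_train_columns_standardised(self, rng):
        X = rng.normal(5, 3, size=(200, 4))
        s = pc.Scaler().fit(X)
        Z = s.transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-9)

    def test_constant_column_passthrough(self, rng):
        X = rng.normal(0, 1, size=(50, 3))
        X[:, 1] = 7.0
        Z = pc.Scaler().fit(X).transform(X)
        np.testing.assert_array_equal(Z[:, 1], X[:, 1])

    def test_test_rows_use_train_statistics(self, rng):
        Xtr = rng.normal(0, 1, size=(100, 2))
        Xte = rng.normal(10, 1, size=(100, 2))
        s = pc.Scaler().fit(Xtr)
        assert pc.Scaler().fit(Xte).transform(Xte).mean() != pytest.approx(
            s.transform(Xte).mean()
        )
        assert s.transform(Xte).mean() > 5  # shifted, not re-centred


class TestResampling:
    def test_duplicate_balances_study_sizes(self, rng):
        X = rng.normal(size=(1156, 3))
        y = np.r_[np.zeros(215, int), np.ones(941, int)]
        Xb, yb = pc.oversample_duplicate(X, y, seed=0)
        assert (yb == 0).sum() == (yb == 1).sum() == 941
        assert len(yb) - len(y) == 726
        # appended rows are exact copies of minority rows
        orig = {row.tobytes() for row in X[:215]}
        assert all(row.tobytes() in orig for row in Xb[1156:])

    def test_duplicate_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        Xb, yb = pc.oversample_duplicate(X, y, seed=3)
        np.testing.assert_array_equal(Xb, X)

    def test_duplicate_seeded_reproducible(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.r_[np.zeros(5, int), np.ones(25, int)]
        a = pc.oversample_duplicate(X, y, seed=9)[0]
        b = pc.oversample_duplicate(X, y, seed=9)[0]
        np.testing.assert_array_equal(a, b)

    def test_smote_synthetic_points_on_parent_segment(self, rng):
        X = rng.normal(size=(120, 2))
        y = np.r_[np.zeros(20, int), np.ones(100, int)]
        Xb, yb, parents = pc.smote(X, y, k=5, seed=4, return_parents=True)
        assert (yb == 0).sum() == (yb == 1).sum()
        synth = Xb[len(y):]
        for s, (i, j) in zip(synth, parents):
            a, b = X[i], X[j]
            seg = b - a
            t = np.dot(s - a, seg) / np.dot(seg, seg)
            assert -1e-12 <= t <= 1 + 1e-12
            assert np.linalg.norm(s - (a + t * seg)) < 1e-12

    def test_smote_two_point_minority_collinear(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0]] + [[5.0, 5.0]] * 8)
        y = np.array([0, 0] + [1] * 8)
        with pytest.warns(UserWarning, match="reducing k"):
            Xb, yb = pc.smote(X, y, k=5, seed=0)
        synth = Xb[10:]
        # all synthetic points on the segment between the two minority rows
        for s in synth:
            assert np.cross(np.array([1.0, 2.0]), s) == pytest.approx(0.0, abs=1e-12)

    def test_undersample_study_sizes(self, rng):
        X = rng.normal(size=(1156, 2))
        y = np.r_[np.zeros(215, int), np.ones(941, int)]
        Xu, yu = pc.undersample(X, y, seed=0)
        assert (yu == 0).sum() == (yu == 1).sum() == 215
        # no new rows created
        orig = {row.tobytes() for row in X}
        assert all(row.tobytes() in orig for row in Xu)

    def test_majority_rows_never_altered(self, rng):
        X = rng.normal(size=(60, 2))
        y = np.r_[np.zeros(10, int), np.ones(50, int)]
        for fn in (pc.oversample_duplicate, pc.smote):
            Xb, yb = fn(X, y, seed=1)[:2]
            np.testing.assert_array_equal(Xb[: len(y)], X)

    def test_class_weights_formula(self):
        y = np.r_[np.zeros(215, int), np.ones(941, int)]
        w = pc.class_weights(y)
        assert w[0] == pytest.approx(1156 / 430)
        assert w[1] == pytest.approx(1156 / 1882)
        yb = np.r_[np.zeros(50, int), np.ones(50, int)]
        assert pc.class_weights(yb) == {0: 1.0, 1: 1.0}
        # scale invariance under whole-dataset duplication
        assert pc.class_weights(np.tile(y, 2)) == w


class TestModels:
    def test_mlp5_parameter_count(self):
        assert pc.build_model("mlp5", 10).n_parameters == 12769

    def test_mono_parameter_count(self):
        assert pc.build_model("mono", 10).n_parameters == 11

    def test_untrained_forward_in_unit_interval(self, rng):
        m = pc.build_model("mlp5", 6, seed=0)
        p = m.predict_proba(rng.normal(size=(40, 6)))
        assert np.all((p > 0) & (p < 1))

    def test_separable_blobs_learned(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (100, 2)), rng.normal(2, 0.5, (100, 2))])
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        m = pc.build_model("mlp5", 2, seed=0)
        pc.train(m, X, y, pc.TrainConfig(epochs=60, sampling="none",
                                         class_weighting=False, seed=0))
        assert ((m.predict_proba(X) >= 0.5) == y).mean() >= 0.95

    def test_zero_epochs_leaves_model_unchanged(self, rng):
        m = pc.build_model("mlp5", 4, seed=1)
        before = [W.copy() for W in m.W]
        X, y = rng.normal(size=(50, 4)), rng.integers(0, 2, 50)
        hist = pc.train(m, X, y, pc.TrainConfig(epochs=0, sampling="none", seed=0))
        for a, b in zip(before, m.W):
            np.testing.assert_array_equal(a, b)
        assert hist["loss"] == []

    def test_history_length_equals_epochs(self, rng):
        m = pc.build_model("mono", 3, seed=0)
        X, y = rng.normal(size=(64, 3)), rng.integers(0, 2, 64)
        hist = pc.train(m, X, y, pc.TrainConfig(epochs=7, sampling="none", seed=0))
        assert len(hist["loss"]) == len(hist["val_accuracy"]) == 7

    def test_irls_matches_sklearn_unpenalised(self, rng):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(300, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = (rng.random(300) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        ours = pc.LogisticRegressionIRLS(3).fit(X, y)
        ref = sklearn_lm.LogisticRegression(C=1e8, tol=1e-10).fit(X, y)
        np.testing.assert_allclose(ours.coef_, ref.coef_.ravel(), atol=1e-4)
        assert ours.intercept_ == pytest.approx(float(ref.intercept_[0]), abs=1e-4)


class TestMetrics:
    def test_perfect_separation(self):
        m = pc.evaluate_binary([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.5)
        assert m["sensitivity"] == m["specificity"] == m["f1"] == m["auc"] == 1.0

    def test_boundary_convention_at_cutoff(self):
        m = pc.evaluate_binary([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5)
        assert m["sensitivity"] == 1.0 and m["specificity"] == 0.0

    def test_auc_equals_pairwise_concordance(self, rng):
        for _ in range(20):
            p = rng.random(100)
            y = (rng.random(100) < 0.4).astype(int)
            if y.min() == y.max():
                continue
            pos, neg = p[y == 1], p[y == 0]
            diff = pos[:, None] - neg[None, :]
            oracle = ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / (pos.size * neg.size)
            assert pc.auc(p, y) == pytest.approx(oracle, abs=1e-12)

    def test_youden_cutoff_smallest_on_ties(self):
        p = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        # any cutoff in (0.2, 0.8] is optimal; the smallest candidate wins
        assert pc.youden_cutoff(p, y) == pytest.approx(0.8)

    def test_single_class_auc_rejected(self):
        with pytest.raises(ValueError):
            pc.auc([0.1, 0.9], [1, 1])


class TestIteratedHoldout:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_study_cohort(
            seed=3,
            n_by_stratum={
                ("male", "control"): 30, ("female", "control"): 30,
                ("male", "asthma"): 60, ("female", "asthma"): 60,
            },
        )

    def _run(self, cohort, **kw):
        defaults = dict(
            feature_spec=pc.FeatureSpec("phase10", include_sex=True),
            config=pc.TrainConfig(epochs=15, seed=0),
            protocol=pc.EvalProtocol(repeats=2, test_per_group=5),
            model_kind="mono",
        )
        defaults.update(kw)
        return pc.iterated_holdout(cohort, defaults.pop("feature_spec"),
                                   defaults.pop("config"), defaults.pop("protocol"),
                                   model_kind=defaults.pop("model_kind"))

    def test_identical_seeds_identical_reports(self, cohort):
        a = self._run(cohort)
        b = self._run(cohort)
        assert a.per_repeat == b.per_repeat
        assert a.aggregate == b.aggregate

    def test_aggregate_recomputable_from_repeats(self, cohort):
        rep = self._run(cohort, protocol=pc.EvalProtocol(repeats=5, test_per_group=5))
        vals = np.array([r["accuracy_control"] for r in rep.per_repeat])
        assert rep.aggregate["accuracy_control"]["mean"] == pytest.approx(vals.mean(), abs=1e-12)
        assert rep.aggregate["accuracy_control"]["sd"] == pytest.approx(
            vals.std(ddof=1), abs=1e-12
        )

    def test_insufficient_class_counts_rejected(self, cohort):
        with pytest.raises(ValueError, match="per class"):
            self._run(cohort, protocol=pc.EvalProtocol(repeats=1, test_per_group=60))

    def test_test_labels_never_touch_fitted_state(self, cohort):
        """Permuting test-set labels cannot change what was fitted on train."""
        X, y = pc.assemble_features(cohort, pc.FeatureSpec("phase10"))
        rng = np.random.default_rng(0)
        test_idx = np.concatenate(
            [rng.choice(np.flatnonzero(y == c), size=5, replace=False) for c in (0, 1)]
        )
        mask = np.zeros(y.size, bool)
        mask[test_idx] = True

        def fit_and_hash(y_test_permuted):
            yy = y.copy()
            yy[mask] = y_test_permuted
            scaler = pc.Scaler().fit(X[~mask])
            Xb, yb = pc.oversample_duplicate(scaler.transform(X[~mask]), yy[~mask], seed=1)
            m = pc.build_model("mono", X.shape[1], seed=1)
            pc.train(m, Xb, yb, pc.TrainConfig(epochs=5, sampling="none", seed=1))
            h = hashlib.sha256()
            for arr in [scaler.mean_, scaler.scale_, Xb, *m.W, *m.b]:
                h.update(np.ascontiguousarray(arr).tobytes())
            return h.hexdigest()

        assert fit_and_hash(y[mask]) == fit_and_hash(1 - y[mask])

    def test_perfectly_separated_classes_scored_perfectly(self):
        rng = np.random.default_rng(1)
        from tests.conftest import make_record

        records = []
        for i in range(30):
            records.append(make_record(f"c{i}", group="control",
                                       R5_in=1.0 + 0.01 * rng.random()))
        for i in range(30):
            records.append(make_record(f"a{i}", group="asthma",
                                       R5_in=9.0 + 0.01 * rng.random()))
        cohort = Cohort(records=records)
        rep = pc.iterated_holdout(
            cohort, pc.FeatureSpec("phase10", include_sex=False),
            pc.TrainConfig(epochs=40, seed=0),
            pc.EvalProtocol(repeats=1, test_per_group=5), "mlp5",
        )
        assert rep.per_repeat[0]["accuracy_control"] == 1.0
        assert rep.per_repeat[0]["accuracy_asthma"] == 1.0

    def test_youden_mode_reports_cutoff(self, cohort):
        rep = self._run(
            cohort,
            protocol=pc.EvalProtocol(repeats=2, test_per_group=5,
                                     metric_mode="youden_metrics"),
        )
        for r in rep.per_repeat:
            assert 0.0 <= r["cutoff"] <= 1.0
            assert {"sensitivity", "specificity", "f1", "auc"} <= set(r)


class TestModelContrasts:
    def test_xor_multilayer_advantage(self):
        """The depth pays off on a pattern no linear model can represent."""
        Xtr, ytr = xor_blobs(100, seed=1)
        Xte, yte = xor_blobs(50, seed=2)
        mlp = pc.build_model("mlp5", 2, seed=1)
        pc.train(mlp, Xtr, ytr, pc.TrainConfig(epochs=120, sampling="none",
                                               class_weighting=False, seed=1))
        acc_mlp = ((mlp.predict_proba(Xte) >= 0.5) == yte).mean()
        lr = pc.build_model("logreg", 2).fit(Xtr, ytr)
        acc_lr = ((lr.predict_proba(Xte) >= 0.5) == yte).mean()
        assert acc_mlp >= 0.9
        assert abs(acc_lr - 0.5) <= 0.1
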