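"""Classifier contracts, CV machinery, session-accuracy statistic."""

import numpy as np
import pytest

import mibci
from mibci.classify import (
    AccuracyCurve,
    ClassifierSpec,
    _stratified_folds,
    crossval_curve,
    run_train_test,
    session_accuracy,
    train_lda,
    train_svm,
)
from mibci.epoching import WindowGrid


def _cloud(rng, mean, n=50, scale=0.1, dim=4):
    return rng.normal(loc=mean, scale=scale, size=(n, dim))


class TestLda:
    def test_separable_clouds_classified_perfectly(self, rng):
        X = np.vstack([_cloud(rng, -1.0), _cloud(rng, 1.0)])
        y = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        clf = train_lda(X, y)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_null_training_accuracy_near_chance(self, rng):
        X = rng.normal(size=(200, 4))
        y = np.r_[np.zeros(100, bool), np.ones(100, bool)]
        clf = train_lda(X, y)
        acc = np.mean(clf.predict(X) == y)
        # training on pure noise: accuracy within a generous binomial band
        # around 1/2 (training optimism shifts it slightly upward)
        assert 0.4 < acc < 0.75

    def test_decision_invariant_to_common_affine_shift(self, rng):
        X = np.vstack([_cloud(rng, -0.3), _cloud(rng, 0.3)])
        y = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        shift = rng.normal(size=4) * 10
        pred_a = train_lda(X, y).predict(X)
        pred_b = train_lda(X + shift, y).predict(X + shift)
        np.testing.assert_array_equal(pred_a, pred_b)

    def test_agrees_with_sklearn_reference(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([_cloud(rng, -0.2, scale=0.5), _cloud(rng, 0.2, scale=0.5)])
        y = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        ours = train_lda(X, y).predict(X)
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(X)
        assert np.mean(ours == ref) > 0.98

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_lda(rng.normal(size=(10, 4)), np.ones(10, bool))


class TestSvm:
    def test_linearly_separable_zero_training_error(self, rng):
        X = np.vstack([_cloud(rng, -1.0), _cloud(rng, 1.0)])
        y = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        clf = train_svm(X, y, ClassifierSpec(kind="SVM_LINEAR"))
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_xor_requires_the_cubic_kernel(self, rng):
        centers = np.array([[-1, -1], [1, 1], [-1, 1], [1, -1]], dtype=float)
        X = np.vstack([c + rng.normal(scale=0.05, size=(25, 2)) for c in centers])
        y = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        linear = train_svm(X, y, ClassifierSpec(kind="SVM_LINEAR"))
        poly = train_svm(X, y, ClassifierSpec(kind="SVM_POLY3"))
        # a linear boundary can at best isolate one corner (75%); the cubic
        # kernel separates XOR exactly
        assert np.mean(linear.predict(X) == y) <= 0.76
        assert np.mean(poly.predict(X) == y) == 1.0

    def test_duplicating_training_points_preserves_decisions(self, rng):
        X = np.vstack([_cloud(rng, -0.5, n=20), _cloud(rng, 0.5, n=20)])
        y = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        probe = rng.normal(size=(50, 4))
        a = train_svm(X, y, ClassifierSpec(kind="SVM_LINEAR")).predict(probe)
        b = train_svm(
            np.vstack([X, X]), np.r_[y, y], ClassifierSpec(kind="SVM_LINEAR")
        ).predict(probe)
        np.testing.assert_array_equal(a, b)

    def test_poly_degree_is_pinned(self):
        with pytest.raises(ValueError):
            ClassifierSpec(kind="SVM_POLY3", poly_degree=2)


class TestAccuracyCurve:
    def test_session_accuracy_is_the_maximum(self):
        curve = AccuracyCurve(starts=(0.0, 0.2, 0.4), acc=np.array([0.5, 0.9, 0.7]))
        assert session_accuracy(curve) == 0.9
        assert curve.argmax_start == 0.2

    def test_tie_breaks_to_earliest_start(self):
        curve = AccuracyCurve(starts=(-2.0, 0.0, 2.0), acc=np.array([0.6, 0.6, 0.6]))
        assert curve.argmax_start == -2.0

    def test_adding_a_window_never_decreases_the_maximum(self, rng):
        acc = rng.uniform(size=12)
        a = AccuracyCurve(starts=tuple(np.arange(12.0)), acc=acc)
        b = AccuracyCurve(starts=tuple(np.arange(13.0)), acc=np.r_[acc, 0.3])
        assert b.session_accuracy >= a.session_accuracy

    def test_out_of_range_accuracies_rejected(self):
        with pytest.raises(ValueError):
            AccuracyCurve(starts=(0.0,), acc=np.array([1.2]))


class TestCrossvalCurve:
    def test_strong_erd_session_decodes_above_85_percent(self, erd_epochs):
        grid = mibci.window_grid(2.0)
        curve = crossval_curve(erd_epochs, grid, ClassifierSpec(kind="LDA", seed=0))
        assert curve.session_accuracy >= 0.85
        # the best window should lie inside the imagery interval
        assert -1.0 <= curve.argmax_start <= 5.0

    def test_reproducible_given_spec(self, small_epochs):
        grid = mibci.window_grid(2.0)
        spec = ClassifierSpec(kind="LDA", seed=3)
        a = crossval_curve(small_epochs, grid, spec, k=4)
        b = crossval_curve(small_epochs, grid, spec, k=4)
        np.testing.assert_array_equal(a.acc, b.acc)

    def test_too_few_trials_per_class_rejected(self, small_epochs):
        grid = mibci.window_grid(2.0)
        with pytest.raises(ValueError, match="fold"):
            crossval_curve(small_epochs, grid, ClassifierSpec(), k=20)

    def test_folds_are_stratified_and_seeded(self):
        y = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        folds = _stratified_folds(y, 4, np.random.default_rng(0))
        for f in range(4):
            assert np.sum((folds == f) & y) == 5
            assert np.sum((folds == f) & ~y) == 5

    def test_no_test_trial_enters_fitting(self, small_epochs, monkeypatch):
        """Corrupting one fold's trials must not change what any other
        fold's training sees: the training-feature hashes for fold f are
        identical whether or not fold f's trials are altered."""
        import mibci.classify as mod

        grid = WindowGrid(T=2.0, step=0.2, starts=(0.0, 1.0))
        spec = ClassifierSpec(kind="LDA", seed=9)
        k = 4
        y = small_epochs.label_array
        folds = _stratified_folds(y, k, np.random.default_rng(spec.seed))

        def capture(epochs):
            seen = []
            orig = mod._train

            def wrapper(X, yy, sp):
                seen.append(hash(X.tobytes()))
                return orig(X, yy, sp)

            monkeypatch.setattr(mod, "_train", wrapper)
            crossval_curve(epochs, grid, spec, k=k)
            monkeypatch.setattr(mod, "_train", orig)
            return np.array(seen).reshape(len(grid.starts), k)

        baseline = capture(small_epochs)
        corrupt_fold = 2
        data = small_epochs.data.copy()
        data[folds == corrupt_fold] = np.random.default_rng(1).normal(
            size=data[folds == corrupt_fold].shape
        )
        corrupted_epochs = small_epochs.select(np.arange(len(y)))
        object.__setattr__(corrupted_epochs, "data", data)
        altered = capture(corrupted_epochs)
        # fold `corrupt_fold` was held out: its training set excludes the
        # corrupted trials, so its hashes must match the baseline exactly
        np.testing.assert_array_equal(
            baseline[:, corrupt_fold], altered[:, corrupt_fold]
        )
        # sanity: the other folds trained on corrupted data and must differ
        assert not np.array_equal(baseline, altered)


class TestRunTrainTest:
    @pytest.fixture(scope="class")
    def runs(self):
        cfg = mibci.SimulationConfig(seed=21, n_trials_per_class=15)
        recs = mibci.simulate_multirun(cfg, 3)
        return [mibci.extract_epochs(mibci.preprocess(r)) for r in recs]

    def test_held_out_runs_decode_well_with_strong_erd(self, runs):
        grid = mibci.window_grid(2.0)
        curves = run_train_test(runs[0], runs[1:], grid, ClassifierSpec(kind="LDA"))
        assert len(curves) == 2
        for c in curves:
            assert c.session_accuracy >= 0.8

    def test_training_run_scores_itself_at_least_as_well(self, runs):
        grid = mibci.window_grid(2.0)
        self_curve, test_curve = run_train_test(
            runs[0], [runs[0], runs[1]], grid, ClassifierSpec(kind="LDA")
        )
        assert self_curve.session_accuracy >= test_curve.session_accuracy - 0.05


class TestDecoderFrontend:
    def test_summary_reports_session_accuracy(self, small_epochs):
        res = mibci.SlidingWindowDecoder(
            small_epochs, classifier="LDA", folds=4, seed=0
        ).fit()
        text = res.summary()
        assert "session accuracy" in text
        assert f"{res.session_accuracy_pct:.2f}%" in text
        assert res.curve.classifier == "LDA"

    def test_percentage_rounding_convention(self, small_epochs):
        res = mibci.SlidingWindowDecoder(
            small_epochs, classifier="LDA", folds=4, seed=0
        ).fit()
        assert res.session_accuracy_pct == pytest.approx(
            100 * res.session_accuracy, abs=0.005
        )
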