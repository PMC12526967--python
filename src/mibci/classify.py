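"""LDA/SVM decoding over the sliding-window grid.

For every window position, CSP and a classifier are fitted inside each
cross-validation training partition only (no test trial ever touches CSP
fitting or feature standardization), held-out trials are scored, and the
fold-mean accuracy forms one point of the accuracy curve.  The session
accuracy is the maximum of that curve (ties broken toward the earliest
window).  Folds are class-stratified, assigned once per epoch set from the
classifier seed, and reused across all window positions, so the
max-over-windows statistic is not inflated by per-window refold variance.

Implementation note: log-variance features are quadratic forms on per-trial
covariances, so each window's trial covariances are computed once and both
CSP fitting and feature extraction reuse them across folds (and across
label permutations in the permutation null); this is numerically identical
to projecting the time series per fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .csp import (
    CSPModel,
    features_from_covariances,
    fit_csp_from_covariances,
    select_filters,
    trial_covariances,
)
from .epoching import EpochSet, WindowGrid, slice_window

__all__ = [
    "ClassifierSpec",
    "AccuracyCurve",
    "train_lda",
    "train_svm",
    "crossval_curve",
    "session_accuracy",
    "run_train_test",
    "permutation_null",
    "SlidingWindowDecoder",
    "DecodingResults",
]

_KINDS = ("LDA", "SVM_LINEAR", "SVM_POLY3")


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier family and hyperparameters.

    ``kind`` is one of LDA, SVM_LINEAR, SVM_POLY3.  SVMs use soft-margin
    cost ``svm_cost`` on train-standardized features; the polynomial kernel
    is the inhomogeneous ``(gamma <x, x'> + 1)^3`` with
    ``gamma = 1/n_features``.  ``seed`` drives the fold assignment.
    """

    kind: str = "LDA"
    svm_cost: float = 1.0
    poly_degree: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        kind = self.kind.upper()
        object.__setattr__(self, "kind", kind)
        if kind not in _KINDS:
            raise ValueError(f"classifier kind must be one of {_KINDS}")
        if kind == "SVM_POLY3" and self.poly_degree != 3:
            raise ValueError("SVM_POLY3 fixes the polynomial degree at 3")


@dataclass(frozen=True)
class AccuracyCurve:
    """Window-start-time -> CV-mean accuracy, with the session statistic."""

    starts: tuple[float, ...]
    acc: np.ndarray = field(repr=False)
    folds: int = 10
    classifier: str = "LDA"

    def __post_init__(self) -> None:
        acc = np.asarray(self.acc, dtype=float)
        object.__setattr__(self, "acc", acc)
        if acc.ndim != 1 or acc.size != len(self.starts):
            raise ValueError("one accuracy per window start required")
        if acc.size == 0:
            raise ValueError("accuracy curve is empty")
        if np.any((acc < 0) | (acc > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def session_accuracy(self) -> float:
        """Max over window positions (fraction in [0, 1])."""
        return float(self.acc.max())

    @property
    def argmax_start(self) -> float:
        """Earliest window start achieving the maximum."""
        return self.starts[int(np.argmax(self.acc))]


def session_accuracy(curve: AccuracyCurve) -> float:
    """Session accuracy: maximum of the window-wise CV-mean accuracies."""
    return curve.session_accuracy


# ---------------------------------------------------------------------------
# classifiers


class _FittedLDA:
    """Two-class Fisher discriminant, pooled covariance, equal priors."""

    def __init__(self, w: np.ndarray, b: float) -> None:
        self.w = w
        self.b = b

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b > 0


def train_lda(X: np.ndarray, y: np.ndarray) -> _FittedLDA:
    """Fisher LDA on features ``X`` with boolean targets ``y``.

    Pooled within-class covariance with a ``1e-9 trace`` ridge; equal
    priors, so the decision boundary passes through the class-mean midpoint.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if np.sum(y) < 2 or np.sum(~y) < 2:
        raise ValueError("LDA needs at least 2 trials per class")
    x0, x1 = X[~y], X[y]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    r0, r1 = x0 - m0, x1 - m1
    pooled = (r0.T @ r0 + r1.T @ r1) / (X.shape[0] - 2)
    pooled = pooled + 1e-9 * np.trace(pooled) * np.eye(X.shape[1])
    try:
        w = np.linalg.solve(pooled, m1 - m0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled covariance singular after ridge"
        ) from err
    return _FittedLDA(w=w, b=float(-w @ (m0 + m1) / 2))


class _FittedSVM:
    def __init__(self, svc, mean: np.ndarray, scale: np.ndarray) -> None:
        self.svc = svc
        self.mean = mean
        self.scale = scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict((X - self.mean) / self.scale).astype(bool)


def train_svm(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> _FittedSVM:
    """Soft-margin SVM (linear or inhomogeneous cubic kernel).

    Features are standardized with training-partition mean/SD before the
    kernel; the fit is deterministic given the spec.
    """
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if np.sum(y) < 1 or np.sum(~y) < 1:
        raise ValueError("SVM needs both classes present")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    if spec.kind == "SVM_LINEAR":
        svc = SVC(C=spec.svm_cost, kernel="linear")
    else:
        svc = SVC(
            C=spec.svm_cost,
            kernel="poly",
            degree=spec.poly_degree,
            gamma=1.0 / X.shape[1],
            coef0=1.0,
        )
    svc.fit(Xs, y)
    if not svc.fit_status_ == 0:
        raise RuntimeError(f"SVM solver did not converge (status {svc.fit_status_})")
    return _FittedSVM(svc, mean, scale)


def _train(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    if spec.kind == "LDA":
        return train_lda(X, y)
    return train_svm(X, y, spec)


# ---------------------------------------------------------------------------
# cross-validation machinery


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold index per trial, class-stratified, from a seeded shuffle."""
    folds = np.empty(y.size, dtype=int)
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"{k}-fold CV needs at least {k} trials per class, got {idx.size}"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _window_cov_tensors(epochs: EpochSet, grid: WindowGrid) -> list[np.ndarray]:
    """Per-window trace-normalized trial covariances (the CV sufficient stats)."""
    return [
        trial_covariances(slice_window(epochs, start, grid.T), normalize=True)
        for start in grid.starts
    ]


def _fold_accuracy(
    covs: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    spec: ClassifierSpec,
    m: int,
) -> float:
    c_l = covs[train & ~y].mean(axis=0)
    c_r = covs[train & y].mean(axis=0)
    model = select_filters(fit_csp_from_covariances(c_l, c_r), m=m)
    F = features_from_covariances(model, covs)
    clf = _train(F[train], y[train], spec)
    pred = clf.predict(F[test])
    return float(np.mean(pred == y[test]))


def _curve_from_covs(
    cov_list: list[np.ndarray],
    y: np.ndarray,
    folds: np.ndarray,
    spec: ClassifierSpec,
    k: int,
    m: int,
) -> np.ndarray:
    acc = np.empty(len(cov_list))
    for wi, covs in enumerate(cov_list):
        fold_acc = np.empty(k)
        for f in range(k):
            test = folds == f
            fold_acc[f] = _fold_accuracy(covs, y, ~test, test, spec, m)
        acc[wi] = fold_acc.mean()
    return acc


def crossval_curve(
    epochs: EpochSet,
    grid: WindowGrid,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 10,
    m: int = 2,
) -> AccuracyCurve:
    """Stratified k-fold CV accuracy at every window position.

    The fold assignment is drawn once from ``spec.seed`` and reused across
    all window positions.  Per position and fold, CSP (and, for SVMs, the
    feature standardization) is fitted on the training trials only.
    """
    y = epochs.label_array
    rng = np.random.default_rng(spec.seed)
    folds = _stratified_folds(y, k, rng)
    cov_list = _window_cov_tensors(epochs, grid)
    acc = _curve_from_covs(cov_list, y, folds, spec, k, m)
    return AccuracyCurve(starts=grid.starts, acc=acc, folds=k, classifier=spec.kind)


def permutation_null(
    epochs: EpochSet,
    grid: WindowGrid,
    spec: ClassifierSpec = ClassifierSpec(),
    k: int = 10,
    n_perm: int = 100,
    seed: int = 0,
    m: int = 2,
) -> np.ndarray:
    """Null distribution of the session accuracy under label permutation.

    Labels are permuted ``n_perm`` times; for each permutation the full
    accuracy curve is recomputed (folds re-stratified on the permuted
    labels) and its maximum retained, giving the max-statistic null that a
    session accuracy must exceed to indicate class information.
    """
    y = epochs.label_array
    rng = np.random.default_rng(seed)
    cov_list = _window_cov_tensors(epochs, grid)
    out = np.empty(n_perm)
    for p in range(n_perm):
        y_perm = rng.permutation(y)
        folds = _stratified_folds(y_perm, k, rng)
        out[p] = _curve_from_covs(cov_list, y_perm, folds, spec, k, m).max()
    return out


def run_train_test(
    train_run: EpochSet,
    test_runs: list[EpochSet],
    grid: WindowGrid,
    spec: ClassifierSpec = ClassifierSpec(),
    m: int = 2,
) -> list[AccuracyCurve]:
    """Calibrate on one run, score held-out runs per window position.

    CSP and the classifier are fitted once per window on the full training
    run; each test run is scored at the same positions.  No test sample
    enters fitting.
    """
    y_train = train_run.label_array
    cov_train = _window_cov_tensors(train_run, grid)
    cov_tests = [_window_cov_tensors(run, grid) for run in test_runs]
    accs = np.zeros((len(test_runs), len(grid)))
    for wi in range(len(grid)):
        covs = cov_train[wi]
        c_l = covs[~y_train].mean(axis=0)
        c_r = covs[y_train].mean(axis=0)
        model = select_filters(fit_csp_from_covariances(c_l, c_r), m=m)
        clf = _train(features_from_covariances(model, covs), y_train, spec)
        for ri, run in enumerate(test_runs):
            F = features_from_covariances(model, cov_tests[ri][wi])
            accs[ri, wi] = float(np.mean(clf.predict(F) == run.label_array))
    return [
        AccuracyCurve(starts=grid.starts, acc=accs[ri], folds=1, classifier=spec.kind)
        for ri in range(len(test_runs))
    ]


# ---------------------------------------------------------------------------
# model / results front end


class SlidingWindowDecoder:
    """Model: sliding-window CSP + classifier decoding of one epoch set.

    Parameters
    ----------
    epochs
        Labeled 9-s trials (both classes present).
    window_length, step
        Analysis window geometry in seconds (T = 2 or 3, step 0.2 in the
        study protocol).
    classifier
        A :class:`ClassifierSpec` or one of ``"LDA"``, ``"SVM_LINEAR"``,
        ``"SVM_POLY3"``.
    folds
        Cross-validation folds (10 in the study).
    seed
        Overrides the spec seed for fold assignment when given.
    """

    def __init__(
        self,
        epochs: EpochSet,
        window_length: float = 2.0,
        step: float = 0.2,
        classifier: ClassifierSpec | str = "LDA",
        folds: int = 10,
        seed: int | None = None,
        m: int = 2,
    ) -> None:
        from .epoching import window_grid
        from .recording import EPOCH_START_S, EPOCH_STOP_S

        if isinstance(classifier, str):
            classifier = ClassifierSpec(kind=classifier)
        if seed is not None:
            classifier = ClassifierSpec(
                kind=classifier.kind,
                svm_cost=classifier.svm_cost,
                poly_degree=classifier.poly_degree,
                seed=seed,
            )
        self.epochs = epochs
        self.spec = classifier
        self.folds = folds
        self.m = m
        self.grid = window_grid(
            window_length,
            step,
            span=(epochs.time0, epochs.time0 + epochs.n_samples / epochs.fs),
            fs=epochs.fs,
        )
        if epochs.n_trials == 0:
            raise ValueError("cannot decode an empty epoch set")

    def fit(self) -> "DecodingResults":
        """Run the cross-validated sweep and return the results object."""
        curve = crossval_curve(self.epochs, self.grid, self.spec, self.folds, self.m)
        return DecodingResults(self, curve)

    def fit_transfer(self, test_runs: list[EpochSet]) -> list["DecodingResults"]:
        """Calibrate on this model's epochs and score each held-out run."""
        curves = run_train_test(self.epochs, test_runs, self.grid, self.spec, self.m)
        return [DecodingResults(self, c) for c in curves]


class DecodingResults:
    """Fitted accuracy curve with the session-accuracy statistic."""

    def __init__(self, model: SlidingWindowDecoder, curve: AccuracyCurve) -> None:
        self.model = model
        self.curve = curve

    @property
    def session_accuracy(self) -> float:
        return self.curve.session_accuracy

    @property
    def session_accuracy_pct(self) -> float:
        """Percentage rounded half-up to 2 decimals (report convention)."""
        import decimal

        return float(
            decimal.Decimal(100 * self.curve.session_accuracy).quantize(
                decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
            )
        )

    def summary(self) -> str:
        c = self.curve
        lines = [
            "Sliding-window decoding results",
            f"  classifier        : {c.classifier}",
            f"  window length     : {self.model.grid.T:g} s, step {self.model.grid.step:g} s",
            f"  folds             : {c.folds}",
            f"  windows evaluated : {len(c.starts)}",
            f"  session accuracy  : {self.session_accuracy_pct:.2f}%",
            f"  best window start : {c.argmax_start:+.1f} s (cue-relative)",
            f"  above 60% level   : {'yes' if c.session_accuracy > 0.6 else 'no'}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Accuracy-vs-window-start curve (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve.starts, 100 * self.curve.acc, marker=".")
        ax.axhline(60, ls="--", color="gray", lw=0.8)
        ax.axvspan(0, 5, color="tab:orange", alpha=0.1, label="MI interval")
        ax.set_xlabel("window start (s, cue-relative)")
        ax.set_ylabel("CV accuracy (%)")
        ax.set_title(f"{self.curve.classifier}, T={self.model.grid.T:g} s")
        return ax

    def __str__(self) -> str:
        return self.summary()
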