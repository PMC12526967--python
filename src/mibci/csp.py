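"""Common Spatial Patterns and normalized log-variance features.

CSP finds spatial filters w maximizing the variance ratio between two
classes by simultaneously diagonalizing the class covariance matrices
C_L and C_R: whiten by the composite C_L + C_R, eigendecompose the whitened
C_L, and back-project.  The resulting projection W (rows = filters)
satisfies W C_L W^T = diag(lambda) and W C_R W^T = diag(1 - lambda) with
eigenvalues sorted descending, so the first filters maximize left-class
variance and the last maximize right-class variance.  With 16 channels the
first 2 and last 2 filters are retained, and each windowed trial X yields
four features

    f_r = log( VAR_r / sum_{r'=1..4} VAR_{r'} ),   Z = W_sel X,

the log of each retained component's share of the summed component
variance (the exp-features of a trial therefore sum to 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epoching import EpochSet
from .montage import Montage

#: Ridge added to the class covariances before whitening, as a fraction of
#: mean channel variance.  CAR leaves the channel-sum direction with zero
#: variance, so the composite is always rank-deficient by one after CAR;
#: the ridge only needs to dominate that direction's float-level noise
#: (~1e-16 relative), and a small value keeps the perturbation of the
#: eigenvalue pairing identity below 1e-8.  Escalates on failure.
RIDGE_EPS = 1e-10
RIDGE_LADDER = (1e-10, 1e-8, 1e-4)

__all__ = [
    "CSPModel",
    "FeatureMatrix",
    "class_covariance",
    "fit_csp",
    "fit_csp_from_covariances",
    "select_filters",
    "logvar_features",
    "trial_covariances",
    "csp_topomap_export",
]


@dataclass(frozen=True)
class CSPModel:
    """Fitted CSP decomposition.

    ``W`` is the channels x channels projection (rows are spatial filters,
    eigenvalue-sorted descending); ``eigvals`` are the left-class variance
    shares in [0, 1]; ``patterns = W^{-1}`` holds the spatial patterns as
    columns (for topographic maps); ``selected`` indexes the retained
    filters (first m and last m rows).
    """

    W: np.ndarray = field(repr=False)
    eigvals: np.ndarray
    patterns: np.ndarray = field(repr=False)
    selected: tuple[int, ...] = ()
    channel_names: tuple[str, ...] = ()

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def W_selected(self) -> np.ndarray:
        if not self.selected:
            raise ValueError("no filters selected; call select_filters first")
        return self.W[list(self.selected)]


@dataclass(frozen=True)
class FeatureMatrix:
    """Trials x 2m log-variance features with class labels."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] != len(self.labels):
            raise ValueError("feature matrix must be trials x features with labels")


def trial_covariances(epochs: EpochSet, normalize: bool = True) -> np.ndarray:
    """Per-trial spatial covariance over time, optionally trace-normalized.

    The temporal mean is removed per channel; normalization divides each
    trial's covariance by its trace (standard CSP practice, equalizing
    per-trial power before averaging).
    """
    X = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    covs = np.einsum("tcs,tds->tcd", X, X) / X.shape[2]
    if normalize:
        traces = np.einsum("tcc->t", covs)
        good = traces > 0
        if not np.all(good):
            warnings.warn(
                f"excluding {int(np.sum(~good))} zero-variance trial(s)",
                stacklevel=2,
            )
            covs = covs[good]
            traces = traces[good]
        covs = covs / traces[:, None, None]
    return covs


def class_covariance(trials: EpochSet) -> np.ndarray:
    """Average trace-normalized spatial covariance of one class's trials."""
    if trials.n_trials < 2:
        raise ValueError("class covariance needs at least 2 trials")
    covs = trial_covariances(trials, normalize=True)
    if covs.shape[0] < 2:
        raise ValueError("fewer than 2 usable trials after exclusions")
    return covs.mean(axis=0)


def fit_csp_from_covariances(
    cov_left: np.ndarray, cov_right: np.ndarray, channel_names: tuple[str, ...] = ()
) -> CSPModel:
    """Simultaneous diagonalization of two class covariance matrices.

    Whitens by the (ridge-regularized) composite ``C_L + C_R``, eigendecomposes
    the whitened ``C_L`` and back-projects, yielding W with
    ``W (C_L + C_R) W^T = I``.  Filters are sign-fixed so each pattern's
    largest-magnitude entry is positive.
    """
    c_l = np.asarray(cov_left, dtype=float)
    c_r = np.asarray(cov_right, dtype=float)
    n = c_l.shape[0]
    mean_var = np.trace(c_l + c_r) / n
    for eps in RIDGE_LADDER:
        # The ridge is split between the class covariances (not only the
        # composite): a direction with zero variance in both classes (the
        # channel-sum after CAR) then gets a whitened eigenvalue of exactly
        # 1/2 and sorts to the middle, so it is never selected.
        ridge = 0.5 * eps * mean_var * np.eye(n)
        c_l = np.asarray(cov_left, dtype=float) + ridge
        c_r = np.asarray(cov_right, dtype=float) + ridge
        reg = c_l + c_r
        evals, evecs = np.linalg.eigh(reg)
        if evals[0] > 1e-12 * evals[-1]:
            if eps != RIDGE_EPS:
                warnings.warn(
                    f"composite covariance ill-conditioned; ridge escalated to {eps:g}",
                    stacklevel=2,
                )
            break
    else:
        raise np.linalg.LinAlgError(
            "composite covariance is rank-deficient beyond regularization"
        )
    whitener = evecs / np.sqrt(evals)  # columns scaled: P = E D^{-1/2}
    s_l = whitener.T @ c_l @ whitener
    s_l = (s_l + s_l.T) / 2
    lam, u = np.linalg.eigh(s_l)
    order = np.argsort(lam)[::-1]  # descending left-class variance share
    lam = lam[order]
    W = (whitener @ u[:, order]).T  # rows are filters
    patterns = np.linalg.inv(W)
    # sign convention: largest-|.| pattern entry positive per filter
    signs = np.sign(patterns[np.argmax(np.abs(patterns), axis=0), np.arange(n)])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    patterns = patterns * signs[None, :]
    return CSPModel(
        W=W,
        eigvals=np.clip(lam, 0.0, 1.0),
        patterns=patterns,
        channel_names=tuple(channel_names),
    )


def fit_csp(left: EpochSet, right: EpochSet) -> CSPModel:
    """Fit CSP on the two classes' windowed trials."""
    if left.n_trials < 2 or right.n_trials < 2:
        raise ValueError("CSP needs at least 2 trials per class")
    return fit_csp_from_covariances(
        class_covariance(left), class_covariance(right), left.channel_names
    )


def select_filters(model: CSPModel, m: int = 2) -> CSPModel:
    """Retain the first m and last m eigenvalue-sorted filters."""
    n = model.n_channels
    if 2 * m > n:
        raise ValueError(f"cannot select 2m={2 * m} filters from {n} channels")
    selected = tuple(range(m)) + tuple(range(n - m, n))
    return replace(model, selected=selected)


def logvar_features(model: CSPModel, epochs: EpochSet) -> FeatureMatrix:
    """Normalized log-variance features of each trial.

    Per trial: project onto the selected filters, take each component's
    temporal variance, and log its share of the summed component variance.
    Invariant to any positive rescaling of a trial's signal.
    """
    covs = trial_covariances(epochs, normalize=False)
    values = features_from_covariances(model, covs)
    return FeatureMatrix(values=values, labels=tuple(epochs.labels))


def features_from_covariances(model: CSPModel, covs: np.ndarray) -> np.ndarray:
    """Log-variance features computed from per-trial covariances.

    The temporal variance of component r is the quadratic form
    ``w_r C w_r^T`` on the trial covariance C, so features need no
    time-domain projection.  The same relative ridge used when fitting is
    added to each trial covariance, which keeps the variance of a filter
    spanning a rank-deficient direction (the channel sum after CAR) finite
    and uninformative instead of producing log(0); the perturbation of
    well-conditioned components is O(1e-8) and features remain invariant to
    trial-wise amplitude scaling.  Used by :func:`logvar_features` and the
    cross-validation fast path.
    """
    w = model.W_selected
    var = np.einsum("rc,tcd,rd->tr", w, covs, w)
    n = covs.shape[1]
    delta = 0.5 * RIDGE_EPS * np.einsum("tcc->t", covs) / n  # per-trial ridge
    var = var + delta[:, None] * np.einsum("rc,rc->r", w, w)[None, :]
    total = var.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("zero total component variance in a trial")
    return np.log(var / total[:, None])


def csp_topomap_export(model: CSPModel, montage: Montage) -> pd.DataFrame:
    """Per-channel weights of each selected filter's spatial pattern.

    One row per montage channel with its 2-D position and one column per
    selected filter (named by rank and eigenvalue), ready for topographic
    plotting.
    """
    if not model.selected:
        model = select_filters(model)
    rows = {
        "channel": list(montage.channel_names),
        "x": montage.positions[:, 0],
        "y": montage.positions[:, 1],
    }
    for idx in model.selected:
        rows[f"filter_{idx + 1} (lambda={model.eigvals[idx]:.3f})"] = model.patterns[
            :, idx
        ]
    return pd.DataFrame(rows)
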