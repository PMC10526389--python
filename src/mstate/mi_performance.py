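"""Motor-imagery session performance: CSP features, cross-validated
classification accuracy, and the high/low grouping.

The accuracy pipeline is stratified 10-fold cross-validation with CSP refit
inside every training fold (no leakage), standardized log-variance features,
and a linear-kernel SVM. A session is "high" iff its mean accuracy exceeds
75% (strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .eeg_core import EpochSet
from .errors import DegenerateMapError, ParameterError

logger = logging.getLogger(__name__)

HIGH_GROUP_THRESHOLD = 75.0  # percent, strict


@dataclass(frozen=True)
class CspModel:
    """Spatial filters (2m x channels) retaining the m most discriminative
    components from each end of the generalized eigenvalue spectrum."""

    filters: np.ndarray
    m: int
    eigenvalues: np.ndarray  # class-1 share of variance per retained filter

    @property
    def n_components(self) -> int:
        return self.filters.shape[0]


@dataclass(frozen=True)
class SessionPerformance:
    subject_id: str
    session_id: str
    accuracy: float      # percent
    accuracy_sd: float   # percent, across folds
    group: str           # "high" | "low"

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 100.0:
            raise ParameterError("accuracy must be in [0, 100]")
        expected = "high" if self.accuracy > HIGH_GROUP_THRESHOLD else "low"
        if self.group != expected:
            raise ParameterError(
                f"group {self.group!r} inconsistent with accuracy {self.accuracy}"
            )


def _epoch_array(epochs: EpochSet | np.ndarray) -> np.ndarray:
    arr = epochs.epochs if isinstance(epochs, EpochSet) else np.asarray(epochs, float)
    if arr.ndim != 3:
        raise ParameterError("epochs must be (n, channels, samples)")
    return arr


def _epoch_scatters(epochs: np.ndarray) -> np.ndarray:
    """Per-epoch scatter matrices E E^T of channel-centered epochs."""
    centered = epochs - epochs.mean(axis=2, keepdims=True)
    return np.einsum("ncs,nds->ncd", centered, centered)


def _class_covariance_from_scatters(
    scatters: np.ndarray, ridge: float = 1e-8
) -> np.ndarray:
    """Mean of trace-normalized per-epoch covariances, ridge-stabilized."""
    c = scatters.shape[1]
    traces = np.trace(scatters, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise DegenerateMapError("zero-variance epoch in covariance estimate")
    cov = (scatters / traces[:, None, None]).mean(axis=0)
    if np.linalg.matrix_rank(cov) < c:
        logger.warning("rank-deficient class covariance; applying ridge")
    return cov + ridge * np.trace(cov) / c * np.eye(c)


def _class_covariance(epochs: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    return _class_covariance_from_scatters(_epoch_scatters(epochs), ridge)


def fit_csp(
    epochs_left: EpochSet | np.ndarray,
    epochs_right: EpochSet | np.ndarray,
    m: int = 3,
) -> CspModel:
    """Common spatial patterns from two classes of epochs.

    Solves ``Sigma_left w = lambda (Sigma_left + Sigma_right) w`` and keeps
    the ``m`` eigenvectors from each end of the spectrum. Each filter's sign
    is fixed so its largest-magnitude coefficient is positive.
    """
    xl = _epoch_array(epochs_left)
    xr = _epoch_array(epochs_right)
    if xl.shape[0] < 2 or xr.shape[0] < 2:
        raise ParameterError("need at least 2 epochs per class")
    if xl.shape[1] != xr.shape[1]:
        raise ParameterError("channel counts differ between classes")
    c = xl.shape[1]
    if 2 * m > c:
        raise ParameterError(f"2m={2 * m} exceeds channel count {c}")
    return _csp_from_covariances(_class_covariance(xl), _class_covariance(xr), m)


def _csp_from_covariances(s1: np.ndarray, s2: np.ndarray, m: int) -> CspModel:
    if 2 * m > s1.shape[0]:
        raise ParameterError(f"2m={2 * m} exceeds channel count {s1.shape[0]}")
    eigvals, eigvecs = scipy.linalg.eigh(s1, s1 + s2)
    order = np.argsort(eigvals)  # ascending: right-dominant first
    keep = np.concatenate([order[:m], order[-m:][::-1]])
    w = eigvecs[:, keep].T
    signs = np.sign(w[np.arange(2 * m), np.argmax(np.abs(w), axis=1)])
    signs[signs == 0] = 1.0
    return CspModel(filters=w * signs[:, None], m=m, eigenvalues=eigvals[keep])


def csp_features(model: CspModel, epochs: EpochSet | np.ndarray) -> np.ndarray:
    """Normalized log-variance features: for component j,
    log(var_j / sum_j' var_j')."""
    x = _epoch_array(epochs)
    if x.shape[1] != model.filters.shape[1]:
        raise ParameterError("epoch channel count does not match CSP model")
    return _features_from_scatters(model.filters, _epoch_scatters(x))


def _features_from_scatters(filters: np.ndarray, scatters: np.ndarray) -> np.ndarray:
    # variance of the filtered component is w S w^T up to the 1/n factor,
    # which cancels in the ratio normalization
    var = np.einsum("jc,ncd,jd->nj", filters, scatters, filters)
    total = var.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise DegenerateMapError("zero-variance epoch in feature extraction")
    return np.log(var / total)


def session_accuracy(
    epochs_left: EpochSet | np.ndarray,
    epochs_right: EpochSet | np.ndarray,
    folds: int = 10,
    seed: int | None = None,
    m: int = 3,
    subject_id: str = "",
    session_id: str = "",
) -> SessionPerformance:
    """Stratified k-fold CSP + linear-SVM accuracy for one session."""
    xl = _epoch_array(epochs_left)
    xr = _epoch_array(epochs_right)
    if xl.shape[0] < folds or xr.shape[0] < folds:
        raise ParameterError(
            f"need at least {folds} epochs per class for {folds}-fold CV"
        )
    x = np.concatenate([xl, xr])
    y = np.concatenate([np.zeros(len(xl), int), np.ones(len(xr), int)])
    scatters = _epoch_scatters(x)  # shared across folds; CSP still refit per fold
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_acc = []
    for train, test in skf.split(x, y):
        csp = _csp_from_covariances(
            _class_covariance_from_scatters(scatters[train][y[train] == 0]),
            _class_covariance_from_scatters(scatters[train][y[train] == 1]),
            m,
        )
        f_train = _features_from_scatters(csp.filters, scatters[train])
        f_test = _features_from_scatters(csp.filters, scatters[test])
        mu = f_train.mean(axis=0)
        sd = f_train.std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel="linear", C=1.0)
        clf.fit((f_train - mu) / sd, y[train])
        fold_acc.append(float(np.mean(clf.predict((f_test - mu) / sd) == y[test])))
    acc = float(np.mean(fold_acc) * 100.0)
    sd = float(np.std(fold_acc, ddof=1) * 100.0)
    group = "high" if acc > HIGH_GROUP_THRESHOLD else "low"
    if isinstance(epochs_left, EpochSet):
        subject_id = subject_id or epochs_left.subject_id
        session_id = session_id or epochs_left.session_id
    return SessionPerformance(
        subject_id=subject_id,
        session_id=session_id,
        accuracy=acc,
        accuracy_sd=sd,
        group=group,
    )
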