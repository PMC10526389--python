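"""Goodness-of-fit measures for choosing the number of microstate classes.

Three measures are computed for each candidate cluster count K:

* GEV — fraction of GFP-weighted topographic variance explained by the
  assigned templates (higher is better, in [0, 1]);
* the cross-validation criterion — residual noise variance times a penalty
  factor that grows with K (lower is better);
* dispersion — summed within-cluster pairwise squared distance per cluster
  member on the peak maps (lower is tighter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMapError, ParameterError
from .microstate import LabelSequence, MicrostateModel, backfit, modified_kmeans

__all__ = [
    "FitReport",
    "spatial_correlation",
    "gev",
    "cv_criterion",
    "dispersion",
    "scan_cluster_numbers",
]


@dataclass(frozen=True)
class FitReport:
    k: int
    gev: float
    cv: float
    dispersion: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ParameterError(f"gev {self.gev} outside [0, 1]")
        if self.cv < 0 or self.dispersion < 0:
            raise ParameterError("cv and dispersion must be non-negative")


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two average-referenced topographies, in [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ParameterError("topographies must have the same channel count")
    u = u - u.mean()
    v = v - v.mean()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateMapError("zero-norm topography in spatial correlation")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def _prep(model: MicrostateModel, labels: LabelSequence, segment: np.ndarray):
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] != model.n_channels:
        raise ParameterError("segment channel count does not match model")
    if len(labels) != segment.shape[1]:
        raise ParameterError("labels do not align with segment samples")
    if labels.labels.size and labels.labels.max() > model.k:
        raise ParameterError("label index exceeds model cluster count")
    return segment


def gev(
    model: MicrostateModel,
    labels: LabelSequence,
    segment: np.ndarray,
    literal_mean: bool = False,
) -> float:
    """Global explained variance of the labeled segment.

    GEV = sum_n C^2(x_n, a_{l_n}) GFP_n^2 / sum_n GFP_n^2, with C^2 the
    squared (hence polarity-invariant) spatial correlation. ``literal_mean``
    additionally divides by the sample count (a variant that no longer
    reaches 1 for a perfect fit).
    """
    segment = _prep(model, labels, segment)
    x = segment - segment.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(x, axis=0)
    total = (norms**2).sum()
    if total <= 0:
        raise DegenerateMapError("all-zero segment in gev")
    a = model.maps / np.linalg.norm(model.maps, axis=1, keepdims=True)
    good = norms > 0
    r = np.zeros(x.shape[1])
    picked = a[labels.labels - 1]  # (S, C)
    r[good] = np.einsum("ij,ji->i", picked[:, :], x)[good] / norms[good]
    value = float((r**2 * norms**2).sum() / total)
    if literal_mean:
        value /= x.shape[1]
    return value


def cv_criterion(
    model: MicrostateModel, labels: LabelSequence, segment: np.ndarray
) -> float:
    """Cross-validation criterion: residual variance with a K-penalty.

    sigma2 = sum_n (x_n'x_n - (a_{l_n}'x_n)^2) / (N (C-1)) with unit-norm
    templates; the criterion is sigma2 * ((C-1)/(C-K-1))^2. Requires
    K <= C - 2.
    """
    segment = _prep(model, labels, segment)
    c = segment.shape[0]
    k = model.k
    if k >= c - 1:
        raise ParameterError(f"cv criterion undefined for K={k} >= C-1={c - 1}")
    x = segment - segment.mean(axis=0, keepdims=True)
    a = model.maps / np.linalg.norm(model.maps, axis=1, keepdims=True)
    picked = a[labels.labels - 1]
    proj = np.einsum("ij,ji->i", picked, x)
    # clamp: at a perfect fit the residual is 0 up to rounding
    resid = np.maximum((x**2).sum(axis=0) - proj**2, 0.0)
    sigma2 = resid.sum() / (x.shape[1] * (c - 1))
    return float(sigma2 * ((c - 1) / (c - k - 1)) ** 2)


def dispersion(
    labels: np.ndarray, peaks: np.ndarray, n_clusters: int | None = None
) -> float:
    """Within-cluster dispersion of the peak maps.

    For cluster k with N_k members, S_k sums squared Euclidean distance over
    ordered member pairs; the result is sum_k S_k / (2 N_k), equal to the
    summed squared distance to each cluster centroid.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    peaks = np.asarray(peaks, dtype=float)
    if labels.size != peaks.shape[0]:
        raise ParameterError("labels and peaks disagree in length")
    present = np.unique(labels)
    if n_clusters is not None:
        expected = np.arange(1, n_clusters + 1)
        if not np.isin(expected, present).all():
            raise ParameterError("empty cluster in dispersion")
    total = 0.0
    for k in present:
        members = peaks[labels == k]
        centroid = members.mean(axis=0)
        total += float(((members - centroid) ** 2).sum())
    return total


def scan_cluster_numbers(
    peaks: np.ndarray,
    segment: np.ndarray,
    fs: float,
    ks: range | list[int] = range(2, 11),
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 100,
) -> tuple[list[FitReport], int]:
    """Fit, backfit and score every K in ``ks``; returns the reports and the
    argmin-CV K.

    Clustering is done on the peak maps; GEV and CV are evaluated on all
    samples of ``segment``. In addition to the random restarts, each K > min(ks)
    gets one warm start built from the previous K's templates plus the peak
    map they fit worst, which keeps GEV non-decreasing in K in practice.
    """
    peaks = np.asarray(peaks, dtype=float)
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    ks = sorted(ks)
    rng = np.random.default_rng(seed)
    reports: list[FitReport] = []
    prev_maps: np.ndarray | None = None
    for k in ks:
        extra = []
        if prev_maps is not None and prev_maps.shape[0] == k - 1:
            a = prev_maps / np.linalg.norm(prev_maps, axis=1, keepdims=True)
            x = peaks - peaks.mean(axis=1, keepdims=True)
            xu = x / np.linalg.norm(x, axis=1, keepdims=True)
            worst = int(np.argmin(np.max((xu @ a.T) ** 2, axis=1)))
            extra.append(np.vstack([prev_maps, peaks[worst]]))
        model = modified_kmeans(
            peaks, k, n_restarts=n_restarts, max_iter=max_iter, seed=rng,
            extra_inits=extra,
        )
        labels = backfit(model, segment, fs=fs)
        peak_labels = backfit(model, peaks.T, fs=fs)
        reports.append(
            FitReport(
                k=k,
                gev=gev(model, labels, segment),
                cv=cv_criterion(model, labels, segment),
                dispersion=dispersion(peak_labels.labels, peaks),
                seed=seed,
            )
        )
        prev_maps = model.maps
    best_k = reports[int(np.argmin([r.cv for r in reports]))].k
    return reports, best_k
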