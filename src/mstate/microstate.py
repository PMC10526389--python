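"""Microstate segmentation: GFP, GMD, GFP-peak picking, modified k-means
clustering of peak topographies, and backfitting.

A topography is a length-N voltage vector across channels. Template maps are
stored average-referenced with unit GFP (root-mean-square across channels
equal to 1). Class labels are 1-based.

Clustering and (by default) backfitting are polarity-invariant: a map and its
negation belong to the same class. A flag restores the literal
polarity-sensitive dissimilarity for backfitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import DegenerateMapError, ParameterError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GfpSeries:
    """Per-sample global field power (microvolts)."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ParameterError("GFP series must be 1-D")
        if np.any(values < 0):
            raise ParameterError("GFP values must be non-negative")
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")


@dataclass(frozen=True)
class MicrostateModel:
    """K template maps (K x N), each average-referenced with unit GFP."""

    maps: np.ndarray
    polarity_invariant: bool = True
    gev_peaks: float = float("nan")  # GEV on the peak set used for fitting
    n_iter: int = 0

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        object.__setattr__(self, "maps", maps)
        if maps.ndim != 2 or maps.shape[0] < 1 or maps.shape[1] < 2:
            raise ParameterError("maps must be (K >= 1) x (N >= 2)")
        gfp_of_maps = np.sqrt((maps**2).mean(axis=1))
        if np.any(np.abs(maps.mean(axis=1)) > 1e-8) or np.any(
            np.abs(gfp_of_maps - 1.0) > 1e-8
        ):
            raise ParameterError("template maps must be average-referenced, unit GFP")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass(frozen=True)
class LabelSequence:
    """Per-sample microstate class indices, 1-based."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ParameterError("labels must be 1-D")
        if labels.size and labels.min() < 1:
            raise ParameterError("labels are 1-based; found label < 1")
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.labels.size


# ---------------------------------------------------------------------------
# Elementary measures

def gfp(segment: np.ndarray, fs: float = 1.0) -> GfpSeries:
    """Global field power: spatial standard deviation of each sample.

    ``segment`` is (channels x samples); value at t is
    sqrt( (1/N) sum_i (v_i(t) - vbar(t))^2 ).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] < 2:
        raise ParameterError("GFP requires at least 2 channels")
    centered = segment - segment.mean(axis=0, keepdims=True)
    return GfpSeries(values=np.sqrt((centered**2).mean(axis=0)), fs=fs)


def _normalize_map(v: np.ndarray) -> np.ndarray:
    """Average-reference and scale to unit GFP; raises on zero field power."""
    v = np.asarray(v, dtype=float).ravel()
    centered = v - v.mean()
    g = np.sqrt((centered**2).mean())
    if g <= 0:
        raise DegenerateMapError("topography has zero global field power")
    return centered / g


def gmd(u: np.ndarray, v: np.ndarray, polarity_invariant: bool = False) -> float:
    """Global map dissimilarity between two topographies.

    Each map is average-referenced and divided by its GFP before the RMS
    difference is taken; range [0, 2], or [0, sqrt(2)] when polarity-invariant
    (the minimum over the sign flip is returned).
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ParameterError("topographies must have the same channel count")
    un = _normalize_map(u)
    vn = _normalize_map(v)
    d = np.sqrt(((un - vn) ** 2).mean())
    if polarity_invariant:
        d = min(d, float(np.sqrt(((un + vn) ** 2).mean())))
    return float(d)


def find_gfp_peaks(g: GfpSeries, min_distance_ms: float = 10.0) -> np.ndarray:
    """Indices of interior local maxima of the GFP curve, at least
    ``min_distance_ms`` apart; of two conflicting candidates the larger
    GFP wins."""
    if min_distance_ms < 1000.0 / g.fs:
        raise ParameterError(
            f"min_distance_ms must be >= one sample period ({1000.0 / g.fs:g} ms)"
        )
    if g.values.size < 3:
        logger.warning("find_gfp_peaks: series shorter than 3 samples")
        return np.empty(0, dtype=int)
    # ceil so that the returned spacing is truly >= min_distance_ms
    distance = max(1, int(np.ceil(min_distance_ms * g.fs / 1000.0 - 1e-9)))
    peaks, _ = find_peaks(g.values, distance=distance)
    return peaks


# ---------------------------------------------------------------------------
# Modified k-means

def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise DegenerateMapError("degenerate (zero) topography in peak set")
    return x / norms


def _principal_map(x: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of x^T x for the rows x assigned to one cluster."""
    scatter = x.T @ x
    eigvals, eigvecs = np.linalg.eigh(scatter)
    a = eigvecs[:, -1]
    # deterministic sign: largest-magnitude coefficient positive
    a = a * np.sign(a[np.argmax(np.abs(a))] or 1.0)
    return a


def _kmeans_once(
    x: np.ndarray,
    xu: np.ndarray,
    w: np.ndarray,
    init_maps: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One run of polarity-invariant microstate k-means.

    x: (n, C) average-referenced peak maps; xu: unit-norm rows of x;
    w: GFP^2 weights. Returns (unit-norm templates, labels0, gev, n_iter).
    """
    a = init_maps.copy()
    w_total = w.sum()
    prev_gev = -np.inf
    gev = 0.0
    labels = np.zeros(x.shape[0], dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        r2 = (xu @ a.T) ** 2  # squared spatial correlations, (n, K)
        labels = np.argmax(r2, axis=1)
        # re-seed empty clusters from the currently worst-fit map
        for k in range(a.shape[0]):
            if not np.any(labels == k):
                worst = int(np.argmin(r2[np.arange(len(labels)), labels]))
                logger.warning("empty cluster %d re-seeded from map %d", k, worst)
                a[k] = xu[worst]
                r2[:, k] = (xu @ a[k]) ** 2
                labels = np.argmax(r2, axis=1)
        gev = float((w * r2[np.arange(len(labels)), labels]).sum() / w_total)
        if it > 1 and gev - prev_gev <= tol * max(abs(prev_gev), 1e-12):
            break
        prev_gev = gev
        for k in range(a.shape[0]):
            members = x[labels == k]
            if len(members):
                a[k] = _principal_map(members)
    return a, labels, gev, it


def modified_kmeans(
    peaks: np.ndarray,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-7,
    seed: int | np.random.Generator | None = None,
    extra_inits: list[np.ndarray] | None = None,
) -> MicrostateModel:
    """Cluster peak topographies into ``k`` polarity-invariant template maps.

    Each restart alternates (a) assigning every map to the template with the
    highest squared spatial correlation and (b) replacing each template by the
    dominant eigenvector of its members' outer-product sum; the restart with
    the highest GEV on the peak set wins. ``extra_inits`` adds deterministic
    warm-start template sets (used by the K-scan).
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.ndim != 2:
        raise ParameterError("peaks must be (n_maps x n_channels)")
    n, c = peaks.shape
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n < k:
        raise ParameterError(f"need at least k={k} peak maps, got {n}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    x = peaks - peaks.mean(axis=1, keepdims=True)
    xu = _unit_rows(x)
    w = (np.linalg.norm(x, axis=1) ** 2) / c  # GFP^2 per peak

    inits: list[np.ndarray] = []
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        inits.append(xu[idx].copy())
    for init in extra_inits or []:
        init = np.asarray(init, dtype=float)
        if init.shape != (k, c):
            raise ParameterError("extra init shape must be (k, n_channels)")
        inits.append(_unit_rows(init - init.mean(axis=1, keepdims=True)))

    best: tuple[float, np.ndarray, int] | None = None
    for init in inits:
        a, _, gev, it = _kmeans_once(x, xu, w, init, max_iter, tol)
        if best is None or gev > best[0]:
            best = (gev, a, it)
    assert best is not None
    gev, a, it = best
    maps = a * np.sqrt(c)  # unit-norm -> unit-GFP
    return MicrostateModel(
        maps=maps, polarity_invariant=True, gev_peaks=gev, n_iter=it
    )


def backfit(
    model: MicrostateModel,
    segment: np.ndarray,
    fs: float = 1.0,
    polarity_invariant: bool | None = None,
) -> LabelSequence:
    """Assign every sample of ``segment`` (channels x samples) to the template
    with minimal GMD.

    Ties go to the lowest class index; zero-GFP samples inherit the previous
    sample's label (the first such sample gets class 1).
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] != model.n_channels:
        raise ParameterError(
            f"segment has {segment.shape[0]} channels, model expects "
            f"{model.n_channels}"
        )
    if polarity_invariant is None:
        polarity_invariant = model.polarity_invariant

    x = segment - segment.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(x, axis=0)
    good = norms > 0
    xn = np.where(good, x / np.where(good, norms, 1.0), 0.0)
    a = model.maps / np.linalg.norm(model.maps, axis=1, keepdims=True)
    r = a @ xn  # (K, S); GMD^2 = 2(1 - r)
    score = np.abs(r) if polarity_invariant else r
    labels = np.argmax(score, axis=0) + 1

    if not good.all():
        # ascending forward fill handles runs of zero-GFP samples
        for i in np.flatnonzero(~good):
            labels[i] = labels[i - 1] if i > 0 else 1
    return LabelSequence(labels=labels, fs=fs)


# ---------------------------------------------------------------------------
# Serialization

def save_model(model: MicrostateModel, path, channel_names=None) -> None:
    """Write template maps as a delimited matrix with a metadata header."""
    header = [
        f"k={model.k}",
        f"polarity_invariant={int(model.polarity_invariant)}",
    ]
    if channel_names is not None:
        header.append("channels=" + ",".join(channel_names))
    np.savetxt(path, model.maps, fmt="%.10g", header="\n".join(header))


def load_model(path) -> MicrostateModel:
    polarity = True
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "polarity_invariant=" in line:
                polarity = bool(int(line.split("=", 1)[1]))
    maps = np.atleast_2d(np.loadtxt(path))
    return MicrostateModel(maps=maps, polarity_invariant=polarity)


def save_labels(seq: LabelSequence, path) -> None:
    np.savetxt(path, seq.labels, fmt="%d", header=f"fs={seq.fs:g}")


def load_labels(path) -> LabelSequence:
    fs = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("=", 1)[1])
    return LabelSequence(labels=np.loadtxt(path, dtype=int), fs=fs)
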