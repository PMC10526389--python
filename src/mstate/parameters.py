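"""Microstate feature parameters from a label sequence.

Four statistics per class: mean duration (ms), occurrence (events/s), time
coverage (fraction of samples), and the off-diagonal transition probability
matrix. Statistics of a class that never appears are reported as NaN
("missing"), never as zero.

The ``boundary_policy`` decides whether the truncated first/last segments of
a sequence count toward duration and occurrence:

* ``"count_all"`` (default) — every segment counts; this keeps the identity
  coverage_k == occurrence_k * mean_duration_k / 1000 exact.
* ``"exclude_truncated"`` — the first and last segment are dropped from
  duration and occurrence (coverage and transitions are unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .microstate import LabelSequence

__all__ = [
    "MicrostateParameters",
    "run_length_encode",
    "compute_parameters",
    "aggregate_parameters",
]

BOUNDARY_POLICIES = ("count_all", "exclude_truncated")


def run_length_encode(labels: np.ndarray) -> list[tuple[int, int]]:
    """Encode a label vector as ordered (class, run length) segments."""
    labels = np.asarray(labels, dtype=int).ravel()
    if labels.size == 0:
        raise ParameterError("empty label sequence")
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    return [(int(labels[a]), int(b - a)) for a, b in zip(starts, stops)]


def run_length_decode(segments: list[tuple[int, int]]) -> np.ndarray:
    return np.concatenate([np.full(n, c, dtype=int) for c, n in segments])


@dataclass(frozen=True)
class MicrostateParameters:
    """Sufficient statistics plus derived per-class parameters.

    The count fields make aggregation across epochs exact: aggregation is
    plain summation of counts (see :func:`aggregate_parameters`).
    """

    n_classes: int
    fs: float
    boundary_policy: str
    seg_count: np.ndarray        # segments per class under the policy
    seg_samples: np.ndarray      # samples in those segments
    counted_samples: int         # total samples spanned by counted segments
    cov_samples: np.ndarray      # samples per class over the whole sequence
    n_samples: int               # total samples (coverage denominator)
    trans_counts: np.ndarray     # (K, K) boundary counts, zero diagonal

    def __post_init__(self) -> None:
        if self.boundary_policy not in BOUNDARY_POLICIES:
            raise ParameterError(f"unknown boundary policy {self.boundary_policy!r}")
        for name in ("seg_count", "seg_samples", "cov_samples"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n_classes,):
                raise ParameterError(f"{name} must have length n_classes")
            object.__setattr__(self, name, arr)
        tc = np.asarray(self.trans_counts, dtype=float)
        if tc.shape != (self.n_classes, self.n_classes):
            raise ParameterError("trans_counts must be K x K")
        if np.any(np.diag(tc) != 0):
            raise ParameterError("transition counts must have zero diagonal")
        object.__setattr__(self, "trans_counts", tc)

    @property
    def mean_duration(self) -> np.ndarray:
        """Per-class mean segment length in ms; NaN for absent classes."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.seg_samples / self.seg_count * 1000.0 / self.fs
        return np.where(self.seg_count > 0, out, np.nan)

    @property
    def occurrence(self) -> np.ndarray:
        """Per-class segments per second of counted signal."""
        denom = self.counted_samples / self.fs
        out = self.seg_count / denom if denom > 0 else np.full(self.n_classes, np.nan)
        return np.where(self.seg_count > 0, out, np.nan)

    @property
    def coverage(self) -> np.ndarray:
        """Fraction of all samples spent in each class (sums to 1)."""
        return self.cov_samples / self.n_samples

    @property
    def tp(self) -> np.ndarray:
        """Row-normalized transition probabilities; rows with no outgoing
        transition are NaN."""
        row = self.trans_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.trans_counts / row
        out[row.ravel() == 0] = np.nan
        return out


def compute_parameters(
    labels: LabelSequence,
    n_classes: int | None = None,
    boundary_policy: str = "count_all",
) -> MicrostateParameters:
    """Compute the four microstate parameters for one label sequence."""
    if boundary_policy not in BOUNDARY_POLICIES:
        raise ParameterError(f"unknown boundary policy {boundary_policy!r}")
    seq = labels.labels
    if seq.size == 0:
        raise ParameterError("empty label sequence")
    k = int(n_classes if n_classes is not None else seq.max())
    if seq.max() > k:
        raise ParameterError("label exceeds n_classes")

    segments = run_length_encode(seq)
    counted = segments
    if boundary_policy == "exclude_truncated":
        counted = segments[1:-1] if len(segments) > 2 else []

    seg_count = np.zeros(k)
    seg_samples = np.zeros(k)
    for cls, length in counted:
        seg_count[cls - 1] += 1
        seg_samples[cls - 1] += length
    cov_samples = np.bincount(seq - 1, minlength=k).astype(float)
    trans = np.zeros((k, k))
    for (a, _), (b, _) in zip(segments, segments[1:]):
        trans[a - 1, b - 1] += 1
    return MicrostateParameters(
        n_classes=k,
        fs=labels.fs,
        boundary_policy=boundary_policy,
        seg_count=seg_count,
        seg_samples=seg_samples,
        counted_samples=int(sum(n for _, n in counted)),
        cov_samples=cov_samples,
        n_samples=int(seq.size),
        trans_counts=trans,
    )


def aggregate_parameters(
    per_epoch: list[MicrostateParameters],
    weights: list[int] | None = None,
) -> MicrostateParameters:
    """Pool parameters over epochs by summing their sufficient statistics.

    Segments never merge across epoch boundaries (epochs are non-contiguous
    windows). ``weights``, if given, must equal each epoch's sample count and
    is used only as a consistency check.
    """
    if not per_epoch:
        raise ParameterError("need at least one epoch")
    k = per_epoch[0].n_classes
    fs = per_epoch[0].fs
    policy = per_epoch[0].boundary_policy
    for p in per_epoch:
        if p.n_classes != k:
            raise ParameterError("inconsistent class count across epochs")
        if p.fs != fs or p.boundary_policy != policy:
            raise ParameterError("inconsistent fs or boundary policy across epochs")
    if weights is not None:
        if len(weights) != len(per_epoch):
            raise ParameterError("weights length mismatch")
        for w, p in zip(weights, per_epoch):
            if int(w) != p.n_samples:
                raise ParameterError("weight does not match epoch sample count")
    return MicrostateParameters(
        n_classes=k,
        fs=fs,
        boundary_policy=policy,
        seg_count=np.sum([p.seg_count for p in per_epoch], axis=0),
        seg_samples=np.sum([p.seg_samples for p in per_epoch], axis=0),
        counted_samples=int(sum(p.counted_samples for p in per_epoch)),
        cov_samples=np.sum([p.cov_samples for p in per_epoch], axis=0),
        n_samples=int(sum(p.n_samples for p in per_epoch)),
        trans_counts=np.sum([p.trans_counts for p in per_epoch], axis=0),
    )
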