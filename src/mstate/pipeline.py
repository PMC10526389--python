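"""End-to-end cohort analysis glue.

Runs the full measurement chain on a synthetic cohort: preprocessing, pooled
(group-level) microstate clustering, backfitting, the four feature
parameters, MI accuracy via CSP + SVM, the spectral-entropy baseline, and
assembles the per-record table consumed by the correlation screen and the
predictor.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .eeg_core import Recording, average_reference, bandpass
from .errors import ParameterError
from .fit_measures import spatial_correlation
from .microstate import (
    LabelSequence,
    MicrostateModel,
    backfit,
    find_gfp_peaks,
    gfp,
    modified_kmeans,
)
from .mi_performance import session_accuracy
from .parameters import compute_parameters
from .predictor import spectral_entropy
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = ["preprocess", "align_model", "collect_peak_maps", "analyze_cohort"]


def preprocess(rec: Recording, band: tuple[float, float] = (7.0, 30.0)) -> Recording:
    """Band-pass then average-reference (the standard pipeline order)."""
    return average_reference(bandpass(rec, *band))


def collect_peak_maps(
    rec: Recording, min_distance_ms: float = 10.0, max_peaks: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """GFP-peak topographies of one recording, optionally subsampled."""
    peaks = find_gfp_peaks(gfp(rec.data, rec.fs), min_distance_ms)
    maps = rec.data[:, peaks].T
    if max_peaks is not None and len(maps) > max_peaks:
        rng = rng or np.random.default_rng(0)
        keep = rng.choice(len(maps), size=max_peaks, replace=False)
        maps = maps[np.sort(keep)]
    return maps


def align_model(
    model: MicrostateModel, reference_maps: np.ndarray
) -> tuple[MicrostateModel, np.ndarray]:
    """Reorder model classes to best match reference maps (|corr| matching).

    Returns the reordered model and the per-class |spatial correlation| to
    the reference after matching.
    """
    reference_maps = np.asarray(reference_maps, dtype=float)
    k = model.k
    if reference_maps.shape[0] != k:
        raise ParameterError("reference map count must equal model K")
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            corr[i, j] = abs(spatial_correlation(reference_maps[i], model.maps[j]))
    rows, cols = linear_sum_assignment(-corr)
    order = cols[np.argsort(rows)]
    reordered = MicrostateModel(
        maps=model.maps[order],
        polarity_invariant=model.polarity_invariant,
        gev_peaks=model.gev_peaks,
        n_iter=model.n_iter,
    )
    return reordered, corr[np.arange(k), order]


def _parameter_row(labels: LabelSequence, k: int) -> dict:
    params = compute_parameters(labels, n_classes=k)
    row: dict[str, float] = {}
    dur = params.mean_duration
    occ = params.occurrence
    cov = params.coverage
    tp = params.tp
    for c in range(k):
        row[f"ms{c + 1}_duration"] = dur[c]
        row[f"ms{c + 1}_occurrence"] = occ[c]
        row[f"ms{c + 1}_coverage"] = cov[c]
        for t in range(k):
            if t != c:
                row[f"tp{c + 1}{t + 1}"] = tp[c, t]
    return row


def analyze_cohort(
    cohort: SyntheticCohort,
    k: int = 4,
    min_distance_ms: float = 10.0,
    peaks_per_record: int = 40,
    n_restarts: int = 20,
    folds: int = 10,
    m_csp: int = 3,
    entropy_channel: str = "C3",
    seed: int = 0,
) -> tuple[pd.DataFrame, MicrostateModel, np.ndarray]:
    """Run the complete analysis over a synthetic cohort.

    Group-level clustering pools subsampled GFP-peak maps from every record;
    fitted classes are reordered against the cohort's planted maps so that
    "MS1"..."MSk" refer to the same planted classes in every run. Returns
    (records table, aligned group model, per-class map recovery |corr|).
    """
    rng = np.random.default_rng(seed)
    band = cohort.config.band

    # pass 1: pooled group-level clustering on subsampled peak maps;
    # recordings are regenerated in pass 2 (deterministic) to bound memory
    pooled_peaks: list[np.ndarray] = []
    for idx in range(cohort.n_records):
        rec, _ = cohort.resting(idx)
        rec = preprocess(rec, band)
        pooled_peaks.append(
            collect_peak_maps(rec, min_distance_ms, peaks_per_record, rng)
        )
    peak_maps = np.vstack(pooled_peaks)
    model = modified_kmeans(peak_maps, k, n_restarts=n_restarts, seed=rng)
    model, recovery = align_model(model, cohort.maps[:k])
    logger.info("group model recovery |corr|: %s", np.round(recovery, 3))

    ch_idx = None
    rows = []
    for idx in range(cohort.n_records):
        rec, _ = cohort.resting(idx)
        rec = preprocess(rec, band)
        if ch_idx is None:
            ch_idx = (
                rec.channel_names.index(entropy_channel)
                if entropy_channel in rec.channel_names
                else 0
            )
        labels = backfit(model, rec.data, fs=rec.fs)
        row = _parameter_row(labels, k)
        row["spectral_entropy"] = spectral_entropy(rec.data[ch_idx], rec.fs, band)
        left, right = cohort.mi(idx)
        perf = session_accuracy(
            left, right, folds=folds, seed=seed + idx, m=m_csp
        )
        subject, session = cohort.record_ids()[idx]
        row.update(
            subject_id=subject,
            session_id=session,
            accuracy=perf.accuracy,
            accuracy_sd=perf.accuracy_sd,
            group=perf.group,
        )
        rows.append(row)
    records = pd.DataFrame(rows)
    return records, model, recovery
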