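"""High/low performer prediction from resting-state microstate parameters.

Implements the correlation screen of parameters against accuracy, feature
normalization without test leakage, a two-feature Fisher LDA, per-session
leave-one-out cross-validation, ROC/AUC (Mann-Whitney with ties counted 1/2),
and the single-channel spectral-entropy baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "RocResult",
    "LdaModel",
    "pearson_r",
    "correlation_table",
    "normalize_feature",
    "lda_fit",
    "loocv_scores",
    "roc_auc",
    "spectral_entropy",
    "evaluate_predictors",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t-transform
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 3:
        raise ParameterError("need equal-length series with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("correlation undefined for a constant series")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


_PARAM_ROWS = ("duration", "occurrence", "coverage", "TP1", "TP2", "TP3", "TP4")


def _sig_flag(p: float) -> str:
    if p < 0.001:
        return "**"
    if 0.01 < p < 0.05:
        return "*"
    return ""


def correlation_table(
    records: pd.DataFrame,
    accuracy_col: str = "accuracy",
    n_classes: int = 4,
) -> pd.DataFrame:
    """Correlation of every microstate parameter with accuracy.

    ``records`` needs columns ``ms{k}_duration``, ``ms{k}_occurrence``,
    ``ms{k}_coverage`` and ``tp{j}{k}`` (probability of the j -> k transition)
    plus the accuracy column. Returns one row per (parameter, class) with r,
    p and a significance flag ('**' p < 0.001, '*' 0.01 < p < 0.05);
    self-transitions are marked absent.
    """
    if len(records) < 3:
        raise ParameterError("need at least 3 records")
    rows = []
    acc = records[accuracy_col].to_numpy(float)
    for param in _PARAM_ROWS:
        for k in range(1, n_classes + 1):
            if param.startswith("TP"):
                target = int(param[2:])
                if target == k:
                    rows.append((param, f"MS{k}", np.nan, np.nan, "/"))
                    continue
                col = f"tp{k}{target}"
            else:
                col = f"ms{k}_{param}"
            values = records[col].to_numpy(float)
            mask = np.isfinite(values) & np.isfinite(acc)
            if mask.sum() < 3 or np.ptp(values[mask]) == 0:
                rows.append((param, f"MS{k}", np.nan, np.nan, ""))
                continue
            r, p = pearson_r(values[mask], acc[mask])
            rows.append((param, f"MS{k}", r, p, _sig_flag(p)))
    return pd.DataFrame(rows, columns=["parameter", "class", "r", "p", "sig"])


def normalize_feature(
    values: np.ndarray,
    method: str = "zscore",
    fit_on: np.ndarray | None = None,
) -> np.ndarray:
    """Normalize a series with statistics estimated on ``fit_on`` only.

    ``fit_on`` is a boolean mask (or index array) of the training subset; by
    default the whole series is used. Values outside the training range are
    not clipped under min-max scaling.
    """
    values = np.asarray(values, dtype=float).ravel()
    train = values if fit_on is None else values[fit_on]
    if train.size == 0 or np.ptp(train) == 0:
        raise ParameterError("constant (or empty) fit subset")
    if method == "zscore":
        return (values - train.mean()) / train.std(ddof=0)
    if method == "minmax":
        lo, hi = train.min(), train.max()
        return (values - lo) / (hi - lo)
    raise ParameterError(f"unknown normalization method {method!r}")


@dataclass(frozen=True)
class LdaModel:
    """Fisher discriminant: score(x) = weights @ x - threshold, positive
    scores favor the positive class."""

    weights: np.ndarray
    threshold: float

    def score(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return x @ self.weights - self.threshold

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.score(x) > 0


def lda_fit(features: np.ndarray, groups: np.ndarray, ridge: float = 1e-8) -> LdaModel:
    """Fisher LDA with pooled within-class covariance and equal priors.

    ``groups`` is boolean (True = positive/high). The threshold sits at the
    midpoint of the projected class means.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    g = np.asarray(groups, dtype=bool).ravel()
    if x.shape[0] != g.size:
        raise ParameterError("features and groups disagree in length")
    if not (g.any() and (~g).any()):
        raise ParameterError("both groups must be non-empty")
    x1, x0 = x[g], x[~g]
    mu1, mu0 = x1.mean(axis=0), x0.mean(axis=0)
    dev1 = x1 - mu1
    dev0 = x0 - mu0
    pooled = (dev1.T @ dev1 + dev0.T @ dev0) / max(x.shape[0] - 2, 1)
    pooled = pooled + ridge * max(np.trace(pooled), 1.0) / x.shape[1] * np.eye(
        x.shape[1]
    )
    weights = np.linalg.solve(pooled, mu1 - mu0)
    threshold = float(weights @ (mu1 + mu0) / 2.0)
    return LdaModel(weights=weights, threshold=threshold)


def loocv_scores(
    features: np.ndarray,
    groups: np.ndarray,
    method: str = "zscore",
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out LDA scores within one session.

    For each record the remaining records are normalized (statistics fit on
    them only), an LDA is fit, and the held-out record is scored. Records
    whose training fold lacks one group — or has a constant feature — get a
    NaN score. Returns (scores, predicted_high).
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    g = np.asarray(groups, dtype=bool).ravel()
    n = x.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 records for LOOCV")
    scores = np.full(n, np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if not (g[mask].any() and (~g[mask]).any()):
            logger.warning("LOOCV fold %d lacks one group; score flagged missing", i)
            continue
        try:
            cols = [
                normalize_feature(x[:, j], method=method, fit_on=mask)
                for j in range(x.shape[1])
            ]
        except ParameterError:
            logger.warning("LOOCV fold %d has a constant feature; flagged", i)
            continue
        xn = np.column_stack(cols)
        model = lda_fit(xn[mask], g[mask])
        scores[i] = float(model.score(xn[i : i + 1])[0])
    return scores, scores > 0


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.auc <= 1.0 + 1e-12):
            raise ParameterError("AUC outside [0, 1]")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ParameterError("ROC curve must be monotone")


def roc_auc(scores: np.ndarray, groups: np.ndarray) -> RocResult:
    """ROC curve (threshold sweep over unique scores) and AUC via the
    Mann-Whitney identity with ties counted 1/2."""
    s = np.asarray(scores, dtype=float).ravel()
    g = np.asarray(groups, dtype=bool).ravel()
    keep = np.isfinite(s)
    s, g = s[keep], g[keep]
    n_pos = int(g.sum())
    n_neg = int((~g).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC undefined with one group absent")

    ranks = stats.rankdata(s)  # average ranks -> ties count 1/2
    auc = float((ranks[g].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    g_sorted = g[order]
    distinct = np.flatnonzero(np.diff(s_sorted)) if s.size > 1 else np.array([], int)
    cuts = np.concatenate([distinct, [s.size - 1]])
    tp = np.cumsum(g_sorted)[cuts]
    fp = np.cumsum(~g_sorted)[cuts]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cuts]])
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def spectral_entropy(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float] = (7.0, 30.0),
) -> float:
    """Normalized Shannon entropy of the in-band power spectral density.

    Welch estimate (1 s Hann windows, 50% overlap); the in-band PSD is
    normalized to a probability mass and its entropy divided by log(bin
    count), giving a value in [0, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    low, high = band
    if not 0 < low < high:
        raise ParameterError("band must satisfy 0 < low < high")
    if x.size < 2 * fs / low:
        raise ParameterError("signal too short for the requested band")
    nperseg = min(int(round(fs)), x.size)
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    mask = (freqs >= low) & (freqs <= high)
    p = psd[mask]
    total = p.sum()
    if total <= 0 or mask.sum() < 2:
        raise ParameterError("zero power (or <2 bins) in the requested band")
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(mask.sum()))


def evaluate_predictors(
    records: pd.DataFrame,
    feature_cols: tuple[str, ...] = ("ms1_occurrence", "ms3_duration"),
    baseline_col: str = "spectral_entropy",
    session_col: str = "session_id",
    group_col: str = "group",
    method: str = "zscore",
) -> dict:
    """Per-session and pooled ROC/AUC for the microstate predictor and the
    spectral-entropy baseline.

    LOOCV is run separately in every session; sessions with a single group
    are excluded (and reported). Pooled curves concatenate per-session LOOCV
    scores after per-session standardization.
    """
    sessions = sorted(records[session_col].unique())
    if len(sessions) < 2:
        raise ParameterError("need at least 2 sessions")
    per_session = []
    pooled: dict[str, list] = {"micro": [], "base": [], "group": []}
    excluded = []
    for sess in sessions:
        sub = records[records[session_col] == sess]
        g = (sub[group_col] == "high").to_numpy()
        if g.all() or not g.any():
            excluded.append(sess)
            logger.warning("session %s has a single group; excluded", sess)
            continue
        feats = sub[list(feature_cols)].to_numpy(float)
        micro_scores, _ = loocv_scores(feats, g, method=method)
        base_scores, _ = loocv_scores(
            sub[[baseline_col]].to_numpy(float), g, method=method
        )
        row = {"session": sess, "n_high": int(g.sum()), "n_low": int((~g).sum())}
        for name, sc in (("microstate", micro_scores), ("entropy", base_scores)):
            ok = np.isfinite(sc)
            row[f"auc_{name}"] = (
                roc_auc(sc[ok], g[ok]).auc if (g[ok].any() and (~g[ok]).any())
                else np.nan
            )
        per_session.append(row)
        ok = np.isfinite(micro_scores) & np.isfinite(base_scores)
        for key, sc in (("micro", micro_scores), ("base", base_scores)):
            if ok.sum() >= 2 and np.ptp(sc[ok]) > 0:
                z = (sc - sc[ok].mean()) / sc[ok].std()
            else:
                z = sc
            pooled[key].extend(z[ok])
        pooled["group"].extend(g[ok])
    groups = np.asarray(pooled["group"], dtype=bool)
    roc_micro = roc_auc(np.asarray(pooled["micro"]), groups)
    roc_base = roc_auc(np.asarray(pooled["base"]), groups)
    return {
        "per_session": pd.DataFrame(per_session),
        "pooled_roc_microstate": roc_micro,
        "pooled_roc_entropy": roc_base,
        "pooled_auc_microstate": roc_micro.auc,
        "pooled_auc_entropy": roc_base.auc,
        "excluded_sessions": excluded,
    }
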