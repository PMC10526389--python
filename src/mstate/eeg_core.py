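"""EEG data model, file I/O and preprocessing.

Conventions used throughout the package: voltages in microvolts, sample
indexing is 0-based, windows are half-open ``[start, stop)``, and durations
are reported in milliseconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import _edf
from .errors import ChannelLookupError, FormatError, ParameterError

logger = logging.getLogger(__name__)

CONDITIONS = ("rest_pretrial", "mi_left", "mi_right")

#: Default sampling rate (Hz) when a source format carries none.
DEFAULT_FS = 250.0


@dataclass(frozen=True)
class Recording:
    """A multichannel EEG recording: ``data`` is (channels x samples) in
    microvolts, row order matches ``channel_names``."""

    data: np.ndarray
    channel_names: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 2:
            raise ParameterError("Recording data must be 2-D (channels x samples)")
        if data.shape[0] != len(self.channel_names):
            raise ParameterError(
                f"channel count {data.shape[0]} != {len(self.channel_names)} names"
            )
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")
        if not np.isfinite(data).all():
            raise ParameterError("Recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, channels, samples); all epochs share the
    channel count and sample count by construction.
    """

    epochs: np.ndarray
    fs: float
    condition: str
    subject_id: str = ""
    session_id: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        epochs = np.asarray(self.epochs, dtype=float)
        if epochs.ndim != 3:
            raise ParameterError("epochs must be 3-D (n, channels, samples)")
        object.__setattr__(self, "epochs", epochs)
        if self.condition not in CONDITIONS:
            raise ParameterError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if not self.fs > 0:
            raise ParameterError("sampling rate must be positive")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


# ---------------------------------------------------------------------------
# I/O

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".channels")


def _read_sidecar(path: Path) -> tuple[list[str], float]:
    names: list[str] = []
    fs = DEFAULT_FS
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.lower().startswith("fs="):
            fs = float(line.split("=", 1)[1])
        else:
            names.append(line)
    if not names:
        raise FormatError(f"{path}: sidecar lists no channels")
    return names, fs


def load_recording(path: str | Path, format: str = "auto") -> Recording:
    """Load a recording from EDF or the delimited matrix + sidecar dialect.

    The matrix dialect is a whitespace/comma-delimited numeric file, one row
    per channel, with a sidecar ``<file>.channels`` holding ``fs=<Hz>`` and
    one electrode name per line.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        data, names, fs = _edf.read_edf(path)
        return Recording(data=data, channel_names=tuple(names), fs=fs)
    if format == "matrix":
        try:
            data = np.atleast_2d(np.loadtxt(path, delimiter=None))
        except ValueError as exc:
            raise FormatError(f"{path}: cannot parse numeric matrix") from exc
        names, fs = _read_sidecar(_sidecar_path(path))
        if data.shape[0] != len(names):
            raise FormatError(
                f"{path}: matrix has {data.shape[0]} rows but sidecar lists "
                f"{len(names)} channels"
            )
        return Recording(data=data, channel_names=tuple(names), fs=fs)
    raise ParameterError(f"unknown format {format!r}")


def save_recording(rec: Recording, path: str | Path, format: str = "auto") -> None:
    """Write a recording as EDF or matrix + sidecar (chosen by extension)."""
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        _edf.write_edf(path, rec.data, list(rec.channel_names), rec.fs)
    elif format == "matrix":
        np.savetxt(path, rec.data, fmt="%.8g")
        sidecar = _sidecar_path(path)
        lines = [f"fs={rec.fs:g}"] + list(rec.channel_names)
        sidecar.write_text("\n".join(lines) + "\n")
    else:
        raise ParameterError(f"unknown format {format!r}")


def read_events(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a two-column event file: sample_index, condition in {left, right}.

    Returns (onsets, conditions).
    """
    onsets: list[int] = []
    conds: list[str] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2 or parts[1] not in ("left", "right"):
            raise FormatError(f"{path}:{ln}: expected '<sample> left|right'")
        onsets.append(int(parts[0]))
        conds.append(parts[1])
    return np.asarray(onsets, dtype=int), conds


# ---------------------------------------------------------------------------
# Preprocessing

def select_channels(rec: Recording, names: Sequence[str]) -> Recording:
    """Restrict a recording to ``names``, reordered to match the request."""
    index = {name: i for i, name in enumerate(rec.channel_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise ChannelLookupError(
            f"electrode(s) not present in recording: {', '.join(missing)}"
        )
    rows = [index[n] for n in names]
    return Recording(
        data=rec.data[rows], channel_names=tuple(names), fs=rec.fs
    )


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward, ``order`` per pass)."""
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def average_reference(rec: Recording) -> Recording:
    """Re-reference to the instantaneous cross-channel mean."""
    if rec.n_channels < 2:
        raise ParameterError("average reference requires at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def bss_artifact_hook(
    rec: Recording, cleaner: Callable[[Recording], Recording] | None = None
) -> Recording:
    """Hook for user-supplied artifact removal; identity when no cleaner given."""
    return cleaner(rec) if cleaner is not None else rec


def extract_pretrial_epochs(
    rec: Recording,
    event_onsets: Iterable[int],
    duration_s: float = 1.0,
    *,
    condition: str = "rest_pretrial",
    subject_id: str = "",
    session_id: str = "",
) -> EpochSet:
    """Cut the ``duration_s`` window ending at (and excluding) each onset.

    Epoch for onset t is ``[t - duration_s*fs, t)``. Onsets too early (or past
    the end of the recording) are skipped with a warning; the count of skipped
    onsets is carried on the returned EpochSet.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    n_win = int(round(duration_s * rec.fs))
    kept: list[np.ndarray] = []
    skipped = 0
    for onset in event_onsets:
        onset = int(onset)
        if onset < n_win or onset > rec.n_samples:
            skipped += 1
            continue
        kept.append(rec.data[:, onset - n_win : onset])
    if skipped:
        logger.warning("extract_pretrial_epochs: skipped %d onset(s)", skipped)
    epochs = (
        np.stack(kept) if kept else np.empty((0, rec.n_channels, n_win))
    )
    return EpochSet(
        epochs=epochs,
        fs=rec.fs,
        condition=condition,
        subject_id=subject_id,
        session_id=session_id,
        n_skipped=skipped,
    )
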