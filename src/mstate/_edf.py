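"""Minimal EDF (European Data Format) reader/writer.

Implements the subset of EDF needed to persist multichannel EEG: a fixed
256-byte header, one 256-byte header block per signal, and contiguous data
records of little-endian 16-bit integers with per-channel physical scaling.
All signals must share one sampling rate. Annotations, discontinuous files
and EDF+ extensions are not supported.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

__all__ = ["read_edf", "write_edf"]

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: object, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    # shortest exact-ish decimal that fits the fixed-width field
    for fmt in (f"{value:g}", f"{value:.10g}", f"{value:.{max(width - 7, 0)}e}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} bytes")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    channel_names: list[str] | tuple[str, ...],
    fs: float,
    *,
    physical_dim: str = "uV",
) -> None:
    """Write a (channels x samples) float array as a single-record EDF file."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    n_ch, n_samp = data.shape
    if n_ch != len(channel_names):
        raise ValueError("channel_names length does not match data rows")
    if fs <= 0:
        raise ValueError("fs must be positive")

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    record_duration = n_samp / fs
    now = _dt.datetime(2000, 1, 1)

    parts = [
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(header_bytes, 8),
        _field("", 44),
        _field(1, 8),
        _num(record_duration, 8),
        _field(n_ch, 4),
    ]
    for name in channel_names:
        parts.append(_field(name, 16))
    parts.extend(_field("", 80) for _ in range(n_ch))
    parts.extend(_field(physical_dim, 8) for _ in range(n_ch))
    parts.extend(_num(v, 8) for v in phys_min)
    parts.extend(_num(v, 8) for v in phys_max)
    parts.extend(_field(_DIG_MIN, 8) for _ in range(n_ch))
    parts.extend(_field(_DIG_MAX, 8) for _ in range(n_ch))
    parts.extend(_field("", 80) for _ in range(n_ch))
    parts.extend(_field(n_samp, 8) for _ in range(n_ch))
    parts.extend(_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        fh.write(digital.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, list[str], float]:
    """Read an EDF file; returns (data, channel_names, fs) with data in
    physical units (channels x samples)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise IOError(f"{path}: truncated EDF header")

    def txt(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", errors="replace").strip()

    try:
        n_records = int(txt(236, 8))
        record_duration = float(txt(244, 8))
        n_ch = int(txt(252, 4))
    except ValueError as exc:
        raise IOError(f"{path}: malformed EDF header") from exc

    off = 256
    names = [txt(off + 16 * i, 16) for i in range(n_ch)]
    off += n_ch * (16 + 80 + 8)
    phys_min = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    phys_max = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dig_min = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    dig_max = np.array([float(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    off += n_ch * 80  # prefiltering
    spr = np.array([int(txt(off + 8 * i, 8)) for i in range(n_ch)])
    off += n_ch * 8
    off += n_ch * 32  # reserved

    if len(set(spr.tolist())) != 1:
        raise IOError(f"{path}: signals with mixed sampling rates not supported")
    n_samp = int(spr[0])
    fs = n_samp / record_duration

    body = np.frombuffer(raw, dtype="<i2", offset=off)
    expected = n_records * n_ch * n_samp
    if body.size < expected:
        raise IOError(f"{path}: data section truncated")
    body = body[:expected].reshape(n_records, n_ch, n_samp)

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = np.concatenate(
        [(body[r].astype(float) - dig_min[:, None]) * scale[:, None] + phys_min[:, None]
         for r in range(n_records)],
        axis=1,
    )
    return data, names, fs
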