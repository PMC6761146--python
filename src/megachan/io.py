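"""Readers and writers for current traces.

Two plain-text interchange formats are supported:

* **Axon Text Format (ATF) 1.0** — the tab-separated text format native to
  pClamp-family acquisition software.  The sampling interval is carried in
  a ``SyncTimeUnits`` header record (microseconds per sample) and the
  remaining metadata in ``Comment=key=value`` records.
* **CSV** — two columns ``time_s,current_pA``; because CSV has no standard
  header block, metadata lives in a sidecar ``<stem>.meta`` file of
  ``key=value`` lines.

Currents are written with 4 decimal places (a 0.1 fA quantum, far below
any realistic noise floor) and the time column as ``index * dt`` so no
cumulative rounding accrues.  Round-tripping therefore preserves the
sample count exactly and each sample to within half the output quantum.
"""

from __future__ import annotations

import math
import os
from typing import Optional, TextIO

import numpy as np

from .trace import ConditionLabel, CurrentTrace

__all__ = [
    "TraceFormatError",
    "TraceDataError",
    "read_trace",
    "write_trace",
]

#: decimal places for the current column; the round-trip quantum is 10**-4 pA
CURRENT_DECIMALS = 4

#: relative jitter above which a time column is rejected as non-uniform
TIME_JITTER_TOL = 1e-6

_META_FLOAT_KEYS = {
    "sampling_rate_hz",
    "v_cis_mv",
    "filter_cutoff_hz",
    "offset_pa",
    "ca_mm",
    "bz423_mm",
    "phaso_mm",
}
_META_STR_KEYS = {"inhibitor", "source"}


class TraceFormatError(ValueError):
    """A file's structure or headers are missing or ambiguous."""


class TraceDataError(ValueError):
    """A file parsed structurally but contains invalid data values."""


def _infer_format(path: str, format: Optional[str]) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("atf", "csv"):
            raise ValueError(f"unknown trace format {format!r}; expected 'atf' or 'csv'")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext == ".atf":
        return "atf"
    if ext == ".csv":
        return "csv"
    raise ValueError(
        f"cannot infer format from extension {ext!r}; pass format='atf' or 'csv'"
    )


def _metadata_items(trace: CurrentTrace) -> list[tuple[str, str]]:
    items: list[tuple[str, str]] = [
        ("sampling_rate_hz", repr(float(trace.sampling_rate))),
        ("v_cis_mv", repr(float(trace.v_cis))),
    ]
    if trace.filter_cutoff is not None:
        items.append(("filter_cutoff_hz", repr(float(trace.filter_cutoff))))
    if trace.offset_note is not None:
        items.append(("offset_pa", repr(float(trace.offset_note))))
    c = trace.condition
    items += [
        ("ca_mm", repr(float(c.ca_mm))),
        ("bz423_mm", repr(float(c.bz423_mm))),
        ("phaso_mm", repr(float(c.phaso_mm))),
        ("inhibitor", c.inhibitor),
    ]
    if c.source is not None:
        items.append(("source", c.source))
    return items


def _build_trace(
    current: np.ndarray, sampling_rate: float, meta: dict[str, str], path: str
) -> CurrentTrace:
    bad = np.flatnonzero(~np.isfinite(current))
    if bad.size:
        raise TraceDataError(
            f"{path}: non-finite current value at data row {int(bad[0]) + 1}"
        )
    cond = ConditionLabel(
        ca_mm=float(meta.get("ca_mm", 0.0)),
        bz423_mm=float(meta.get("bz423_mm", 0.0)),
        phaso_mm=float(meta.get("phaso_mm", 0.0)),
        inhibitor=str(meta.get("inhibitor", "none")),
        source=meta.get("source"),
    )
    return CurrentTrace(
        samples=current,
        sampling_rate=sampling_rate,
        v_cis=float(meta.get("v_cis_mv", 0.0)),
        condition=cond,
        filter_cutoff=(
            float(meta["filter_cutoff_hz"]) if "filter_cutoff_hz" in meta else None
        ),
        offset_note=float(meta["offset_pa"]) if "offset_pa" in meta else None,
    )


def _check_uniform_time(time: np.ndarray, path: str) -> float:
    """Return dt; raise if the time column is non-monotonic or jittery."""
    dt_all = np.diff(time)
    if np.any(dt_all <= 0):
        raise TraceFormatError(f"{path}: time column is not strictly increasing")
    dt = float(np.median(dt_all))
    if np.max(np.abs(dt_all - dt)) > TIME_JITTER_TOL * dt:
        raise TraceFormatError(
            f"{path}: time column is not uniformly sampled "
            f"(relative jitter exceeds {TIME_JITTER_TOL:g})"
        )
    return dt


# ---------------------------------------------------------------------------
# ATF 1.0
# ---------------------------------------------------------------------------

def _write_atf(trace: CurrentTrace, fh: TextIO) -> None:
    meta = _metadata_items(trace)
    sync_us = 1e6 / trace.sampling_rate  # microseconds per sample
    records = [f'"SyncTimeUnits={sync_us:.10g}"']
    records += [f'"Comment={k}={v}"' for k, v in meta]
    fh.write("ATF\t1.0\n")
    fh.write(f"{len(records)}\t2\n")
    for rec in records:
        fh.write(rec + "\n")
    fh.write('"Time (s)"\t"Current (pA)"\n')
    dt = trace.dt
    for i, x in enumerate(trace.samples):
        fh.write(f"{i * dt:.10g}\t{x:.{CURRENT_DECIMALS}f}\n")


def _read_atf(path: str) -> CurrentTrace:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().split()
        if len(first) < 2 or first[0] != "ATF":
            raise TraceFormatError(f"{path}: not an ATF file (missing 'ATF' magic)")
        if first[1] != "1.0":
            raise TraceFormatError(f"{path}: unsupported ATF version {first[1]}")
        counts = fh.readline().split()
        if len(counts) != 2:
            raise TraceFormatError(f"{path}: malformed ATF record-count line")
        n_records, n_cols = int(counts[0]), int(counts[1])
        if n_cols != 2:
            raise TraceFormatError(
                f"{path}: expected 2 columns (time, current), found {n_cols}"
            )
        meta: dict[str, str] = {}
        sync_us: Optional[float] = None
        for _ in range(n_records):
            rec = fh.readline().strip().strip('"')
            if rec.startswith("SyncTimeUnits="):
                sync_us = float(rec.split("=", 1)[1])
            elif rec.startswith("Comment="):
                kv = rec.split("=", 2)
                if len(kv) == 3:
                    meta[kv[1]] = kv[2]
        fh.readline()  # column-title line
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[0] < 1 or data.shape[1] != 2:
        raise TraceFormatError(f"{path}: no data rows or wrong column count")
    time, current = data[:, 0], data[:, 1]
    if sync_us is not None:
        if not (math.isfinite(sync_us) and sync_us > 0):
            raise TraceFormatError(f"{path}: invalid SyncTimeUnits {sync_us}")
        sampling_rate = 1e6 / sync_us
        if time.size >= 2:
            _check_uniform_time(time, path)
    else:
        if time.size < 2:
            raise TraceFormatError(
                f"{path}: sampling interval is ambiguous "
                "(no SyncTimeUnits header and fewer than 2 rows)"
            )
        sampling_rate = 1.0 / _check_uniform_time(time, path)
    return _build_trace(current, sampling_rate, meta, path)


# ---------------------------------------------------------------------------
# CSV + sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".meta"


def _write_csv(trace: CurrentTrace, path: str) -> None:
    dt = trace.dt
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,current_pA\n")
        for i, x in enumerate(trace.samples):
            fh.write(f"{i * dt:.10g},{x:.{CURRENT_DECIMALS}f}\n")
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        for k, v in _metadata_items(trace):
            fh.write(f"{k}={v}\n")


def _read_sidecar(path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def _read_csv(path: str) -> CurrentTrace:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        if cols[:2] != ["time_s", "current_pA"]:
            raise TraceFormatError(
                f"{path}: expected header 'time_s,current_pA', got {header!r}"
            )
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[0] < 1:
        raise TraceFormatError(f"{path}: no data rows")
    time, current = data[:, 0], data[:, 1]
    meta = _read_sidecar(path)
    # the sidecar's declared rate is exact; the printed time column only
    # corroborates uniformity
    if "sampling_rate_hz" in meta:
        sampling_rate = float(meta["sampling_rate_hz"])
        if time.size >= 2:
            _check_uniform_time(time, path)
    elif time.size >= 2:
        sampling_rate = 1.0 / _check_uniform_time(time, path)
    else:
        raise TraceFormatError(
            f"{path}: sampling interval is ambiguous "
            "(single row and no sampling_rate_hz in sidecar)"
        )
    return _build_trace(current, sampling_rate, meta, path)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_trace(path: str, format: Optional[str] = None) -> CurrentTrace:
    """Read a current trace from an ATF 1.0 or CSV file.

    The format is inferred from the extension unless given explicitly.
    Raises :class:`TraceFormatError` for structural problems (missing or
    ambiguous sampling interval, non-uniform time column) and
    :class:`TraceDataError` for non-finite sample values.
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return _read_atf(path) if fmt == "atf" else _read_csv(path)


def write_trace(trace: CurrentTrace, path: str, format: Optional[str] = None) -> str:
    """Write a trace to ATF 1.0 or CSV (plus ``.meta`` sidecar); returns
    the path written."""
    fmt = _infer_format(path, format)
    if fmt == "atf":
        with open(path, "w", encoding="utf-8") as fh:
            _write_atf(trace, fh)
    else:
        _write_csv(trace, path)
    return path
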