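"""Read/write current traces and event tables; pool recordings for analysis.

Two trace containers are supported natively:

* ``tabular`` — CSV with a ``#``-prefixed ``key=value`` metadata header and a
  single ``current_pA`` column; diffable, intended for small fixtures.
* ``binary`` — the same metadata header followed by a raw little-endian
  float64 block; intended for long recordings.

Axon Binary Format (``abf``) reading is optional and requires the ``pyabf``
package; it is never written.

Event tables are CSV with the fixed schema
``recording_id, start_time_us, dwell_us, i_b_pA, normalized_blockade, label``.
Normalization is always per-recording: pooling recordings never rescales
per-event features.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import BaselineEstimate, CurrentTrace, EventRecord

__all__ = [
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "events_to_frame",
    "frame_to_events",
    "RecordingSet",
    "concatenate_recordings",
    "SchemaError",
]

EVENT_COLUMNS = [
    "recording_id",
    "start_time_us",
    "dwell_us",
    "i_b_pA",
    "normalized_blockade",
    "label",
]

_BINARY_MAGIC = "#POREPULSE-BINARY v1"
_TABULAR_MAGIC = "#POREPULSE-TRACE v1"


class SchemaError(ValueError):
    """An event table or trace file does not match the expected schema."""


def _meta_lines(trace: CurrentTrace) -> list[str]:
    lines = [f"#sampling_interval_us={trace.sampling_interval!r}"]
    if trace.filter_cutoff is not None:
        lines.append(f"#filter_cutoff_khz={trace.filter_cutoff!r}")
    if trace.voltage is not None:
        lines.append(f"#voltage_mv={trace.voltage!r}")
    if trace.label:
        lines.append(f"#label={trace.label}")
    return lines


def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, value = body.split("=", 1)
        meta[key.strip()] = value.strip()
    kwargs: dict = {}
    if "sampling_interval_us" not in meta:
        raise SchemaError("trace header missing sampling_interval_us")
    try:
        kwargs["sampling_interval"] = float(meta["sampling_interval_us"])
    except ValueError as exc:
        raise SchemaError("unparseable sampling_interval_us in header") from exc
    if "filter_cutoff_khz" in meta:
        kwargs["filter_cutoff"] = float(meta["filter_cutoff_khz"])
    if "voltage_mv" in meta:
        kwargs["voltage"] = float(meta["voltage_mv"])
    kwargs["label"] = meta.get("label", "")
    return kwargs


def write_trace(trace: CurrentTrace, path: str | os.PathLike, format_id: str = "tabular") -> Path:
    """Write a trace to ``path`` in the given format; returns the path."""
    path = Path(path)
    if format_id == "tabular":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_TABULAR_MAGIC + "\n")
            for line in _meta_lines(trace):
                fh.write(line + "\n")
            fh.write("current_pA\n")
            np.savetxt(fh, trace.samples, fmt="%.6f")
    elif format_id == "binary":
        with open(path, "wb") as fh:
            header = [_BINARY_MAGIC, *_meta_lines(trace),
                      f"#DATA n={trace.n_samples} dtype=float64"]
            fh.write(("\n".join(header) + "\n").encode("utf-8"))
            fh.write(np.ascontiguousarray(trace.samples, dtype="<f8").tobytes())
    elif format_id == "abf":
        raise ValueError("writing Axon Binary Format is not supported")
    else:
        raise ValueError(f"unknown trace format {format_id!r}")
    return path


def read_trace(path: str | os.PathLike, format_id: str = "tabular") -> CurrentTrace:
    """Read a trace written by :func:`write_trace` (or an ABF file)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_id == "tabular":
        return _read_tabular(path)
    if format_id == "binary":
        return _read_binary(path)
    if format_id == "abf":
        return _read_abf(path)
    raise ValueError(f"unknown trace format {format_id!r}")


def _read_tabular(path: Path) -> CurrentTrace:
    header: list[str] = []
    body_start = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                header.append(line.rstrip("\n"))
                body_start += len(line)
            else:
                break
    kwargs = _parse_meta(header)
    with open(path, "r", encoding="utf-8") as fh:
        fh.seek(body_start)
        df = pd.read_csv(fh)
    if "current_pA" not in df.columns:
        raise SchemaError("tabular trace missing current_pA column")
    samples = df["current_pA"].to_numpy(dtype=float)
    if samples.size == 0:
        raise ValueError("no samples in trace file")
    finite = np.isfinite(samples)
    if not finite.all():
        idx = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite sample at index {idx}")
    return CurrentTrace(samples=samples, **kwargs)


def _read_binary(path: Path) -> CurrentTrace:
    with open(path, "rb") as fh:
        header: list[str] = []
        while True:
            line = fh.readline()
            if not line.startswith(b"#"):
                raise SchemaError("binary trace header not terminated by #DATA line")
            text = line.decode("utf-8").rstrip("\n")
            header.append(text)
            if text.startswith("#DATA"):
                break
        if header[0] != _BINARY_MAGIC:
            raise SchemaError("not a porepulse binary trace")
        data_line = header[-1]
        fields = dict(
            item.split("=", 1) for item in data_line.split() if "=" in item
        )
        n = int(fields["n"])
        samples = np.frombuffer(fh.read(n * 8), dtype="<f8")
        if samples.size != n:
            raise SchemaError("binary trace truncated")
    kwargs = _parse_meta(header[1:-1])
    if n == 0:
        raise ValueError("no samples in trace file")
    return CurrentTrace(samples=samples.copy(), **kwargs)


def _read_abf(path: Path) -> CurrentTrace:
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading Axon Binary Format requires the optional 'pyabf' package "
            "(pip install porepulse[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover - optional dependency
    abf.setSweep(0)
    return CurrentTrace(
        samples=np.asarray(abf.sweepY, dtype=float),
        sampling_interval=1e6 / abf.dataRate,
        label=Path(path).stem,
    )


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

def events_to_frame(events: list[EventRecord]) -> pd.DataFrame:
    rows = [
        {
            "recording_id": ev.recording_id,
            "start_time_us": ev.start_time,
            "dwell_us": ev.dwell,
            "i_b_pA": ev.i_b,
            "normalized_blockade": ev.normalized_blockade,
            "label": "" if ev.label is None else ev.label,
        }
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[EventRecord]:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event table missing column(s): {', '.join(missing)}")
    events = []
    for row in df.itertuples(index=False):
        label = getattr(row, "label")
        if label is None or (isinstance(label, float) and np.isnan(label)):
            label = None
        label = None if label in (None, "") else str(label)
        events.append(
            EventRecord(
                recording_id=str(getattr(row, "recording_id")),
                start_time=float(getattr(row, "start_time_us")),
                dwell=float(getattr(row, "dwell_us")),
                i_b=float(getattr(row, "i_b_pA")),
                normalized_blockade=float(getattr(row, "normalized_blockade")),
                label=label,
            )
        )
    return events


def write_events(events: list[EventRecord], path: str | os.PathLike) -> Path:
    """Write events to CSV with the fixed schema; empty lists yield a header-only file."""
    path = Path(path)
    events_to_frame(events).to_csv(path, index=False)
    return path


def read_events(path: str | os.PathLike) -> list[EventRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return frame_to_events(df)


# ---------------------------------------------------------------------------
# Recording sets
# ---------------------------------------------------------------------------

@dataclass
class RecordingSet:
    """Events from multiple recordings, each with its own baseline.

    Normalized blockade is computed against each recording's own open-pore
    current before pooling, so recordings with different I0 can be analyzed
    together.
    """

    events: dict[str, list[EventRecord]] = field(default_factory=dict)
    baselines: dict[str, BaselineEstimate | None] = field(default_factory=dict)

    def add_recording(
        self,
        recording_id: str,
        events: list[EventRecord],
        baseline: BaselineEstimate | None,
    ) -> None:
        if recording_id in self.events:
            raise ValueError(f"duplicate recording id {recording_id!r}")
        self.events[recording_id] = list(events)
        self.baselines[recording_id] = baseline


def concatenate_recordings(recording_set: RecordingSet) -> list[EventRecord]:
    """Pool events from all recordings, preserving per-event features.

    Every recording must carry a baseline (proof that its events were
    normalized against its own I0).  The pooled list is ordered by recording
    id, then by event start time.
    """
    pooled: list[EventRecord] = []
    for rec_id in sorted(recording_set.events):
        baseline = recording_set.baselines.get(rec_id)
        if baseline is None:
            raise ValueError(f"recording {rec_id!r} lacks a baseline estimate")
        pooled.extend(
            sorted(recording_set.events[rec_id], key=lambda ev: ev.start_time)
        )
    return pooled
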