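"""Core record types shared across the resistive-pulse analysis pipeline.

Conventions used throughout the package:

* current in picoamperes (pA),
* time in microseconds (μs) internally; dwell-time *modes* are reported in
  milliseconds (ms) at the presentation layer,
* normalized blockade level ``(I0 - Ib) / I0`` is dimensionless in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CurrentTrace", "BaselineEstimate", "EventRecord"]


@dataclass
class CurrentTrace:
    """A sampled ionic-current recording through a single nanopore.

    Parameters
    ----------
    samples
        Current values in pA, in acquisition order.
    sampling_interval
        Time per sample in μs (e.g. 4.0 for 250 kHz digitization).
    filter_cutoff
        Low-pass cutoff in kHz applied to the signal, or ``None`` for an
        unfiltered trace.
    voltage
        Applied trans-membrane potential in mV, if known.
    label
        Free-text recording identifier.
    """

    samples: np.ndarray
    sampling_interval: float
    filter_cutoff: float | None = None
    voltage: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("no samples: a trace requires at least one sample")
        if not (np.isfinite(self.sampling_interval) and self.sampling_interval > 0):
            raise ValueError("sampling_interval must be a positive number of μs")
        finite = np.isfinite(self.samples)
        if not finite.all():
            idx = int(np.flatnonzero(~finite)[0])
            raise ValueError(f"non-finite sample at index {idx}")
        if self.filter_cutoff is not None and not self.filter_cutoff > 0:
            raise ValueError("filter_cutoff must be positive (kHz) or None")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Total recorded duration in seconds."""
        return self.n_samples * self.sampling_interval * 1e-6

    def time_us(self) -> np.ndarray:
        """Sample timestamps in μs from the start of the recording."""
        return np.arange(self.n_samples, dtype=float) * self.sampling_interval


@dataclass(frozen=True)
class BaselineEstimate:
    """Open-pore baseline statistics: mean current I0 and noise SD δ."""

    i0: float
    delta: float
    n_samples_used: int

    def __post_init__(self) -> None:
        if not self.i0 > 0:
            raise ValueError("baseline i0 must be positive")
        if self.delta < 0:
            raise ValueError("baseline delta must be non-negative")

    def threshold(self, k: float = 5.0) -> float:
        """Event-detection threshold ``I0 - k * δ``."""
        return self.i0 - k * self.delta


# Records with normalized blockade at or below zero are physically suspect
# (the event current met or exceeded the open-pore level); they are kept but
# flagged so downstream filters can drop them.  Values below this floor are
# rejected outright.
_BLOCKADE_FLOOR = -0.1


@dataclass
class EventRecord:
    """One detected (or simulated ground-truth) blockade event.

    ``start_index``/``end_index`` delimit the half-open sample interval
    ``[start, end)`` in the source trace; they are ``None`` for events loaded
    from an event table, where only times survive.
    """

    recording_id: str
    start_time: float  # μs from the start of the recording
    dwell: float  # μs
    i_b: float  # mean blockade current, pA
    normalized_blockade: float
    label: str | None = None
    start_index: int | None = None
    end_index: int | None = None
    flagged: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.dwell > 0:
            raise ValueError("event dwell must be positive")
        if self.start_index is not None and self.end_index is not None:
            if not self.end_index > self.start_index:
                raise ValueError("event end_index must exceed start_index")
        nb = self.normalized_blockade
        if not (nb > _BLOCKADE_FLOOR and nb <= 1.0):
            raise ValueError(
                f"normalized blockade {nb!r} outside ({_BLOCKADE_FLOOR}, 1]"
            )
        if nb <= 0.0:
            self.flagged = True
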