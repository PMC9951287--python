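"""Baseline estimation, threshold event detection, and event measurement.

Detection follows the classical resistive-pulse rule: an event is a maximal
run of samples below ``I0 - k * δ`` (default k = 5), where I0 and δ are the
mean and SD of the open-pore baseline.  Dwell time is the span between the
threshold crossings; the blockade current ``Ib`` is the mean of the event
interior; the normalized blockade level is ``(I0 - Ib) / I0``.

Because the anti-aliasing low-pass filter rounds event edges, the first and
last samples of an event partially belong to the transition.  When the trace
records a filter cutoff, the interior mean additionally excludes a settling
guard of ``0.5 / f_c`` on each side (≈ 100 μs at 5 kHz); the guard is waived
whenever it would leave no interior samples.
"""

from __future__ import annotations

import numpy as np

from .records import BaselineEstimate, CurrentTrace, EventRecord

__all__ = [
    "estimate_baseline",
    "detect_events",
    "measure_event",
    "normalized_blockade",
    "filter_translocations",
    "BaselineConvergenceError",
]

#: Bumping/translocation dwell boundary (μs): events at or below this are
#: molecules probing the pore mouth, not translocations.
BUMPING_DWELL_US = 200.0


class BaselineConvergenceError(RuntimeError):
    """Iterative baseline estimation failed to converge.

    Carries the last iterate in ``last_estimate``.
    """

    def __init__(self, message: str, last_estimate: BaselineEstimate):
        super().__init__(message)
        self.last_estimate = last_estimate


def estimate_baseline(
    trace: CurrentTrace,
    k_exclude: float = 5.0,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> BaselineEstimate:
    """Estimate open-pore mean I0 and noise SD δ, excluding event samples.

    Seeded robustly from the median and scaled MAD (blockade events can pull
    a plain mean/SD far enough that no sample falls below ``mean - k·SD``),
    then iterated: retain samples ``>= i0 - k_exclude * δ``, recompute mean
    and SD, repeat until both change by less than ``tol`` (pA).
    """
    x = trace.samples
    if x.size < 1000:
        raise ValueError("baseline estimation requires at least 1000 samples")
    if k_exclude <= 0:
        raise ValueError("k_exclude must be positive")

    med = float(np.median(x))
    mad_sd = 1.4826 * float(np.median(np.abs(x - med)))
    i0, delta = med, mad_sd
    for _ in range(max_iter):
        mask = x >= i0 - k_exclude * delta
        n_used = int(mask.sum())
        if n_used == 0:
            raise ValueError("baseline estimation retained no samples")
        new_i0 = float(x[mask].mean())
        new_delta = float(x[mask].std())
        if abs(new_i0 - i0) < tol and abs(new_delta - delta) < tol:
            return BaselineEstimate(i0=new_i0, delta=new_delta, n_samples_used=n_used)
        i0, delta = new_i0, new_delta
    raise BaselineConvergenceError(
        f"baseline estimate did not converge within {max_iter} iterations",
        BaselineEstimate(i0=i0, delta=delta, n_samples_used=n_used),
    )


def normalized_blockade(i0: float, i_b: float) -> float:
    """Normalized blockade level ``(I0 - Ib) / I0``."""
    if not i0 > 0:
        raise ValueError("i0 must be positive")
    return (i0 - i_b) / i0


def _settle_samples(trace: CurrentTrace) -> int:
    """Samples to skip at each event edge for filter settling (0.5 / f_c)."""
    if trace.filter_cutoff is None:
        return 0
    settle_us = 0.5 / (trace.filter_cutoff * 1e3) * 1e6
    return int(round(settle_us / trace.sampling_interval))


def measure_event(
    trace: CurrentTrace,
    start: int,
    end: int,
    baseline: BaselineEstimate | None = None,
    settle_samples: int | None = None,
) -> tuple[float, float]:
    """Measure one event: (dwell μs, mean blockade current Ib pA).

    ``[start, end)`` is the half-open sample interval between the threshold
    crossings.  The Ib mean is over the interior: the boundary samples are
    excluded when at least one interior sample remains, and a filter-settling
    guard is additionally excluded when the trace records a low-pass cutoff
    (waived progressively for short events).
    """
    n = end - start
    if n <= 0 or start < 0 or end > trace.n_samples:
        raise ValueError("invalid event boundaries")
    dwell = n * trace.sampling_interval
    if settle_samples is None:
        settle_samples = _settle_samples(trace)
    lo, hi = start + 1 + settle_samples, end - 1 - settle_samples
    if hi <= lo:
        lo, hi = start + 1, end - 1  # guard waived
    if hi <= lo:
        lo, hi = start, end  # boundary exclusion waived (< 3 samples)
    i_b = float(trace.samples[lo:hi].mean())
    return dwell, i_b


def _refine_midpoint(
    samples: np.ndarray, start: int, end: int, i0: float, i_b: float
) -> tuple[int, int]:
    """Move event boundaries to the half-amplitude crossings.

    The k·δ threshold sits near the top of the blockade, so with a low-pass
    filtered trace the crossing boundaries overstate the dwell by roughly the
    filter rise time.  The 50 %-amplitude crossings of a (zero-phase
    filtered) rectangular pulse coincide with its true edges, so dwell is
    measured between the first and last sample below ``(I0 + Ib) / 2``
    within the run.  Falls back to the original boundaries when no sample
    reaches the midpoint level (very shallow or truncated events).
    """
    midlevel = 0.5 * (i0 + i_b)
    seg = samples[start:end]
    deep = np.flatnonzero(seg < midlevel)
    if deep.size == 0:
        return start, end
    return start + int(deep[0]), start + int(deep[-1]) + 1


def detect_events(
    trace: CurrentTrace,
    baseline: BaselineEstimate,
    k: float = 5.0,
    min_samples: int = 2,
    recording_id: str | None = None,
    refine_midpoint: bool | None = None,
) -> list[EventRecord]:
    """Detect blockade events as maximal runs below ``I0 - k * δ``.

    Runs shorter than ``min_samples`` are ignored; runs touching either end
    of the trace are discarded (their dwell is unknowable).  Events are
    returned in time order and do not overlap.  Only downward excursions are
    considered: analytes block current, they do not enhance it.

    ``refine_midpoint`` re-measures boundaries at the half-amplitude
    crossings to undo the filter-broadening of threshold-crossing dwell;
    it defaults to on for filtered traces and off otherwise.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    rec_id = recording_id if recording_id is not None else (trace.label or "trace")
    if refine_midpoint is None:
        refine_midpoint = trace.filter_cutoff is not None

    threshold = baseline.threshold(k)
    below = trace.samples < threshold
    padded = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)

    dt = trace.sampling_interval
    settle = _settle_samples(trace)
    events: list[EventRecord] = []
    for s, e in zip(starts, ends):
        if e - s < min_samples:
            continue
        if s == 0 or e == trace.n_samples:
            continue  # touches a trace end
        dwell, i_b = measure_event(trace, int(s), int(e), baseline, settle)
        if refine_midpoint:
            s, e = _refine_midpoint(trace.samples, int(s), int(e), baseline.i0, i_b)
            if e - s < 1:
                continue
            dwell, i_b = measure_event(trace, int(s), int(e), baseline, settle)
        nb = normalized_blockade(baseline.i0, i_b)
        if nb <= -0.1 or nb > 1.0:
            continue  # not a physical blockade of this baseline
        events.append(
            EventRecord(
                recording_id=rec_id,
                start_time=float(s * dt),
                dwell=dwell,
                i_b=i_b,
                normalized_blockade=nb,
                start_index=int(s),
                end_index=int(e),
            )
        )
    return events


def filter_translocations(
    events: list[EventRecord],
    min_dwell: float = BUMPING_DWELL_US,
    min_blockade: float | None = None,
) -> list[EventRecord]:
    """Drop bumping events: keep dwell > ``min_dwell`` (μs) and, when given,
    normalized blockade >= ``min_blockade``.  Flagged events are dropped."""
    kept = []
    for ev in events:
        if ev.flagged:
            continue
        if not ev.dwell > min_dwell:
            continue
        if min_blockade is not None and ev.normalized_blockade < min_blockade:
            continue
        kept.append(ev)
    return kept
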