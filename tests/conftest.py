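"""Shared fixtures: small simulated recordings and event-building helpers."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from porepulse import (
    EventRecord,
    SimulationConfig,
    default_population_library,
    detect_events,
    estimate_baseline,
    filter_translocations,
    simulate_recording,
)


@pytest.fixture(scope="session")
def library():
    return default_population_library()


def make_config(pop_names, duration, seed, rates=None, library=None, **kwargs):
    """SimulationConfig over named library populations, optionally re-rated."""
    library = library or default_population_library()
    pops = []
    for i, name in enumerate(pop_names):
        p = library[name]
        if rates is not None:
            p = dataclasses.replace(p, rate=rates[i])
        pops.append(p)
    return SimulationConfig(duration=duration, populations=pops, seed=seed, **kwargs)


def run_detection(config, min_blockade=0.35):
    """simulate → baseline → detect → translocation-filter; returns all stages."""
    trace, truth = simulate_recording(config)
    baseline = estimate_baseline(trace)
    events = detect_events(trace, baseline)
    translocations = filter_translocations(events, min_blockade=min_blockade)
    return trace, truth, baseline, events, translocations


def events_from_population(pop, n, rng, recording_id="synthetic"):
    """Build EventRecords directly from a population's generating
    distributions (no trace rendering), labeled with the population name."""
    from porepulse.synthetic_data import sample_population_events

    events = []
    t = 0.0
    for dwell, blockade, name in sample_population_events(pop, n, rng):
        events.append(
            EventRecord(
                recording_id=recording_id,
                start_time=t,
                dwell=dwell,
                i_b=115.0 * (1 - blockade),
                normalized_blockade=blockade,
                label=name,
            )
        )
        t += dwell + 1e4
    return events


def match_to_truth(truth, events, tol_us=300.0):
    """Match detected events to ground-truth events by start time.

    Returns (matched pairs as index tuples, unmatched truth, unmatched events).
    """
    pairs = []
    used = set()
    starts = np.array([ev.start_time for ev in events])
    for i in range(len(truth)):
        t0 = truth.start_us[i]
        if starts.size == 0:
            continue
        j = int(np.argmin(np.abs(starts - t0)))
        if abs(starts[j] - t0) <= tol_us and j not in used:
            pairs.append((i, j))
            used.add(j)
    unmatched_truth = [i for i in range(len(truth)) if i not in {p[0] for p in pairs}]
    unmatched_events = [j for j in range(len(events)) if j not in used]
    return pairs, unmatched_truth, unmatched_events


@pytest.fixture(scope="session")
def fpa_small_run(library):
    """A modest FPA-only recording (~800 translocations) shared by tests."""
    config = make_config(["FPA"], duration=40.0, seed=101)
    return run_detection(config)
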