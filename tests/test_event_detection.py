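"""Baseline estimation, threshold detection, and event measurement."""

from __future__ import annotations

import numpy as np
import pytest

from porepulse import (
    BaselineEstimate,
    CurrentTrace,
    detect_events,
    estimate_baseline,
    filter_translocations,
    measure_event,
    normalized_blockade,
)
from tests.conftest import make_config, match_to_truth, run_detection


def constant_trace(value=115.0, n=2000, **kwargs):
    kwargs.setdefault("sampling_interval", 4.0)
    return CurrentTrace(samples=np.full(n, value), **kwargs)


def trace_with_events(
    n=100_000, i0=115.0, noise_sd=1.7, depth=17.0, dwell_samples=250,
    spacing=2500, seed=0, n_events=10,
):
    """Rectangular events injected into iid Gaussian noise (no filter)."""
    rng = np.random.default_rng(seed)
    samples = rng.normal(i0, noise_sd, n)
    starts = []
    for i in range(n_events):
        s = 5000 + i * spacing
        samples[s:s + dwell_samples] -= depth
        starts.append(s)
    return CurrentTrace(samples=samples, sampling_interval=4.0), starts


class TestBaseline:
    def test_constant_trace(self):
        est = estimate_baseline(constant_trace())
        assert est.i0 == 115.0
        assert est.delta == 0.0

    def test_gaussian_recovery(self):
        rng = np.random.default_rng(1)
        n = 200_000
        trace = CurrentTrace(rng.normal(114.98, 1.67, n), 4.0)
        est = estimate_baseline(trace)
        assert abs(est.i0 - 114.98) < 3 * 1.67 / np.sqrt(n)
        assert abs(est.delta - 1.67) < 3 * 1.67 / np.sqrt(2 * n)

    def test_event_contaminated_recovery(self):
        """10 % of samples inside deep blockades must not drag I0 down."""
        rng = np.random.default_rng(2)
        n = 100_000
        samples = rng.normal(115.0, 1.7, n)
        samples[::10] = rng.normal(115.0 * 0.4, 1.7, n // 10)  # b = 0.6
        est = estimate_baseline(CurrentTrace(samples, 4.0))
        assert abs(est.i0 - 115.0) < 0.5

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            estimate_baseline(constant_trace(n=500))


class TestDetect:
    def test_constant_trace_no_events(self):
        trace = constant_trace()
        baseline = estimate_baseline(trace)
        assert detect_events(trace, baseline) == []

    def test_injected_events_all_found(self):
        trace, starts = trace_with_events()
        baseline = estimate_baseline(trace)
        events = detect_events(trace, baseline)
        assert len(events) == len(starts)
        for ev, s in zip(events, starts):
            assert abs(ev.dwell - 1000.0) <= 2 * 4.0  # ±2 samples
            assert abs(ev.start_index - s) <= 2

    def test_shallow_events_mostly_missed(self):
        """Events 3δ deep sit above the 5δ threshold on average; with a
        4-sample run requirement the chance of four consecutive noise
        excursions below −2δ is vanishing."""
        trace, starts = trace_with_events(depth=3 * 1.7, n_events=40, seed=3)
        baseline = estimate_baseline(trace)
        events = detect_events(trace, baseline, min_samples=4)
        assert len(events) / len(starts) < 0.05

    def test_deep_vs_shallow_detection_ordering(self):
        deep, starts = trace_with_events(depth=10 * 1.7, seed=4)
        shallow, _ = trace_with_events(depth=3 * 1.7, seed=4)
        bl_deep = estimate_baseline(deep)
        bl_shallow = estimate_baseline(shallow)
        n_deep = len(detect_events(deep, bl_deep))
        n_shallow = len(detect_events(shallow, bl_shallow))
        assert n_deep == len(starts)
        assert n_shallow < n_deep

    def test_k_monotonicity(self):
        """Raising k (deepening the threshold) never yields more events:
        events of graded depth drop out one by one."""
        samples = np.full(20_000, 115.0)
        for i, depth in enumerate(range(3, 11)):  # depths 3δ..10δ with δ = 1
            s = 1000 + i * 2000
            samples[s:s + 250] = 115.0 - depth
        trace = CurrentTrace(samples, 4.0)
        baseline = BaselineEstimate(115.0, 1.0, 20_000)
        counts = [
            len(detect_events(trace, baseline, k=k))
            for k in (2.5, 3.5, 5.0, 6.5, 8.5, 10.5)
        ]
        assert counts[0] == 8 and counts[-1] == 0
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_invalid_k_rejected(self):
        trace = constant_trace()
        baseline = estimate_baseline(trace)
        with pytest.raises(ValueError):
            detect_events(trace, baseline, k=0)

    def test_noiseless_delta_zero_is_legal(self):
        """δ = 0 on a noiseless synthetic trace: any drop is an event."""
        samples = np.full(5000, 115.0)
        samples[1000:1250] = 42.55
        trace = CurrentTrace(samples, 4.0)
        baseline = BaselineEstimate(115.0, 0.0, 4750)
        events = detect_events(trace, baseline)
        assert len(events) == 1
        assert events[0].dwell == 1000.0
        assert events[0].i_b == pytest.approx(42.55)

    def test_events_touching_trace_ends_discarded(self):
        samples = np.full(5000, 115.0)
        samples[:100] = 40.0
        samples[-100:] = 40.0
        samples[2000:2200] = 40.0
        trace = CurrentTrace(samples, 4.0)
        events = detect_events(trace, BaselineEstimate(115.0, 0.0, 4800))
        assert len(events) == 1
        assert events[0].start_index == 2000

    def test_brute_force_equivalence(self):
        """Threshold-rule detection equals an independent exhaustive scan."""
        trace, _ = trace_with_events(n=50_000, seed=6, n_events=15, spacing=3000)
        baseline = estimate_baseline(trace)
        events = detect_events(trace, baseline, refine_midpoint=False)

        # independent brute-force scan
        thr = baseline.i0 - 5 * baseline.delta
        expected = []
        run_start = None
        for i, v in enumerate(trace.samples):
            if v < thr and run_start is None:
                run_start = i
            elif v >= thr and run_start is not None:
                if i - run_start >= 2 and run_start > 0:
                    expected.append((run_start, i))
                run_start = None
        # (a trailing run would touch the end; none is expected here)
        got = [(ev.start_index, ev.end_index) for ev in events]
        assert got == expected


class TestMeasure:
    def test_dwell_arithmetic(self):
        trace = constant_trace(n=5000)
        dwell, _ = measure_event(trace, 100, 350)
        assert dwell == 250 * 4.0  # 1000 μs

    def test_two_sample_event_uses_both_samples(self):
        samples = np.full(2000, 115.0)
        samples[500] = 40.0
        samples[501] = 42.0
        trace = CurrentTrace(samples, 4.0)
        _, i_b = measure_event(trace, 500, 502)
        assert i_b == pytest.approx(41.0)

    def test_interior_excludes_boundaries(self):
        samples = np.full(2000, 115.0)
        samples[500:600] = 42.0
        samples[500] = 80.0  # partial boundary samples
        samples[599] = 80.0
        trace = CurrentTrace(samples, 4.0)  # unfiltered: no settle guard
        _, i_b = measure_event(trace, 500, 600)
        assert i_b == pytest.approx(42.0)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            measure_event(constant_trace(), 10, 10)

    @pytest.mark.parametrize(
        "i0, i_b, expected",
        [(115.0, 115.0, 0.0), (115.0, 0.0, 1.0), (114.98, 42.54, 0.630)],
    )
    def test_normalized_blockade(self, i0, i_b, expected):
        assert normalized_blockade(i0, i_b) == pytest.approx(expected, abs=5e-4)

    def test_normalized_blockade_requires_positive_i0(self):
        with pytest.raises(ValueError):
            normalized_blockade(0.0, 10.0)


class TestTranslocationFilter:
    def test_all_short_events_removed(self, fpa_small_run):
        _, _, _, events, _ = fpa_small_run
        short = [ev for ev in events if ev.dwell < 200]
        assert filter_translocations(short) == []

    def test_identity_with_no_bounds(self, fpa_small_run):
        _, _, _, events, _ = fpa_small_run
        unflagged = [ev for ev in events if not ev.flagged]
        assert filter_translocations(events, min_dwell=0.0) == unflagged

    def test_retains_labeled_translocations(self, fpa_small_run):
        """>99 % of true translocations survive the 200 μs bumping filter:
        the smallest dwell mode (0.62 ms) sits well above the cut."""
        _, truth, _, events, translocations = fpa_small_run
        trans_truth_idx = [
            i for i in range(len(truth)) if truth.population[i] != "bumping"
        ]
        pairs, _, _ = match_to_truth(truth, translocations)
        matched_truth = {i for i, _ in pairs}
        retained = sum(1 for i in trans_truth_idx if i in matched_truth)
        assert retained / len(trans_truth_idx) > 0.99


class TestEndToEnd:
    def test_detection_bijection_on_clean_recording(self, fpa_small_run):
        """On a clean simulated recording, detected translocations pair
        one-to-one with true translocations."""
        _, truth, _, events, translocations = fpa_small_run
        pairs, unmatched_truth, unmatched_events = match_to_truth(
            truth, translocations
        )
        trans_truth = [i for i in range(len(truth))
                       if truth.population[i] != "bumping"]
        # every true translocation is found
        missed = set(trans_truth) - {i for i, _ in pairs}
        assert len(missed) / len(trans_truth) < 0.005
        # dwell errors are within 2 samples + the filter rise allowance
        dt = 4.0
        errs = [
            abs(translocations[j].dwell - truth.dwell_us[i])
            for i, j in pairs
            if truth.population[i] != "bumping"
        ]
        assert np.median(errs) < 2 * dt + 70.0
        assert np.quantile(errs, 0.95) < 2 * dt + 70.0

    def test_single_population_blockade_unbiased(self):
        """Pipeline-recovered blockade center of one simulated population
        stays within 0.005 of the generating mean."""
        from porepulse import fit_gaussians

        config = make_config(["FPA"], duration=60.0, seed=401)
        _, _, _, _, translocations = run_detection(config)
        assert len(translocations) > 1000
        blockades = np.array([ev.normalized_blockade for ev in translocations])
        fit = fit_gaussians(blockades, k=1)
        assert abs(fit.components[0].center - 0.63) < 0.005
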