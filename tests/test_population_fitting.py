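"""Histogram fits: Gaussian blockade components, log-normal dwell modes."""

from __future__ import annotations

import numpy as np
import pytest

from porepulse import (
    EventSelectionBox,
    build_histogram,
    fit_gaussians,
    fit_lognormal,
    population_signature,
    repeated_fit,
    select_box,
)
from porepulse.population_fitting import FitError, UnresolvedPeaksError
from tests.conftest import events_from_population


class TestHistogram:
    def test_identical_values_single_bin(self):
        hist = build_histogram(np.full(100, 0.63), "blockade")
        assert np.count_nonzero(hist.counts) == 1
        assert hist.counts.sum() == 100

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0.1, 0.9, 1234)
        hist = build_histogram(values, "blockade")
        assert hist.counts.sum() == 1234

    def test_argmax_bin_near_true_mean(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.63, 0.01, 10_000)
        hist = build_histogram(values, "blockade")
        peak_center = hist.centers[np.argmax(hist.counts)]
        bin_width = hist.bin_edges[1] - hist.bin_edges[0]
        assert abs(peak_center - 0.63) <= bin_width

    def test_dwell_bins_log_spaced(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(8.0, 0.6, 500)
        hist = build_histogram(values, "dwell")
        ratios = hist.bin_edges[1:] / hist.bin_edges[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([], "blockade")


class TestGaussianFit:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0.63, 0.01, 3000)
        fit = fit_gaussians(values, k=1)
        assert abs(fit.components[0].center - 0.63) < 0.005
        assert abs(fit.components[0].width - 0.01) < 0.005

    def test_two_component_recovery(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([
            rng.normal(0.71, 0.02, 1500), rng.normal(0.61, 0.01, 1500)
        ])
        fit = fit_gaussians(values, k=2)
        centers = fit.centers
        assert abs(centers[0] - 0.61) < 0.01
        assert abs(centers[1] - 0.71) < 0.01

    def test_centers_sorted(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([
            rng.normal(0.43, 0.01, 800), rng.normal(0.55, 0.01, 800),
            rng.normal(0.71, 0.02, 800),
        ])
        fit = fit_gaussians(values, k=3)
        assert np.all(np.diff(fit.centers) > 0)

    def test_identical_values_degenerate(self):
        with pytest.raises(FitError, match="nonzero bins"):
            fit_gaussians(np.full(500, 0.63), k=1)

    def test_k_beyond_visible_peaks_rejected(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([
            rng.normal(0.43, 0.01, 2000), rng.normal(0.63, 0.01, 2000)
        ])  # two visible peaks
        with pytest.raises(UnresolvedPeaksError):
            fit_gaussians(values, k=4)

    def test_explicit_init_overrides_peak_detection(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([
            rng.normal(0.61, 0.01, 2000), rng.normal(0.63, 0.01, 2000)
        ])  # merged bump: one visible peak
        fit = fit_gaussians(values, k=2, init=[0.61, 0.63])
        assert abs(fit.centers[0] - 0.61) < 0.01
        assert abs(fit.centers[1] - 0.63) < 0.01

    def test_center_agrees_with_sample_mean(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0.55, 0.012, 5000)
        fit = fit_gaussians(values, k=1)
        bin_width = 0.01
        assert abs(fit.components[0].center - values.mean()) < 2 * bin_width


class TestLogNormalFit:
    def test_mode_recovery(self):
        rng = np.random.default_rng(9)
        mu = np.log(5740.0) + 0.36
        dwells = rng.lognormal(mu, 0.6, 10_000)
        fit = fit_lognormal(dwells)
        assert abs(fit.components[0].mode - 5740.0) / 5740.0 < 0.05

    def test_mode_identity_exact(self):
        rng = np.random.default_rng(10)
        dwells = rng.lognormal(7.0, 0.5, 1000)
        comp = fit_lognormal(dwells).components[0]
        assert comp.mode == pytest.approx(np.exp(comp.mu - comp.sigma**2), rel=1e-12)

    def test_histogram_vs_mle_agreement(self):
        rng = np.random.default_rng(11)
        dwells = rng.lognormal(np.log(950) + 0.36, 0.6, 10_000)
        hist_mode = fit_lognormal(dwells, method="histogram").components[0].mode
        mle_mode = fit_lognormal(dwells, method="mle").components[0].mode
        assert abs(hist_mode - mle_mode) / mle_mode < 0.05

    def test_degenerate_sample_returns_common_value(self):
        fit = fit_lognormal(np.full(100, 2500.0))
        assert fit.components[0].mode == pytest.approx(2500.0)

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal(np.array([100.0, -5.0] * 50))

    def test_small_sample_rejected(self):
        with pytest.raises(FitError, match="50"):
            fit_lognormal(np.full(10, 100.0) + np.arange(10))


class TestRepeatedFit:
    def test_single_repeat_zero_sd(self):
        rng = np.random.default_rng(12)
        values = rng.normal(0.63, 0.01, 2000)
        fit = repeated_fit(values, lambda v: fit_gaussians(v, k=1),
                           n_repeats=1, seed=0)
        assert fit.param_sd[0]["center"] == 0.0

    def test_bootstrap_sd_scale(self):
        """Three bootstrap fits on an FPA-sized sample give a center sd of
        the same order as the printed ±0.01 uncertainties."""
        rng = np.random.default_rng(13)
        values = rng.normal(0.63, 0.01, 3000)
        fit = repeated_fit(values, lambda v: fit_gaussians(v, k=1),
                           n_repeats=3, seed=1)
        assert 0.0 < fit.param_sd[0]["center"] < 0.02

    def test_deterministic_values_propagate_degenerate_error(self):
        values = np.full(200, 0.5)
        with pytest.raises(FitError):
            repeated_fit(values, lambda v: fit_gaussians(v, k=1), seed=2)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(14)
        values = rng.normal(0.55, 0.01, 1000)
        f1 = repeated_fit(values, lambda v: fit_gaussians(v, k=1), seed=7)
        f2 = repeated_fit(values, lambda v: fit_gaussians(v, k=1), seed=7)
        assert f1.components[0].center == f2.components[0].center
        assert f1.param_sd[0]["center"] == f2.param_sd[0]["center"]


class TestBoxSelection:
    def test_full_box_identity(self, library):
        rng = np.random.default_rng(15)
        events = events_from_population(library["FPA"], 200, rng)
        box = EventSelectionBox(0.0, 1.0, 0.0, 1e9)
        assert select_box(events, box) == events

    def test_disjoint_box_empty(self, library):
        rng = np.random.default_rng(16)
        events = events_from_population(library["FPA"], 100, rng)
        box = EventSelectionBox(0.9, 1.0, 1e5, 1e6)
        assert select_box(events, box) == []

    def test_box_purity_for_separated_populations(self, library):
        """A ±3 sd box around a population keeps ≥ 95 % own-label events
        when neighbors are ≥ 4 sd away."""
        rng = np.random.default_rng(17)
        events = (
            events_from_population(library["FPA-6"], 1000, rng)  # 0.43
            + events_from_population(library["FPA-3"], 1000, rng)  # 0.55
        )
        box = EventSelectionBox(0.43 - 0.03, 0.43 + 0.03, 0.0, 1e9)
        kept = select_box(events, box)
        purity = np.mean([ev.label == "FPA-6" for ev in kept])
        assert purity >= 0.95

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            EventSelectionBox(0.5, 0.4, 0.0, 1.0)


class TestPopulationSignature:
    def test_fpa6_signature(self, library):
        rng = np.random.default_rng(18)
        events = events_from_population(library["FPA-6"], 3000, rng)
        sig = population_signature(events, seed=0)
        assert abs(sig.blockade_mean - 0.43) < 0.01
        assert abs(sig.dwell_mode_ms - 0.95) / 0.95 < 0.10

    def test_box_selected_fpa_p1_signature(self, library):
        """Box selection around the higher-blockade conformer of the
        phosphorylated peptide recovers its (0.71, 0.62 ms) signature."""
        rng = np.random.default_rng(19)
        events = (
            events_from_population(library["FPA-P1"], 2000, rng)
            + events_from_population(library["FPA-P2"], 2000, rng)
        )
        box = EventSelectionBox(0.71 - 0.06, 0.71 + 0.06, 0.0, 1e9)
        sig = population_signature(select_box(events, box), seed=1)
        assert abs(sig.blockade_mean - 0.71) < 0.01
        assert abs(sig.dwell_mode_ms - 0.62) / 0.62 < 0.10

    def test_too_few_events_rejected(self, library):
        rng = np.random.default_rng(20)
        events = events_from_population(library["FPA"], 49, rng)
        with pytest.raises(ValueError, match="50"):
            population_signature(events)
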