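# Methods

`porepulse` implements the single-molecule analysis used to discriminate
short peptides — fibrinopeptide A (FPA), its Ser3-phosphorylated form
(which adopts two conformations, FPA-P1 and FPA-P2), and its N-terminal
cleavage derivatives FPA-3 and FPA-6 — from ionic-current recordings
through an aerolysin nanopore. Each peptide population is characterized by
a dual electrical signature: a Gaussian distribution of normalized
blockade levels and a log-normal distribution of dwell times. The package
simulates such recordings with known ground truth, detects and measures
blockade events, fits the per-population distributions, and decomposes
mixtures.

## Signal model

At a fixed applied potential the open pore passes a stable current
I₀ (pA) with Gaussian noise of SD δ. While an analyte occupies the pore
the current drops to the blockade level I_b for the dwell time. Per event
the analysis extracts:

- **dwell time** τ (μs), the duration between the event boundaries;
- **normalized blockade level** b = (I₀ − I_b)/I₀, dimensionless in (0, 1].

A population is summarized by the pair (blockade mean, most probable
dwell). Dwell times are log-normal; the reported "most probable value" is
the mode of the linear-scale density, **mode = exp(μ − σ²)** for
log-normal parameters (μ, σ).

Two event classes occur: *translocations/interactions* (dwell > 200 μs,
higher blockade) and *bumping* events from molecules that probe the pore
mouth without entering (brief, < 200 μs, shallow blockade).

## Synthetic recordings

The generator (`synthetic_data`) emulates the acquisition conditions of
the source recordings:

| parameter | default | meaning |
|---|---|---|
| `i0` | 115 pA | open-pore current |
| `noise_sd` | 1.7 pA | baseline SD **of the filtered trace** |
| `sampling_interval` | 4 μs | 250 kHz digitization |
| `filter_cutoff` | 5 kHz | 4-pole Bessel low-pass, applied zero-phase |
| `rate` (per population) | 20 events/s | Poisson arrival rate |
| `dwell_sigma` | 0.6 | log-normal shape (recordings report only modes; 0.6 reproduces the observed single-decade dwell spread) |
| `min_gap_us` | 500 μs | minimum inter-event gap |

The five library populations carry the measured signatures
(blockade mean ± SD / dwell mode): FPA 0.63 ± 0.01 / 5.74 ms,
FPA-P1 0.71 ± 0.02 / 0.62 ms, FPA-P2 0.61 ± 0.01 / 4.41 ms,
FPA-3 0.55 ± 0.01 / 2.50 ms, FPA-6 0.43 ± 0.01 / 0.95 ms. The bumping
population defaults to blockade 0.25 ± 0.08, dwell mode 40 μs (σ = 0.5),
with rate equal to the summed translocation rates.

Events are rendered rectangular (two-level); the low-pass filter supplies
the finite rise and fall. Intra-event current fluctuation beyond the
baseline noise is not modeled, since only the event-mean blockade is
analyzed. Because `noise_sd` is defined as the SD of the *filtered*
baseline — the quantity a recording's open-pore statistics report — the
injected white noise is pre-scaled by the filter's noise gain
(√mean|H|⁴ for forward-backward filtering), computed from the filter's
frequency response.

Arrivals are Poisson per population; overlap-violating arrivals are
re-drawn uniformly (counts are preserved, so realized totals remain
Poisson). A configuration whose expected pore occupancy
Σ rate · mean-dwell exceeds 0.5 is rejected as infeasible. A single seeded
generator drives all draws in a documented order, so a seed reproduces a
recording bit-for-bit.

## Event detection

- **Baseline.** I₀ and δ are estimated by iterated truncation: seed from
  the median and scaled MAD (a plain mean/SD can be dragged so far by deep
  blockades that no sample falls 5 SDs below it), then repeatedly retain
  samples ≥ I₀ − 5δ and recompute mean/SD until both move < 10⁻³ pA.
- **Threshold rule.** An event is a maximal run of ≥ 2 samples below
  I₀ − kδ with k = 5. Runs touching the trace ends are discarded; upward
  excursions are ignored (analytes only block current at this polarity).
- **Midpoint refinement (filtered traces).** The 5δ line sits at ~10 % of
  a deep event's amplitude, so crossing-to-crossing dwell overstates the
  true dwell by roughly the filter rise time (≈ 96 μs at 5 kHz zero-phase;
  +15 % on a 0.62 ms mode). Boundaries are therefore moved to the
  half-amplitude crossings, which for a zero-phase-filtered rectangular
  pulse coincide with the true edges. Unfiltered traces keep the raw
  crossings, where the rule is already exact.
- **Blockade current.** I_b is the mean of the event interior, excluding
  the boundary samples and, when the trace records a filter cutoff, a
  settling guard of 0.5/f_c per edge (≈ 100 μs at 5 kHz); the guard is
  waived progressively for events too short to retain an interior sample.
- **Translocation filter.** Events with dwell ≤ 200 μs are bumping and are
  dropped. The pipeline additionally applies a blockade floor of 0.35 —
  between the bumping cloud (0.25 ± 0.08) and the lowest translocation
  population (0.43) — because filter broadening lets ~2 % of bumping
  events past the dwell cut, enough to contaminate mixture fits.

## Distribution fitting

Blockade histograms use 100 linear bins on [0, 1] (0.01-wide bins resolve
the 0.01-scale population separations); dwell histograms use 50 log-spaced
bins. Fits are least squares on histogram counts, mirroring the
interactive-analysis workflow the measurements came from; for the
log-normal, the closed-form MLE is available as an independent
cross-check (`method="mle"`). On log-spaced bins a log-normal's counts are
Gaussian in ln τ (the Jacobian absorbs 1/τ), so the dwell fit is a single
Gaussian fit in log space returning μ and σ directly.

Multi-Gaussian fits are initialized from smoothed-histogram peak detection
(5-bin moving average; local maxima above 5 % of the global maximum).
Parameter uncertainties are the SDs over three seeded full-size bootstrap
resamples — the package's interpretation of "independent fits" that yields
a data-driven spread from one recording. Components are matched across
repeats and reported sorted by center; no identifiability treatment beyond
sorting is applied.

## Mixture decomposition and assignment

The blockade axis leads: a k-component Gaussian fit locates the
populations; each component seeds a selection box (center ± 3 fitted
widths, full dwell range); a log-normal fit of the boxed dwells completes
each signature. Component weights come from the fitted Gaussian areas.

Two close populations (0.61 and 0.63 with widths 0.01, at equal weights)
sum to an analytically *unimodal* histogram, so peak-seeded fitting cannot
reach k. In that case the fit is seeded from a Gaussian-mixture model on
the raw blockade values, and the requested k is accepted only when it
improves the AIC over the number of visible peaks: oversplitting a
homogeneous population costs ≳ +10 AIC units while a genuinely present
close pair gains well below zero, so the fixed AIC penalty separates the
cases at the sample sizes where peaks first merge (the stronger,
n-dependent BIC penalty was found to reject genuinely present pairs at
n ≈ 10⁴). The mixture model only initializes; reported parameters always
come from the histogram least-squares fit. Components closer than 2.5
pooled widths are flagged `overlapping`: their ensemble parameters are
distinct, but individual events cannot be attributed with confidence.

Single events are assigned to the component minimizing the standardized
distance √(((b − c)/w)² + ((ln τ − ln mode)/σ)²), with ties broken toward
the higher-blockade component and a cutoff of 4 units beyond which events
are "unassigned" (keeps bumping-tail stragglers out of population
statistics). Event-level assignment accuracy is a property of this
artifact, not a claim about the source measurements, which identify
populations only at the ensemble level.

## Numerical choices and degenerate inputs

- Truncation of the blockade Gaussian to (0, 1) is by resampling; all
  library populations sit ≥ 43 SDs from the bounds, so the induced mean
  shift is < 10⁻³.
- Gaussian fits require ≥ 3k + 1 nonzero bins; all-identical samples are
  rejected as degenerate. A σ → 0 dwell sample returns its common value as
  the mode.
- δ = 0 (noiseless synthetic traces) is legal in detection; the threshold
  degenerates to I₀.
- Baseline non-convergence raises an error carrying the last iterate.
- Bootstrap resamples whose fit fails are re-drawn up to 5 times.

## What the simulator does and does not capture

Passing tests show that the analysis chain recovers the generating
parameters under the stated noise model. Real recordings additionally
contain baseline drift, 1/f and interference noise, capacitive transients,
intra-event sub-states, voltage- and concentration-dependent capture
rates, and possible interconversion between the two phosphopeptide
conformations within a recording — none of which are modeled (the two
conformations are simulated as independent populations). Dwell modes are
generated with a single shape parameter σ = 0.6 for every population;
real dwell distributions need not share a shape. Recovery results
therefore validate the software, not the biology.

## Problem sizes

Each acceptance-scale run simulates 85–170 s of recording at 250 kHz
(21–43 M samples; 3 300–11 200 translocations). The five-population
mixture uses 15 events/s per population — five populations at 20/s would
put the expected pore occupancy at the 0.5 feasibility bound — and the
three-population mixture uses FPA at 20/s with the two phosphopeptide
conformations at 10/s each (equimolar FPA vs FPA-P).

## Known limitations

- ABF reading requires the optional `pyabf` dependency; the two native
  formats cover simulated and exported data.
- The settling guard assumes the recorded cutoff describes a Bessel-like
  low-pass; exotic filters would need a different guard.
- Overlapping components (flagged) make the per-component dwell fits of a
  mixture mutually contaminated; box-select and refit for clean dwell
  estimates when populations are separable on dwell.
- No multi-level event segmentation, CUSUM change-point detection, or
  adaptive baseline tracking.
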