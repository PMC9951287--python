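# porepulse

Simulation and analysis of nanopore resistive-pulse recordings for
peptide discrimination.

Fibrinopeptide A (FPA) is a 16-residue coagulation biomarker released
from fibrinogen by thrombin. In blood it coexists with a
Ser3-phosphorylated form (FPA-P) and with N-terminally truncated
derivatives (FPA-3, FPA-6), and the relative levels of these species are
clinically informative — but immunoassays cross-react between them.
Single-molecule nanopore sensing resolves them: each peptide driven
through an aerolysin pore produces blockade events whose **normalized
blockade level** b = (I₀ − I_b)/I₀ and **dwell time** τ form a
population-specific dual electrical signature. The phosphorylated form
even shows two discrete conformations (FPA-P1, FPA-P2) with distinct
signatures.

`porepulse` is for researchers building or evaluating such analyses. It
provides:

- a **simulator** for ionic-current recordings: Gaussian open-pore
  baseline, Poisson event arrivals, per-population Gaussian blockades and
  log-normal dwells, 4-pole Bessel low-pass filtering, and a "bumping"
  population of brief shallow events — with exact ground truth;
- **event detection** by the classical threshold rule: events are maximal
  runs of samples below I₀ − 5δ, where I₀ and δ are the open-pore mean and
  SD estimated by iterated truncation;
- **population fitting**: Gaussian components on blockade histograms,
  log-normal fits on dwell histograms reporting the most probable dwell
  mode = exp(μ − σ²), with bootstrap repeated-fit uncertainties;
- **mixture discrimination**: blockade-led decomposition into population
  signatures, per-event assignment, and confusion-matrix scoring against
  ground truth.

See `docs/methods.md` for the model, estimators, and design choices.

## Worked example

Simulate a 20 s FPA-only recording (open pore 115 pA, noise 1.7 pA,
5 kHz filter, 4 μs sampling), detect events, and fit the population:

```python
from porepulse import (SimulationConfig, default_population_library,
                       simulate_recording, estimate_baseline, detect_events,
                       filter_translocations, population_signature)

library = default_population_library()
config = SimulationConfig(duration=20.0, populations=[library["FPA"]], seed=5)
trace, truth = simulate_recording(config)

baseline = estimate_baseline(trace)
events = detect_events(trace, baseline)            # threshold I0 - 5*delta
trans = filter_translocations(events, min_blockade=0.35)  # drop bumping
sig = population_signature(trans, seed=5)
print(f"blockade {sig.blockade_mean:.3f} ± {sig.blockade_sd:.3f}, "
      f"dwell mode {sig.dwell_mode_ms:.2f} ± {sig.dwell_mode_sd:.2f} ms, "
      f"n = {sig.n_events}")
```

The same run through the CLI:

```bash
cat > fpa.yaml <<EOF
seed: 5
output_dir: out1
simulation:
  duration: 20.0
  populations: [FPA]
detection: {}
fitting:
  components: 1
EOF
porepulse run --config fpa.yaml
```

prints

```
porepulse report
================
stages run: simulate, detect, fit
baseline: I0 = 114.98 pA, delta = 1.73 pA
events: 749 detected, 419 translocations
populations (blockade mean ± sd / dwell mode ± sd (ms) / n):
        P1: 0.631 ± 0.001 / 5.50 ± 0.12 ms / 419
```

Reading it: the baseline estimator recovered the open-pore current and its
noise (114.98 ± 1.73 pA against the generating 115 ± 1.7); 749 blockade
events crossed the 5δ threshold, of which 419 were translocations (the
rest are bumping events shorter than 200 μs); the fitted signature,
blockade 0.631 and most probable dwell 5.50 ms, matches the generating
FPA population (0.63, 5.74 ms) within the uncertainty of ~400 events.
The `±` spreads are SDs over three bootstrap re-fits. Longer recordings
(≥ 3000 events) recover the blockade center within ±0.01 and the dwell
mode within a few percent.

Mixtures work the same way with `classification: {components: 5}` in the
config, or `porepulse classify --events translocations.csv --components 5`
on an event table; the report then lists one signature per population,
sorted by blockade level, with closely spaced components flagged as
overlapping.

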