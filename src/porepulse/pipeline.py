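"""Composable simulate → detect → fit → classify pipeline with manifests.

All stage parameters are validated before any stage runs; every
intermediate is persisted to the output directory; a manifest records the
package version, the global seed, and a hash of the effective parameters,
so a run is reproducible from its manifest alone.

Randomness flows from the single global seed: the simulation uses the seed
itself, fitting bootstrap uses ``seed + 1``, classification ``seed + 2``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .records import BaselineEstimate, CurrentTrace
from .synthetic_data import (
    PopulationModel,
    SimulationConfig,
    default_population_library,
    simulate_recording,
)
from .event_detection import (
    BUMPING_DWELL_US,
    detect_events,
    estimate_baseline,
    filter_translocations,
)
from .population_fitting import (
    EventSelectionBox,
    FitResult,
    PopulationSignature,
    fit_gaussians,
    fit_lognormal,
    repeated_fit,
)
from .discrimination import MixtureDecomposition, assign_events, decompose_mixture
from .trace_io import events_to_frame, write_events, write_trace

__all__ = [
    "DetectionParams",
    "FittingParams",
    "ClassificationParams",
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "run_pipeline",
    "report",
]

logger = logging.getLogger("porepulse")

#: Default blockade floor separating the bumping cloud (≈ 0.25 ± 0.08) from
#: the lowest translocation population (≈ 0.43): translocations show longer
#: dwell *and* higher blockade than bumping events.
DEFAULT_MIN_BLOCKADE = 0.35


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs before it are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class DetectionParams:
    k: float = 5.0
    min_samples: int = 2
    min_dwell_us: float = BUMPING_DWELL_US
    min_blockade: float | None = DEFAULT_MIN_BLOCKADE

    def validate(self) -> None:
        if self.k <= 0:
            raise ValueError("detection k must be positive")
        if self.min_samples < 1:
            raise ValueError("detection min_samples must be >= 1")
        if self.min_dwell_us < 0:
            raise ValueError("detection min_dwell_us must be non-negative")


@dataclass
class FittingParams:
    components: int = 1
    bins: int | None = None
    repeats: int = 3

    def validate(self) -> None:
        if self.components < 1:
            raise ValueError("fitting components must be >= 1")
        if self.repeats < 1:
            raise ValueError("fitting repeats must be >= 1")


@dataclass
class ClassificationParams:
    components: int = 2
    boxes: list[EventSelectionBox] | None = None

    def validate(self) -> None:
        if self.components < 1:
            raise ValueError("classification components must be >= 1")
        if self.boxes is not None and len(self.boxes) != self.components:
            raise ValueError("need one box per classification component")


def _build_populations(spec: list, rates: list[float] | None) -> list[PopulationModel]:
    library = default_population_library()
    pops: list[PopulationModel] = []
    for entry in spec:
        if isinstance(entry, str):
            if entry not in library:
                raise ValueError(f"unknown population {entry!r}; "
                                 f"library has {sorted(library)}")
            pops.append(library[entry])
        elif isinstance(entry, dict):
            pops.append(PopulationModel(**entry))
        else:
            raise ValueError("population entries must be names or parameter maps")
    if rates is not None:
        if len(rates) != len(pops):
            raise ValueError("rates must match populations one-to-one")
        pops = [replace(p, rate=r) for p, r in zip(pops, rates)]
    return pops


@dataclass
class PipelineConfig:
    """Validated stage parameters for one pipeline run."""

    seed: int = 0
    output_dir: Path = Path("porepulse-out")
    simulation: SimulationConfig | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    fitting: FittingParams | None = None
    classification: ClassificationParams | None = None
    persist_trace: bool = True

    def validate(self) -> None:
        self.detection.validate()
        if self.fitting is not None:
            self.fitting.validate()
        if self.classification is not None:
            self.classification.validate()

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        seed = int(raw.get("seed", 0))
        cfg = cls(seed=seed, output_dir=Path(raw.get("output_dir", "porepulse-out")))
        if "simulation" in raw:
            sim = dict(raw["simulation"])
            pops = _build_populations(sim.pop("populations", []), sim.pop("rates", None))
            sim.pop("seed", None)
            cfg.simulation = SimulationConfig(populations=pops, seed=seed, **sim)
        if "detection" in raw:
            cfg.detection = DetectionParams(**raw["detection"])
        if "fitting" in raw:
            cfg.fitting = FittingParams(**raw["fitting"])
        if "classification" in raw:
            cls_raw = dict(raw["classification"])
            boxes = cls_raw.pop("boxes", None)
            if boxes is not None:
                boxes = [EventSelectionBox(**b) for b in boxes]
            cfg.classification = ClassificationParams(boxes=boxes, **cls_raw)
        cfg.persist_trace = bool(raw.get("persist_trace", True))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    def parameter_hash(self) -> str:
        """Hash of every effective parameter (excluding the output path)."""
        def encode(obj):
            if isinstance(obj, Path):
                return None
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return str(obj)

        payload = {
            "seed": self.seed,
            "simulation": None if self.simulation is None else asdict(self.simulation),
            "detection": asdict(self.detection),
            "fitting": None if self.fitting is None else asdict(self.fitting),
            "classification": None
            if self.classification is None
            else asdict(self.classification),
        }
        canonical = json.dumps(payload, sort_keys=True, default=encode)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    trace: CurrentTrace | None = None
    truth: object = None
    baseline: BaselineEstimate | None = None
    events: list = field(default_factory=list)
    translocations: list = field(default_factory=list)
    blockade_fit: FitResult | None = None
    dwell_fit: FitResult | None = None
    decomposition: MixtureDecomposition | None = None
    assignments: list | None = None
    stages_run: list[str] = field(default_factory=list)


def _signature_dict(sig: PopulationSignature) -> dict:
    return {
        "name": sig.name,
        "blockade_mean": sig.blockade_mean,
        "blockade_sd": sig.blockade_sd,
        "dwell_mode_ms": sig.dwell_mode_ms,
        "dwell_mode_sd": sig.dwell_mode_sd,
        "n_events": sig.n_events,
        "weight": sig.weight,
        "overlapping": sig.overlapping,
    }


def _fit_dict(fit: FitResult) -> dict:
    comps = []
    for i, c in enumerate(fit.components):
        d = dict(c.__dict__)
        if fit.kind == "lognormal":
            d["mode"] = c.mode
        if fit.param_sd is not None:
            d["sd"] = fit.param_sd[i]
        comps.append(d)
    return {
        "kind": fit.kind,
        "components": comps,
        "n_events": fit.n_events,
        "residual_rms": fit.residual_rms,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages in order, persisting intermediates."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config)

    manifest = {
        "porepulse_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stages_run": result.stages_run,
    }

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                fn()
            except Exception as exc:
                _write_json(out / "manifest.json", manifest)
                raise PipelineStageError(name, exc) from exc
            result.stages_run.append(name)
            logger.info("stage %s done in %.2f s", name, time.monotonic() - t0)
        return wrap

    if config.simulation is not None:
        @stage("simulate")
        def _simulate():
            trace, truth = simulate_recording(config.simulation)
            result.trace, result.truth = trace, truth
            truth.to_frame().to_csv(out / "truth.csv", index=False)
            if config.persist_trace:
                write_trace(trace, out / "trace.bin", "binary")
            logger.info("simulated %d events over %.1f s", len(truth),
                        config.simulation.duration)

    if result.trace is not None:
        @stage("detect")
        def _detect():
            baseline = estimate_baseline(result.trace)
            events = detect_events(
                result.trace, baseline,
                k=config.detection.k, min_samples=config.detection.min_samples,
            )
            trans = filter_translocations(
                events,
                min_dwell=config.detection.min_dwell_us,
                min_blockade=config.detection.min_blockade,
            )
            result.baseline, result.events, result.translocations = (
                baseline, events, trans,
            )
            _write_json(out / "baseline.json", {
                "i0": baseline.i0, "delta": baseline.delta,
                "n_samples_used": baseline.n_samples_used,
            })
            write_events(events, out / "events.csv")
            write_events(trans, out / "translocations.csv")
            logger.info("detected %d events, %d translocations after filtering",
                        len(events), len(trans))

    if config.fitting is not None and result.translocations:
        @stage("fit")
        def _fit():
            trans = result.translocations
            blockades = np.array([ev.normalized_blockade for ev in trans])
            dwells = np.array([ev.dwell for ev in trans])
            fp = config.fitting
            result.blockade_fit = repeated_fit(
                blockades,
                lambda v: fit_gaussians(v, k=fp.components, n_bins=fp.bins),
                n_repeats=fp.repeats, seed=config.seed + 1,
            )
            result.dwell_fit = repeated_fit(
                dwells, fit_lognormal, n_repeats=fp.repeats, seed=config.seed + 1,
            )
            _write_json(out / "fit.json", {
                "blockade": _fit_dict(result.blockade_fit),
                "dwell": _fit_dict(result.dwell_fit),
            })

    if config.classification is not None and result.translocations:
        @stage("classify")
        def _classify():
            cp = config.classification
            dec = decompose_mixture(
                result.translocations, k=cp.components, boxes=cp.boxes,
                seed=config.seed + 2,
            )
            result.decomposition = dec
            result.assignments = assign_events(result.translocations, dec)
            _write_json(out / "decomposition.json", {
                "signatures": [_signature_dict(s) for s in dec.signatures],
                "n_events": dec.n_events,
            })
            labeled = events_to_frame(result.translocations)
            labeled["assigned"] = [a[0] for a in result.assignments]
            labeled["score"] = [a[1] for a in result.assignments]
            labeled.to_csv(out / "labeled_events.csv", index=False)

    text, payload = report(result)
    (out / "report.txt").write_text(text, encoding="utf-8")
    _write_json(out / "report.json", payload)
    _write_json(out / "manifest.json", manifest)
    return result


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=float)


def report(result: PipelineResult) -> tuple[str, dict]:
    """Human-readable summary plus a machine-readable payload.

    Populations are tabulated as ``blockade mean ± sd / dwell mode ± sd (ms)
    / n events``.
    """
    signatures: list[PopulationSignature] = []
    if result.decomposition is not None:
        signatures = result.decomposition.signatures
    elif result.blockade_fit is not None and result.dwell_fit is not None:
        bl = result.blockade_fit
        if len(bl.components) == 1 and len(result.dwell_fit.components) == 1:
            c = bl.components[0]
            d = result.dwell_fit.components[0]
            signatures = [PopulationSignature(
                blockade_mean=c.center,
                blockade_sd=(bl.param_sd[0]["center"] if bl.param_sd else float("nan")),
                dwell_mode_ms=d.mode * 1e-3,
                dwell_mode_sd=(result.dwell_fit.param_sd[0]["mode"] * 1e-3
                               if result.dwell_fit.param_sd else float("nan")),
                n_events=bl.n_events, name="P1",
                blockade_width=c.width, dwell_sigma=d.sigma,
            )]

    lines = ["porepulse report", "=" * 16]
    lines.append(f"stages run: {', '.join(result.stages_run) or 'none'}")
    if result.baseline is not None:
        lines.append(
            f"baseline: I0 = {result.baseline.i0:.2f} pA, "
            f"delta = {result.baseline.delta:.2f} pA"
        )
    lines.append(
        f"events: {len(result.events)} detected, "
        f"{len(result.translocations)} translocations"
    )
    if not signatures:
        lines.append("no populations")
    else:
        lines.append("populations (blockade mean ± sd / dwell mode ± sd (ms) / n):")
        for sig in signatures:
            flag = "  [overlapping]" if sig.overlapping else ""
            lines.append(
                f"  {sig.name or '-':>8}: {sig.blockade_mean:.3f} ± "
                f"{sig.blockade_sd:.3f} / {sig.dwell_mode_ms:.2f} ± "
                f"{sig.dwell_mode_sd:.2f} ms / {sig.n_events}{flag}"
            )
    payload = {
        "stages_run": list(result.stages_run),
        "n_events": len(result.events),
        "n_translocations": len(result.translocations),
        "baseline": None if result.baseline is None else {
            "i0": result.baseline.i0, "delta": result.baseline.delta,
        },
        "populations": [_signature_dict(s) for s in signatures],
    }
    return "\n".join(lines) + "\n", payload
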