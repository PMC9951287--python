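"""Histogram construction and population-distribution fitting.

Blockade-level histograms are fit with sums of Gaussians; dwell-time
histograms with log-normals.  Fits are least squares on histogram counts
(the workflow used by interactive electrophysiology software); maximum
likelihood is available as an independent cross-check for the log-normal.
Parameter uncertainties come from repeated fits on bootstrap resamples,
three by default.

A log-normal whose histogram is built on log-spaced bins is a Gaussian in
``ln x`` (the Jacobian absorbs the ``1/x`` factor), so the dwell fit is a
single Gaussian fit in log space whose center is μ and width is σ; the most
probable dwell is ``exp(μ - σ²)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, signal

from .records import EventRecord

__all__ = [
    "HistogramSpec",
    "GaussianComponent",
    "LogNormalComponent",
    "FitResult",
    "EventSelectionBox",
    "PopulationSignature",
    "build_histogram",
    "fit_gaussians",
    "fit_lognormal",
    "repeated_fit",
    "select_box",
    "population_signature",
    "FitError",
    "UnresolvedPeaksError",
]

#: Default number of linear blockade bins on [0, 1]; 0.01-wide bins resolve
#: the 0.01-scale separations between neighboring peptide populations.
BLOCKADE_BINS = 100
#: Default number of log-spaced dwell bins over the data range.
DWELL_BINS = 50

_SMOOTH_WINDOW = 5  # bins, moving average for peak-finding initialization
_PEAK_FLOOR = 0.05  # fraction of global max a peak must reach


class FitError(RuntimeError):
    """A distribution fit failed (degenerate data or non-convergence)."""


class UnresolvedPeaksError(FitError):
    """Fewer peaks are resolvable in the histogram than components requested."""


@dataclass
class HistogramSpec:
    """Binned values: linear bins for blockade, log-spaced bins for dwell."""

    bin_edges: np.ndarray
    counts: np.ndarray
    axis: str  # {"blockade", "dwell"}

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have one fewer entry than bin_edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        if self.axis == "dwell":
            return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_histogram(
    values: Sequence[float], axis: str, n_bins: int | None = None
) -> HistogramSpec:
    """Histogram blockade levels (linear on [0, 1]) or dwell times (log bins)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if axis == "blockade":
        n_bins = BLOCKADE_BINS if n_bins is None else n_bins
        edges = np.linspace(0.0, 1.0, n_bins + 1)
    elif axis == "dwell":
        if np.any(values <= 0):
            raise ValueError("dwell values must be positive")
        n_bins = DWELL_BINS if n_bins is None else n_bins
        lo, hi = values.min(), values.max()
        if lo == hi:  # all identical: a single degenerate bin, padded
            lo, hi = lo * 0.99, hi * 1.01
        edges = np.geomspace(lo, hi, n_bins + 1)
        edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max value
    else:
        raise ValueError(f"unknown histogram axis {axis!r}")
    counts, _ = np.histogram(values, bins=edges)
    return HistogramSpec(bin_edges=edges, counts=counts, axis=axis)


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float
    center: float
    width: float


@dataclass(frozen=True)
class LogNormalComponent:
    amplitude: float
    mu: float  # of ln(dwell), dwell in the units of the fitted values
    sigma: float

    @property
    def mode(self) -> float:
        """Most probable value, ``exp(mu - sigma^2)``."""
        return float(np.exp(self.mu - self.sigma**2))


@dataclass
class FitResult:
    """Fitted component parameters, optionally with repeated-fit spreads.

    ``param_sd`` (one dict per component, same order) holds the standard
    deviation of each parameter over bootstrap repeats; it is ``None`` for a
    single fit.
    """

    kind: str  # {"gaussian", "lognormal"}
    components: list
    n_events: int
    residual_rms: float
    param_sd: list[dict] | None = None

    @property
    def centers(self) -> np.ndarray:
        if self.kind == "gaussian":
            return np.array([c.center for c in self.components])
        return np.array([c.mode for c in self.components])


def _gaussian_sum(x: np.ndarray, *params: float) -> np.ndarray:
    out = np.zeros_like(x)
    for amp, cen, wid in zip(params[0::3], params[1::3], params[2::3]):
        out = out + amp * np.exp(-0.5 * ((x - cen) / wid) ** 2)
    return out


def _find_peaks(counts: np.ndarray) -> np.ndarray:
    smoothed = np.convolve(counts, np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW, "same")
    if smoothed.max() <= 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(smoothed, height=_PEAK_FLOOR * smoothed.max())
    order = np.argsort(smoothed[peaks])[::-1]
    return peaks[order]  # tallest first


def fit_gaussians(
    data: HistogramSpec | Sequence[float],
    k: int = 1,
    init: Sequence[float] | None = None,
    n_bins: int | None = None,
    init_widths: Sequence[float] | None = None,
) -> FitResult:
    """Least-squares fit of a sum of ``k`` Gaussians to a blockade histogram.

    ``data`` may be raw normalized-blockade values (a histogram is built
    with the default binning) or a ready :class:`HistogramSpec`.  Centers
    are initialized from smoothed-histogram peak detection unless ``init``
    supplies them; components are returned sorted by center.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hist = data if isinstance(data, HistogramSpec) else build_histogram(
        np.asarray(data, dtype=float), "blockade", n_bins
    )
    x, y = hist.centers, hist.counts
    n_events = int(y.sum())
    nonzero = int(np.count_nonzero(y))
    if nonzero < 3 * k + 1:
        raise FitError(
            f"only {nonzero} nonzero bins; need at least {3 * k + 1} "
            f"for a {k}-component fit (degenerate or too-narrow sample)"
        )
    bin_width = float(np.median(np.diff(hist.bin_edges)))

    if init is not None:
        centers0 = np.asarray(list(init), dtype=float)
        if centers0.size != k:
            raise ValueError("init must supply one center per component")
    else:
        peaks = _find_peaks(y)
        if peaks.size < k:
            raise UnresolvedPeaksError(
                f"found {peaks.size} peak(s) in the histogram but k={k}; "
                "supply explicit initial centers"
            )
        centers0 = np.sort(x[peaks[:k]])

    if init_widths is not None:
        widths0 = np.asarray(list(init_widths), dtype=float)
    else:
        widths0 = np.full(k, 1.5 * bin_width)
    amps0 = np.interp(centers0, x, y).clip(min=1.0)

    p0, lower, upper = [], [], []
    span = hist.bin_edges[-1] - hist.bin_edges[0]
    for a, c, w in zip(amps0, centers0, widths0):
        p0 += [a, c, w]
        lower += [0.0, hist.bin_edges[0], bin_width * 0.2]
        upper += [max(2.0 * y.max(), 10.0), hist.bin_edges[-1], span]
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_sum, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc

    comps = [
        GaussianComponent(float(a), float(c), float(w))
        for a, c, w in zip(popt[0::3], popt[1::3], popt[2::3])
    ]
    comps.sort(key=lambda c: c.center)
    resid = float(np.sqrt(np.mean((y - _gaussian_sum(x, *popt)) ** 2)))
    return FitResult("gaussian", comps, n_events, resid)


def fit_lognormal(
    dwells: Sequence[float],
    n_bins: int | None = None,
    method: str = "histogram",
) -> FitResult:
    """Fit a log-normal to dwell times; the mode ``exp(μ - σ²)`` is the
    most probable dwell, in the units of ``dwells``.

    ``method="histogram"`` (default) performs a least-squares Gaussian fit
    to the log-binned histogram; ``method="mle"`` uses the closed-form
    maximum-likelihood estimates, an independent cross-check.
    """
    dwells = np.asarray(dwells, dtype=float)
    if np.any(dwells <= 0):
        raise ValueError("dwell values must be positive")
    if dwells.size < 50:
        raise FitError(f"need at least 50 dwell values, got {dwells.size}")

    log_d = np.log(dwells)
    if dwells.min() == dwells.max():
        # Degenerate σ → 0 sample: the most probable value is the common value.
        comp = LogNormalComponent(float(dwells.size), float(log_d[0]), 0.0)
        return FitResult("lognormal", [comp], int(dwells.size), 0.0)
    if method == "mle":
        mu, sigma = float(log_d.mean()), float(log_d.std())
        return FitResult(
            "lognormal", [LogNormalComponent(float(dwells.size), mu, sigma)],
            int(dwells.size), 0.0,
        )
    if method != "histogram":
        raise ValueError(f"unknown fit method {method!r}")

    hist = build_histogram(dwells, "dwell", n_bins)
    y = hist.counts
    log_x = np.log(hist.centers)
    nonzero = int(np.count_nonzero(y))
    if nonzero < 4:
        raise FitError("degenerate dwell histogram: fewer than 4 nonzero bins")
    mu0, sigma0 = float(log_d.mean()), max(float(log_d.std()), 1e-3)
    p0 = [float(y.max()), mu0, sigma0]
    try:
        popt, _ = optimize.curve_fit(
            _gaussian_sum, log_x, y, p0=p0,
            bounds=([0.0, log_x[0] - 1.0, 1e-4],
                    [np.inf, log_x[-1] + 1.0, 10.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"log-normal fit did not converge: {exc}") from exc
    amp, mu, sigma = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((y - _gaussian_sum(log_x, *popt)) ** 2)))
    return FitResult(
        "lognormal", [LogNormalComponent(amp, mu, sigma)], int(dwells.size), resid
    )


def _component_params(comp) -> dict:
    if isinstance(comp, GaussianComponent):
        return {"amplitude": comp.amplitude, "center": comp.center, "width": comp.width}
    return {"amplitude": comp.amplitude, "mu": comp.mu, "sigma": comp.sigma,
            "mode": comp.mode}


def repeated_fit(
    values: Sequence[float],
    fit_fn: Callable[[np.ndarray], FitResult],
    n_repeats: int = 3,
    seed: int | None = None,
    max_retries: int = 5,
) -> FitResult:
    """Repeat a fit on full-size bootstrap resamples; report mean ± sd.

    Returns a :class:`FitResult` whose component parameters are the means
    over repeats and whose ``param_sd`` holds the per-parameter standard
    deviations.  Components are matched across repeats by sorted order.
    A resample whose fit fails is re-drawn, up to ``max_retries`` times each.
    """
    values = np.asarray(values, dtype=float)
    base = fit_fn(values)  # the base fit must succeed
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)

    per_repeat: list[list[dict]] = []
    for _ in range(n_repeats):
        last_exc: Exception | None = None
        for _attempt in range(max_retries):
            resample = rng.choice(values, size=values.size, replace=True)
            try:
                result = fit_fn(resample)
            except FitError as exc:
                last_exc = exc
                continue
            if len(result.components) == len(base.components):
                per_repeat.append([_component_params(c) for c in result.components])
                break
            last_exc = FitError("component count changed on resample")
        else:
            raise FitError(
                f"bootstrap fit failed after {max_retries} retries: {last_exc}"
            )

    n_comp = len(base.components)
    mean_comps, sds = [], []
    for i in range(n_comp):
        keys = per_repeat[0][i].keys()
        mean = {k: float(np.mean([r[i][k] for r in per_repeat])) for k in keys}
        sd = {k: float(np.std([r[i][k] for r in per_repeat])) for k in keys}
        if base.kind == "gaussian":
            mean_comps.append(
                GaussianComponent(mean["amplitude"], mean["center"], mean["width"])
            )
        else:
            mean_comps.append(
                LogNormalComponent(mean["amplitude"], mean["mu"], mean["sigma"])
            )
        sds.append(sd)
    return FitResult(base.kind, mean_comps, base.n_events, base.residual_rms, sds)


@dataclass(frozen=True)
class EventSelectionBox:
    """A closed rectangle in (blockade, dwell) space; dwell bounds in ms."""

    blockade_min: float
    blockade_max: float
    dwell_min_ms: float
    dwell_max_ms: float

    def __post_init__(self) -> None:
        if not (self.blockade_max >= self.blockade_min):
            raise ValueError("empty blockade interval")
        if not (self.dwell_max_ms >= self.dwell_min_ms):
            raise ValueError("empty dwell interval")


def select_box(
    events: list[EventRecord], box: EventSelectionBox
) -> list[EventRecord]:
    """Retain events inside the closed box (dwell compared in ms)."""
    out = [
        ev
        for ev in events
        if box.blockade_min <= ev.normalized_blockade <= box.blockade_max
        and box.dwell_min_ms <= ev.dwell * 1e-3 <= box.dwell_max_ms
    ]
    return out


@dataclass
class PopulationSignature:
    """The dual electrical signature of one population:
    blockade mean ± sd and most probable dwell (ms) ± sd,
    with the spreads taken over repeated fits."""

    blockade_mean: float
    blockade_sd: float
    dwell_mode_ms: float
    dwell_mode_sd: float
    n_events: int
    blockade_width: float = float("nan")  # fitted Gaussian width
    dwell_sigma: float = float("nan")  # fitted log-normal shape
    name: str = ""
    weight: float = 1.0
    overlapping: bool = False


def population_signature(
    events: list[EventRecord],
    n_repeats: int = 3,
    seed: int | None = None,
) -> PopulationSignature:
    """Fit the (blockade, dwell) signature of a single event population."""
    if len(events) < 50:
        raise ValueError(f"need at least 50 events, got {len(events)}")
    blockades = np.array([ev.normalized_blockade for ev in events])
    dwells = np.array([ev.dwell for ev in events])

    bl_fit = repeated_fit(
        blockades, lambda v: fit_gaussians(v, k=1), n_repeats=n_repeats, seed=seed
    )
    dw_fit = repeated_fit(
        dwells, fit_lognormal, n_repeats=n_repeats,
        seed=None if seed is None else seed + 1,
    )
    bl = bl_fit.components[0]
    dw = dw_fit.components[0]
    return PopulationSignature(
        blockade_mean=bl.center,
        blockade_sd=bl_fit.param_sd[0]["center"],
        dwell_mode_ms=dw.mode * 1e-3,
        dwell_mode_sd=dw_fit.param_sd[0]["mode"] * 1e-3,
        n_events=len(events),
        blockade_width=bl.width,
        dwell_sigma=dw.sigma,
    )
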