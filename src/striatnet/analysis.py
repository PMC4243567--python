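"""Measurement procedures for paired network simulations.

Covers IPSP extraction from inhibition ON/OFF trace pairs (signed
amplitude by the max/min rule on the difference trace, first
presynaptic spike only), double-exponential IPSP fitting
``V = scale * (exp(-t/T1) - exp(-t/T2))`` with an R^2 >= 80 % acceptance
filter, a one-sample z-test with the (-1.96, 1.96) equivalence band,
peri-event spike histograms, post-event suppression fractions, pooled
ensemble spike-timing SD, and per-cell firing-rate statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .simulator import RasterSet

__all__ = [
    "IPSPRecord",
    "FitResult",
    "ZTestResult",
    "PeriEventHistogram",
    "SuppressionSummary",
    "extract_ipsp",
    "fit_double_exponential",
    "one_sample_ztest",
    "perievent_histogram",
    "suppression_fraction",
    "ensemble_spike_sd",
    "rate_stats",
    "double_exp_peak_time",
]


@dataclass
class IPSPRecord:
    cell: int
    baseline: float  # mV at the presynaptic spike time (OFF trace)
    difference: np.ndarray  # mV, ON - OFF over the analysis window
    times: np.ndarray  # ms, relative to the presynaptic spike
    amplitude: float  # mV, signed extremum (max/min rule)
    presyn_spike_time: float  # ms
    excluded: bool  # identically-zero difference (no IPSP present)


def extract_ipsp(
    trace_on: np.ndarray,
    trace_off: np.ndarray,
    dt: float,
    presyn_spike_time: float,
    window: float = 100.0,
    cell: int = -1,
) -> IPSPRecord:
    """IPSP from a paired-subtraction trace pair.

    The difference ON - OFF is restricted to ``[t_spike, t_spike +
    window]``; the signed amplitude is whichever of the maximum or
    minimum has the greater absolute value.  A difference that is
    identically zero (cell unaffected by the toggled inhibition) is
    flagged ``excluded`` rather than reported as a zero-amplitude IPSP.
    Only the first presynaptic spike should be passed in.
    """
    trace_on = np.asarray(trace_on, float)
    trace_off = np.asarray(trace_off, float)
    if trace_on.shape != trace_off.shape:
        raise ValueError("paired traces must share shape (same dt and duration)")
    i0 = int(round(presyn_spike_time / dt))
    i1 = min(len(trace_on), i0 + int(round(window / dt)) + 1)
    if i0 >= len(trace_on):
        raise ValueError("presynaptic spike time beyond trace end")
    diff = trace_on[i0:i1] - trace_off[i0:i1]
    times = np.arange(len(diff)) * dt
    vmax, vmin = float(diff.max()), float(diff.min())
    amplitude = vmax if abs(vmax) >= abs(vmin) else vmin
    excluded = bool(np.all(diff == 0.0))
    return IPSPRecord(
        cell=cell,
        baseline=float(trace_off[i0]),
        difference=diff,
        times=times,
        amplitude=amplitude,
        presyn_spike_time=presyn_spike_time,
        excluded=excluded,
    )


@dataclass
class FitResult:
    T1: float  # ms, slower time constant (T1 >= T2 by convention)
    T2: float  # ms
    scale: float
    r_squared: float
    accepted: bool  # r_squared >= 0.80

    ACCEPT_THRESHOLD = 0.80


def double_exp_peak_time(T1: float, T2: float) -> float:
    """Peak location of exp(-t/T1) - exp(-t/T2)."""
    return np.log(T1 / T2) * T1 * T2 / (T1 - T2)


def _double_exp(t, scale, T1, T2):
    return scale * (np.exp(-t / T1) - np.exp(-t / T2))


def fit_double_exponential(
    difference: np.ndarray,
    dt: float = 1.0,
    times: np.ndarray | None = None,
) -> FitResult:
    """Least-squares fit of ``scale * (exp(-t/T1) - exp(-t/T2))``.

    The trace must be onset-aligned (t = 0 at the IPSP start).  The
    functional form is symmetric under (T1, T2, scale) ->
    (T2, T1, -scale); the returned result uses the T1 >= T2 ordering.
    A fit is ``accepted`` when R^2 >= 0.80; optimizer failure yields a
    rejected result with R^2 = -inf.
    """
    y = np.asarray(difference, float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to fit")
    t = np.asarray(times, float) if times is not None else np.arange(len(y)) * dt

    i_peak = int(np.argmax(np.abs(y)))
    peak = y[i_peak] if y[i_peak] != 0 else 1e-12
    t_peak = max(t[i_peak], dt)
    # seed: peak time fixes the T1/T2 combination; late decay ~ T1
    x0 = np.array([peak * 2.0, max(3.0 * t_peak, 1.0), max(t_peak, 0.5)])

    def resid(p):
        scale, T1, T2 = p
        return _double_exp(t, scale, T1, T2) - y

    try:
        sol = least_squares(
            resid, x0,
            bounds=([-np.inf, 1e-3, 1e-3], [np.inf, 1e4, 1e4]),
            max_nfev=2000,
        )
    except Exception:
        return FitResult(np.nan, np.nan, np.nan, -np.inf, False)
    scale, T1, T2 = sol.x
    if T1 < T2:  # swap to the canonical ordering (sign flips)
        T1, T2, scale = T2, T1, -scale
    ss_res = float(np.sum((y - _double_exp(t, scale, T1, T2)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
    return FitResult(float(T1), float(T2), float(scale), r2,
                     bool(r2 >= FitResult.ACCEPT_THRESHOLD))


@dataclass
class ZTestResult:
    z: float
    equivalent: bool  # z strictly inside (-1.96, 1.96)


def one_sample_ztest(sample_values, mu0: float) -> ZTestResult:
    """z = (mean - mu0) / (sd / sqrt(n)); equivalence means |z| < 1.96.

    The band is open: |z| = 1.96 exactly is *not* equivalent.
    """
    x = np.asarray(sample_values, float)
    if len(x) < 2:
        raise ValueError("need at least two samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero sample variance")
    z = float((x.mean() - mu0) / (sd / np.sqrt(len(x))))
    return ZTestResult(z, bool(-1.96 < z < 1.96))


@dataclass
class PeriEventHistogram:
    bin_edges: np.ndarray  # ms relative to event
    counts: np.ndarray
    n_events: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _subset_spike_times(raster: RasterSet, pop: str, cells) -> np.ndarray:
    all_cells, times = raster.cells_times(pop)
    if cells is None:
        return times
    mask = np.isin(all_cells, np.asarray(list(cells), dtype=np.int64))
    return times[mask]


def perievent_histogram(
    raster: RasterSet,
    event_times,
    window: tuple[float, float] = (-50.0, 50.0),
    binsize: float = 1.0,
    pop: str = "msn",
    cells=None,
) -> PeriEventHistogram:
    """Spike counts binned by offset to each reference event.

    Every (spike, event) pair whose offset falls inside ``window`` is
    counted; events near the recording edges keep their (truncated)
    windows rather than being discarded.
    """
    events = np.asarray(event_times, float)
    if len(events) == 0:
        raise ValueError("event list is empty")
    if binsize <= 0 or window[0] >= window[1]:
        raise ValueError("need binsize > 0 and an ordered window")
    spikes = _subset_spike_times(raster, pop, cells)
    edges = np.arange(window[0], window[1] + binsize * 0.5, binsize)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for ev in events:
        offs = spikes - ev
        offs = offs[(offs >= window[0]) & (offs <= window[1])]
        c, _ = np.histogram(offs, bins=edges)
        counts += c
    return PeriEventHistogram(edges, counts, len(events))


@dataclass
class SuppressionSummary:
    window: tuple[float, float]  # ms after each event
    spikes_off: int
    spikes_on: int
    fraction_remaining: float  # spikes_on / spikes_off


def _count_in_windows(spikes: np.ndarray, events: np.ndarray,
                      window: tuple[float, float]) -> int:
    total = 0
    for ev in events:
        total += int(np.count_nonzero(
            (spikes > ev + window[0]) & (spikes <= ev + window[1])
        ))
    return total


def suppression_fraction(
    raster_on: RasterSet,
    raster_off: RasterSet,
    event_times,
    window: tuple[float, float] = (5.0, 30.0),
    pop: str = "msn",
    cells=None,
) -> SuppressionSummary:
    """Fraction of post-event spikes remaining with inhibition ON.

    Counts subset spikes inside ``(event + window[0], event + window[1]]``
    for both rasters of a paired run; the default window is 5-30 ms
    after each event.
    """
    events = np.asarray(event_times, float)
    if len(events) == 0:
        raise ValueError("event list is empty")
    s_on = _count_in_windows(_subset_spike_times(raster_on, pop, cells), events, window)
    s_off = _count_in_windows(_subset_spike_times(raster_off, pop, cells), events, window)
    if s_off == 0:
        raise ValueError("no OFF-condition spikes in the analysis windows")
    return SuppressionSummary(tuple(window), s_off, s_on, s_on / s_off)


def ensemble_spike_sd(
    raster: RasterSet,
    rhythm_event_times,
    window: tuple[float, float] = (0.0, 62.5),
    pop: str = "msn",
    cells=None,
) -> float:
    """Pooled SD (population convention, n denominator) of spike offsets
    relative to their rhythm event, over all events with spikes."""
    events = np.asarray(rhythm_event_times, float)
    spikes = _subset_spike_times(raster, pop, cells)
    offsets = []
    for ev in events:
        sel = spikes[(spikes > ev + window[0]) & (spikes <= ev + window[1])]
        offsets.append(sel - ev)
    pooled = np.concatenate(offsets) if offsets else np.empty(0)
    if len(pooled) == 0:
        raise ValueError("no spikes in any event window")
    return float(pooled.std(ddof=0))


def rate_stats(raster: RasterSet, duration: float, pop: str = "msn",
               bins: int = 20) -> dict:
    """Per-cell firing rates: mean, SD across cells, and a histogram."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    cells, _ = raster.cells_times(pop)
    n = raster.n_cells[pop]
    counts = np.bincount(cells, minlength=n)
    rates = counts / duration * 1000.0
    hist, edges = np.histogram(rates, bins=bins)
    return {
        "mean_hz": float(rates.mean()) if n else 0.0,
        "sd_hz": float(rates.std(ddof=0)) if n else 0.0,
        "rates": rates,
        "hist_counts": hist,
        "hist_edges": edges,
    }
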