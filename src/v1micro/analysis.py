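"""Response statistics computed from spike records.

Windowed per-neuron population rates, trial-averaged PSTHs with onset
latencies, edge-normalised column profiles for the figure-ground analyses
(each trial's layer-2/3 Pyr rates divided by that trial's mean edge-column
response, or trial-averaged rates divided by a pooled reference), and a
spectral estimate of population-rate oscillation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .lif import SpikeRecord


def _population_indices(rec: SpikeRecord, population: str,
                        column: int = 0) -> np.ndarray:
    if rec.manifest is None:
        raise ValueError("spike record has no population manifest")
    m = rec.manifest
    row = m[(m["name"] == population) & (m["column"] == column)]
    if not len(row):
        raise KeyError(f"no population {population!r} in column {column}")
    start, stop = int(row["start"].iloc[0]), int(row["stop"].iloc[0])
    if stop <= start:
        raise ValueError(f"population {population!r} is empty")
    return start, stop


def population_rate(rec: SpikeRecord, population: str, window: tuple,
                    column: int = 0) -> float:
    """Mean rate (Hz per neuron) of a population in a time window (ms)."""
    t0, t1 = window
    if not 0 <= t0 < t1 <= rec.duration + 1e-9:
        raise ValueError(f"window {window} outside run of {rec.duration} ms")
    start, stop = _population_indices(rec, population, column)
    n = stop - start
    mask = ((rec.neurons >= start) & (rec.neurons < stop)
            & (rec.times > t0) & (rec.times <= t1))
    return float(np.sum(mask)) / (n * (t1 - t0) * 1e-3)


@dataclass
class PSTH:
    """Trial-averaged peri-stimulus time histogram of one population."""

    population: str
    bin_width: float  # ms
    edges: np.ndarray  # bin edges, ms
    rate: np.ndarray  # mean rate per bin, Hz/neuron
    n_trials: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def psth(trials: list, population: str, bin_width: float = 5.0,
         column: int = 0) -> PSTH:
    """Average the population rate over trials in fixed bins."""
    if not trials:
        raise ValueError("need at least one trial")
    duration = trials[0].duration
    edges = np.arange(0.0, duration + bin_width * 0.5, bin_width)
    acc = np.zeros(len(edges) - 1)
    for rec in trials:
        start, stop = _population_indices(rec, population, column)
        mask = (rec.neurons >= start) & (rec.neurons < stop)
        hist, _ = np.histogram(rec.times[mask], bins=edges)
        acc += hist / ((stop - start) * bin_width * 1e-3)
    return PSTH(population, bin_width, edges, acc / len(trials), len(trials))


def onset_latency(p: PSTH, baseline: tuple, k: float = 3.0,
                  persist: int = 2) -> float | None:
    """First time the PSTH exceeds baseline mean + k*SD for ``persist`` bins.

    Returns the left edge (ms) of the first qualifying bin at or after the
    end of the baseline window, or None if no sustained crossing occurs.
    """
    b0, b1 = baseline
    in_base = (p.centers >= b0) & (p.centers < b1)
    if not np.any(in_base):
        raise ValueError("baseline window contains no bins")
    mu = p.rate[in_base].mean()
    sd = p.rate[in_base].std(ddof=1) if in_base.sum() > 1 else 0.0
    thresh = mu + k * sd
    above = p.rate > thresh
    first = np.searchsorted(p.edges, b1) - 1
    for i in range(max(first, 0), len(above) - persist + 1):
        if np.all(above[i:i + persist]):
            return float(p.edges[i])
    return None


def onset_latencies(psths: dict, baseline: tuple, k: float = 3.0,
                    persist: int = 2) -> dict:
    """Latency per population plus their rank order (absent = None).

    Returns ``{"latency": {pop: ms | None}, "order": [pops sorted by
    latency, absent last]}``.
    """
    lat = {name: onset_latency(p, baseline, k, persist)
           for name, p in psths.items()}
    present = sorted((v, k_) for k_, v in lat.items() if v is not None)
    order = [k_ for _, k_ in present] + [k_ for k_, v in lat.items()
                                         if v is None]
    return {"latency": lat, "order": order}


@dataclass
class ColumnProfile:
    """Normalised per-column layer-2/3 Pyr response."""

    columns: np.ndarray  # 0-based column indices
    mean: np.ndarray  # normalised mean response per column
    sem: np.ndarray  # standard error over trials
    mode: str  # per_trial_edge_mean | pooled_reference
    n_trials: int
    n_excluded: int = 0
    raw_mean: np.ndarray | None = None  # Hz/neuron before normalisation


def column_rates(rec: SpikeRecord, window: tuple, n_columns: int,
                 population: str = "L23_Pyr") -> np.ndarray:
    """Per-column population rate (Hz/neuron) in the window."""
    return np.array([population_rate(rec, population, window, column=c)
                     for c in range(n_columns)])


def edge_normalized_profile(trials: list, edge_columns: tuple,
                            window: tuple, n_columns: int,
                            mode: str = "per_trial_edge_mean",
                            reference: float | None = None,
                            population: str = "L23_Pyr") -> ColumnProfile:
    """Column response profile normalised to the edge-column mean.

    ``edge_columns`` are 0-based indices.  In per-trial mode each trial's
    column rates are divided by that trial's edge mean before averaging
    (trials with zero edge response are excluded and counted); in pooled
    mode the trial-averaged rates are divided by the supplied ``reference``
    scalar.
    """
    if len(trials) < 2:
        raise ValueError("need >= 2 trials for standard errors")
    edge_columns = np.asarray(edge_columns, dtype=int)
    rates = np.stack([column_rates(r, window, n_columns, population)
                      for r in trials])
    if mode == "per_trial_edge_mean":
        edge_mean = rates[:, edge_columns].mean(axis=1)
        keep = edge_mean > 0
        n_exc = int(np.sum(~keep))
        if not np.any(keep):
            raise ValueError("every trial has zero edge response")
        normed = rates[keep] / edge_mean[keep, None]
        mean = normed.mean(axis=0)
        sem = normed.std(axis=0, ddof=1) / np.sqrt(keep.sum())
        n_used = int(keep.sum())
    elif mode == "pooled_reference":
        if reference is None or reference <= 0:
            raise ValueError("pooled mode needs a positive reference")
        mean = rates.mean(axis=0) / reference
        sem = rates.std(axis=0, ddof=1) / np.sqrt(len(trials)) / reference
        n_exc, n_used = 0, len(trials)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return ColumnProfile(np.arange(n_columns), mean, sem, mode, n_used,
                         n_exc, raw_mean=rates.mean(axis=0))


def oscillation_frequency(rate_series: np.ndarray, dt_ms: float,
                          fmin: float = 2.0, fmax: float = 100.0,
                          peak_factor: float = 15.0):
    """Dominant oscillation frequency of a population-rate series.

    Mean-removed periodogram; returns ``(frequency_hz, power_ratio)`` of
    the largest spectral peak in [fmin, fmax] if its power exceeds
    ``peak_factor`` times the median in-band power, else None (no peak
    above the noise floor).  The series should cover >= 500 ms.
    """
    x = np.asarray(rate_series, dtype=float)
    if len(x) * dt_ms < 500.0:
        raise ValueError("need at least 500 ms of rate data")
    fs = 1000.0 / dt_ms
    freqs, power = signal.periodogram(x - x.mean(), fs=fs)
    band = (freqs >= fmin) & (freqs <= fmax)
    if not np.any(band) or np.all(power[band] == 0):
        return None
    f_b, p_b = freqs[band], power[band]
    i = int(np.argmax(p_b))
    floor = np.median(p_b)
    if floor <= 0 or p_b[i] < peak_factor * floor:
        return None
    return float(f_b[i]), float(p_b[i] / floor)


def binned_population_rate(rec: SpikeRecord, population: str,
                           bin_width: float = 1.0,
                           column: int = 0) -> tuple:
    """(bin centers ms, Hz/neuron series) for spectral analysis."""
    start, stop = _population_indices(rec, population, column)
    edges = np.arange(0.0, rec.duration + bin_width * 0.5, bin_width)
    mask = (rec.neurons >= start) & (rec.neurons < stop)
    hist, _ = np.histogram(rec.times[mask], bins=edges)
    rate = hist / ((stop - start) * bin_width * 1e-3)
    return 0.5 * (edges[:-1] + edges[1:]), rate
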