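"""Stimulus protocols: background drives, thalamic inputs, experiment presets.

Background: every neuron receives an aggregate Poisson barrage equal to its
population's external fiber count times the cell-type-specific rate per
fiber (layer-2/3 PV/SST/VIP share the merged inhibitory fiber count but
keep their own per-fiber rates).

Thalamus: 902 thalamic cells attach to each column, projecting independent
Poisson trains onto layers 4 and 6 (E and I) with the base-model
connection probabilities.  All thalamic cells of a column fire at that
column's stimulus rate from 400 ms after simulation onset for 100 ms
(10 ms for the transient-pulse protocol).

Four experiment presets cover the study designs: a single-column transient
pulse, a figure-ground stimulus (columns 5-9 of 13 at 80 Hz on a 40 Hz
ground), a two-object stimulus (80 Hz at column 5, 60 Hz at column 8) with
a sweep of the long-range Pyr->SST connection probability, and a top-down
gain protocol (one 80 Hz column) with a factorial grid of homogeneous VIP
and SST background rates.  Columns are numbered 1..13 as in the stimulus
layouts; internally they map to 0-based ring positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import params as P
from .lif import Drives, ExternalInput, simulate
from .network import build_network, _bernoulli_pairs

#: populations sharing each external-fiber count
_FIBER_GROUP = {
    "L23_Pyr": "L23E", "L23_PV": "L23I", "L23_SST": "L23I", "L23_VIP": "L23I",
    "L4_E": "L4E", "L4_I": "L4I", "L5_E": "L5E", "L5_I": "L5I",
    "L6_E": "L6E", "L6_I": "L6I",
}


@dataclass(frozen=True)
class BackgroundSpec:
    """Resolved background drive of one population."""

    population: str
    n_fibers: int
    rate_per_fiber: float

    @property
    def aggregate_rate(self) -> float:
        """Total Poisson event rate per neuron (Hz)."""
        return self.n_fibers * self.rate_per_fiber


def background_drive(overrides: dict | None = None) -> dict:
    """Resolve the default background table with per-population overrides.

    ``overrides`` maps population name -> rate per fiber (Hz).  Returns
    ``{population: BackgroundSpec}``.
    """
    overrides = overrides or {}
    unknown = set(overrides) - set(P.BACKGROUND_RATES)
    if unknown:
        raise KeyError(f"unknown populations in background overrides: "
                       f"{sorted(unknown)}")
    out = {}
    for pop, rate in P.BACKGROUND_RATES.items():
        rate = overrides.get(pop, rate)
        if rate < 0:
            raise ValueError(f"negative background rate for {pop}")
        out[pop] = BackgroundSpec(pop, P.BACKGROUND_FIBERS[_FIBER_GROUP[pop]],
                                  rate)
    return out


def background_rate_array(graph, overrides: dict | None = None) -> np.ndarray:
    """Per-neuron aggregate background event rate (Hz) for a built graph."""
    spec = background_drive(overrides)
    rates = np.zeros(graph.n_neurons)
    for pop in graph.populations:
        a, b = graph.index_range(pop.name, pop.column)
        rates[a:b] = spec[pop.name].aggregate_rate
    return rates


@dataclass(frozen=True)
class ThalamicSpec:
    """Thalamic afferents: per-column rates and timing."""

    column_rates: tuple  # Hz, one per column
    onset: float = 400.0
    duration: float = 100.0
    cells_per_column: int = P.N_THALAMIC_PER_COLUMN

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.column_rates):
            raise ValueError("thalamic rates must be >= 0")
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("invalid thalamic timing")


def thalamic_input(graph, thalamic: ThalamicSpec,
                   seed: int = 0) -> ExternalInput:
    """Draw the thalamic fan-out for a built graph.

    902 cells per column (independent of any scale factor) project to that
    column's L4 and L6 populations with the base-model probabilities;
    synapses use the default excitatory peak and intracolumnar excitatory
    delays.  Fan-out is deterministic in (graph spec, seed).
    """
    if len(thalamic.column_rates) != graph.n_columns:
        raise ValueError(f"need {graph.n_columns} column rates, got "
                         f"{len(thalamic.column_rates)}")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, 1]))
    m = thalamic.cells_per_column
    pre_l, post_l = [], []
    for col in range(graph.n_columns):
        fiber0 = col * m
        for pop, prob in P.PD_THALAMIC_PROB.items():
            name = f"{pop[:-1]}_{pop[-1]}"  # L4E -> L4_E
            a, b = graph.index_range(name, col)
            i, j = _bernoulli_pairs(rng, m, b - a, prob, False)
            pre_l.append(i + fiber0)
            post_l.append(j + a)
    pre = np.concatenate(pre_l)
    post = np.concatenate(post_l)
    k = len(pre)
    w_mean, w_sd = P.PEAK_EXC_DEFAULT
    weight = np.maximum(rng.normal(w_mean, w_sd, k), w_mean * 1e-3)
    d_mean, d_sd = P.DELAY_INTRA_EXC
    delay = np.maximum(rng.normal(d_mean, d_sd, k), P.DT_DEFAULT)
    channel = np.zeros(k, dtype=np.uint8)  # default excitatory kinetics
    rates = np.repeat(np.asarray(thalamic.column_rates, float), m)
    return ExternalInput(m * graph.n_columns, pre, post, weight, delay,
                         channel, rates, thalamic.onset,
                         thalamic.onset + thalamic.duration)


@dataclass(frozen=True)
class ExperimentSpec:
    """A fully specified simulation experiment."""

    name: str
    n_columns: int = 13
    scale: float = 1.0
    trials: int = 100
    run_length: float = 700.0
    window: tuple = (400.0, 500.0)  # analysis window, ms
    thalamic: ThalamicSpec = ThalamicSpec((0.0,) * 13)
    bg_overrides: dict = field(default_factory=dict)
    prob_overrides: dict = field(default_factory=dict)  # intercolumnar rules
    sweep: dict = field(default_factory=dict)  # rule/parameter -> grid
    compensation: str = "none"  # scaled builds keep full-size probabilities
    edge_columns: tuple = ()   # 1-based column labels
    figure_columns: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.thalamic.column_rates) != self.n_columns:
            raise ValueError("thalamic rate vector length != n_columns")
        if self.thalamic.onset + self.thalamic.duration > self.run_length:
            raise ValueError("stimulus extends past the run length")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thalamic"] = asdict(self.thalamic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        d = dict(d)
        th = d.pop("thalamic")
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown experiment keys: {sorted(unknown)}")
        for key in ("window", "edge_columns", "figure_columns"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(thalamic=ThalamicSpec(tuple(th["column_rates"]),
                                         th["onset"], th["duration"],
                                         th["cells_per_column"]), **d)


def col0(label: int, n_columns: int = 13) -> int:
    """1-based column label -> 0-based ring index."""
    if not 1 <= label <= n_columns:
        raise ValueError(f"column label {label} out of 1..{n_columns}")
    return label - 1


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def make_pulse_experiment(pulse_rate: float = 80.0, trials: int = 100,
                          sst_bg_rate: float | None = None,
                          vip_bg_rate: float | None = None,
                          scale: float = 1.0, seed: int = 0) -> ExperimentSpec:
    """Single-column transient pulse: one 10 ms wave of thalamic spikes.

    ``sst_bg_rate`` / ``vip_bg_rate`` override the per-fiber background
    rates of the SST / VIP populations (the raised-SST, lowered-VIP and
    raised-VIP variants).  A zero ``pulse_rate`` leaves the column at its
    spontaneous level.
    """
    bg = {}
    if sst_bg_rate is not None:
        bg["L23_SST"] = sst_bg_rate
    if vip_bg_rate is not None:
        bg["L23_VIP"] = vip_bg_rate
    return ExperimentSpec(
        name="pulse", n_columns=1, scale=scale, trials=trials,
        run_length=700.0, window=(350.0, 600.0),
        thalamic=ThalamicSpec((pulse_rate,), onset=400.0, duration=10.0),
        bg_overrides=bg, seed=seed)


def make_figure_ground(fig_rate: float = 80.0, ground_rate: float = 40.0,
                       figure_cols: tuple = (5, 6, 7, 8, 9),
                       pyr_pyr_prob: float | None = None,
                       trials: int = 100, scale: float = 1.0,
                       seed: int = 0) -> ExperimentSpec:
    """Figure-ground stimulus: a block of figure columns on a ground.

    Thalamic cells of figure columns fire at ``fig_rate`` and all others at
    ``ground_rate`` during 400-500 ms.  The outermost figure columns are
    the edges; analysis normalises each trial's column profile to its edge
    mean.  ``pyr_pyr_prob`` optionally overrides the intercolumnar Pyr->Pyr
    probability (default 6.6%).
    """
    n = 13
    rates = [ground_rate] * n
    for c in figure_cols:
        rates[col0(c, n)] = fig_rate
    prob = {} if pyr_pyr_prob is None else {"Pyr->Pyr": pyr_pyr_prob}
    return ExperimentSpec(
        name="figure_ground", n_columns=n, scale=scale, trials=trials,
        run_length=600.0, window=(400.0, 500.0),
        thalamic=ThalamicSpec(tuple(rates), onset=400.0, duration=100.0),
        prob_overrides=prob,
        edge_columns=(min(figure_cols), max(figure_cols)),
        figure_columns=tuple(sorted(figure_cols)), seed=seed)


def make_two_object(dom_col: int = 5, dom_rate: float = 80.0,
                    nondom_col: int = 8, nondom_rate: float = 60.0,
                    ground: float = 40.0, trials: int = 100,
                    pyr_sst_grid: tuple = (0.002, 0.004, 0.01, 0.02, 0.04),
                    scale: float = 1.0, seed: int = 0) -> ExperimentSpec:
    """Two objects (dominant and non-dominant column) in a ground.

    Includes a sweep grid of the long-range Pyr->SST connection
    probability from the 0.2% baseline up to 20x (4%).
    """
    if dom_col == nondom_col:
        raise ValueError("dominant and non-dominant columns must differ")
    n = 13
    rates = [ground] * n
    rates[col0(dom_col, n)] = dom_rate
    rates[col0(nondom_col, n)] = nondom_rate
    return ExperimentSpec(
        name="two_object", n_columns=n, scale=scale, trials=trials,
        run_length=600.0, window=(400.0, 500.0),
        thalamic=ThalamicSpec(tuple(rates), onset=400.0, duration=100.0),
        sweep={"Pyr->SST": tuple(pyr_sst_grid)},
        figure_columns=(dom_col, nondom_col), seed=seed)


def make_topdown(pref_col: int = 7, pref_rate: float = 80.0,
                 ground: float = 40.0,
                 vip_bg_grid: tuple = (2.0, 8.0, 14.0),
                 sst_bg_grid: tuple = (2.0, 8.0),
                 trials: int = 100, scale: float = 1.0,
                 seed: int = 0) -> ExperimentSpec:
    """Top-down gain protocol: one preferred column, homogeneous modulation.

    A factorial grid of VIP x SST per-fiber background rates, applied
    identically in every column (non-specific top-down drive); the output
    of interest is the preferred vs non-preferred Pyr response per grid
    cell.
    """
    if not vip_bg_grid or not sst_bg_grid:
        raise ValueError("background grids must be non-empty")
    n = 13
    rates = [ground] * n
    rates[col0(pref_col, n)] = pref_rate
    return ExperimentSpec(
        name="topdown", n_columns=n, scale=scale, trials=trials,
        run_length=600.0, window=(400.0, 500.0),
        thalamic=ThalamicSpec(tuple(rates), onset=400.0, duration=100.0),
        sweep={"L23_VIP_bg": tuple(vip_bg_grid),
               "L23_SST_bg": tuple(sst_bg_grid)},
        figure_columns=(pref_col,), seed=seed)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


def trial_seed(spec_seed: int, trial: int) -> np.random.SeedSequence:
    """Counter-based per-trial seed; independent of execution order."""
    return np.random.SeedSequence([spec_seed & 0x7FFFFFFF, trial])


def run_experiment(spec: ExperimentSpec, dt: float = P.DT_DEFAULT,
                   graph=None, record_v=(),
                   rebuild_per_trial: bool = True) -> list:
    """Run all trials of an experiment; returns SpikeRecords.

    Trials are independent simulations: by default the network and the
    thalamic fan-out are redrawn per trial (alongside the Poisson inputs),
    so quenched connectivity disorder averages out.  All seeds derive from
    ``spec.seed`` by a counter-based scheme, making the result independent
    of execution order.  Passing a pre-built ``graph`` (or
    ``rebuild_per_trial=False``) freezes the connectivity across trials.
    """
    fixed_graph = graph
    if fixed_graph is None and not rebuild_per_trial:
        fixed_graph = build_network(
            n_columns=spec.n_columns, scale=spec.scale, seed=spec.seed,
            prob_overrides=spec.prob_overrides,
            compensation=spec.compensation, dt=dt)
    records = []
    bg = thal = None
    for trial in range(spec.trials):
        seeds = trial_seed(spec.seed, trial).generate_state(2) & 0x7FFFFFFF
        if fixed_graph is None:
            g = build_network(
                n_columns=spec.n_columns, scale=spec.scale,
                seed=int(seeds[1]), prob_overrides=spec.prob_overrides,
                compensation=spec.compensation, dt=dt)
        else:
            g = fixed_graph
        if bg is None or fixed_graph is None:
            bg = background_rate_array(g, spec.bg_overrides)
            thal = thalamic_input(g, spec.thalamic, seed=int(g.seed))
        drives = Drives(bg_rate=bg, external=[thal])
        records.append(simulate(g, drives, spec.run_length, dt=dt,
                                seed=int(seeds[0]), record_v=record_v))
    return records
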