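"""Construction of the single- and multi-column spiking network graphs.

A column contains layers 2/3, 4, 5 and 6.  Layers 4–6 each hold one
excitatory and one inhibitory population; layer 2/3 splits its inhibitory
cells into PV, SST and VIP classes with cell-type-specific synaptic
parameters, while its pyramidal cells form the excitatory population.
Interlaminar wiring follows the layered-microcircuit probability map of the
base model (Potjans–Diesmann lineage), treating the three superficial
interneuron classes identically.  Within layer 2/3 the merged inhibitory
synapse budgets (I->E and I->I, from the base model's probabilities) are
re-split across cell-type-specific pathways using the experimentally
reported per-class connection weights.

Multiple columns are joined in a one-dimensional ring (periodic boundary)
through four superficial pathways only: short-range Pyr->Pyr, Pyr->PV and
PV->Pyr links to nearest neighbours, and long-range Pyr->SST links reaching
four columns to each side.  Intercolumnar synapses reuse the intracolumnar
parameters but with five-fold longer conduction delays.

The output is a :class:`NetworkGraph`: population index ranges plus an
explicit synapse table (pre, post, weight, delay, receptor channel), fully
determined by the build specification and a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import params as P

logger = logging.getLogger(__name__)

#: superficial population short names, in layout order
L23_TYPES = ("Pyr", "PV", "SST", "VIP")

#: all per-column populations in index order
POPULATION_ORDER = ("L23_Pyr", "L23_PV", "L23_SST", "L23_VIP",
                    "L4_E", "L4_I", "L5_E", "L5_I", "L6_E", "L6_I")

#: map population -> merged base-model population (for probability lookup)
PD_KEY = {"L23_Pyr": "L23E", "L23_PV": "L23I", "L23_SST": "L23I",
          "L23_VIP": "L23I", "L4_E": "L4E", "L4_I": "L4I",
          "L5_E": "L5E", "L5_I": "L5I", "L6_E": "L6E", "L6_I": "L6I"}

EXC_POPS = {"L23_Pyr", "L4_E", "L5_E", "L6_E"}

#: global receptor-channel table: one channel per distinct PSC decay tau (ms)
CHANNEL_TAUS = tuple(sorted({P.TAU_SYN_DEFAULT, *P.TAU_SYN.values()}))
_CHANNEL_OF_TAU = {tau: i for i, tau in enumerate(CHANNEL_TAUS)}


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One homogeneous cell group: name, size, column index."""

    name: str
    count: int
    column: int = 0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("population count must be >= 0")


@dataclass(frozen=True)
class SynapseTypeSpec:
    """Per-pathway synaptic parameters.

    ``peak``/``peak_sd`` in pA (excitatory positive, inhibitory negative),
    ``tau`` the PSC decay constant (ms), ``delay``/``delay_sd`` in ms.
    """

    source: str
    target: str
    peak: float
    peak_sd: float
    tau: float
    delay: float
    delay_sd: float

    def __post_init__(self) -> None:
        if self.peak == 0:
            raise ValueError("synaptic peak current must be nonzero")
        if self.tau <= 0 or self.delay <= 0:
            raise ValueError("tau and delay must be positive")

    @property
    def channel(self) -> int:
        return _CHANNEL_OF_TAU[self.tau]


@dataclass(frozen=True)
class ConnectionRule:
    """A wiring rule between two populations.

    Either Bernoulli with probability ``p`` per ordered pair, or a fixed
    synapse ``budget`` realised by uniform pre/post sampling with multapses.
    ``offsets`` lists relative column indices (0 = intracolumnar), applied
    periodically.
    """

    source: str
    target: str
    syn: SynapseTypeSpec
    p: float | None = None
    budget: int | None = None
    offsets: tuple = (0,)
    name: str = ""

    def __post_init__(self) -> None:
        if (self.p is None) == (self.budget is None):
            raise ValueError("rule needs exactly one of p or budget")
        if self.p is not None and not 0.0 <= self.p <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass
class NetworkGraph:
    """Assembled circuit: population ranges plus an explicit synapse table."""

    populations: list  # of PopulationSpec, in global index order
    offsets: np.ndarray  # start index per population (len = n_pops + 1)
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray  # pA
    delay: np.ndarray  # ms
    channel: np.ndarray  # receptor channel id on the target
    rule_id: np.ndarray  # provenance: index into rule_names per synapse
    rule_names: list
    seed: int = 0
    n_columns: int = 1
    scale: float = 1.0
    compensation: str = "none"
    intercolumnar_probs: dict | None = None  # table used at build time

    @property
    def n_neurons(self) -> int:
        return int(self.offsets[-1])

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def index_range(self, name: str, column: int = 0) -> tuple:
        """Global [start, stop) index range of a population."""
        for i, pop in enumerate(self.populations):
            if pop.name == name and pop.column == column:
                return int(self.offsets[i]), int(self.offsets[i + 1])
        raise KeyError(f"no population {name!r} in column {column}")

    def neuron_indices(self, name: str, column: int = 0) -> np.ndarray:
        a, b = self.index_range(name, column)
        return np.arange(a, b)

    def population_of(self) -> np.ndarray:
        """Per-neuron population index (into ``self.populations``)."""
        out = np.empty(self.n_neurons, dtype=np.int32)
        for i in range(len(self.populations)):
            out[self.offsets[i]:self.offsets[i + 1]] = i
        return out

    def synapse_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre": self.pre, "post": self.post, "weight": self.weight,
            "delay": self.delay, "channel": self.channel,
            "rule_id": self.rule_id,
        })

    def manifest_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": [p.name for p in self.populations],
            "column": [p.column for p in self.populations],
            "count": [p.count for p in self.populations],
            "start": self.offsets[:-1],
            "stop": self.offsets[1:],
        })


# ---------------------------------------------------------------------------
# Deterministic partition helpers
# ---------------------------------------------------------------------------


def split_superficial_inhibitory(n_inh: int) -> tuple:
    """Partition superficial inhibitory cells into (PV, SST, VIP) counts.

    VIP takes 24% and SST 30% (round-half-even); PV absorbs the remainder,
    so the total is conserved exactly.
    """
    if n_inh < 0:
        raise ValueError("n_inh must be >= 0")
    n_vip = int(np.rint(P.VIP_FRACTION * n_inh))
    n_sst = int(np.rint(P.SST_FRACTION * n_inh))
    n_pv = n_inh - n_vip - n_sst
    if n_pv < 0:
        raise ValueError("negative PV remainder")
    return n_pv, n_sst, n_vip


def allocate_inhibitory_synapses(total_budget: int,
                                 weights: Sequence[float],
                                 source_sizes: Sequence[int]) -> np.ndarray:
    """Split a synapse budget across pathways by weight x source size.

    Largest-remainder rounding conserves the budget exactly (ties broken by
    larger quota, then lower index).
    """
    weights = np.asarray(weights, dtype=float)
    sizes = np.asarray(source_sizes, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    shares = weights * sizes
    total_w = shares.sum()
    if total_w <= 0:
        raise ValueError("zero total weight")
    if total_budget < 0:
        raise ValueError("budget must be >= 0")
    quota = total_budget * shares / total_w
    counts = np.floor(quota).astype(int)
    rem = total_budget - counts.sum()
    if rem:
        frac = quota - np.floor(quota)
        order = sorted(range(len(quota)),
                       key=lambda i: (-frac[i], -quota[i], i))
        for i in order[:rem]:
            counts[i] += 1
    return counts


def inc_ratio_check(peak_a: float, tau_a: float, p_a: float,
                    peak_b: float, tau_b: float, p_b: float) -> float:
    """Ratio of individual neuronal contributions of two pathways.

    INC = connection probability x PSC charge, and for an exponential PSC
    the charge is peak x tau; so the ratio is
    ``(p_a*peak_a*tau_a) / (p_b*peak_b*tau_b)``.  Consistency utility only.
    """
    denom = p_b * peak_b * tau_b
    if denom == 0:
        raise ZeroDivisionError("zero denominator in INC ratio")
    return (p_a * peak_a * tau_a) / denom


# ---------------------------------------------------------------------------
# Column / network specification
# ---------------------------------------------------------------------------


def _scaled(n: int, scale: float) -> int:
    return max(int(np.rint(n * scale)), 1) if n > 0 else 0


def column_populations(column: int = 0, scale: float = 1.0) -> list:
    """Population list of one column (optionally scaled down)."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    n23i = _scaled(P.NEURON_COUNTS["L23"]["I"], scale)
    n_pv, n_sst, n_vip = split_superficial_inhibitory(n23i)
    pops = [
        PopulationSpec("L23_Pyr", _scaled(P.NEURON_COUNTS["L23"]["E"], scale), column),
        PopulationSpec("L23_PV", n_pv, column),
        PopulationSpec("L23_SST", n_sst, column),
        PopulationSpec("L23_VIP", n_vip, column),
    ]
    for layer in ("L4", "L5", "L6"):
        for ei in ("E", "I"):
            pops.append(PopulationSpec(
                f"{layer}_{ei}", _scaled(P.NEURON_COUNTS[layer][ei], scale),
                column))
    return pops


def _syn_params(source: str, target: str) -> tuple:
    """(peak, peak_sd, tau) for an intracolumnar pathway."""
    s_type = source.split("_")[1] if "_" in source else source
    t_type = target.split("_")[1] if "_" in target else target
    superficial = source.startswith("L23") and target.startswith("L23")
    key = f"{s_type}->{t_type}"
    if source == "L4_E" and target == "L23_Pyr":
        peak, sd = P.PEAK_CURRENTS["L4E->Pyr"]
        return peak, sd, P.TAU_SYN_DEFAULT
    if superficial and key in P.PEAK_CURRENTS:
        peak, sd = P.PEAK_CURRENTS[key]
    elif source in EXC_POPS:
        peak, sd = P.PEAK_EXC_DEFAULT
    else:
        peak, sd = P.PEAK_INH_DEFAULT
    tau = P.TAU_SYN.get(key, P.TAU_SYN_DEFAULT) if superficial \
        else P.TAU_SYN_DEFAULT
    return peak, sd, tau


def _syn_spec(source: str, target: str, inter: bool = False) -> SynapseTypeSpec:
    peak, sd, tau = _syn_params(source, target)
    exc = source in EXC_POPS
    if inter:
        delay, dsd = P.DELAY_INTER_EXC if exc else P.DELAY_INTER_INH
    else:
        delay, dsd = P.DELAY_INTRA_EXC if exc else P.DELAY_INTRA_INH
    return SynapseTypeSpec(source, target, peak, sd, tau, delay, dsd)


def column_rules(sizes: dict, conn_prob: dict | None = None,
                 weights_i_to_e: dict | None = None,
                 weights_i_to_i: dict | None = None) -> list:
    """Intracolumnar wiring rules for one column of given population sizes.

    ``conn_prob`` is the merged-population probability map
    (target -> source -> p); superficial I->E and I->I pathways are realised
    as fixed budgets split by the cell-type weighting factors.
    """
    prob = conn_prob or P.PD_CONN_PROB
    w_ie = weights_i_to_e or P.WEIGHTS_I_TO_E
    w_ii = weights_i_to_i or P.WEIGHTS_I_TO_I
    rules: list[ConnectionRule] = []

    def p_of(target: str, source: str) -> float:
        try:
            return prob[PD_KEY[target]][PD_KEY[source]]
        except KeyError as exc:
            raise KeyError(f"no connection probability for "
                           f"{source}->{target}") from exc

    inh23 = ("L23_PV", "L23_SST", "L23_VIP")

    # --- superficial excitatory pathways: Bernoulli with base-model P_EE/P_EI
    rules.append(ConnectionRule("L23_Pyr", "L23_Pyr",
                                _syn_spec("L23_Pyr", "L23_Pyr"),
                                p=p_of("L23_Pyr", "L23_Pyr"),
                                name="L23_Pyr->L23_Pyr"))
    for tgt in inh23:
        rules.append(ConnectionRule("L23_Pyr", tgt,
                                    _syn_spec("L23_Pyr", tgt),
                                    p=p_of(tgt, "L23_Pyr"),
                                    name=f"L23_Pyr->{tgt}"))

    # --- superficial inhibitory budgets, split by cell-type weights
    n_e = sizes["L23_Pyr"]
    n_i = sizes["L23_PV"] + sizes["L23_SST"] + sizes["L23_VIP"]
    p_ie = p_of("L23_Pyr", "L23_PV")  # merged I->E probability
    p_ii = p_of("L23_PV", "L23_PV")   # merged I->I probability

    budget_ie = int(np.rint(p_ie * n_i * n_e))
    pairs_ie = list(w_ie)
    counts = allocate_inhibitory_synapses(
        budget_ie, [w_ie[k] for k in pairs_ie],
        [sizes[f"L23_{k.split('->')[0]}"] for k in pairs_ie])
    for key, n_syn in zip(pairs_ie, counts):
        src = f"L23_{key.split('->')[0]}"
        rules.append(ConnectionRule(src, "L23_Pyr", _syn_spec(src, "L23_Pyr"),
                                    budget=int(n_syn), name=f"{src}->L23_Pyr"))

    budget_ii = int(np.rint(p_ii * n_i * n_i))
    pairs_ii = list(w_ii)
    counts = allocate_inhibitory_synapses(
        budget_ii, [w_ii[k] for k in pairs_ii],
        [sizes[f"L23_{k.split('->')[0]}"] for k in pairs_ii])
    for key, n_syn in zip(pairs_ii, counts):
        s_t, t_t = key.split("->")
        src, tgt = f"L23_{s_t}", f"L23_{t_t}"
        rules.append(ConnectionRule(src, tgt, _syn_spec(src, tgt),
                                    budget=int(n_syn), name=f"{src}->{tgt}"))

    # --- interlaminar and deep-layer pathways: merged probabilities,
    #     superficial interneuron classes treated identically
    deep = ("L4_E", "L4_I", "L5_E", "L5_I", "L6_E", "L6_I")
    for src in POPULATION_ORDER:
        for tgt in POPULATION_ORDER:
            if src.startswith("L23") and tgt.startswith("L23"):
                continue  # handled above
            if src in deep or tgt in deep:
                p = p_of(tgt, src)
                if p > 0:
                    rules.append(ConnectionRule(src, tgt, _syn_spec(src, tgt),
                                                p=p, name=f"{src}->{tgt}"))
    return rules


def intercolumnar_rules(rules_table: dict | None = None) -> list:
    """The four superficial intercolumnar rule families (per column offset).

    Returns (source, target, probability, offsets, SynapseTypeSpec with
    intercolumnar delays).
    """
    table = rules_table or P.INTERCOLUMNAR_RULES
    out = []
    for key, (p, reach) in table.items():
        s_t, t_t = key.split("->")
        src, tgt = f"L23_{s_t}", f"L23_{t_t}"
        out.append(ConnectionRule(src, tgt, _syn_spec(src, tgt, inter=True),
                                  p=p, offsets=tuple(reach),
                                  name=f"{src}->{tgt}:inter"))
    return out


# ---------------------------------------------------------------------------
# Realisation
# ---------------------------------------------------------------------------


def _bernoulli_pairs(rng: np.random.Generator, n_pre: int, n_post: int,
                     p: float, exclude_self: bool) -> tuple:
    """Sample the edge set of an independent-Bernoulli bipartite rule.

    Draws the total count from the exact binomial and then places that many
    distinct ordered pairs uniformly (rejecting duplicates and, for
    recurrent rules, autapses) — equivalent to per-pair Bernoulli sampling.
    """
    n_pairs = n_pre * n_post - (n_pre if exclude_self else 0)
    if n_pairs <= 0 or p <= 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    k = int(rng.binomial(n_pairs, p))
    if k == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64))

    def distinct(m: int) -> np.ndarray:
        """m distinct flat pair codes, uniform over the allowed grid."""
        got = np.empty(0, dtype=np.int64)
        while len(got) < m:
            draw = rng.integers(0, n_pre * n_post,
                                size=int((m - len(got)) * 1.2) + 16)
            if exclude_self:
                draw = draw[draw // n_post != draw % n_post]
            got = np.unique(np.concatenate([got, draw]))
        if len(got) > m:
            got = rng.choice(got, size=m, replace=False)
        return got

    if k > n_pairs // 2:
        # dense rule: sample the complement to avoid rejection blow-up
        excluded = distinct(n_pairs - k)
        allowed = np.arange(n_pre * n_post, dtype=np.int64)
        if exclude_self:
            allowed = allowed[allowed // n_post != allowed % n_post]
        chosen = np.setdiff1d(allowed, excluded, assume_unique=True)
    else:
        chosen = distinct(k)
    return chosen // n_post, chosen % n_post


def _budget_pairs(rng: np.random.Generator, n_pre: int, n_post: int,
                  k: int) -> tuple:
    """Uniform pre/post sampling with replacement (multapses allowed)."""
    return (rng.integers(0, n_pre, size=k), rng.integers(0, n_post, size=k))


def _draw_weights(rng, syn: SynapseTypeSpec, k: int,
                  w_scale: float) -> np.ndarray:
    w = rng.normal(syn.peak * w_scale, syn.peak_sd * w_scale, size=k)
    # truncate to preserve sign (Dale's law)
    eps = abs(syn.peak) * w_scale * 1e-3
    if syn.peak > 0:
        return np.maximum(w, eps)
    return np.minimum(w, -eps)


def _draw_delays(rng, syn: SynapseTypeSpec, k: int, dt: float) -> np.ndarray:
    return np.maximum(rng.normal(syn.delay, syn.delay_sd, size=k), dt)


def build_network(n_columns: int = 1, scale: float = 1.0, seed: int = 0,
                  conn_prob: dict | None = None,
                  intercolumnar: dict | None = None,
                  prob_overrides: dict | None = None,
                  compensation: str = "none",
                  dt: float = P.DT_DEFAULT) -> NetworkGraph:
    """Assemble the full circuit (1..n columns, periodic ring).

    ``scale`` shrinks every population; connection probabilities, synaptic
    weights and background fiber counts are left unchanged by default
    (``compensation="none"``), so recurrent coupling weakens with the scale
    and the full-size build is the reference.  Two compensation modes
    preserve each neuron's expected in-degree x weight product instead:
    ``"probability"`` divides connection probabilities by the scale (capped
    at 1, remainder moved onto the weight) and synapse budgets by the
    scale; ``"weight"`` multiplies peak currents by 1/scale.  Both trade
    faithfulness of input correlations for mean drive and can flip the
    bistable VIP/SST spontaneous state at small scales (see the methods
    note).  ``prob_overrides`` patches intercolumnar probabilities by rule
    key (e.g. ``{"Pyr->SST": 0.04}``).  Deterministic in (spec, seed).
    """
    if compensation not in ("probability", "weight", "none",
                            "intercolumnar"):
        raise ValueError(f"unknown compensation mode {compensation!r}")
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    inter_table = dict(intercolumnar or P.INTERCOLUMNAR_RULES)
    if prob_overrides:
        unknown = set(prob_overrides) - set(inter_table)
        if unknown:
            raise KeyError(f"unknown intercolumnar rules: {sorted(unknown)}")
        for key, p in prob_overrides.items():
            inter_table[key] = (p, inter_table[key][1])
    max_reach = max((max(abs(o) for o in reach)
                     for _, reach in inter_table.values()), default=0)
    if n_columns > 1 and max_reach > n_columns // 2:
        raise ValueError(f"intercolumnar reach {max_reach} exceeds "
                         f"floor(n_columns/2) = {n_columns // 2}")

    populations: list[PopulationSpec] = []
    for col in range(n_columns):
        populations.extend(column_populations(col, scale))
    counts = np.array([p.count for p in populations], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(counts)])
    pop_index = {(p.name, p.column): i for i, p in enumerate(populations)}
    sizes = {p.name: p.count for p in populations if p.column == 0}

    intra = column_rules(sizes, conn_prob=conn_prob)
    inter = intercolumnar_rules(inter_table)

    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    pre_l, post_l, w_l, d_l, ch_l, rid_l = [], [], [], [], [], []
    rule_names: list[str] = []

    def realise(rule: ConnectionRule, src_col: int, tgt_col: int) -> None:
        n_pre = sizes[rule.source]
        n_post = sizes[rule.target]
        inter = src_col != tgt_col
        mode = compensation
        if mode == "intercolumnar":
            # preserve long-range in-degrees only; local wiring unscaled
            mode = "probability" if inter else "none"
        w_scale = 1.0
        if rule.p is not None:
            p_eff = rule.p
            if mode == "probability":
                p_eff = rule.p / scale
                if p_eff > 1.0:
                    w_scale = p_eff  # remainder carried by the weight
                    p_eff = 1.0
            elif mode == "weight":
                w_scale = 1.0 / scale
            same = (rule.source == rule.target) and (src_col == tgt_col)
            i, j = _bernoulli_pairs(rng, n_pre, n_post, p_eff, same)
        else:
            budget = rule.budget
            if mode == "probability":
                budget = int(np.rint(budget / scale))
            elif mode == "weight":
                w_scale = 1.0 / scale
            i, j = _budget_pairs(rng, n_pre, n_post, budget)
        k = len(i)
        rid = len(rule_names)
        rule_names.append(f"{rule.name}@c{src_col}->c{tgt_col}")
        if k == 0:
            return
        a = offsets[pop_index[(rule.source, src_col)]]
        b = offsets[pop_index[(rule.target, tgt_col)]]
        pre_l.append(i + a)
        post_l.append(j + b)
        w_l.append(_draw_weights(rng, rule.syn, k, w_scale))
        d_l.append(_draw_delays(rng, rule.syn, k, dt))
        ch_l.append(np.full(k, rule.syn.channel, dtype=np.uint8))
        rid_l.append(np.full(k, rid, dtype=np.int32))

    for col in range(n_columns):
        for rule in intra:
            realise(rule, col, col)
    if n_columns > 1:
        for col in range(n_columns):
            for rule in inter:
                for off in rule.offsets:
                    realise(rule, col, (col + off) % n_columns)

    cat = (lambda xs, dt_: np.concatenate(xs).astype(dt_) if xs
           else np.empty(0, dt_))
    graph = NetworkGraph(
        populations=populations, offsets=offsets,
        pre=cat(pre_l, np.int32), post=cat(post_l, np.int32),
        weight=cat(w_l, np.float64), delay=cat(d_l, np.float64),
        channel=cat(ch_l, np.uint8), rule_id=cat(rid_l, np.int32),
        rule_names=rule_names, seed=seed, n_columns=n_columns, scale=scale,
        compensation=compensation, intercolumnar_probs=inter_table)
    logger.info("built network: %d columns, %d neurons, %d synapses",
                n_columns, graph.n_neurons, graph.n_synapses)
    return graph


def build_column(scale: float = 1.0, seed: int = 0, **kwargs) -> NetworkGraph:
    """Single-column convenience wrapper around :func:`build_network`."""
    return build_network(n_columns=1, scale=scale, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def expected_rule_counts(graph: NetworkGraph) -> pd.DataFrame:
    """Per-rule realised counts with binomial expectation z-scores."""
    sizes = {p.name: p.count for p in graph.populations if p.column == 0}
    intra = {r.name: r for r in column_rules(sizes)}
    inter = {r.name: r
             for r in intercolumnar_rules(graph.intercolumnar_probs)}
    realised = np.bincount(graph.rule_id, minlength=len(graph.rule_names))
    rows = []
    for rid, tag in enumerate(graph.rule_names):
        name = tag.split("@")[0]
        rule = intra.get(name) or inter.get(name.replace(":inter", "") + ":inter")
        if rule is None:
            continue
        n_pre, n_post = sizes[rule.source], sizes[rule.target]
        is_inter = name.endswith(":inter")
        mode = graph.compensation
        if mode == "intercolumnar":
            mode = "probability" if is_inter else "none"
        if rule.p is not None:
            p_eff = rule.p
            if mode == "probability":
                p_eff = min(rule.p / graph.scale, 1.0)
            same_cols = tag.split("@")[1].split("->")
            same = (rule.source == rule.target
                    and same_cols[0] == same_cols[1])
            n_pairs = n_pre * n_post - (n_pre if same else 0)
            mean = n_pairs * p_eff
            sd = np.sqrt(n_pairs * p_eff * (1 - p_eff))
        else:
            budget = float(rule.budget)
            if mode == "probability":
                budget = float(np.rint(budget / graph.scale))
            mean, sd = budget, 0.0
        z = (realised[rid] - mean) / sd if sd > 0 else 0.0
        rows.append({"rule": tag, "realised": int(realised[rid]),
                     "expected": mean, "z": z})
    return pd.DataFrame(rows)


def validate_network(graph: NetworkGraph) -> dict:
    """Check structural invariants; returns a report dict.

    Verifies index ranges, Dale's law (weight sign matches source E/I
    class), and that each Bernoulli rule's realised count is within 5 sigma
    of its binomial expectation.
    """
    report: dict = {"n_neurons": graph.n_neurons,
                    "n_synapses": graph.n_synapses, "failures": []}
    if graph.n_synapses and (graph.pre.min() < 0
                             or graph.pre.max() >= graph.n_neurons
                             or graph.post.min() < 0
                             or graph.post.max() >= graph.n_neurons):
        report["failures"].append("synapse index out of range")

    # Dale's law: excitatory-source weights > 0, inhibitory-source < 0
    exc_mask = np.zeros(graph.n_neurons, dtype=bool)
    for pop in graph.populations:
        if pop.name in EXC_POPS:
            a, b = graph.index_range(pop.name, pop.column)
            exc_mask[a:b] = True
    src_exc = exc_mask[graph.pre] if graph.n_synapses else np.empty(0, bool)
    n_dale = int(np.sum((graph.weight <= 0) & src_exc)
                 + np.sum((graph.weight >= 0) & ~src_exc))
    report["dale_violations"] = n_dale
    if n_dale:
        report["failures"].append(f"{n_dale} Dale's-law violations")

    counts = expected_rule_counts(graph)
    report["rule_counts"] = counts
    bad = counts[np.abs(counts["z"]) > 5.0]
    if len(bad):
        report["failures"].append(
            f"{len(bad)} rules outside 5 sigma: {list(bad['rule'])}")
    report["ok"] = not report["failures"]
    return report
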