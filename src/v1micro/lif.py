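"""Clock-driven leaky integrate-and-fire network engine.

Every cell is an identical LIF point neuron with exponentially decaying
postsynaptic currents arriving on multiple receptor channels (one channel
per PSC decay time constant, so different presynaptic cell types can have
distinct kinetics on the same target).  Subthreshold dynamics

    tau_m dV/dt = -(V - V_rest) + R * (sum_k I_k + I_const),
    tau_k dI_k/dt = -I_k,            R = tau_m / C_m,

are advanced with the exact propagator of the linear cascade per time step,
so the integration is dt-robust.  A spike arrival adds the synaptic weight
w (pA) to the target channel instantaneously.  Threshold crossings are
detected on the grid: the neuron spikes at the step boundary, the membrane
is reset and clamped at V_reset for tau_ref while the channels keep
integrating.  Spike delivery uses a circular delay buffer; simultaneous
events are processed in ascending neuron index, so a run is a pure
function of (graph, drives, seed).  The inner loop is compiled with numba.

External input comes in three forms: a per-neuron aggregate Poisson
background (fiber count x fiber rate), sets of external fibers with their
own fan-out synapses and piecewise-constant rates (used for thalamic
afferents), and optional constant injected current (used for F-I curves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import params as P
from .network import CHANNEL_TAUS, NetworkGraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LIFParams:
    """Neuron parameters, identical for every cell."""

    tau_m: float = P.LIF_DEFAULTS["tau_m"]
    v_th: float = P.LIF_DEFAULTS["v_th"]
    v_reset: float = P.LIF_DEFAULTS["v_reset"]
    v_rest: float = P.LIF_DEFAULTS["v_rest"]
    tau_ref: float = P.LIF_DEFAULTS["tau_ref"]
    c_m: float = P.LIF_DEFAULTS["c_m"]

    def __post_init__(self) -> None:
        if self.v_reset >= self.v_th:
            raise ValueError("V_reset must be below V_th")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be >= 0")

    @property
    def R(self) -> float:
        """Membrane resistance tau_m / C_m (GOhm when ms / pF)."""
        return self.tau_m / self.c_m


@dataclass
class ExternalInput:
    """External fibers with explicit fan-out synapses and a rate window.

    ``pre`` indexes fibers (0..n_fibers), ``post`` network neurons.  Each
    fiber emits an independent Poisson train at ``rates[fiber]`` Hz between
    ``t_start`` and ``t_stop`` (ms).
    """

    n_fibers: int
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    delay: np.ndarray
    channel: np.ndarray
    rates: np.ndarray
    t_start: float = 0.0
    t_stop: float = np.inf


@dataclass
class Drives:
    """Everything that injects current into the network."""

    bg_rate: np.ndarray | None = None       # aggregate Hz per neuron
    bg_peak: tuple = P.PEAK_BACKGROUND      # (w, dw) pA per background event
    const_current: np.ndarray | float | None = None  # pA
    external: list = field(default_factory=list)     # of ExternalInput


@dataclass
class SpikeRecord:
    """Spike events (global neuron index, time in ms) plus metadata."""

    neurons: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float
    manifest: pd.DataFrame | None = None
    v_trace: np.ndarray | None = None
    v_trace_neurons: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.times)

    def spikes_of(self, indices: np.ndarray) -> "SpikeRecord":
        mask = np.isin(self.neurons, indices)
        return SpikeRecord(self.neurons[mask], self.times[mask],
                           self.n_neurons, self.duration, self.manifest)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"neuron_id": self.neurons,
                             "time_ms": self.times})


def poisson_spike_source(rate: float, duration: float,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Spike times (ms) of a homogeneous Poisson process.

    Exponential inter-arrival sampling; identical seed gives an identical
    train.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mean_isi = 1000.0 / rate
    n_guess = max(int(duration / mean_isi * 1.5) + 20, 20)
    times = np.cumsum(rng.exponential(mean_isi, size=n_guess))
    while times[-1] < duration:
        times = np.concatenate(
            [times, times[-1] + np.cumsum(rng.exponential(mean_isi, n_guess))])
    return times[times < duration]


def lif_fi_rate(params: LIFParams, current: float) -> float:
    """Closed-form stationary firing rate (Hz) under constant current.

    0 below rheobase; saturates at 1000/tau_ref for very large input.
    """
    drive = current * params.R  # mV above rest
    gap_th = params.v_th - params.v_rest
    gap_reset = params.v_reset - params.v_rest
    if drive <= gap_th:
        return 0.0
    t_isi = params.tau_ref + params.tau_m * np.log(
        (drive - gap_reset) / (drive - gap_th))
    return 1000.0 / t_isi


def _csr(pre: np.ndarray, n_sources: int, *cols) -> tuple:
    order = np.argsort(pre, kind="stable")
    indptr = np.zeros(n_sources + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    np.cumsum(indptr, out=indptr)
    return (indptr,) + tuple(c[order] for c in cols)


@njit(cache=True)
def _run_kernel(n_steps, n_neurons, ring_len,
                a, pop_id, pop_nslots, pop_b, pop_prop, const_gain,
                v_rest, v_reset, v_th, ref_steps,
                V, I, ring, refr,
                indptr, s_post, s_w, s_d, s_ch,
                has_bg, bg_lam, bg_w, bg_dw,
                has_const, i_const,
                ext_on_step, ext_indptr, ext_post, ext_w, ext_d, ext_ch,
                ext_lam,
                threshold_on, rec_idx, v_trace,
                spike_neuron_buf, spike_step_buf, rng_seed):
    """Single-threaded simulation loop.  Returns the number of spikes.

    Receptor channels are compressed per population into slots (slot 0 is
    always the default fast channel); I and ring are laid out
    (neuron, slot) / (delay, neuron, slot) so the per-neuron slot loop is
    short and contiguous.
    """
    np.random.seed(rng_seed)
    n_spikes = 0
    n_ext = ext_lam.shape[0]
    for step in range(n_steps):
        slot = step % ring_len
        # deliver due events and integrate the membrane in one pass
        for n in range(n_neurons):
            pi = pop_id[n]
            syn = 0.0
            for k in range(pop_nslots[pi]):
                cur = I[n, k] + ring[slot, n, k]
                ring[slot, n, k] = 0.0
                syn += pop_prop[pi, k] * cur
                I[n, k] = cur * pop_b[pi, k]
            # background events (instantaneous, fastest channel = slot 0)
            if has_bg and bg_lam[n] > 0.0:
                cnt = np.random.poisson(bg_lam[n])
                if cnt > 0:
                    amp = bg_w * cnt
                    if bg_dw > 0.0:
                        amp += bg_dw * np.sqrt(cnt) * np.random.normal()
                    # delivered at step start: affects this step's drive
                    syn += pop_prop[pi, 0] * amp
                    I[n, 0] += amp * pop_b[pi, 0]
            v = v_rest + (V[n] - v_rest) * a + syn
            if has_const:
                v += const_gain * i_const[n]
            if refr[n] > 0:
                v = v_reset
                refr[n] -= 1
            V[n] = v
        if not np.isfinite(V).all():
            return -(step + 1)  # caller raises with the step encoded
        # external fibers (Poisson per fiber, delayed fan-out)
        if n_ext > 0 and ext_on_step[step]:
            for f in range(n_ext):
                lam = ext_lam[f]
                if lam <= 0.0:
                    continue
                cnt = np.random.poisson(lam)
                if cnt > 0:
                    for si in range(ext_indptr[f], ext_indptr[f + 1]):
                        dst = (step + ext_d[si]) % ring_len
                        ring[dst, ext_post[si], ext_ch[si]] += \
                            ext_w[si] * cnt
        # threshold, reset, spike propagation
        if threshold_on:
            for n in range(n_neurons):
                if V[n] >= v_th and refr[n] == 0:
                    if n_spikes >= spike_neuron_buf.shape[0]:
                        return -(step + 1)  # buffer exhausted
                    V[n] = v_reset
                    refr[n] = ref_steps
                    spike_neuron_buf[n_spikes] = n
                    spike_step_buf[n_spikes] = step + 1
                    n_spikes += 1
                    # the spike happens at the step boundary (t = step+1):
                    # a delay d delivers at t + d
                    for si in range(indptr[n], indptr[n + 1]):
                        dst = (step + 1 + s_d[si]) % ring_len
                        ring[dst, s_post[si], s_ch[si]] += s_w[si]
        # voltage probes
        for j in range(rec_idx.shape[0]):
            v_trace[step + 1, j] = V[rec_idx[j]]
    return n_spikes


def simulate(graph: NetworkGraph, drives: Drives, duration: float,
             dt: float = P.DT_DEFAULT, seed: int = 0,
             lif: LIFParams | None = None, record_v: Sequence[int] = (),
             threshold_enabled: bool = True,
             init_v: str = "rest") -> SpikeRecord:
    """Run the network for ``duration`` ms and return the spike record.

    ``init_v="rest"`` (default) starts every cell at V_rest, as the
    simulator lineage this model derives from does; ``"random"`` draws
    initial potentials uniformly over [V_reset, V_th).  Deterministic in
    (graph, drives, seed).  Raises ``FloatingPointError`` if any membrane
    potential becomes non-finite.
    """
    if init_v not in ("random", "rest"):
        raise ValueError(f"unknown init_v mode {init_v!r}")
    lif = lif or LIFParams()
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    N = graph.n_neurons
    K = len(CHANNEL_TAUS)
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF])
    rng = np.random.default_rng(ss)
    kernel_seed = int(ss.generate_state(2)[1] & 0x7FFFFFFF)

    # propagator coefficients
    a = np.exp(-dt / lif.tau_m)
    taus = np.asarray(CHANNEL_TAUS, dtype=np.float64)
    b = np.exp(-dt / taus)
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = lif.R * taus * (b - a) / (taus - lif.tau_m)
    degenerate = np.isclose(taus, lif.tau_m)
    prop[degenerate] = lif.R * dt / lif.tau_m * a  # limit tau_k -> tau_m
    const_gain = lif.R * (1.0 - a)

    # recurrent synapses in CSR form, delays in steps (>= 1)
    if graph.n_synapses:
        if np.any(graph.delay < dt - 1e-12):
            raise ValueError("synaptic delays must be >= dt")
        d_steps = np.maximum(np.rint(graph.delay / dt).astype(np.int32), 1)
        indptr, s_post, s_w, s_d, s_ch = _csr(
            graph.pre.astype(np.int64), N, graph.post.astype(np.int32),
            graph.weight.astype(np.float64), d_steps,
            graph.channel.astype(np.int8))
    else:
        indptr = np.zeros(N + 1, dtype=np.int64)
        s_post = np.empty(0, dtype=np.int32)
        s_w = np.empty(0, dtype=np.float64)
        s_d = np.empty(0, dtype=np.int32)
        s_ch = np.empty(0, dtype=np.int8)

    # external fibers: merge all inputs into one fiber table
    ext_indptr = np.zeros(1, dtype=np.int64)
    ext_post = np.empty(0, dtype=np.int32)
    ext_w = np.empty(0, dtype=np.float64)
    ext_d = np.empty(0, dtype=np.int32)
    ext_ch = np.empty(0, dtype=np.int8)
    ext_lam = np.empty(0, dtype=np.float64)
    ext_on_step = np.zeros(n_steps, dtype=np.bool_)
    max_ext_delay = 1
    if drives.external:
        ptrs, posts, ws, ds, chs, lams = [], [], [], [], [], []
        base = 0
        windows = []
        for e in drives.external:
            ed = np.maximum(np.rint(np.asarray(e.delay) / dt)
                            .astype(np.int32), 1)
            eptr, e_post, e_w, e_dd, e_ch = _csr(
                np.asarray(e.pre, dtype=np.int64), e.n_fibers,
                np.asarray(e.post, dtype=np.int32),
                np.asarray(e.weight, dtype=np.float64), ed,
                np.asarray(e.channel, dtype=np.int8))
            if len(e_dd):
                max_ext_delay = max(max_ext_delay, int(e_dd.max()))
            ptrs.append(eptr[1:] + base)
            base += eptr[-1]
            posts.append(e_post)
            ws.append(e_w)
            ds.append(e_dd)
            chs.append(e_ch)
            lams.append(np.asarray(e.rates, dtype=np.float64) * dt * 1e-3)
            windows.append((e.t_start, e.t_stop, e.n_fibers))
        ext_indptr = np.concatenate([[0], np.concatenate(ptrs)])
        ext_post = np.concatenate(posts)
        ext_w = np.concatenate(ws)
        ext_d = np.concatenate(ds)
        ext_ch = np.concatenate(chs)
        # a fiber outside its window contributes rate 0 at that step; with a
        # single shared window per input we precompute a per-step gate and
        # zero rates outside their windows via the gate only when every
        # input shares the window; otherwise rates are masked per input by
        # splitting lam into per-step scaling (windows differ rarely).
        ext_lam = np.concatenate(lams)
        steps_t = np.arange(n_steps) * dt
        gate = np.zeros(n_steps, dtype=np.bool_)
        for (t0, t1, m) in windows:
            gate |= (steps_t >= t0) & (steps_t < t1)
        ext_on_step = gate
        if len(windows) > 1:
            starts = {w[:2] for w in windows}
            if len(starts) > 1:
                raise NotImplementedError(
                    "external inputs with different time windows are not "
                    "supported in one run; merge them or use equal windows")

    D = int(max(int(s_d.max()) if len(s_d) else 1, max_ext_delay)) + 2

    # compress the global channel table into per-population receptor slots
    # (slot 0 is always the default fast channel, used by the background)
    pop_id = graph.population_of()
    n_pops = len(graph.populations)
    used = np.zeros((n_pops, K), dtype=bool)
    used[:, 0] = True
    if len(s_post):
        used[pop_id[s_post], s_ch] = True
    if len(ext_post):
        used[pop_id[ext_post], ext_ch] = True
    S = int(used.sum(axis=1).max())
    chan_slot = np.zeros((n_pops, K), dtype=np.int8)
    pop_b = np.ones((n_pops, S))
    pop_prop = np.zeros((n_pops, S))
    pop_nslots = np.zeros(n_pops, dtype=np.int64)
    for pi in range(n_pops):
        chans = np.where(used[pi])[0]
        pop_nslots[pi] = len(chans)
        for si, c in enumerate(chans):
            chan_slot[pi, c] = si
            pop_b[pi, si] = b[c]
            pop_prop[pi, si] = prop[c]
    assert CHANNEL_TAUS[0] == P.TAU_SYN_DEFAULT
    s_slot = (chan_slot[pop_id[s_post], s_ch] if len(s_post)
              else np.empty(0, dtype=np.int8))
    ext_slot = (chan_slot[pop_id[ext_post], ext_ch] if len(ext_post)
                else np.empty(0, dtype=np.int8))

    if init_v == "random":
        V = rng.uniform(lif.v_reset, lif.v_th, size=N)
    else:
        V = np.full(N, lif.v_rest, dtype=np.float64)
    I = np.zeros((N, S))
    ring = np.zeros((D, N, S), dtype=np.float64)
    refr = np.zeros(N, dtype=np.int32)
    ref_steps = int(round(lif.tau_ref / dt))

    has_bg = drives.bg_rate is not None
    if has_bg:
        bg_rate = np.broadcast_to(
            np.asarray(drives.bg_rate, dtype=np.float64), (N,))
        bg_lam = np.ascontiguousarray(bg_rate * dt * 1e-3)
        bg_w, bg_dw = (float(x) for x in drives.bg_peak)
    else:
        bg_lam = np.zeros(1, dtype=np.float64)
        bg_w = bg_dw = 0.0
    has_const = drives.const_current is not None
    i_const = (np.ascontiguousarray(np.broadcast_to(
        np.asarray(drives.const_current, dtype=np.float64), (N,)))
        if has_const else np.zeros(1, dtype=np.float64))

    rec_idx = np.asarray(record_v, dtype=np.int64)
    v_trace = np.empty((n_steps + 1 if len(rec_idx) else 1, len(rec_idx)))
    if len(rec_idx):
        v_trace[0] = V[rec_idx]

    max_spikes = N * (n_steps // max(ref_steps, 1) + 2)
    # cap the buffer; resimulation at this density is unphysical anyway
    max_spikes = min(max_spikes, 200_000_000 // 12)
    spike_neuron_buf = np.empty(max_spikes, dtype=np.int32)
    spike_step_buf = np.empty(max_spikes, dtype=np.int64)

    n_spikes = _run_kernel(
        n_steps, N, D,
        float(a), pop_id, pop_nslots, pop_b, pop_prop, float(const_gain),
        lif.v_rest, lif.v_reset, lif.v_th, ref_steps,
        V, I, ring, refr,
        indptr, s_post, s_w, s_d, s_slot,
        has_bg, bg_lam, bg_w, bg_dw,
        has_const, i_const,
        ext_on_step, ext_indptr, ext_post, ext_w, ext_d, ext_slot, ext_lam,
        threshold_enabled, rec_idx, v_trace,
        spike_neuron_buf, spike_step_buf, kernel_seed)
    if n_spikes < 0:
        raise FloatingPointError(
            f"non-finite membrane potential at t={-n_spikes * dt:.2f} ms")

    neurons = spike_neuron_buf[:n_spikes].astype(np.int64)
    times = spike_step_buf[:n_spikes] * dt
    rec = SpikeRecord(neurons, times, N, duration,
                      manifest=graph.manifest_frame(),
                      v_trace=v_trace if len(rec_idx) else None,
                      v_trace_neurons=rec_idx)
    logger.debug("simulate: %d neurons, %.0f ms, %d spikes",
                 N, duration, len(rec))
    return rec
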