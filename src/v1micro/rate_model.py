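"""Four-population firing-rate model of the layer-2/3 microcircuit.

The superficial layer is reduced to four interacting populations — pyramidal
(e), PV (p), SST (s) and VIP (v) cells — whose firing rates follow
Wilson–Cowan-type dynamics

    tau_m * df_x/dt = -f_x + g_x(net_x),

where ``net_x`` is the net synaptic drive (applied current plus weighted
recurrent rates, pA) and the gain function is a thresholded square root,
``g_x(u) = c_x * sqrt(u - theta)`` for ``u > theta`` and 0 otherwise, fitted
to the F-I curve of the leaky integrate-and-fire neuron used in the spiking
network (c = 5.33 Hz/sqrt(pA), theta = 360 pA).

The structural sign pattern follows the known connectivity of the three
interneuron classes: PV inhibits Pyr and itself, SST inhibits everybody but
itself, VIP mainly inhibits SST.  Net drives:

    net_e = I_e + S_ee f_e - S_ep f_p - S_es f_s - S_ev f_v
    net_p = I_p + S_pe f_e - S_pp f_p - S_ps f_s
    net_s = I_s + S_se f_e - S_sv f_v
    net_v = I_v + S_ve f_e - S_vp f_p - S_vs f_s

Besides direct integration, the module enumerates steady states by active-set
decomposition (a population is either silent with subthreshold drive, or
active with f = g(net)), classifies their stability from the Jacobian, scans
an applied current over a grid to trace solution branches, and locates the
SST-silencing and VIP-activation input thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import chain, combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .params import RATE_MODEL_DEFAULTS

logger = logging.getLogger(__name__)

POPS = ("e", "p", "s", "v")

#: residual tolerance for accepting a fixed point (Hz)
FIXED_POINT_TOL = 1e-8
#: deduplication tolerance between fixed points (Hz)
DEDUP_TOL = 1e-4
#: eigenvalue real part within +/- this of 0 -> "marginal"
EIG_TOL = 1e-9
#: drive within this of theta counts as sitting on the gain kink (pA)
KINK_TOL = 1e-7


# ---------------------------------------------------------------------------
# Parameters and states
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateModelParams:
    """Coefficients of the four-population rate equations.

    Synaptic weights ``S_xy`` (pA/Hz, all non-negative; inhibitory signs are
    structural), applied currents ``I_x`` (pA), threshold ``theta`` (pA),
    membrane time constant ``tau_m`` (ms) and per-population gain
    coefficients (Hz per sqrt(pA)).
    """

    S_ee: float = RATE_MODEL_DEFAULTS["S_ee"]
    S_ep: float = RATE_MODEL_DEFAULTS["S_ep"]
    S_es: float = RATE_MODEL_DEFAULTS["S_es"]
    S_ev: float = RATE_MODEL_DEFAULTS["S_ev"]
    S_pe: float = RATE_MODEL_DEFAULTS["S_pe"]
    S_pp: float = RATE_MODEL_DEFAULTS["S_pp"]
    S_ps: float = RATE_MODEL_DEFAULTS["S_ps"]
    S_se: float = RATE_MODEL_DEFAULTS["S_se"]
    S_sv: float = RATE_MODEL_DEFAULTS["S_sv"]
    S_ve: float = RATE_MODEL_DEFAULTS["S_ve"]
    S_vp: float = RATE_MODEL_DEFAULTS["S_vp"]
    S_vs: float = RATE_MODEL_DEFAULTS["S_vs"]
    I_e: float = RATE_MODEL_DEFAULTS["I_e"]
    I_p: float = RATE_MODEL_DEFAULTS["I_p"]
    I_s: float = RATE_MODEL_DEFAULTS["I_s"]
    I_v: float = RATE_MODEL_DEFAULTS["I_v"]
    theta: float = RATE_MODEL_DEFAULTS["theta"]
    tau_m: float = RATE_MODEL_DEFAULTS["tau_m"]
    gain_coeff_e: float = RATE_MODEL_DEFAULTS["gain_coeff_e"]
    gain_coeff_p: float = RATE_MODEL_DEFAULTS["gain_coeff_p"]
    gain_coeff_s: float = RATE_MODEL_DEFAULTS["gain_coeff_s"]
    gain_coeff_v: float = RATE_MODEL_DEFAULTS["gain_coeff_v"]

    def __post_init__(self) -> None:
        for name in ("S_ee", "S_ep", "S_es", "S_ev", "S_pe", "S_pp", "S_ps",
                     "S_se", "S_sv", "S_ve", "S_vp", "S_vs"):
            if getattr(self, name) < 0:
                raise ValueError(f"synaptic weight {name} must be >= 0 "
                                 "(inhibition is applied structurally)")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        for pop in POPS:
            if getattr(self, f"gain_coeff_{pop}") <= 0:
                raise ValueError("gain coefficients must be positive")

    @property
    def gain_coeffs(self) -> np.ndarray:
        return np.array([getattr(self, f"gain_coeff_{x}") for x in POPS])

    @property
    def applied(self) -> np.ndarray:
        return np.array([getattr(self, f"I_{x}") for x in POPS])

    def with_input(self, pop: str, value: float) -> "RateModelParams":
        """Return a copy with the applied current of ``pop`` replaced."""
        if pop not in POPS:
            raise ValueError(f"unknown population {pop!r}")
        return replace(self, **{f"I_{pop}": float(value)})

    @classmethod
    def from_dict(cls, d: dict) -> "RateModelParams":
        unknown = set(d) - set(RATE_MODEL_DEFAULTS)
        if unknown:
            raise KeyError(f"unknown rate-model keys: {sorted(unknown)}")
        return cls(**{**RATE_MODEL_DEFAULTS, **d})

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in RATE_MODEL_DEFAULTS}


@dataclass(frozen=True)
class RateState:
    """Firing rates (Hz) of the four populations."""

    f_e: float = 0.0
    f_p: float = 0.0
    f_s: float = 0.0
    f_v: float = 0.0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.as_array()):
            raise ValueError("firing rates must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_e, self.f_p, self.f_s, self.f_v])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "RateState":
        return cls(*(float(x) for x in a))


@dataclass(frozen=True)
class SteadyState:
    """A fixed point: rates, active populations, stability, eigenvalues."""

    state: RateState
    active_set: frozenset
    stability: str  # stable | unstable | oscillatory | marginal
    eigenvalues: tuple = ()

    @property
    def rates(self) -> np.ndarray:
        return self.state.as_array()


@dataclass
class BranchScan:
    """Steady states along a one-parameter sweep of an applied current."""

    varied_input: str
    grid: np.ndarray
    solutions: list  # list (per grid value) of lists of SteadyState
    limit_cycle_ranges: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a table: varied_value, branch_id, f_e..f_v, stability."""
        rows = []
        for value, sols in zip(self.grid, self.solutions):
            for branch_id, ss in enumerate(sols):
                rows.append({
                    "varied_value": value, "branch_id": branch_id,
                    "f_e": ss.state.f_e, "f_p": ss.state.f_p,
                    "f_s": ss.state.f_s, "f_v": ss.state.f_v,
                    "stability": ss.stability,
                })
        return pd.DataFrame(rows, columns=["varied_value", "branch_id",
                                           "f_e", "f_p", "f_s", "f_v",
                                           "stability"])

    def max_stable_pyr(self) -> np.ndarray:
        """Per grid point, the largest stable-branch Pyr rate (NaN if none)."""
        out = np.full(len(self.grid), np.nan)
        for i, sols in enumerate(self.solutions):
            stable = [s.state.f_e for s in sols if s.stability == "stable"]
            if stable:
                out[i] = max(stable)
        return out


# ---------------------------------------------------------------------------
# Gain and dynamics
# ---------------------------------------------------------------------------


def gain(drive, coeff: float, theta: float):
    """Thresholded square-root gain: ``coeff*sqrt(drive-theta)`` above theta.

    Total and continuous; returns 0 at and below threshold.  Accepts scalars
    or arrays.
    """
    excess = np.maximum(np.asarray(drive, dtype=float) - theta, 0.0)
    out = coeff * np.sqrt(excess)
    return float(out) if np.isscalar(drive) else out


def net_drives(f: np.ndarray, p: RateModelParams) -> np.ndarray:
    """Net synaptic drive (pA) of each population given rates ``f``."""
    fe, fp, fs, fv = f
    return np.array([
        p.I_e + p.S_ee * fe - p.S_ep * fp - p.S_es * fs - p.S_ev * fv,
        p.I_p + p.S_pe * fe - p.S_pp * fp - p.S_ps * fs,
        p.I_s + p.S_se * fe - p.S_sv * fv,
        p.I_v + p.S_ve * fe - p.S_vp * fp - p.S_vs * fs,
    ])


def _gain_vec(u: np.ndarray, p: RateModelParams) -> np.ndarray:
    excess = np.maximum(u - p.theta, 0.0)
    return p.gain_coeffs * np.sqrt(excess)


def _deriv(f: np.ndarray, p: RateModelParams) -> np.ndarray:
    return (-f + _gain_vec(net_drives(f, p), p)) / p.tau_m


def rate_derivatives(state: RateState, params: RateModelParams) -> np.ndarray:
    """d/dt of the four rates (Hz/ms)."""
    return _deriv(state.as_array(), params)


def integrate_rates(params: RateModelParams, initial: RateState,
                    duration: float, dt: float = 0.05):
    """Integrate the rate equations with fixed-step RK4.

    Returns ``(times, trajectory)`` where ``trajectory`` has shape
    ``(n_steps+1, 4)``.  Raises ``FloatingPointError`` if the state becomes
    non-finite.  Rates stay non-negative from non-negative initial
    conditions because the gain is non-negative; a floor at 0 guards against
    round-off undershoot only.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    traj = np.empty((n + 1, 4))
    f = initial.as_array().astype(float)
    traj[0] = f
    for i in range(n):
        k1 = _deriv(f, params)
        k2 = _deriv(f + 0.5 * dt * k1, params)
        k3 = _deriv(f + 0.5 * dt * k2, params)
        k4 = _deriv(f + dt * k3, params)
        f = f + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                f"non-finite rate state at t={t[i + 1]:.3f} ms: {f}")
        f = np.maximum(f, 0.0)
        traj[i + 1] = f
    return t, traj


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------


def _powerset(items: Sequence[str]) -> Iterable[tuple]:
    return chain.from_iterable(combinations(items, r)
                               for r in range(len(items) + 1))


def enumerate_steady_states(params: RateModelParams, n_starts: int = 80,
                            rate_range: tuple = (0.1, 200.0),
                            seed: int = 0,
                            extra_starts: Sequence = ()) -> list:
    """Enumerate fixed points by active-set decomposition.

    For each of the 16 subsets of populations, solves ``f_x = g(net_x)`` for
    the active populations by multi-start root finding (rates sampled
    log-uniformly over ``rate_range``), keeps solutions whose silent
    populations have net drive <= theta, deduplicates, and classifies
    stability.  Completeness is relative to the multi-start grid;
    ``extra_starts`` (4-vectors of rates) warm-start every compatible
    active set, which keeps branch tracking robust near folds where basins
    shrink.
    """
    rng = np.random.default_rng(seed)
    idx = {x: i for i, x in enumerate(POPS)}
    found: list[SteadyState] = []
    n_failures = 0
    p = params
    W = np.array([  # dnet_x/df_y, structural signs
        [p.S_ee, -p.S_ep, -p.S_es, -p.S_ev],
        [p.S_pe, -p.S_pp, -p.S_ps, 0.0],
        [p.S_se, 0.0, 0.0, -p.S_sv],
        [p.S_ve, -p.S_vp, -p.S_vs, 0.0],
    ])
    coeffs = params.gain_coeffs
    applied = params.applied

    for subset in _powerset(POPS):
        active = [idx[x] for x in subset]
        silent = [i for i in range(4) if i not in active]

        if not active:
            f = np.zeros(4)
            if np.all(net_drives(f, params)[silent] <= params.theta + 1e-12):
                found.append(_classified(params, f, frozenset()))
            continue

        # substitute s_a = sqrt(net_a - theta) (so f_a = c_a s_a): the
        # active-subsystem equations become quadratic in s — smooth, no kink
        A = np.ix_(active, active)
        W_cc = W[A] * coeffs[active][None, :]
        I_act = applied[active] - params.theta

        def residual(s, W_cc=W_cc, I_act=I_act):
            return s * s - (I_act + W_cc @ s)

        def jac(s, W_cc=W_cc):
            return np.diag(2.0 * s) - W_cc

        starts = list(np.sqrt(np.exp(rng.uniform(
            np.log(rate_range[0]), np.log(rate_range[1]),
            size=(n_starts, len(active)))) / coeffs[active]))
        for warm in extra_starts:
            w = np.maximum(np.asarray(warm, dtype=float)[active], 1e-3)
            starts.append(np.sqrt(w / coeffs[active]))
        for x0 in starts:
            sol = optimize.root(residual, x0, jac=jac, method="hybr")
            if not sol.success:
                n_failures += 1
                continue
            s_a = sol.x
            if np.any(s_a <= 1e-9):
                continue  # population left the active set
            fa = coeffs[active] * s_a
            f = np.zeros(4)
            f[active] = fa
            u = net_drives(f, params)
            if np.max(np.abs(fa - _gain_vec(u, params)[active])) > FIXED_POINT_TOL:
                continue
            if silent and np.any(u[silent] > params.theta + 1e-9):
                continue  # silent population would be driven above threshold
            if any(np.max(np.abs(f - s.rates)) < DEDUP_TOL for s in found):
                continue
            found.append(_classified(params, f, frozenset(subset)))

    if n_failures:
        logger.debug("enumerate_steady_states: %d non-converged starts",
                     n_failures)
    found.sort(key=lambda s: tuple(-s.rates))
    return found


def jacobian(params: RateModelParams, f: np.ndarray) -> np.ndarray:
    """Jacobian of the rate dynamics at ``f`` (right-hand gain derivative).

    For an active population the gain slope is ``c / (2 sqrt(u - theta))``;
    for a silent population with subthreshold drive the row is pure decay.
    Populations sitting exactly on the threshold kink are handled by the
    caller (labelled marginal).
    """
    u = net_drives(f, params)
    # dnet_x/df_y with structural signs
    p = params
    W = np.array([
        [p.S_ee, -p.S_ep, -p.S_es, -p.S_ev],
        [p.S_pe, -p.S_pp, -p.S_ps, 0.0],
        [p.S_se, 0.0, 0.0, -p.S_sv],
        [p.S_ve, -p.S_vp, -p.S_vs, 0.0],
    ])
    slope = np.zeros(4)
    above = u > params.theta
    slope[above] = params.gain_coeffs[above] / (
        2.0 * np.sqrt(u[above] - params.theta))
    J = (slope[:, None] * W - np.eye(4)) / params.tau_m
    return J


def classify_stability(params: RateModelParams, ss: SteadyState,
                       confirm_cycle: bool = False):
    """Label a fixed point stable/unstable/oscillatory/marginal.

    All eigenvalue real parts negative -> stable.  A positive real part with
    a complex pair marks a candidate oscillation; with ``confirm_cycle`` the
    label "oscillatory" is only kept if integration from a nearby perturbed
    state exhibits a sustained limit cycle.  Drives sitting exactly on the
    gain kink, or eigenvalues within tolerance of the imaginary axis, give
    "marginal" — never a guess.
    """
    f = ss.rates
    u = net_drives(f, params)
    resid = np.max(np.abs(f - _gain_vec(u, params)))
    if resid > 1e-6:
        raise ValueError(f"not a fixed point (residual {resid:.2e} Hz)")
    if np.any(np.abs(u - params.theta) < KINK_TOL):
        return "marginal", ()
    eig = np.linalg.eigvals(jacobian(params, f))
    if np.any(np.abs(eig.real) < EIG_TOL):
        return "marginal", tuple(eig)
    if np.all(eig.real < 0):
        return "stable", tuple(eig)
    label = "unstable"
    if np.any((eig.real > 0) & (np.abs(eig.imag) > 0)):
        label = "oscillatory"
        if confirm_cycle:
            cyc = detect_limit_cycle(params, RateState.from_array(
                np.maximum(f + 0.5, 0.0)))
            if cyc is None:
                label = "unstable"
    return label, tuple(eig)


def _classified(params: RateModelParams, f: np.ndarray,
                active: frozenset) -> SteadyState:
    ss = SteadyState(RateState.from_array(f), active, "unknown")
    label, eig = classify_stability(params, ss)
    return SteadyState(ss.state, active, label, eig)


def detect_limit_cycle(params: RateModelParams, start: RateState,
                       duration: float = 2000.0, discard: float = 1000.0,
                       dt: float = 0.05, min_amplitude: float = 0.5):
    """Integrate and test for a sustained oscillation of the Pyr rate.

    Returns ``(min_fe, max_fe, period_ms)`` if after discarding the
    transient the Pyr rate keeps a peak-to-peak excursion above
    ``min_amplitude`` Hz with a stable inter-peak interval, else None.
    """
    _, traj = integrate_rates(params, start, duration, dt)
    fe = traj[int(discard / dt):, 0]
    if np.ptp(fe) < min_amplitude:
        return None
    # peaks of the Pyr rate
    interior = (fe[1:-1] > fe[:-2]) & (fe[1:-1] >= fe[2:])
    peaks = np.where(interior)[0] + 1
    if len(peaks) < 3:
        return None
    intervals = np.diff(peaks) * dt
    if np.std(intervals) > 0.1 * np.mean(intervals):
        return None  # no stable period
    return float(fe.min()), float(fe.max()), float(np.mean(intervals))


# ---------------------------------------------------------------------------
# Branch scans and thresholds
# ---------------------------------------------------------------------------


def scan_input(params: RateModelParams, varied: str, grid: Sequence[float],
               n_starts: int = 50, seed: int = 0,
               detect_cycles: bool = True) -> BranchScan:
    """Sweep one applied current over ``grid``, collecting steady states.

    Grid must be strictly increasing.  Per grid point the fixed points are
    enumerated and classified; contiguous runs of grid values where an
    oscillatory fixed point exists and integration confirms a sustained
    cycle are reported as ``limit_cycle_ranges``.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    solutions = []
    cycle_flags = []
    for value in grid:
        p = params.with_input(varied, value)
        try:
            sols = enumerate_steady_states(p, n_starts=n_starts, seed=seed)
        except Exception as exc:  # keep scanning on per-point failure
            logger.warning("scan point %s=%s failed: %s", varied, value, exc)
            solutions.append([])
            cycle_flags.append(False)
            continue
        solutions.append(sols)
        has_cycle = False
        if detect_cycles and any(s.stability == "oscillatory" for s in sols):
            s0 = next(s for s in sols if s.stability == "oscillatory")
            has_cycle = detect_limit_cycle(
                p, RateState.from_array(np.maximum(s0.rates + 0.5, 0))
            ) is not None
        cycle_flags.append(has_cycle)

    ranges = []
    start = None
    for i, flag in enumerate(cycle_flags):
        if flag and start is None:
            start = grid[i]
        if not flag and start is not None:
            ranges.append((start, grid[i - 1]))
            start = None
    if start is not None:
        ranges.append((start, grid[-1]))
    return BranchScan(f"I_{varied}" if len(varied) == 1 else varied,
                      grid, solutions, ranges)


def _pyr_active(params: RateModelParams, I_s: float, rate_floor: float,
                n_starts: int, seed: int, warm: Sequence = ()):
    """Stable attractor (point or cycle) keeping f_e above floor, or None."""
    p = params.with_input("s", I_s)
    sols = enumerate_steady_states(p, n_starts=n_starts, seed=seed,
                                   extra_starts=warm)
    for s in sols:
        if s.stability == "stable" and s.state.f_e > rate_floor:
            return s
    for s in sols:
        if s.stability == "oscillatory":
            cyc = detect_limit_cycle(p, RateState.from_array(
                np.maximum(s.rates + 0.5, 0.0)))
            if cyc is not None and cyc[1] > rate_floor:
                return s
    return None


def sst_silencing_threshold(params: RateModelParams, grid_step: float = 0.5,
                            scan_range: tuple = (340.0, 420.0),
                            rate_floor: float = 0.01, n_starts: int = 80,
                            seed: int = 0) -> float:
    """Smallest SST input above which no attractor keeps Pyr cells firing.

    Scans I_s over ``scan_range`` coarsely, then bisects the last
    active->silent transition down to ``grid_step`` (<= 1 pA).  The
    Pyr-active branch found at each step warm-starts the next solve, so the
    branch is tracked reliably up to its fold.  Raises if Pyr-active
    attractors persist over the whole range.
    """
    if grid_step > 1.0:
        raise ValueError("grid step must be <= 1 pA")
    lo, hi = scan_range
    coarse = np.arange(lo, hi + 1e-9, 5.0)
    warm: list = []
    states = []
    for v in coarse:
        s = _pyr_active(params, v, rate_floor, n_starts, seed, warm)
        states.append(s)
        if s is not None:
            warm = [s.rates]
    if states[-1] is not None:
        raise RuntimeError("threshold not in range: Pyr-active attractors "
                           f"persist up to I_s={hi} pA")
    if not any(s is not None for s in states):
        return float(lo)
    i_last = max(i for i, s in enumerate(states) if s is not None)
    a, b = float(coarse[i_last]), float(coarse[i_last] + 5.0)
    warm = [states[i_last].rates]
    while b - a > grid_step:
        mid = 0.5 * (a + b)
        s = _pyr_active(params, mid, rate_floor, n_starts, seed, warm)
        if s is not None:
            a = mid
            warm = [s.rates]
        else:
            b = mid
    return b


def vip_activation_threshold(params: RateModelParams) -> float:
    """Minimum VIP input that yields a positive VIP rate with all other
    populations silent.

    With f_e = f_p = f_s = 0 the VIP net drive is I_v alone, so the rate
    g(I_v - theta) turns positive exactly at theta.
    """
    assert gain(params.theta, params.gain_coeff_v, params.theta) == 0.0
    return float(params.theta)
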