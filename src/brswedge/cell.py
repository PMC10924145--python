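"""Single-cell simulation protocols and action-potential feature extraction.

The ionic model lives in :mod:`brswedge.ord`; this module drives it: pacing
to a limit cycle, recording AP traces, measuring APD at arbitrary
repolarization levels, classifying spike-and-dome vs. dome-less morphology,
and scanning G_to multipliers for the loss-of-dome bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import ord as _ord
from .ord import N_STATES, initial_state, step_cells


@dataclass(frozen=True)
class ChannelScales:
    """Multiplicative scaling of maximal conductances (defaults 1.0)."""
    gto: float = 1.0
    gks: float = 1.0
    gna: float = 1.0

    def __post_init__(self):
        for name in ("gto", "gks", "gna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} scale must be >= 0")


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic stimulation protocol.

    ``ode_dt`` is in microseconds (<= 50); everything else in ms / uA/uF.
    The default stimulus (-80 uA/uF for 0.5 ms) is strong, brief and
    supra-threshold.
    """
    cycle_length: float = 800.0
    n_beats: int = 1
    stim_amplitude: float = -80.0
    stim_duration: float = 0.5
    ode_dt: float = 50.0

    def __post_init__(self):
        if self.ode_dt > 50.0 or self.ode_dt <= 0:
            raise ValueError("ode_dt must be in (0, 50] microseconds")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")

    @property
    def dt_ms(self) -> float:
        return self.ode_dt * 1e-3


@dataclass
class APTrace:
    """Sampled transmembrane-voltage time course (one or more beats)."""
    time: np.ndarray  # ms, strictly increasing
    v: np.ndarray     # mV

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.time.shape != self.v.shape:
            raise ValueError("time and v must have matching shapes")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class APFeatures:
    apd90: float
    peak_v: float
    resting_v: float
    amplitude: float
    has_dome: bool


@njit(cache=True)
def _integrate(Y, epi, gto, gks, gna, passive, ina_tt, dt, n_steps,
               stim_amp, stim_steps, record_every, vout):
    """Run ``n_steps`` with a stimulus on the first ``stim_steps`` steps.

    If ``record_every > 0``, voltage of every cell is written to ``vout``
    (shape: n_samples x n_cells) every ``record_every`` steps, starting with
    the pre-step state.
    """
    n = Y.shape[0]
    istim = np.zeros(n)
    isample = 0
    for k in range(n_steps):
        if record_every > 0 and k % record_every == 0:
            for c in range(n):
                vout[isample, c] = Y[c, 0]
            isample += 1
        amp = stim_amp if k < stim_steps else 0.0
        for c in range(n):
            istim[c] = amp
        step_cells(Y, epi, gto, gks, gna, passive, istim, dt, ina_tt)
    return isample


def _as_param_arrays(n, epi, scales):
    epi_arr = np.full(n, bool(epi))
    gto = np.full(n, float(scales.gto))
    gks = np.full(n, float(scales.gks))
    gna = np.full(n, float(scales.gna))
    passive = np.zeros(n, dtype=np.bool_)
    return epi_arr, gto, gks, gna, passive


def step_cell(state, dt_us, epi=True, scales=ChannelScales(), i_stim=0.0,
              ina_tt=False):
    """Advance a single cell state by one step of ``dt_us`` microseconds."""
    if dt_us > 50.0:
        raise ValueError("dt must be <= 50 us")
    y = np.array(state, dtype=float).reshape(1, N_STATES)
    epi_a, gto, gks, gna, passive = _as_param_arrays(1, epi, scales)
    step_cells(y, epi_a, gto, gks, gna, passive,
               np.array([float(i_stim)]), dt_us * 1e-3, ina_tt)
    if abs(y[0, 0]) > 200.0:
        raise RuntimeError("integration unstable: |V| > 200 mV after step")
    return y[0]


def pace_batch(epi, scales_list, protocol=PacingProtocol(), tol=1e-3,
               max_beats=600, ina_tt=False, initial=None):
    """Pace a batch of cells with (possibly different) conductance scalings
    to their steady-state limit cycle.

    Convergence: relative max-norm of the state change between the diastolic
    points (beat onsets) of consecutive beats below ``tol`` for every cell.

    Returns (states, info) where ``states`` is (n_cells, 41) end-diastolic
    and ``info`` carries beats used, final per-cell distance and a converged
    flag per cell.
    """
    n = len(scales_list)
    epi_arr = np.asarray(epi, dtype=np.bool_)
    if epi_arr.shape == ():
        epi_arr = np.full(n, bool(epi))
    gto = np.array([s.gto for s in scales_list])
    gks = np.array([s.gks for s in scales_list])
    gna = np.array([s.gna for s in scales_list])
    passive = np.zeros(n, dtype=np.bool_)
    if initial is None:
        Y = np.tile(initial_state(), (n, 1))
    else:
        Y = np.array(initial, dtype=float).reshape(n, N_STATES).copy()

    dt = protocol.dt_ms
    steps = int(round(protocol.cycle_length / dt))
    stim_steps = int(round(protocol.stim_duration / dt))
    dummy = np.empty((1, n))

    delta = np.full(n, np.inf)
    beats = 0
    if np.isinf(tol):
        _integrate(Y, epi_arr, gto, gks, gna, passive, ina_tt, dt, steps,
                   protocol.stim_amplitude, stim_steps, 0, dummy)
        return Y, {"beats": 1, "delta": delta, "converged": np.ones(n, bool)}
    while beats < max_beats:
        prev = Y.copy()
        _integrate(Y, epi_arr, gto, gks, gna, passive, ina_tt, dt, steps,
                   protocol.stim_amplitude, stim_steps, 0, dummy)
        beats += 1
        delta = np.max(np.abs(Y - prev) / (np.abs(prev) + 1e-4), axis=1)
        if np.all(delta < tol):
            break
    converged = delta < tol
    return Y, {"beats": beats, "delta": delta, "converged": converged}


_STEADY_CACHE: dict = {}


def steady_states_batch(entries, protocol=PacingProtocol(), tol=1e-3,
                        max_beats=600, ina_tt=False):
    """Memoized steady states for a list of (epi, ChannelScales) entries.

    Uncached entries are paced together in one batch; results are cached
    per parameter set for reuse across scenarios.
    """
    def key_of(epi, sc):
        return (bool(epi), sc.gto, sc.gks, sc.gna, protocol.cycle_length,
                protocol.stim_amplitude, protocol.stim_duration,
                protocol.ode_dt, tol, max_beats, ina_tt)

    keys = [key_of(e, s) for e, s in entries]
    missing = [i for i, k in enumerate(keys) if k not in _STEADY_CACHE]
    info = {"beats": 0, "converged": True}
    if missing:
        Y, binfo = pace_batch(np.array([entries[i][0] for i in missing]),
                              [entries[i][1] for i in missing], protocol,
                              tol=tol, max_beats=max_beats, ina_tt=ina_tt)
        for j, i in enumerate(missing):
            _STEADY_CACHE[keys[i]] = (
                Y[j].copy(), {"beats": binfo["beats"],
                              "converged": bool(binfo["converged"][j])})
        info["beats"] = binfo["beats"]
        info["converged"] = bool(np.all(binfo["converged"]))
    states = np.stack([_STEADY_CACHE[k][0] for k in keys])
    return states, info


def steady_state(epi=True, scales=ChannelScales(), protocol=PacingProtocol(),
                 tol=1e-3, max_beats=600, ina_tt=False):
    """Memoized single-cell steady state for one parameter set."""
    states, _ = steady_states_batch([(epi, scales)], protocol, tol,
                                    max_beats, ina_tt)
    key = (bool(epi), scales.gto, scales.gks, scales.gna,
           protocol.cycle_length, protocol.stim_amplitude,
           protocol.stim_duration, protocol.ode_dt, tol, max_beats, ina_tt)
    return states[0], _STEADY_CACHE[key][1]


def pace_to_steady(epi=True, scales=ChannelScales(),
                   protocol=PacingProtocol(), tol=1e-3, max_beats=600,
                   ina_tt=False):
    """Limit-cycle end-diastolic state for one cell (see ``pace_batch``)."""
    y, info = steady_state(epi, scales, protocol, tol, max_beats, ina_tt)
    return y, info


def record_beat(states, epi, scales_list, protocol=PacingProtocol(),
                sample_ms=0.25, ina_tt=False):
    """Simulate one paced beat from given states, recording all voltages.

    Returns (times, V) with V of shape (n_samples, n_cells); ``states`` is
    advanced in place to the end of the beat.
    """
    n = states.shape[0]
    epi_arr = np.asarray(epi, dtype=np.bool_)
    if epi_arr.shape == ():
        epi_arr = np.full(n, bool(epi))
    gto = np.array([s.gto for s in scales_list])
    gks = np.array([s.gks for s in scales_list])
    gna = np.array([s.gna for s in scales_list])
    passive = np.zeros(n, dtype=np.bool_)
    dt = protocol.dt_ms
    steps = int(round(protocol.cycle_length / dt))
    stim_steps = int(round(protocol.stim_duration / dt))
    rec_every = max(1, int(round(sample_ms / dt)))
    n_samp = (steps + rec_every - 1) // rec_every
    vout = np.empty((n_samp, n))
    _integrate(states, epi_arr, gto, gks, gna, passive, ina_tt, dt, steps,
               protocol.stim_amplitude, stim_steps, rec_every, vout)
    times = np.arange(n_samp) * rec_every * dt
    return times, vout


def steady_trace(epi=True, scales=ChannelScales(),
                 protocol=PacingProtocol(), sample_ms=0.25, tol=1e-3,
                 max_beats=600, ina_tt=False) -> APTrace:
    """AP trace of the steady-state beat for one parameter set."""
    y, _ = steady_state(epi, scales, protocol, tol, max_beats, ina_tt)
    t, V = record_beat(y.reshape(1, -1).copy(), epi, [scales], protocol,
                       sample_ms, ina_tt)
    return APTrace(t, V[:, 0])


def _upstroke_anchor(trace: APTrace):
    """Index of maximum dV/dt (upstroke anchor); error if no upstroke."""
    dv = np.diff(trace.v) / np.diff(trace.time)
    k = int(np.argmax(dv))
    if dv[k] < 10.0:
        raise ValueError("trace has no upstroke (max dV/dt < 10 mV/ms)")
    return k, dv


def apd(trace: APTrace, level: float = 90.0) -> float:
    """Action-potential duration at ``level``% repolarization.

    Measured from the time of maximum upstroke dV/dt to the downward
    crossing of ``resting_v + (1 - level/100) * amplitude``, with linear
    interpolation between samples.  Amplitude is resting-to-peak.
    """
    if not (0.0 < level < 100.0):
        raise ValueError("level must be in (0, 100)")
    k, _ = _upstroke_anchor(trace)
    t_up = trace.time[k]
    resting = trace.v[0]
    peak = float(np.max(trace.v[k:]))
    thr = resting + (1.0 - level / 100.0) * (peak - resting)
    ipk = k + int(np.argmax(trace.v[k:]))
    below = np.flatnonzero(trace.v[ipk:] <= thr)
    if below.size == 0:
        raise ValueError("AP does not repolarize to requested level")
    i = ipk + below[0]
    if i == 0:
        return 0.0
    v0, v1 = trace.v[i - 1], trace.v[i]
    t0, t1 = trace.time[i - 1], trace.time[i]
    t_cross = t0 + (thr - v0) / (v1 - v0) * (t1 - t0) if v1 != v0 else t1
    return float(t_cross - t_up)


def detect_dome(trace: APTrace, rebound_mv: float = 5.0,
                plateau_mv: float = 0.0, plateau_ms: float = 50.0) -> bool:
    """True iff the AP keeps (or regains) its dome after the phase-1 notch.

    After the earliest local minimum following the upstroke peak the voltage
    must either rise again by >= ``rebound_mv`` or remain above
    ``plateau_mv`` for >= ``plateau_ms``.
    """
    k, _ = _upstroke_anchor(trace)
    v = trace.v
    t = trace.time
    # upstroke peak: first local maximum at/after the anchor
    ipk = None
    for i in range(max(k, 1), len(v) - 1):
        if v[i] >= v[i - 1] and v[i] >= v[i + 1]:
            ipk = i
            break
    if ipk is None:
        ipk = int(np.argmax(v[k:])) + k
    # earliest local minimum after the peak
    imin = None
    for i in range(ipk + 1, len(v) - 1):
        if v[i] <= v[i - 1] and v[i] < v[i + 1]:
            imin = i
            break
    if imin is None:
        return False  # monotone decay: no notch, no dome
    if np.max(v[imin:]) - v[imin] >= rebound_mv:
        return True
    j = imin
    while j < len(v) and v[j] > plateau_mv:
        j += 1
    if j > imin and (t[min(j, len(t) - 1)] - t[imin]) >= plateau_ms:
        return True
    return False


def features(trace: APTrace, cycle_length: float | None = None) -> APFeatures:
    """Summary AP features of a single-beat trace."""
    k, _ = _upstroke_anchor(trace)
    resting = float(trace.v[0])
    peak = float(np.max(trace.v[k:]))
    a90 = apd(trace, 90.0)
    return APFeatures(apd90=a90, peak_v=peak, resting_v=resting,
                      amplitude=peak - resting, has_dome=detect_dome(trace))


def gto_collapse_threshold(epi=True, fold_values=tuple(range(1, 21)),
                           protocol=PacingProtocol(), tol=1e-3,
                           max_beats=600, ina_tt=False):
    """Loss-of-dome bifurcation scan over G_to multipliers.

    Each fold is paced to its own steady state (all folds in one batch);
    dome presence and APD90 are measured on the steady-state beat.

    Returns (threshold_fold_or_None, table) where table is a list of dicts
    with keys fold, apd90_ms, has_dome.
    """
    folds = list(fold_values)
    if 1 not in folds:
        raise ValueError("fold_values must include 1 (baseline)")
    if sorted(folds) != folds:
        raise ValueError("fold_values must be ascending")
    scales = [ChannelScales(gto=f) for f in folds]
    Y, info = pace_batch(epi, scales, protocol, tol=tol,
                         max_beats=max_beats, ina_tt=ina_tt)
    t, V = record_beat(Y, epi, scales, protocol, sample_ms=0.25,
                       ina_tt=ina_tt)
    table = []
    threshold = None
    for j, f in enumerate(folds):
        tr = APTrace(t, V[:, j])
        dome = detect_dome(tr)
        table.append({"fold": f, "apd90_ms": apd(tr, 90.0),
                      "has_dome": dome})
        if threshold is None and not dome:
            threshold = f
    return threshold, table
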