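"""Ionic-model unit tests: current scaling, integrator consistency,
AP feature extraction and the loss-of-dome classifier."""

import numpy as np
import pytest

from brswedge import ord as ordm
from brswedge.cell import (APTrace, ChannelScales, PacingProtocol, apd,
                           detect_dome, features, pace_batch, record_beat,
                           steady_state, step_cell)
from brswedge.ord import derivatives, initial_state


def test_resting_steady_state_is_fixed_point(epi_trace):
    """After steady pacing, the end-diastolic state barely moves."""
    y, info = steady_state(True, ChannelScales(), PacingProtocol())
    dydt, _ = derivatives(y, epi=True)
    assert info["converged"]
    assert abs(dydt[ordm.IV]) < 1e-3  # mV/ms


def test_gto_scale_zero_silences_ito():
    y = initial_state()
    y[ordm.IV] = 0.0  # depolarized: Ito would flow if conducting
    y[ordm.IA] = 0.5
    y[ordm.IIF] = y[ordm.IIS] = 0.8
    _, cur = derivatives(y, epi=True, scales=(0.0, 1.0, 1.0))
    assert cur["Ito"] == 0.0


def test_epi_ito_exceeds_endo_at_identical_state():
    """The epicardial variant carries a 4-fold larger I_to conductance."""
    y = initial_state()
    y[ordm.IV] = 20.0
    y[ordm.IA] = 0.6
    y[ordm.IIF] = y[ordm.IIS] = 0.7
    _, epi_cur = derivatives(y, epi=True)
    _, endo_cur = derivatives(y, epi=False)
    assert epi_cur["Ito"] > endo_cur["Ito"] > 0
    # identical gating state: the ratio is the conductance ratio times the
    # epi inactivation-shift factor; it must exceed the raw 4-fold scaling
    # divided by any kinetic factor (which does not apply at fixed state)
    assert epi_cur["Ito"] == pytest.approx(4.0 * endo_cur["Ito"])


def test_nonfinite_state_rejected_with_variable_name():
    y = initial_state()
    y[ordm.ICAI] = np.nan
    with pytest.raises(ValueError, match="cai"):
        derivatives(y, epi=True)


def test_step_halving_self_consistency():
    """Two 25 us steps track one 50 us step within 0.1 mV at diastole."""
    y, _ = steady_state(True, ChannelScales(), PacingProtocol())
    a = step_cell(y, 50.0)
    b = step_cell(step_cell(y, 25.0), 25.0)
    assert abs(a[ordm.IV] - b[ordm.IV]) < 0.1


def test_rest_is_quiescent_without_stimulus():
    """Unstimulated cell: < 0.5 mV drift over 10 s from the paced
    diastolic state, and once relaxed, < 1e-3 mV over a further 50 ms."""
    from brswedge.cell import _as_param_arrays, _integrate
    y, _ = steady_state(True, ChannelScales(), PacingProtocol())
    Y = y.reshape(1, -1).copy()
    epi, gto, gks, gna, passive = _as_param_arrays(1, True, ChannelScales())
    dummy = np.empty((1, 1))
    v0 = Y[0, ordm.IV]
    _integrate(Y, epi, gto, gks, gna, passive, False, 0.05, 200_000,
               0.0, 0, 0, dummy)
    assert abs(Y[0, ordm.IV] - v0) < 0.5
    v1 = Y[0, ordm.IV]
    _integrate(Y, epi, gto, gks, gna, passive, False, 0.05, 1000,
               0.0, 0, 0, dummy)
    assert abs(Y[0, ordm.IV] - v1) < 1e-3


def test_suprathreshold_stimulus_fires_upstroke():
    y, _ = steady_state(True, ChannelScales(), PacingProtocol())
    Y = y.reshape(1, -1).copy()
    t, V = record_beat(Y, True, [ChannelScales()],
                       PacingProtocol(cycle_length=50.0), sample_ms=0.05)
    dvdt = np.diff(V[:, 0]) / np.diff(t)
    assert dvdt.max() > 100.0


def test_gate_bounds_and_concentration_positivity(epi_trace):
    y, _ = steady_state(True, ChannelScales(gto=14.0), PacingProtocol())
    gates = y[ordm.GATE_MASK]
    assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
    conc = y[[ordm.INAI, ordm.INASS, ordm.IKI, ordm.IKSS, ordm.ICAI,
              ordm.ICASS, ordm.ICANSR, ordm.ICAJSR]]
    assert np.all(conc > 0.0)


def test_apd_on_synthetic_trapezoid_is_analytic():
    """Trapezoid AP: rest -85, instantaneous upstroke to +35 at t=10 ms,
    plateau to t=50, linear 200 ms ramp back to rest; APD90 has a closed
    form: crossing of -73 mV at t=230 ms, upstroke anchor at t=10."""
    t = np.arange(0.0, 300.0, 0.1)
    v = np.interp(t, [0, 10, 11, 50, 250, 300], [-85, -85, 35, 35, -85, -85])
    tr = APTrace(t, v)
    assert apd(tr, 90.0) == pytest.approx(220.0, abs=0.3)
    assert apd(tr, 50.0) < apd(tr, 90.0)


def test_apd_requires_repolarization():
    t = np.arange(0.0, 100.0, 0.5)
    v = np.interp(t, [0, 10, 11, 100], [-85, -85, 35, 30])
    with pytest.raises(ValueError, match="repolarize"):
        apd(APTrace(t, v), 90.0)


def test_dome_detection_baseline_vs_spiky(epi_trace):
    assert detect_dome(epi_trace)
    from brswedge.cell import steady_trace
    spiky = steady_trace(True, ChannelScales(gto=20.0), PacingProtocol())
    assert not detect_dome(spiky)


def test_dome_rejects_monotone_triangular_decay():
    t = np.arange(0.0, 120.0, 0.25)
    v = np.interp(t, [0, 10, 10.5, 18, 120], [-85, -85, 40, -20, -85])
    assert not detect_dome(APTrace(t, v))


def test_apd90_monotone_in_gks():
    prot = PacingProtocol()
    scales = [ChannelScales(gks=g) for g in (1.0, 1.5, 2.0, 2.5, 3.0)]
    Y, _ = pace_batch(True, scales, prot, max_beats=600)
    t, V = record_beat(Y, True, scales, prot)
    apds = [apd(APTrace(t, V[:, j]), 90.0) for j in range(len(scales))]
    assert np.all(np.diff(apds) < 0.0)


def test_gna_half_lowers_upstroke_velocity_and_amplitude():
    prot = PacingProtocol()
    scales = [ChannelScales(), ChannelScales(gna=0.5)]
    Y, _ = pace_batch(True, scales, prot, max_beats=600)
    t, V = record_beat(Y, True, scales, prot, sample_ms=0.05)
    dv = np.diff(V, axis=0) / np.diff(t)[:, None]
    assert dv[:, 1].max() < dv[:, 0].max()
    f0 = features(APTrace(t, V[:, 0]))
    f1 = features(APTrace(t, V[:, 1]))
    assert f1.amplitude < f0.amplitude


def test_apd90_insensitive_to_ode_step_halving():
    """APD90 of the post-steady beat changes < 1 ms for dt 50 -> 25 us."""
    y, _ = steady_state(True, ChannelScales(), PacingProtocol())
    out = {}
    for dt in (50.0, 25.0):
        prot = PacingProtocol(ode_dt=dt)
        t, V = record_beat(y.reshape(1, -1).copy(), True,
                           [ChannelScales()], prot, sample_ms=0.25)
        out[dt] = apd(APTrace(t, V[:, 0]), 90.0)
    assert abs(out[50.0] - out[25.0]) < 1.0


def test_pacing_with_infinite_tolerance_returns_after_one_beat():
    Y, info = pace_batch(True, [ChannelScales()], PacingProtocol(),
                         tol=np.inf)
    assert info["beats"] == 1


def test_instability_guard_rejects_large_dt():
    with pytest.raises(ValueError):
        step_cell(initial_state(), 100.0)
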