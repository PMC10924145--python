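"""Anisotropic monodomain reaction–diffusion solver (linear FEM).

The monodomain equation

    beta * Cm * dVm/dt = div(sigma grad Vm) - beta * Iion + beta * Istim

is discretized with linear simplicial finite elements (consistent mass
matrix by default) and integrated with the Crank–Nicolson scheme, operator-
split against the ionic model at a shared time step (Godunov splitting:
ionic step, then diffusion step).  With Vm in mV, t in ms, coordinates in
mm, sigma in S/m, beta in 1/m and Cm in uF/cm^2, the diffusion coefficient
sigma/(beta*Cm) enters in mm^2/ms as 1e5 * sigma / (beta * cm).

Stimuli are transmembrane current densities (uA/uF) applied to node sets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import ord as _ord
from .cell import (ChannelScales, PacingProtocol, pace_batch,
                   steady_states_batch)
from .geometry import ConductivityField, Mesh


@dataclass
class SolverConfig:
    """Monodomain solver parameters.

    ``dt``: shared ODE/PDE step in microseconds.  ``beta``: surface-to-
    volume ratio (1/m).  ``cm``: specific membrane capacitance (uF/cm^2).
    ``ina_tt``: use the conduction-calibrated I_Na variant in tissue.
    """
    dt: float = 50.0
    theta: float = 0.5
    beta: float = 140000.0
    cm: float = 1.0
    linear_tol: float = 1e-8
    mass_lumping: bool = False
    ina_tt: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.5 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0.5, 1]")
        if self.beta <= 0 or self.cm <= 0:
            raise ValueError("beta and cm must be positive")

    @property
    def dt_ms(self) -> float:
        return self.dt * 1e-3

    @property
    def diff_scale(self) -> float:
        """sigma (S/m) -> diffusivity (mm^2/ms) conversion factor."""
        return 1.0e5 / (self.beta * self.cm)


def _element_gradients(mesh: Mesh):
    """Per-element shape-function gradients and measures.

    Returns (grads, vols): grads has shape (n_cells, d+1, d), vols the
    element measures; raises on singular element Jacobians.
    """
    X = mesh.points[mesh.cells]          # (m, d+1, d)
    d = mesh.dim
    E = np.swapaxes(X[:, 1:, :] - X[:, :1, :], 1, 2)   # (m, d, d) columns
    det = np.linalg.det(E) if d > 1 else E[:, 0, 0]
    bad = np.flatnonzero(np.abs(det) < 1e-14)
    if bad.size:
        raise ValueError(f"singular element Jacobian in element {bad[0]}")
    from math import factorial
    vols = np.abs(det) / factorial(d)
    Einv = np.linalg.inv(E) if d > 1 else 1.0 / E
    # barycentric coordinates: lambda_i(x) = (E^{-1} (x - x_0))_i, so the
    # gradient of shape function i (i = 1..d) is row i of E^{-1};
    # node 0 gradient = -sum(others)
    g_rest = Einv                                     # (m, d, d) rows
    g0 = -g_rest.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g_rest], axis=1)      # (m, d+1, d)
    return grads, vols


def conductivity_tensors(fibers: np.ndarray, cond: ConductivityField):
    """Per-element sigma = sigma_t I + (sigma_l - sigma_t) f f^T."""
    m, d = fibers.shape
    eye = np.eye(d)[None, :, :]
    ff = fibers[:, :, None] * fibers[:, None, :]
    return cond.sigma_t[:, None, None] * eye \
        + (cond.sigma_l - cond.sigma_t)[:, None, None] * ff


def assemble_tensor_stiffness(mesh: Mesh, sigma_elem: np.ndarray):
    """Stiffness matrix from per-element conductivity tensors
    (``sigma_elem``: (m, d, d)) and the element measures used."""
    grads, vols = _element_gradients(mesh)
    d = mesh.dim
    nn = mesh.n_nodes
    Ke = np.einsum("mad,mde,mbe,m->mab", grads, sigma_elem, grads, vols)
    rows = np.repeat(mesh.cells, d + 1, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, d + 1)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(nn, nn)).tocsr()
    return K, vols


def isotropic_stiffness(mesh: Mesh, sigma: np.ndarray):
    """Stiffness matrix for per-element isotropic conductivity."""
    m, d = len(mesh.cells), mesh.dim
    sig = np.asarray(sigma)[:, None, None] * np.eye(d)[None, :, :]
    K, _ = assemble_tensor_stiffness(mesh, sig)
    return K


class FEMSystem:
    """Assembled mass/stiffness matrices and the factorized CN operator."""

    def __init__(self, mesh: Mesh, fibers: np.ndarray,
                 cond: ConductivityField, config: SolverConfig):
        self.mesh = mesh
        self.config = config
        d = mesh.dim
        nn = mesh.n_nodes
        sig = conductivity_tensors(fibers, cond)
        self.K, vols = assemble_tensor_stiffness(mesh, sig)
        # consistent mass: vol/((d+1)(d+2)) * (1 + delta_ab)
        mloc = (np.ones((d + 1, d + 1)) + np.eye(d + 1)) / ((d + 1) * (d + 2))
        Me = vols[:, None, None] * mloc[None, :, :]
        rows = np.repeat(mesh.cells, d + 1, axis=1).ravel()
        cols = np.tile(mesh.cells, (1, d + 1)).ravel()
        M = sp.coo_matrix((Me.ravel(), (rows, cols)),
                          shape=(nn, nn)).tocsr()
        if config.mass_lumping:
            M = sp.diags(np.asarray(M.sum(axis=1)).ravel())
        self.M = M.tocsr()
        alpha = config.dt_ms * config.diff_scale
        th = config.theta
        self.A = (self.M + th * alpha * self.K).tocsc()
        self.B = (self.M - (1.0 - th) * alpha * self.K).tocsr()
        self._lu = splu(self.A)
        self.total_volume = float(vols.sum())

    def cn_step(self, vm: np.ndarray) -> np.ndarray:
        """One Crank–Nicolson diffusion step."""
        rhs = self.B @ vm
        out = self._lu.solve(rhs)
        res = np.linalg.norm(self.A @ out - rhs)
        scale = np.linalg.norm(rhs)
        if scale > 0 and res > self.config.linear_tol * max(scale, 1.0) * 1e3:
            raise RuntimeError(f"CN solve residual {res:.2e} too large")
        return out


@dataclass
class Stimulus:
    nodes: np.ndarray
    onset: float = 10.0       # ms within each cycle
    duration: float = 1.0     # ms
    amplitude: float = -80.0  # uA/uF

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        if self.nodes.size == 0:
            raise ValueError("stimulus node set is empty")


@dataclass
class StimulusProtocol:
    stimuli: list
    cycle_length: float = 800.0
    n_beats: int = 3

    def __post_init__(self):
        for s in self.stimuli:
            if s.onset < 0 or s.onset + s.duration > self.cycle_length:
                raise ValueError("stimulus window outside the cycle")


@dataclass
class TissueCellFields:
    """Per-node membrane parameters for the coupled simulation."""
    epi: np.ndarray                  # bool, epicardial variant
    gto: np.ndarray
    gks: np.ndarray
    gna: np.ndarray
    passive: np.ndarray              # bool, ablated (leak membrane)

    @classmethod
    def uniform(cls, n, epi=True, scales=ChannelScales()):
        return cls(np.full(n, bool(epi)), np.full(n, scales.gto),
                   np.full(n, scales.gks), np.full(n, scales.gna),
                   np.zeros(n, dtype=bool))

    def params_matrix(self):
        return np.column_stack([self.epi.astype(float), self.gto,
                                self.gks, self.gna,
                                self.passive.astype(float)])


@dataclass
class VmHistory:
    """Node x time voltage history of the result beat, 1 ms sampling."""
    times: np.ndarray     # ms from result-beat onset
    vm: np.ndarray        # (n_times, n_nodes), mV
    meta: dict = field(default_factory=dict)

    @property
    def node_hash(self) -> str:
        return self.meta.get("node_hash", "")


def mesh_node_hash(mesh: Mesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.points).tobytes())
    return h.hexdigest()[:16]


def init_states_by_cluster(fields: TissueCellFields, similarity=0.10,
                           protocol=PacingProtocol(), tol=1e-3,
                           max_beats=600, ina_tt=True):
    """Steady-state initial states via parameter clustering.

    Nodes are grouped so members of a cluster differ by less than
    ``similarity`` (relative) in every continuous parameter (geometric
    binning, bin width log(1+similarity)); one steady-state pacing run per
    cluster representative (the member mean), broadcast to all members.
    Passive nodes form their own cluster and start at the leak reversal.
    """
    n = len(fields.epi)

    def binkey(x):
        if x <= 0:
            return -10**9
        return int(np.floor(np.log(x) / np.log(1.0 + similarity) + 1e-12))

    keys = {}
    assign = np.empty(n, dtype=np.int64)
    for i in range(n):
        if fields.passive[i]:
            key = ("passive",)
        else:
            key = (bool(fields.epi[i]), binkey(fields.gto[i]),
                   binkey(fields.gks[i]), binkey(fields.gna[i]))
        assign[i] = keys.setdefault(key, len(keys))
    n_clusters = len(keys)
    reps = []
    rep_epi = []
    for key, c in keys.items():
        members = np.flatnonzero(assign == c)
        if key == ("passive",):
            reps.append(None)
            rep_epi.append(True)
            continue
        reps.append(ChannelScales(gto=float(fields.gto[members].mean()),
                                  gks=float(fields.gks[members].mean()),
                                  gna=float(fields.gna[members].mean())))
        rep_epi.append(bool(fields.epi[members[0]]))
    active = [c for c in range(n_clusters) if reps[c] is not None]
    states = np.tile(_ord.initial_state(), (n_clusters, 1))
    info = {"n_clusters": n_clusters, "beats": 0}
    if active:
        Y, pinfo = steady_states_batch(
            [(rep_epi[c], reps[c]) for c in active], protocol,
            tol=tol, max_beats=max_beats, ina_tt=ina_tt)
        for j, c in enumerate(active):
            states[c] = Y[j]
        info["beats"] = pinfo["beats"]
        info["converged"] = pinfo["converged"]
    for c in range(n_clusters):
        if reps[c] is None:
            states[c, _ord.IV] = _ord.E_PASSIVE
    out = states[assign]
    return out, assign, info


def run_simulation(mesh: Mesh, fields: TissueCellFields, system: FEMSystem,
                   protocol: StimulusProtocol,
                   initial_states: np.ndarray | None = None,
                   sample_ms: float = 1.0, record_beats="last",
                   init_kwargs=None):
    """Operator-split monodomain run over the beat schedule.

    Returns a :class:`VmHistory` of the result (last) beat, sampled every
    ``sample_ms``.  ``record_beats='all'`` records the full schedule.
    """
    cfg = system.config
    n = mesh.n_nodes
    if initial_states is None:
        initial_states, _, _ = init_states_by_cluster(
            fields, protocol=PacingProtocol(
                cycle_length=protocol.cycle_length),
            ina_tt=cfg.ina_tt, **(init_kwargs or {}))
    Y = np.ascontiguousarray(initial_states, dtype=float)
    if Y.shape != (n, _ord.N_STATES):
        raise ValueError("initial states misaligned with mesh")
    dt = cfg.dt_ms
    steps_per_beat = int(round(protocol.cycle_length / dt))
    rec_every = max(1, int(round(sample_ms / dt)))
    record_from = 0 if record_beats == "all" else protocol.n_beats - 1

    istim = np.zeros(n)
    windows = []
    for s in protocol.stimuli:
        k0 = int(round(s.onset / dt))
        k1 = k0 + max(1, int(round(s.duration / dt)))
        windows.append((s.nodes, k0, k1, s.amplitude))

    times = []
    frames = []
    for beat in range(protocol.n_beats):
        for k in range(steps_per_beat):
            if beat >= record_from and k % rec_every == 0:
                t_in_beat = k * dt + (beat - record_from) \
                    * protocol.cycle_length
                v = Y[:, _ord.IV]
                if not np.all(np.abs(v) < 200.0):
                    nid = int(np.argmax(np.abs(v)))
                    raise RuntimeError(
                        f"instability at beat {beat} t={k * dt:.2f} ms "
                        f"node {nid}: V={v[nid]:.1f} mV")
                times.append(t_in_beat)
                frames.append(v.copy())
            istim[:] = 0.0
            for nodes, k0, k1, amp in windows:
                if k0 <= k < k1:
                    istim[nodes] = amp
            _ord.step_cells(Y, fields.epi, fields.gto, fields.gks,
                            fields.gna, fields.passive, istim, dt,
                            cfg.ina_tt)
            Y[:, _ord.IV] = system.cn_step(Y[:, _ord.IV])
    hist = VmHistory(np.array(times), np.array(frames),
                     meta={"cycle_length": protocol.cycle_length,
                           "n_beats": protocol.n_beats,
                           "node_hash": mesh_node_hash(mesh),
                           "dt_us": cfg.dt, "sample_ms": sample_ms})
    hist.meta["final_states"] = Y
    return hist


def make_passive(fields: TissueCellFields, nodes) -> TissueCellFields:
    """Ablate a node set: replace membranes by a resting leak."""
    out = TissueCellFields(fields.epi.copy(), fields.gto.copy(),
                           fields.gks.copy(), fields.gna.copy(),
                           fields.passive.copy())
    out.passive[np.asarray(nodes, dtype=np.int64)] = True
    return out


def activation_times(history: VmHistory, threshold=-40.0) -> np.ndarray:
    """Per-node upstroke crossing time of ``threshold`` (ms), linearly
    interpolated; NaN where the node never activates."""
    vm = history.vm
    t = history.times
    n = vm.shape[1]
    lat = np.full(n, np.nan)
    above = vm >= threshold
    started_below = ~above[0]
    for j in range(n):
        if not started_below[j]:
            if np.all(above[:, j]):
                continue
            # wait for return below threshold, then first crossing
            k0 = int(np.argmax(~above[:, j]))
        else:
            k0 = 0
        idx = np.flatnonzero(above[k0 + 1:, j]) if k0 + 1 < len(t) else []
        if len(idx) == 0:
            continue
        i = k0 + 1 + idx[0]
        v0, v1 = vm[i - 1, j], vm[i, j]
        frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
        lat[j] = t[i - 1] + frac * (t[i] - t[i - 1])
    return lat


def measure_cv(history: VmHistory, mesh: Mesh, probe_a: int, probe_b: int,
               threshold=-40.0) -> float:
    """Conduction velocity between two probe nodes in m/s (== mm/ms)."""
    pa, pb = mesh.points[probe_a], mesh.points[probe_b]
    dist = float(np.linalg.norm(pb - pa))
    if dist < 5.0:
        raise ValueError("probes must be >= 5 mm apart")
    lat = activation_times(history, threshold)
    ta, tb = lat[probe_a], lat[probe_b]
    if np.isnan(ta) or np.isnan(tb):
        raise RuntimeError("probe node not activated")
    if tb == ta:
        raise RuntimeError("zero activation-time difference between probes")
    return dist / abs(tb - ta)
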