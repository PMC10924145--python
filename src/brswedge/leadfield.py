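"""Lead-field forward ECG computation on the torso volume conductor.

Each electrode's lead field is the quasi-static potential produced by a
unit current injected at that electrode and withdrawn at a common
reference electrode (reciprocity).  The electrode potential generated by
cardiac activity is then

    phi_e(t) = - z_e^T K_i Vm(t)

where K_i is the stiffness matrix of the heart assembled with the
intracellular conductivity tensor and z_e the lead-field solution
restricted to heart nodes.  The raw lead-field potentials alone are
dimensionally incomplete as a transfer matrix; combining them with the
intracellular stiffness yields the standard reciprocity form (uniform Vm
produces exactly zero signal because K_i annihilates constants).

For the delayed-depolarization substrate only the intracellular weighting
(K_i) uses the reduced conductivities; the torso (extracellular) side is
left unchanged.

Precordial-style leads are re-referenced to Wilson's central terminal
(mean of LA, RA, LL) at trace level, which cancels the arbitrary choice
of current-return electrode.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .fem import (VmHistory, assemble_tensor_stiffness,
                  conductivity_tensors, isotropic_stiffness)
from .geometry import ConductivityField, Mesh, TorsoModel


def _torso_lu(torso: TorsoModel, ground: int):
    """Factorized torso stiffness with one node grounded (cached)."""
    key = ("_lu", ground)
    cache = torso.meta.setdefault("_solver_cache", {})
    if key not in cache:
        K = isotropic_stiffness(torso.mesh, torso.sigma).tolil()
        K[ground, :] = 0.0
        K[:, ground] = 0.0
        K[ground, ground] = 1.0
        cache[key] = splu(K.tocsc())
    return cache[key]


def compute_lead_field(torso: TorsoModel, electrode: str,
                       reference: str = "REF") -> np.ndarray:
    """Unit-current lead-field potential over all torso nodes.

    Injects +1 at ``electrode``, withdraws -1 at ``reference``; the
    reference node is also used as potential ground (its choice cancels
    after WCT re-referencing).
    """
    if electrode not in torso.electrodes:
        raise KeyError(f"unknown electrode {electrode!r}")
    if reference not in torso.electrodes:
        raise KeyError(f"unknown reference electrode {reference!r}")
    e = torso.electrodes[electrode]
    r = torso.electrodes[reference]
    if e == r:
        return np.zeros(torso.mesh.n_nodes)
    lu = _torso_lu(torso, r)
    b = np.zeros(torso.mesh.n_nodes)
    b[e] = 1.0
    b[r] = 0.0  # grounded row
    phi = lu.solve(b)
    phi[r] = 0.0
    return phi


def intracellular_stiffness(heart: Mesh, fibers: np.ndarray,
                            cond: ConductivityField):
    sig = conductivity_tensors(fibers, cond)
    K, _ = assemble_tensor_stiffness(heart, sig)
    return K


@dataclass
class LeadFieldMatrix:
    """Electrode-to-myocardium transfer operator: ecg(t) = Z @ Vm(t)."""
    Z: np.ndarray            # (n_leads, n_heart_nodes)
    labels: list
    meta: dict = field(default_factory=dict)

    @property
    def node_hash(self) -> str:
        return self.meta.get("node_hash", "")


def build_matrix(torso: TorsoModel, fibers: np.ndarray,
                 cond: ConductivityField, leads=None,
                 reference: str = "REF",
                 variant: str = "baseline") -> LeadFieldMatrix:
    """Lead-field matrix for the given electrodes.

    ``cond`` is the intracellular conductivity field of the heart (pass
    the substrate-reduced field for the delayed-depolarization variant and
    set ``variant`` accordingly; torso conductivities are not touched).
    """
    if leads is None:
        leads = [k for k in torso.electrodes if k != reference]
    Ki = intracellular_stiffness(torso.heart, fibers, cond).tocsr()
    hmap = torso.heart_node_map
    rowsZ = np.empty((len(leads), torso.heart.n_nodes))
    for i, name in enumerate(leads):
        phi = compute_lead_field(torso, name, reference)
        rowsZ[i] = -(Ki @ phi[hmap])
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(torso.heart.points).tobytes())
    meta = {"node_hash": h.hexdigest()[:16], "variant": variant,
            "reference": reference,
            "torso_sigma_hash": hashlib.sha256(
                np.ascontiguousarray(torso.sigma).tobytes()).hexdigest()[:16]}
    return LeadFieldMatrix(Z=rowsZ, labels=list(leads), meta=meta)


@dataclass
class ECGTrace:
    """Multi-lead potential time series at the history's sampling."""
    time: np.ndarray           # ms
    data: np.ndarray           # (n_times, n_leads), mV (model scale)
    labels: list
    meta: dict = field(default_factory=dict)

    def lead(self, name: str) -> np.ndarray:
        return self.data[:, self.labels.index(name)]


def wilson_central_terminal(trace: ECGTrace) -> np.ndarray:
    """Mean of the LA, RA and LL electrode potentials per frame."""
    for name in ("LA", "RA", "LL"):
        if name not in trace.labels:
            raise ValueError(f"limb lead {name} missing")
    return (trace.lead("LA") + trace.lead("RA") + trace.lead("LL")) / 3.0


def ecg_from_vm(Z: LeadFieldMatrix, history: VmHistory,
                baseline_window: tuple = (0.0, 8.0),
                reference: str = "wct") -> ECGTrace:
    """Map a transmembrane-voltage history to ECG traces.

    Precordial-style leads (labels starting with 'V') are re-referenced to
    Wilson's central terminal; each lead's baseline (mean over the
    pre-stimulus ``baseline_window``) is subtracted.
    """
    if Z.node_hash and history.node_hash and Z.node_hash != history.node_hash:
        raise ValueError("lead-field matrix and history node order differ")
    raw = history.vm @ Z.Z.T
    trace = ECGTrace(history.times.copy(), raw, list(Z.labels),
                     meta={"reference": "ground"})
    if reference == "wct":
        wct = wilson_central_terminal(trace)
        data = trace.data.copy()
        for i, lab in enumerate(trace.labels):
            if lab.startswith("V"):
                data[:, i] = data[:, i] - wct
        trace = ECGTrace(trace.time, data, trace.labels,
                         meta={"reference": "wct"})
    t0, t1 = baseline_window
    sel = (trace.time >= t0) & (trace.time <= t1)
    if np.any(sel):
        trace.data = trace.data - trace.data[sel].mean(axis=0, keepdims=True)
    trace.meta["baseline_window"] = (t0, t1)
    return trace
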