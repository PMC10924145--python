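"""Named end-to-end scenarios contrasting the Brugada substrate models.

Pipeline per scenario: synthetic wedge geometry -> per-node membrane
parameters -> cluster-based steady-state initialization -> monodomain beat
protocol -> lead-field ECG -> morphology features.

Scenarios
---------
healthy            : no substrate modification
delayed_depol      : substrate conductivity reduced (0.09 -> 0.009 S/m
                     longitudinal toward the center, transverse /1000)
delayed_depol_na50 : delayed_depol plus global G_Na x 0.5
early_repol        : G_to x fold (default 20) in substrate cells only
early_repol_na50   : early_repol plus global G_Na x 0.5
ablation           : delayed_depol substrate rendered electrically passive

The default geometry is the fast 2D transmural-sheet mode (30 x 10 mm at
0.5 mm target edge); 3D slabs are available through GeometryConfig.  The
substrate-facing lead is the grid electrode directly over the substrate
center ("V2_ICS3").
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cell as _cell
from .cell import APTrace, ChannelScales, PacingProtocol, apd, detect_dome
from .features import ActivationMap, ECGFeatures, FeatureConfig, \
    activation_map, extract_features
from .fem import (FEMSystem, SolverConfig, Stimulus, StimulusProtocol,
                  TissueCellFields, VmHistory, init_states_by_cluster,
                  make_passive, measure_cv, run_simulation)
from .geometry import (ConductivityField, Mesh, SubstrateSpec,
                       assign_fibers, assign_variants, baseline_conductivity,
                       build_strand, build_torso, build_wedge,
                       define_substrate, gks_gradient, substrate_nodes)
from .leadfield import LeadFieldMatrix, build_matrix, ecg_from_vm

SCENARIO_NAMES = ("healthy", "delayed_depol", "delayed_depol_na50",
                  "early_repol", "early_repol_na50", "ablation")

SUBSTRATE_LEAD = "V2_ICS3"


@dataclass(frozen=True)
class GeometryConfig:
    dims: tuple = (40.0, 10.0)       # 2D sheet by default; 3 entries -> 3D
    target_edge: float = 0.5
    jitter: float = 0.25
    seed: int = 0
    fiber_endo: float = 60.0
    fiber_epi: float = -60.0
    padding: float = 20.0   # torso margin; precordial electrodes sit this
                            # far above the epicardial face


@dataclass(frozen=True)
class ScenarioConfig:
    name: str = "healthy"
    geometry: GeometryConfig = GeometryConfig()
    diameter: float | None = None    # default 0.5 x wedge width
    max_thickness: float = 2.2
    gto_fold: float = 20.0           # early-repolarization substrate
    gna_scale: float = 1.0
    n_beats: int = 3
    cycle_length: float = 800.0
    stim_onset: float = 10.0
    stim_duration: float = 1.0
    stim_amplitude: float = -80.0
    solver: SolverConfig = field(default_factory=SolverConfig)
    substrate_profile: str = "uniform"

    def substrate_spec(self) -> SubstrateSpec:
        dia = self.diameter
        if dia is None:
            dia = 0.5 * self.geometry.dims[0]
        return SubstrateSpec(diameter=dia, max_thickness=self.max_thickness,
                             profile=self.substrate_profile)


def make_scenario(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {SCENARIO_NAMES}")
    geo = overrides.pop("geometry", GeometryConfig(seed=seed))
    if geo.seed != seed:
        geo = replace(geo, seed=seed)
    gna = 0.5 if name.endswith("_na50") else overrides.pop("gna_scale", 1.0)
    return ScenarioConfig(name=name, geometry=geo, gna_scale=gna,
                          **overrides)


@dataclass
class ScenarioResult:
    name: str
    config: ScenarioConfig
    history: VmHistory
    ecg: object                       # ECGTrace
    features: ECGFeatures
    act_map: ActivationMap
    substrate_node_ids: np.ndarray
    mesh: Mesh
    meta: dict = field(default_factory=dict)

    @property
    def substrate_lead(self) -> str:
        labels = self.ecg.labels
        if SUBSTRATE_LEAD in labels:
            return SUBSTRATE_LEAD
        return [l for l in labels if l.startswith("V")][0]

    def j_point(self, lead=None) -> float:
        lead = lead or self.substrate_lead
        return self.features.per_lead[lead].j_point_mv


_GEO_CACHE: dict = {}


def _geometry_bundle(geo: GeometryConfig, spec: SubstrateSpec):
    """Mesh, fibers, substrate fields, torso and lead-field matrices,
    cached per geometry+substrate parameters."""
    key = (geo, spec.diameter, spec.max_thickness, spec.profile,
           spec.sigma_l_edge, spec.sigma_l_center,
           spec.transverse_attenuation)
    if key in _GEO_CACHE:
        return _GEO_CACHE[key]
    wall = geo.dims[-1]
    mesh = build_wedge(geo.dims, geo.target_edge, geo.jitter, geo.seed,
                       snap_planes=(wall - spec.max_thickness,))
    fibers = assign_fibers(mesh, geo.fiber_endo, geo.fiber_epi)
    base_cond = baseline_conductivity(mesh)
    sub_mask, reduced_cond = define_substrate(mesh, spec, base_cond)
    sub_nodes = substrate_nodes(mesh, spec)
    torso = build_torso(mesh, padding=geo.padding)
    Z_base = build_matrix(torso, fibers, base_cond, variant="baseline")
    Z_dd = build_matrix(torso, fibers, reduced_cond,
                        variant="delayed_depol")
    # ablated tissue (scar) has no intact membranes and no intracellular
    # continuity: near-zero conductivity in scar elements for both the
    # monodomain operator and the lead-field weighting
    abl_cond = ConductivityField(
        np.where(sub_mask, 1e-9, base_cond.sigma_l),
        np.where(sub_mask, 1e-9, base_cond.sigma_t))
    Z_abl = build_matrix(torso, fibers, abl_cond, variant="ablation")
    # nodes all of whose incident elements are scar: fully decoupled core
    n_inc = np.zeros(mesh.n_nodes, dtype=np.int64)
    n_sub = np.zeros(mesh.n_nodes, dtype=np.int64)
    np.add.at(n_inc, mesh.cells.ravel(), 1)
    np.add.at(n_sub, mesh.cells[sub_mask].ravel(), 1)
    scar_core = np.flatnonzero((n_inc > 0) & (n_sub == n_inc))
    bundle = dict(mesh=mesh, fibers=fibers, base_cond=base_cond,
                  sub_mask=sub_mask, reduced_cond=reduced_cond,
                  sub_nodes=sub_nodes, torso=torso, Z_base=Z_base,
                  Z_dd=Z_dd, Z_abl=Z_abl, abl_cond=abl_cond,
                  scar_core_nodes=scar_core)
    _GEO_CACHE[key] = bundle
    return bundle


def _tissue_fields(mesh: Mesh, config: ScenarioConfig,
                   bundle: dict) -> TissueCellFields:
    n = mesh.n_nodes
    epi = assign_variants(mesh.depth)
    fields = TissueCellFields(
        epi=epi, gto=np.ones(n), gks=gks_gradient(mesh.apexbase),
        gna=np.full(n, config.gna_scale), passive=np.zeros(n, dtype=bool))
    if config.name.startswith("early_repol"):
        fields.gto[bundle["sub_nodes"]] = config.gto_fold
    if config.name == "ablation":
        fields = make_passive(fields, bundle["scar_core_nodes"])
    return fields


def run_scenario(config: ScenarioConfig,
                 feature_config: FeatureConfig = FeatureConfig(),
                 sample_ms: float = 1.0) -> ScenarioResult:
    """Execute one named scenario end to end (result beat = last beat)."""
    t_start = time.time()
    spec = config.substrate_spec()
    bundle = _geometry_bundle(config.geometry, spec)
    mesh = bundle["mesh"]
    if config.name == "ablation":
        cond, Z = bundle["abl_cond"], bundle["Z_abl"]
    elif config.name.startswith("delayed_depol"):
        cond, Z = bundle["reduced_cond"], bundle["Z_dd"]
    else:
        cond, Z = bundle["base_cond"], bundle["Z_base"]
    fields = _tissue_fields(mesh, config, bundle)
    system = FEMSystem(mesh, bundle["fibers"], cond, config.solver)
    stim_nodes = mesh.endo_nodes
    protocol = StimulusProtocol(
        [Stimulus(stim_nodes, onset=config.stim_onset,
                  duration=config.stim_duration,
                  amplitude=config.stim_amplitude)],
        cycle_length=config.cycle_length, n_beats=config.n_beats)
    states, assign, init_info = init_states_by_cluster(
        fields, protocol=PacingProtocol(cycle_length=config.cycle_length),
        ina_tt=config.solver.ina_tt)
    history = run_simulation(mesh, fields, system, protocol,
                             initial_states=states, sample_ms=sample_ms)
    ecg = ecg_from_vm(Z, history,
                      baseline_window=(0.0, config.stim_onset - 1.0))
    if feature_config.blank_window is None:
        feature_config = replace(
            feature_config,
            blank_window=(config.stim_onset - 0.5,
                          config.stim_onset + config.stim_duration + 1.5))
    feats = extract_features(ecg, feature_config)
    amap = activation_map(history, mesh, bundle["sub_nodes"])
    return ScenarioResult(
        name=config.name, config=config, history=history, ecg=ecg,
        features=feats, act_map=amap,
        substrate_node_ids=bundle["sub_nodes"], mesh=mesh,
        meta={"runtime_s": time.time() - t_start,
              "init": {k: v for k, v in init_info.items()},
              "n_nodes": mesh.n_nodes})


def sweep(base: ScenarioConfig, parameter: str, values):
    """Run ``base`` across parameter values sharing the geometry seed.

    ``parameter`` is one of diameter, thickness, gto_scale, gna_scale.
    Returns (results, summary DataFrame with J-point, ST class and
    substrate delay per value).
    """
    field_map = {"diameter": "diameter", "thickness": "max_thickness",
                 "gto_scale": "gto_fold", "gna_scale": "gna_scale"}
    if parameter not in field_map:
        raise ValueError(f"cannot sweep {parameter!r}")
    results = []
    rows = []
    for v in values:
        cfg = replace(base, **{field_map[parameter]: float(v)})
        try:
            res = run_scenario(cfg)
        except Exception as exc:   # record and continue
            rows.append({parameter: v, "error": str(exc)})
            results.append(None)
            continue
        lead = res.substrate_lead
        lf = res.features.per_lead[lead]
        rows.append({parameter: v, "j_point_mv": lf.j_point_mv,
                     "st_class": lf.st_class,
                     "t_polarity": lf.t_polarity,
                     "substrate_delay_ms": res.act_map.substrate_delay,
                     "lead": lead})
        results.append(res)
    return results, pd.DataFrame(rows)


def single_cell_study(fold_values=tuple(range(1, 21)),
                      protocol=PacingProtocol(), ina_tt=False):
    """Single-cell G_to bifurcation study (epicardial variant).

    Returns dict with the loss-of-dome threshold fold, APD90 at that
    fold, and the full fold table as a DataFrame.
    """
    threshold, table = _cell.gto_collapse_threshold(
        epi=True, fold_values=fold_values, protocol=protocol,
        ina_tt=ina_tt)
    df = pd.DataFrame(table)
    apd_at = None
    if threshold is not None:
        apd_at = float(df.loc[df["fold"] == threshold, "apd90_ms"].iloc[0])
    return {"threshold_fold": threshold, "apd90_at_threshold_ms": apd_at,
            "table": df}


def strand_cv(sigma_l: float, edge: float = 0.25, length: float = 30.0,
              config: SolverConfig | None = None,
              probes=(10.0, 20.0)) -> float:
    """Plane-wave conduction velocity on a uniform 1D strand (m/s)."""
    config = config or SolverConfig()
    mesh = build_strand(length, edge)
    m = len(mesh.cells)
    fib = np.ones((m, 1))
    cond = ConductivityField(np.full(m, sigma_l), np.full(m, sigma_l))
    system = FEMSystem(mesh, fib, cond, config)
    fields = TissueCellFields.uniform(mesh.n_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=config.ina_tt)
    stim = np.flatnonzero(mesh.points[:, 0] <= 1.0)
    prot = StimulusProtocol([Stimulus(stim, onset=5.0)],
                            cycle_length=300.0, n_beats=1)
    hist = run_simulation(mesh, fields, system, prot,
                          initial_states=states)
    ia = int(np.argmin(np.abs(mesh.points[:, 0] - probes[0])))
    ib = int(np.argmin(np.abs(mesh.points[:, 0] - probes[1])))
    return measure_cv(hist, mesh, ia, ib)


def cv_studies(sigmas=(0.18, 0.09, 0.009), edges=(0.25, 0.125)):
    """Strand CV table across conductivities and mesh resolutions.

    Returns dict with the DataFrame, the 2-fold and 20-fold CV reduction
    ratios at the finest-but-one resolution, and the convergence delta at
    the baseline conductivity.
    """
    rows = []
    for edge in edges:
        for s in sigmas:
            e = edge
            if s <= 0.01:
                e = min(edge, 0.1)  # slow propagation needs a finer grid
            try:
                cv = strand_cv(s, edge=e)
                rows.append({"sigma_l": s, "edge_mm": e, "cv_m_s": cv})
            except RuntimeError as exc:
                rows.append({"sigma_l": s, "edge_mm": e, "cv_m_s": np.nan,
                             "note": str(exc)})
    df = pd.DataFrame(rows)
    base_edge = edges[0]
    cv0 = df[(df.sigma_l == sigmas[0]) & (df.edge_mm == base_edge)
             ].cv_m_s.iloc[0]
    cv1 = df[(df.sigma_l == sigmas[1]) & (df.edge_mm == base_edge)
             ].cv_m_s.iloc[0]
    cv2 = df[df.sigma_l == sigmas[2]].cv_m_s.dropna().iloc[0]
    fine = df[(df.sigma_l == sigmas[0]) & (df.edge_mm == edges[-1])
              ].cv_m_s.iloc[0]
    return {"table": df, "ratio_2x": float(cv0 / cv1),
            "ratio_20x": float(cv0 / cv2),
            "convergence_rel": float(abs(fine - cv0) / cv0)}


def substrate_traces(result: ScenarioResult):
    """AP traces (1 ms sampling) of the substrate nodes of a scenario."""
    sub = result.substrate_node_ids
    t = result.history.times
    return [APTrace(t, result.history.vm[:, j]) for j in sub]


def substrate_dome_lost(result: ScenarioResult) -> bool:
    """Majority vote of the dome criterion over substrate-node traces."""
    traces = substrate_traces(result)
    lost = 0
    total = 0
    for tr in traces:
        try:
            has = detect_dome(tr)
        except ValueError:      # not activated: does not vote
            continue
        total += 1
        lost += (not has)
    if total == 0:
        raise RuntimeError("no activated substrate nodes")
    return lost > total / 2


def tissue_gto_threshold(fold_lo: int = 14, fold_hi: int = 24,
                         seed: int = 0, **overrides):
    """Minimal substrate G_to fold with tissue-level loss of dome.

    Runs the early-repolarization scenario on the default wedge for
    integer folds, locating the smallest fold whose substrate loses the
    dome (bisection over [fold_lo, fold_hi]; assumes monotone dome loss,
    which is verified at the bracketing endpoints).
    Returns dict with the threshold and the folds evaluated.
    """
    evaluated = {}

    def lost(fold: int) -> bool:
        if fold not in evaluated:
            cfg = make_scenario("early_repol", seed=seed,
                                gto_fold=float(fold), **overrides)
            evaluated[fold] = substrate_dome_lost(run_scenario(cfg))
        return evaluated[fold]

    if lost(fold_lo):
        return {"threshold_fold": fold_lo, "evaluated": evaluated,
                "note": "dome already lost at the lowest fold scanned"}
    if not lost(fold_hi):
        return {"threshold_fold": None, "evaluated": evaluated,
                "note": "no collapse in range"}
    lo, hi = fold_lo, fold_hi      # dome at lo, lost at hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if lost(mid):
            hi = mid
        else:
            lo = mid
    return {"threshold_fold": hi, "evaluated": evaluated}
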