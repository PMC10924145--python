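"""Monodomain FEM: assembly identities, Crank–Nicolson diffusion against
the heat-kernel closed form, cluster initialization, propagation and CV
measurement on small tissue."""

import numpy as np
import pytest

from brswedge.cell import ChannelScales, PacingProtocol
from brswedge.fem import (FEMSystem, SolverConfig, Stimulus,
                          StimulusProtocol, TissueCellFields,
                          activation_times, init_states_by_cluster,
                          make_passive, measure_cv, run_simulation)
from brswedge.geometry import (ConductivityField, Mesh,
                               baseline_conductivity, build_strand,
                               build_wedge)


def _uniform_system(mesh, sigma_l=0.18, sigma_t=0.08, **cfg_kw):
    m = len(mesh.cells)
    fib = np.zeros((m, mesh.dim))
    fib[:, 0] = 1.0
    cond = ConductivityField(np.full(m, sigma_l), np.full(m, sigma_t))
    return FEMSystem(mesh, fib, cond, SolverConfig(**cfg_kw)), fib, cond


def test_stiffness_rows_annihilate_constants():
    mesh = build_wedge((12.0, 6.0), 0.6, jitter=0.25, seed=1)
    sysm, _, _ = _uniform_system(mesh)
    ones = np.ones(mesh.n_nodes)
    assert np.max(np.abs(sysm.K @ ones)) < 1e-10
    # symmetry
    assert abs(sysm.K - sysm.K.T).max() < 1e-12


def test_mass_matrix_sums_to_mesh_volume():
    mesh = build_wedge((12.0, 6.0, 4.0), 1.0, jitter=0.2, seed=2)
    sysm, _, _ = _uniform_system(mesh)
    assert sysm.M.sum() == pytest.approx(mesh.volumes().sum(), rel=1e-8)
    assert sysm.M.sum() == pytest.approx(12.0 * 6.0 * 4.0, rel=1e-6)


def test_anisotropic_tensor_energy_matches_sigma():
    """For a unit potential gradient along/across the fiber axis, the
    dissipated energy density equals sigma_l / sigma_t exactly."""
    mesh = build_wedge((10.0, 10.0), 1.0, jitter=0.0, seed=0)
    sysm, _, _ = _uniform_system(mesh, 0.18, 0.08)
    x = mesh.points[:, 0].copy()
    y = mesh.points[:, 1].copy()
    area = 100.0
    assert x @ (sysm.K @ x) == pytest.approx(0.18 * area, rel=1e-10)
    assert y @ (sysm.K @ y) == pytest.approx(0.08 * area, rel=1e-10)


def test_cn_step_preserves_uniform_state():
    mesh = build_wedge((12.0, 6.0), 0.6, jitter=0.25, seed=3)
    sysm, _, _ = _uniform_system(mesh)
    v = np.full(mesh.n_nodes, -85.0)
    out = sysm.cn_step(v)
    assert np.allclose(out, v, atol=1e-9)


def test_gaussian_diffusion_matches_heat_kernel():
    """Passive CN diffusion of a Gaussian: mass-weighted variance grows at
    2*D per axis within 2% of the closed form."""
    mesh = build_wedge((24.0, 24.0), 0.4, jitter=0.0, seed=0)
    sigma = 0.1
    sysm, _, _ = _uniform_system(mesh, sigma, sigma)
    D = sigma * sysm.config.diff_scale  # mm^2/ms
    c = mesh.points - 12.0
    u = np.exp(-(c ** 2).sum(axis=1) / (2 * 1.0 ** 2))

    def var_x(u):
        w = sysm.M @ u
        return float((w * c[:, 0] ** 2).sum() / w.sum())

    v0 = var_x(u)
    n_steps = 200
    for _ in range(n_steps):
        u = sysm.cn_step(u)
    v1 = var_x(u)
    t = n_steps * sysm.config.dt_ms
    assert (v1 - v0) == pytest.approx(2.0 * D * t, rel=0.02)


def test_cluster_init_counts():
    n = 60
    f = TissueCellFields.uniform(n)
    _, assign, info = init_states_by_cluster(f, max_beats=2)
    assert info["n_clusters"] == 1
    # two variants, no gradients -> 2 clusters
    f2 = TissueCellFields.uniform(n)
    f2.epi[: n // 2] = False
    _, _, info2 = init_states_by_cluster(f2, max_beats=2)
    assert info2["n_clusters"] == 2


def test_cluster_init_gks_gradient_bins():
    """Greedy 10%-similarity binning of a 1..3 gradient: the cluster count
    equals the brute-force count of occupied geometric bins."""
    n = 200
    gks = np.linspace(1.0, 3.0, n)
    f = TissueCellFields.uniform(n)
    f.gks = gks
    _, assign, info = init_states_by_cluster(f, similarity=0.10,
                                             max_beats=1)
    expected = len({int(np.floor(np.log(g) / np.log(1.1) + 1e-12))
                    for g in gks})
    assert info["n_clusters"] == expected
    # members of one cluster differ < 10% in gks
    for c in range(info["n_clusters"]):
        vals = gks[assign == c]
        assert vals.max() / vals.min() < 1.1 + 1e-9


@pytest.fixture(scope="module")
def strand_run():
    """One paced beat on a uniform 30 mm strand at nominal conductivity."""
    mesh = build_strand(30.0, 0.25)
    m = len(mesh.cells)
    fib = np.ones((m, 1))
    cond = ConductivityField(np.full(m, 0.18), np.full(m, 0.18))
    sysm = FEMSystem(mesh, fib, cond, SolverConfig(ina_tt=True))
    fields = TissueCellFields.uniform(mesh.n_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=True)
    stim = np.flatnonzero(mesh.points[:, 0] <= 1.0)
    prot = StimulusProtocol([Stimulus(stim, onset=5.0)],
                            cycle_length=300.0, n_beats=1)
    hist = run_simulation(mesh, fields, sysm, prot, initial_states=states)
    return mesh, hist


def test_no_stimulus_stays_flat():
    mesh = build_strand(12.0, 0.5)
    sysm, _, cond = _uniform_system(mesh, 0.18, 0.18, ina_tt=True)
    fields = TissueCellFields.uniform(mesh.n_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=True)
    prot = StimulusProtocol(
        [Stimulus(np.array([0]), onset=5.0, amplitude=0.0)],
        cycle_length=100.0, n_beats=1)
    hist = run_simulation(mesh, fields, sysm, prot, initial_states=states)
    assert np.max(np.abs(hist.vm - hist.vm[0])) < 0.5


def test_planar_wave_every_node_activates_once(strand_run):
    mesh, hist = strand_run
    lat = activation_times(hist)
    assert np.all(np.isfinite(lat))
    # single monotone wavefront away from the stimulus
    inner = (mesh.points[:, 0] > 2.0)
    x = mesh.points[inner, 0]
    order = np.argsort(x)
    assert np.all(np.diff(lat[inner][order]) > -0.6)
    # exactly one upstroke crossing per node
    for j in range(0, mesh.n_nodes, 17):
        v = hist.vm[:, j]
        crossings = np.sum((v[:-1] < -40.0) & (v[1:] >= -40.0))
        assert crossings == 1


def test_measured_cv_in_calibration_band(strand_run):
    mesh, hist = strand_run
    ia = int(np.argmin(np.abs(mesh.points[:, 0] - 10.0)))
    ib = int(np.argmin(np.abs(mesh.points[:, 0] - 20.0)))
    cv = measure_cv(hist, mesh, ia, ib)
    assert 0.6 <= cv <= 0.7


def test_measure_cv_rejects_close_probes(strand_run):
    mesh, hist = strand_run
    with pytest.raises(ValueError, match="5 mm"):
        measure_cv(hist, mesh, 0, 1)


def test_deterministic_rerun_bit_identical(strand_run):
    mesh, hist = strand_run
    m = len(mesh.cells)
    fib = np.ones((m, 1))
    cond = ConductivityField(np.full(m, 0.18), np.full(m, 0.18))
    sysm = FEMSystem(mesh, fib, cond, SolverConfig(ina_tt=True))
    fields = TissueCellFields.uniform(mesh.n_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=True)
    stim = np.flatnonzero(mesh.points[:, 0] <= 1.0)
    prot = StimulusProtocol([Stimulus(stim, onset=5.0)],
                            cycle_length=300.0, n_beats=1)
    hist2 = run_simulation(mesh, fields, sysm, prot,
                           initial_states=states)
    assert np.array_equal(hist2.vm, hist.vm)


def test_passive_region_carries_no_upstroke(tiny_geometry):
    """Ablated nodes in a weakly coupled (substrate-like) region never
    fire; the surrounding active tissue still does."""
    mesh = build_wedge(tiny_geometry.dims, tiny_geometry.target_edge,
                       tiny_geometry.jitter, tiny_geometry.seed)
    m = len(mesh.cells)
    fib = np.zeros((m, 2))
    fib[:, 0] = 1.0
    in_region = (mesh.centroids()[:, 0] > 10.0) \
        & (mesh.centroids()[:, 1] > 3.0)
    cond = ConductivityField(np.where(in_region, 0.009, 0.18),
                             np.where(in_region, 8e-5, 0.08))
    sysm = FEMSystem(mesh, fib, cond, SolverConfig(ina_tt=True))
    fields = TissueCellFields.uniform(mesh.n_nodes)
    passive_nodes = np.flatnonzero((mesh.points[:, 0] > 10.5)
                                   & (mesh.points[:, 1] > 3.4))
    fields = make_passive(fields, passive_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=True)
    prot = StimulusProtocol([Stimulus(mesh.endo_nodes, onset=5.0)],
                            cycle_length=300.0, n_beats=1)
    hist = run_simulation(mesh, fields, sysm, prot, initial_states=states)
    dv = np.diff(hist.vm, axis=0) / np.diff(hist.times)[:, None]
    assert dv[:, passive_nodes].max() < 10.0
    border = np.flatnonzero((mesh.points[:, 0] < 9.0)
                            & (mesh.depth >= 0.5))
    assert dv[:, border].max() > 50.0


def test_anisotropy_cv_faster_along_fibers(tiny_geometry):
    """With sigma_l > sigma_t, propagation along fibers outruns the
    transmural direction."""
    mesh = build_wedge((16.0, 6.0), 0.8, jitter=0.1, seed=3)
    sysm, _, _ = _uniform_system(mesh, 0.18, 0.08, ina_tt=True)
    fields = TissueCellFields.uniform(mesh.n_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=True)
    corner = np.flatnonzero((mesh.points[:, 0] <= 0.9)
                            & (mesh.points[:, 1] <= 0.9))
    prot = StimulusProtocol([Stimulus(corner, onset=5.0)],
                            cycle_length=300.0, n_beats=1)
    hist = run_simulation(mesh, fields, sysm, prot, initial_states=states)
    lat = activation_times(hist)
    along = int(np.argmin(np.linalg.norm(
        mesh.points - np.array([6.0, 0.0]), axis=1)))
    across = int(np.argmin(np.linalg.norm(
        mesh.points - np.array([0.0, 6.0]), axis=1)))
    assert lat[along] < lat[across]


def test_3d_slab_propagates_from_endocardial_face():
    """Coarse 3D tetrahedral slab: a paced beat activates every node."""
    mesh = build_wedge((8.0, 8.0, 4.0), 1.0, jitter=0.15, seed=2)
    sysm, _, _ = _uniform_system(mesh, 0.18, 0.08, ina_tt=True)
    fields = TissueCellFields.uniform(mesh.n_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=True)
    prot = StimulusProtocol([Stimulus(mesh.endo_nodes, onset=5.0)],
                            cycle_length=300.0, n_beats=1)
    hist = run_simulation(mesh, fields, sysm, prot, initial_states=states)
    lat = activation_times(hist)
    assert np.all(np.isfinite(lat))
    assert lat[mesh.epi_nodes].mean() > lat[mesh.endo_nodes].mean()


def test_instability_abort_reports_location():
    mesh = build_strand(12.0, 0.5)
    sysm, _, _ = _uniform_system(mesh, 0.18, 0.18, ina_tt=True)
    fields = TissueCellFields.uniform(mesh.n_nodes)
    states, _, _ = init_states_by_cluster(fields, ina_tt=True)
    states[:, 0] = 500.0  # blatantly unphysical start
    prot = StimulusProtocol([Stimulus(np.array([0]), onset=5.0)],
                            cycle_length=50.0, n_beats=1)
    with pytest.raises(RuntimeError, match="instability"):
        run_simulation(mesh, fields, sysm, prot, initial_states=states)
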