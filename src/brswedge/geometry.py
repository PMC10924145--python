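"""Synthetic wedge/torso geometry generation.

A jittered structured simplicial mesh of a transmural myocardial wedge
stands in for patient anatomy: the last coordinate axis is the transmural
direction (0 = endocardial face, max = epicardial face), the first axis the
apex–base direction.  A 2D mode (transmural sheet) is provided for fast
runs; the 3D mode builds tetrahedra via Kuhn subdivision of a box lattice.

The torso is a conforming extension of the same lattice: the heart block
keeps its (jittered) nodes and elements, outer layers coarsen geometrically
toward the torso boundary.  Electrodes standing in for the parasternal
V1/V2 x ICS2–4 grid sit on the anterior face (the side beyond the
epicardium), with LA/RA/LL reference electrodes at remote boundary sites.

Units: coordinates in mm, conductivities in S/m.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial as _factorial

import numpy as np

# Table of organ conductivities available for torso fidelity runs (S/m)
ORGAN_CONDUCTIVITIES = {
    "fat": 0.035,
    "skin": 0.0002,
    "blood": 0.7,
    "lungs": 0.03,
    "intestines": 0.01,
    "kidney": 0.05,
    "liver": 0.02,
    "spleen": 0.03,
}

BACKGROUND_SIGMA = 0.2  # homogeneous torso default, S/m

# Kuhn subdivision of the unit cube into 6 tetrahedra along the main
# diagonal (conforming across neighbouring cubes without parity flips).
_KUHN_PERMS = list(itertools.permutations(range(3)))


@dataclass
class Mesh:
    """Simplicial mesh: segments (1D), triangles (2D) or tetrahedra (3D)."""
    points: np.ndarray          # (n_nodes, dim), mm
    cells: np.ndarray           # (n_cells, dim+1), 0-based node ids
    region: np.ndarray = None   # (n_cells,) int labels
    depth: np.ndarray = None    # (n_nodes,) transmural coordinate in [0,1]
    apexbase: np.ndarray = None  # (n_nodes,) apex-base coordinate in [0,1]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.region is None:
            self.region = np.zeros(len(self.cells), dtype=np.int64)

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    def volumes(self) -> np.ndarray:
        """Element measures (length / area / volume), all positive."""
        X = self.points[self.cells]
        d = self.dim
        E = X[:, 1:, :] - X[:, :1, :]
        if d == 1:
            return np.abs(E[:, 0, 0])
        det = np.linalg.det(E)
        return np.abs(det) / float(_factorial(d))

    def edge_lengths(self) -> np.ndarray:
        d = self.dim
        pairs = list(itertools.combinations(range(d + 1), 2))
        segs = [np.linalg.norm(self.points[self.cells[:, a]]
                               - self.points[self.cells[:, b]], axis=1)
                for a, b in pairs]
        return np.concatenate(segs)

    @property
    def endo_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.depth == 0.0)

    @property
    def epi_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.depth == 1.0)


def _axis_coords(length: float, target_edge: float) -> np.ndarray:
    n = max(2, int(round(length / target_edge)) + 1)
    return np.linspace(0.0, length, n)


def _grid_points(axes):
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def _grid_cells(shape):
    """Simplices of a structured grid with node-count ``shape``.

    2D: two triangles per quad, consistent diagonal.  3D: six tetrahedra
    per hexahedron (Kuhn subdivision, conforming).
    """
    dim = len(shape)
    if dim == 1:
        n = shape[0]
        return np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    strides = np.ones(dim, dtype=np.int64)
    for k in range(dim - 2, -1, -1):
        strides[k] = strides[k + 1] * shape[k + 1]
    if dim == 2:
        ni, nj = shape
        i, j = np.meshgrid(np.arange(ni - 1), np.arange(nj - 1),
                           indexing="ij")
        v00 = (i * strides[0] + j * strides[1]).ravel()
        v10 = v00 + strides[0]
        v01 = v00 + strides[1]
        v11 = v10 + strides[1]
        t1 = np.stack([v00, v10, v11], axis=1)
        t2 = np.stack([v00, v11, v01], axis=1)
        return np.concatenate([t1, t2], axis=0)
    ni, nj, nk = shape
    i, j, k = np.meshgrid(np.arange(ni - 1), np.arange(nj - 1),
                          np.arange(nk - 1), indexing="ij")
    base = (i * strides[0] + j * strides[1] + k * strides[2]).ravel()
    cells = []
    for perm in _KUHN_PERMS:
        off = np.zeros(4, dtype=np.int64)
        acc = 0
        verts = [0]
        for p in perm:
            acc += strides[p]
            verts.append(acc)
        arr = np.stack([base + v for v in verts], axis=1)
        cells.append(arr)
    return np.concatenate(cells, axis=0)


def _fix_degenerate(points, cells, lattice_points, interior, max_iter=10):
    """Pull jittered interior nodes back toward the lattice until every
    element has positive measure."""
    d = points.shape[1]
    for _ in range(max_iter):
        X = points[cells]
        E = X[:, 1:, :] - X[:, :1, :]
        if d == 1:
            vol = E[:, 0, 0]
        else:
            vol = np.linalg.det(E)
        bad = np.abs(vol) < 1e-12
        if d > 1:
            # orientation must match the unjittered lattice's
            Xl = lattice_points[cells]
            El = Xl[:, 1:, :] - Xl[:, :1, :]
            bad |= np.sign(vol) != np.sign(np.linalg.det(El))
        if not np.any(bad):
            return points
        nodes = np.unique(cells[bad])
        nodes = nodes[interior[nodes]]
        points[nodes] = 0.5 * (points[nodes] + lattice_points[nodes])
    raise RuntimeError("could not untangle jittered mesh; reduce jitter")


def build_wedge(dims=(40.0, 10.0), target_edge=0.5, jitter=0.25,
                seed=0, snap_planes=()) -> Mesh:
    """Jittered structured wedge mesh with transmural coordinates.

    ``dims``: (length_x[, width_y], wall_thickness) in mm — 2 entries give
    a 2D transmural sheet, 3 entries a 3D slab.  Interior nodes are
    perturbed by ``jitter * target_edge`` (uniform per axis, seeded) to
    avoid grid-aligned propagation artefacts; boundary-face nodes stay on
    the lattice so the transmural coordinate is exact there.

    ``snap_planes``: transmural coordinates (mm) to which the nearest
    lattice plane is moved and at which jitter of the transmural component
    is suppressed — used to boundary-fit internal material interfaces
    (e.g. the substrate thickness cap) so that element-wise region
    membership does not leave jagged leak paths across them.
    """
    dims = tuple(float(v) for v in dims)
    if target_edge > min(dims) / 4:
        raise ValueError("target_edge must be <= min(dims)/4")
    if not (0.0 <= jitter < 0.4):
        raise ValueError("jitter must be in [0, 0.4)")
    axes = [_axis_coords(L, target_edge) for L in dims]
    wallax = axes[-1]
    for z in snap_planes:
        if not (0.0 < z < dims[-1]):
            raise ValueError("snap plane outside the wall")
        k = int(np.argmin(np.abs(wallax - z)))
        k = min(max(k, 1), len(wallax) - 2)
        wallax[k] = float(z)
    shape = tuple(len(a) for a in axes)
    lattice = _grid_points(axes)
    cells = _grid_cells(shape)

    idx = np.unravel_index(np.arange(lattice.shape[0]), shape)
    interior = np.ones(lattice.shape[0], dtype=bool)
    for k, nk in enumerate(shape):
        interior &= (idx[k] > 0) & (idx[k] < nk - 1)

    rng = np.random.default_rng(seed)
    pts = lattice.copy()
    disp = rng.uniform(-1.0, 1.0, size=lattice.shape) * jitter * target_edge
    for z in snap_planes:   # keep interface planes flat transmurally
        disp[lattice[:, -1] == float(z), -1] = 0.0
    pts[interior] += disp[interior]
    pts = _fix_degenerate(pts, cells, lattice, interior)

    # transmural depth and apex-base coordinate from lattice indices:
    # exact 0/1 on the faces and monotone across the wall by construction
    depth = idx[-1] / (shape[-1] - 1)
    apexbase = idx[0] / (shape[0] - 1)
    mesh = Mesh(points=pts, cells=cells, depth=depth, apexbase=apexbase,
                meta={"dims": dims, "target_edge": target_edge,
                      "jitter": jitter, "seed": seed, "axes": axes,
                      "shape": shape, "lattice": lattice})
    mesh.meta["mean_edge"] = float(mesh.edge_lengths().mean())
    return mesh


def build_strand(length=30.0, edge=0.25) -> Mesh:
    """1D cable mesh for conduction-velocity studies."""
    x = _axis_coords(length, edge)
    pts = x.reshape(-1, 1)
    cells = _grid_cells((len(x),))
    depth = np.zeros(len(x))
    return Mesh(points=pts, cells=cells, depth=depth,
                apexbase=x / x[-1], meta={"dims": (length,), "axes": [x],
                                          "target_edge": edge})


def assign_variants(depth: np.ndarray) -> np.ndarray:
    """Endo/epi assignment: inner quarter of the wall (depth < 0.25) is
    endocardial, the outer three quarters epicardial.  Returns a boolean
    array, True = epicardial."""
    depth = np.asarray(depth)
    if np.any((depth < 0) | (depth > 1)):
        raise ValueError("depth must lie in [0, 1]")
    return depth >= 0.25


def assign_fibers(mesh: Mesh, endo_angle=60.0, epi_angle=-60.0) -> np.ndarray:
    """Per-element unit fiber vectors with linear transmural rotation.

    3D: the fiber lies in the wall-tangent plane, rotated from
    ``endo_angle`` to ``epi_angle`` (degrees, about the wall normal) as
    depth goes 0 -> 1.  2D (transmural sheet) and 1D: the in-plane fiber
    runs along the first axis (rotation is out of plane there).
    """
    for ang in (endo_angle, epi_angle):
        if not (-90.0 < ang <= 90.0):
            raise ValueError("fiber angles must lie in (-90, 90] degrees")
    el_depth = mesh.depth[mesh.cells].mean(axis=1)
    f = np.zeros((len(mesh.cells), mesh.dim))
    if mesh.dim < 3:
        f[:, 0] = 1.0
        return f
    theta = np.deg2rad(endo_angle + (epi_angle - endo_angle) * el_depth)
    f[:, 0] = np.cos(theta)
    f[:, 1] = np.sin(theta)
    return f


def gks_gradient(apexbase: np.ndarray) -> np.ndarray:
    """Linear 3-fold apex->base increase of the IKs maximal conductance:
    scale 1 at the apex (a=0) to 3 at the base (a=1)."""
    a = np.asarray(apexbase)
    return 1.0 + 2.0 * a


@dataclass
class SubstrateSpec:
    """Epicardial substrate patch (delayed-depolarization parameters).

    ``center``: in-plane coordinates of the patch midpoint on the
    epicardial face (defaults to the face center).  Longitudinal
    conductivity falls linearly from ``sigma_l_edge`` at the rim to
    ``sigma_l_center`` at the midpoint; transverse conductivity is divided
    by ``transverse_attenuation``.
    """
    diameter: float = 20.0
    max_thickness: float = 2.2
    center: tuple | None = None
    sigma_l_edge: float = 0.09
    sigma_l_center: float = 0.009
    transverse_attenuation: float = 1000.0
    profile: str = "uniform"   # or "lens" (spherical-cap thickness taper)

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.sigma_l_center >= self.sigma_l_edge:
            raise ValueError("sigma_l_center must be < sigma_l_edge")
        if self.profile not in ("uniform", "lens"):
            raise ValueError("profile must be 'uniform' or 'lens'")


@dataclass
class ConductivityField:
    """Per-element monodomain conductivities (S/m)."""
    sigma_l: np.ndarray
    sigma_t: np.ndarray

    def __post_init__(self):
        if np.any(self.sigma_l <= 0) or np.any(self.sigma_t <= 0):
            raise ValueError("conductivities must be positive")


def baseline_conductivity(mesh: Mesh, sigma_l=0.18, sigma_t=0.08):
    n = len(mesh.cells)
    return ConductivityField(np.full(n, sigma_l), np.full(n, sigma_t))


def define_substrate(mesh: Mesh, spec: SubstrateSpec,
                     base: ConductivityField | None = None):
    """Mark substrate elements and build the reduced-conductivity field.

    Substrate: elements whose centroid lies within ``diameter/2`` of the
    patch center (distance in the epicardial plane) and within the
    thickness cap of the epicardial surface.  Returns (element mask,
    ConductivityField); elements outside the substrate keep the baseline
    values exactly.
    """
    if base is None:
        base = baseline_conductivity(mesh)
    dims = mesh.meta["dims"]
    wall = dims[-1]
    if spec.max_thickness > wall:
        raise ValueError("substrate thicker than the wall")
    cen = mesh.centroids()
    inplane = cen[:, :-1]
    if spec.center is None:
        center = np.array([0.5 * d for d in dims[:-1]])
    else:
        center = np.asarray(spec.center, dtype=float)
    r = np.linalg.norm(inplane - center, axis=1)
    dist_from_epi = wall - cen[:, -1]
    R = spec.diameter / 2.0
    if spec.profile == "uniform":
        cap = np.full_like(r, spec.max_thickness)
    else:  # lens: spherical-cap taper, max at center, 0 at rim
        cap = spec.max_thickness * np.sqrt(np.clip(1.0 - (r / R) ** 2,
                                                   0.0, None))
    mask = (r <= R) & (dist_from_epi <= cap)
    if not np.any(mask):
        raise ValueError("substrate does not intersect mesh")
    sigma_l = base.sigma_l.copy()
    sigma_t = base.sigma_t.copy()
    sigma_l[mask] = (spec.sigma_l_center
                     + (spec.sigma_l_edge - spec.sigma_l_center)
                     * (r[mask] / R))
    sigma_t[mask] = base.sigma_t[mask] / spec.transverse_attenuation
    return mask, ConductivityField(sigma_l, sigma_t)


def substrate_nodes(mesh: Mesh, spec: SubstrateSpec) -> np.ndarray:
    """Nodes inside the substrate region (for G_to modification/ablation)."""
    dims = mesh.meta["dims"]
    wall = dims[-1]
    inplane = mesh.points[:, :-1]
    if spec.center is None:
        center = np.array([0.5 * d for d in dims[:-1]])
    else:
        center = np.asarray(spec.center, dtype=float)
    r = np.linalg.norm(inplane - center, axis=1)
    dist_from_epi = wall - mesh.points[:, -1]
    R = spec.diameter / 2.0
    if spec.profile == "uniform":
        cap = np.full_like(r, spec.max_thickness)
    else:
        cap = spec.max_thickness * np.sqrt(np.clip(1.0 - (r / R) ** 2,
                                                   0.0, None))
    return np.flatnonzero((r <= R) & (dist_from_epi <= cap + 1e-9))


# ---------------------------------------------------------------------------
# Torso volume conductor
# ---------------------------------------------------------------------------

@dataclass
class TorsoModel:
    mesh: Mesh
    sigma: np.ndarray                  # per-element isotropic conductivity
    electrodes: dict                   # name -> torso node id
    heart_node_map: np.ndarray         # heart node id -> torso node id
    heart: Mesh
    meta: dict = field(default_factory=dict)

    @property
    def limb_leads(self):
        return [k for k in ("LA", "RA", "LL") if k in self.electrodes]

    @property
    def precordial_leads(self):
        return [k for k in self.electrodes if k.startswith("V")]


def _extend_axis(coords, pad_lo, pad_hi, growth=1.6):
    """Extend a monotone coordinate array by geometrically coarsening
    steps on both sides until the padding is covered."""
    h = coords[1] - coords[0]
    lo = [coords[0]]
    step = h
    while coords[0] - lo[-1] < pad_lo:
        step *= growth
        lo.append(lo[-1] - step)
    hi = [coords[-1]]
    step = coords[-1] - coords[-2]
    while hi[-1] - coords[-1] < pad_hi:
        step *= growth
        hi.append(hi[-1] + step)
    return np.concatenate([lo[:0:-1], coords, hi[1:]])


def _snap_to_boundary_node(torso_pts, shape, target, axis, side):
    """Nearest node on the given boundary face of the structured torso."""
    idx = np.unravel_index(np.arange(len(torso_pts)), shape)
    face = idx[axis] == (0 if side == "lo" else shape[axis] - 1)
    cand = np.flatnonzero(face)
    d = np.linalg.norm(torso_pts[cand] - target, axis=1)
    return int(cand[np.argmin(d)])


def build_torso(heart: Mesh, padding=40.0, organ_blocks=None,
                background_sigma=BACKGROUND_SIGMA,
                substrate_center=None, growth=1.6) -> TorsoModel:
    """Conforming torso box around the heart wedge with electrodes.

    The torso lattice reuses the heart's axis coordinates inside the heart
    block (so heart nodes are a subset of torso nodes, with their jittered
    positions) and coarsens geometrically outward by ``padding`` mm on
    every side.  The face beyond the epicardium (last axis, high side) is
    the anterior chest face carrying the precordial-style electrode grid.

    ``organ_blocks``: optional list of (name, (lo corner, hi corner),
    sigma) axis-aligned boxes overriding the homogeneous conductivity.
    """
    dims = heart.meta["dims"]
    if padding < 2.0 * dims[-1]:
        raise ValueError("padding must be >= 2x heart extent toward the "
                         "electrode face")
    axes_h = heart.meta["axes"]
    axes_t = [_extend_axis(a, padding, padding, growth=growth)
              for a in axes_h]
    shape_t = tuple(len(a) for a in axes_t)
    pts = _grid_points(axes_t)
    cells = _grid_cells(shape_t)

    # map heart lattice nodes into the torso lattice and transplant the
    # heart's jittered coordinates
    offs = [int(np.searchsorted(axes_t[k], axes_h[k][0] - 1e-12))
            for k in range(len(axes_t))]
    shape_h = heart.meta["shape"]
    idx_h = np.unravel_index(np.arange(heart.n_nodes), shape_h)
    strides_t = np.ones(len(shape_t), dtype=np.int64)
    for k in range(len(shape_t) - 2, -1, -1):
        strides_t[k] = strides_t[k + 1] * shape_t[k + 1]
    heart_map = sum((idx_h[k] + offs[k]) * strides_t[k]
                    for k in range(len(shape_t)))
    pts[heart_map] = heart.points

    torso_mesh = Mesh(points=pts, cells=cells,
                      meta={"axes": axes_t, "shape": shape_t,
                            "dims_heart": dims})
    sigma = np.full(len(cells), float(background_sigma))
    if organ_blocks:
        cen = torso_mesh.centroids()
        for name, (lo, hi), s in organ_blocks:
            lo = np.asarray(lo, float)
            hi = np.asarray(hi, float)
            inside = np.all((cen >= lo) & (cen <= hi), axis=1)
            sigma[inside] = float(s)

    # electrodes on the anterior face (last axis, high side)
    d = heart.dim
    if substrate_center is None:
        substrate_center = np.array([0.5 * v for v in dims[:-1]])
    else:
        substrate_center = np.asarray(substrate_center, float)
    z_top = axes_t[-1][-1]
    electrodes = {}
    row_pitch = max(dims[0] / 4.0, 8.0)
    rows = {"ICS2": -row_pitch, "ICS3": 0.0, "ICS4": row_pitch}
    if d == 3:
        col_pitch = max(dims[1] / 4.0, 8.0)
        cols = {"V1": -col_pitch, "V2": 0.0}
        for rname, dx in rows.items():
            for cname, dy in cols.items():
                tgt = np.array([substrate_center[0] + dx,
                                substrate_center[1] + dy, z_top])
                electrodes[f"{cname}_{rname}"] = _snap_to_boundary_node(
                    pts, shape_t, tgt, axis=d - 1, side="hi")
    else:
        for rname, dx in rows.items():
            tgt = np.array([substrate_center[0] + dx, z_top])
            electrodes[f"V2_{rname}"] = _snap_to_boundary_node(
                pts, shape_t, tgt, axis=d - 1, side="hi")
    # limb electrodes at remote boundary positions
    lo0, hi0 = axes_t[0][0], axes_t[0][-1]
    z_bot = axes_t[-1][0]
    if d == 3:
        mid1 = 0.5 * (axes_t[1][0] + axes_t[1][-1])
        electrodes["RA"] = _snap_to_boundary_node(
            pts, shape_t, np.array([lo0, mid1, z_top]), d - 1, "hi")
        electrodes["LA"] = _snap_to_boundary_node(
            pts, shape_t, np.array([hi0, mid1, z_top]), d - 1, "hi")
        electrodes["LL"] = _snap_to_boundary_node(
            pts, shape_t, np.array([hi0, mid1, z_bot]), d - 1, "lo")
        electrodes["REF"] = _snap_to_boundary_node(
            pts, shape_t, np.array([lo0, mid1, z_bot]), d - 1, "lo")
    else:
        electrodes["RA"] = _snap_to_boundary_node(
            pts, shape_t, np.array([lo0, z_top]), d - 1, "hi")
        electrodes["LA"] = _snap_to_boundary_node(
            pts, shape_t, np.array([hi0, z_top]), d - 1, "hi")
        electrodes["LL"] = _snap_to_boundary_node(
            pts, shape_t, np.array([hi0, z_bot]), d - 1, "lo")
        electrodes["REF"] = _snap_to_boundary_node(
            pts, shape_t, np.array([lo0, z_bot]), d - 1, "lo")

    model = TorsoModel(mesh=torso_mesh, sigma=sigma, electrodes=electrodes,
                       heart_node_map=heart_map, heart=heart,
                       meta={"padding": padding,
                             "background_sigma": background_sigma,
                             "substrate_center": tuple(substrate_center)})
    if not np.allclose(torso_mesh.points[heart_map], heart.points):
        raise AssertionError("heart nodes are not a subset of torso nodes")
    return model
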