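"""Surface meshes: data model, synthetic left-atrial geometry, LA sections, I/O.

Patient CT-derived atrial geometries are emulated by a parametric generator:
an ellipsoidal shell (scaled to a realistic anteroposterior LA dimension of
~48 mm) with four pulmonary-vein (PV) ostia extended into short tubes, an open
mitral annulus, and an appendage protrusion.  Every node is labeled with one
of ten anatomical sections used throughout the analysis:

R1 septum, R2 anterior wall, R3 LA appendage, R4 peri-mitral area,
R5 posterior inferior wall, R6 posterior wall, R7-R10 the left upper/lower
and right upper/lower PVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import ConvexHull

UNLABELED = 0
REGION_NAMES = {
    0: "UNLABELED",
    1: "R1_septum", 2: "R2_anterior", 3: "R3_appendage", 4: "R4_perimitral",
    5: "R5_posterior_inferior", 6: "R6_posterior",
    7: "R7_left_upper_pv", 8: "R8_left_lower_pv",
    9: "R9_right_upper_pv", 10: "R10_right_lower_pv",
}
PV_REGIONS = (7, 8, 9, 10)
N_REGIONS = 10


class MeshError(ValueError):
    """Invalid mesh, failed generation, or malformed mesh file."""


@dataclass
class SurfaceMesh:
    """Triangulated surface with lumped node areas and region labels.

    Node areas are barycentric-lumped (one third of every incident triangle),
    so they are positive and partition the total triangle area exactly.
    """

    points: np.ndarray                 # (n, 3) mm
    triangles: np.ndarray              # (m, 3) int
    region: np.ndarray = None          # (n,) int, 0 = unlabeled
    boundary: np.ndarray = None        # (n,) bool, orifice rims
    node_area: np.ndarray = None       # (n,) mm^2
    point_data: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        n = len(self.points)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be an (m, 3) index array")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= n:
            raise MeshError("triangle indices outside node range")
        t = self.triangles
        if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
            raise MeshError("degenerate triangle with repeated vertex")
        if self.region is None:
            self.region = np.zeros(n, dtype=np.int16)
        else:
            self.region = np.asarray(self.region, dtype=np.int16)
        if self.node_area is None:
            self.node_area = self._lumped_areas()
        if np.any(self.node_area[self._referenced_mask()] <= 0):
            raise MeshError("non-positive lumped node area")
        if self.boundary is None:
            self.boundary = self._boundary_mask()

    # -- construction helpers ------------------------------------------------

    def _referenced_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.points), dtype=bool)
        mask[self.triangles] = True
        return mask

    def triangle_areas(self) -> np.ndarray:
        p = self.points
        t = self.triangles
        c = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
        return 0.5 * np.linalg.norm(c, axis=1)

    def _lumped_areas(self) -> np.ndarray:
        ta = self.triangle_areas()
        area = np.zeros(len(self.points))
        for k in range(3):
            np.add.at(area, self.triangles[:, k], ta / 3.0)
        return area

    def edges(self, unique: bool = True) -> np.ndarray:
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0) if unique else e

    def _boundary_edges(self) -> np.ndarray:
        e = self.edges(unique=False)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def _boundary_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.points), dtype=bool)
        be = self._boundary_edges()
        if len(be):
            mask[be] = True
        return mask

    # -- descriptors ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def euler_characteristic(self) -> int:
        return self.n_nodes - len(self.edges()) + self.n_triangles

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex index loops of every open boundary."""
        be = self._boundary_edges()
        if len(be) == 0:
            return []
        nbr: dict[int, list[int]] = {}
        for a, b in be:
            nbr.setdefault(int(a), []).append(int(b))
            nbr.setdefault(int(b), []).append(int(a))
        seen = set()
        loops = []
        for start in nbr:
            if start in seen:
                continue
            loop = [start]
            seen.add(start)
            prev, cur = None, start
            while True:
                nxt = [x for x in nbr[cur] if x != prev]
                if not nxt or nxt[0] in seen:
                    break
                prev, cur = cur, nxt[0]
                loop.append(cur)
                seen.add(cur)
            loops.append(np.array(loop))
        return loops

    def min_angle_deg(self) -> float:
        p = self.points
        t = self.triangles
        angles = []
        for k in range(3):
            a = p[t[:, k]]
            b = p[t[:, (k + 1) % 3]]
            c = p[t[:, (k + 2) % 3]]
            u, v = b - a, c - a
            cosang = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))

    def adjacency(self) -> sp.csr_matrix:
        """Edge graph weighted by Euclidean edge length (for geodesics)."""
        e = self.edges()
        w = np.linalg.norm(self.points[e[:, 0]] - self.points[e[:, 1]], axis=1)
        n = self.n_nodes
        g = sp.coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                         np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
        return g.tocsr()

    def region_areas(self) -> dict[int, float]:
        out = {}
        for r in range(1, N_REGIONS + 1):
            out[r] = float(self.node_area[self.region == r].sum())
        return out

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.points.copy(), self.triangles.copy(),
                           self.region.copy(), self.boundary.copy(),
                           self.node_area.copy(),
                           {k: v.copy() for k, v in self.point_data.items()})


# ---------------------------------------------------------------------------
# planar substrates for calibration
# ---------------------------------------------------------------------------

def make_sheet(nx: int, ny: int, dx: float) -> SurfaceMesh:
    """Planar right-triangulated rectangular sheet in the z=0 plane."""
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must be >= 2")
    xs, ys = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dx, indexing="xy")
    pts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * ny)])
    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx + 1
            d = a + nx
            tris.append((a, b, c))
            tris.append((a, c, d))
    return SurfaceMesh(pts, np.array(tris))


def make_cable(n: int, dx: float) -> SurfaceMesh:
    """Thin two-row strip of length (n-1)*dx for 1-D propagation."""
    return make_sheet(n, 2, dx)


# ---------------------------------------------------------------------------
# synthetic left atrium
# ---------------------------------------------------------------------------

# canonical orifice and landmark directions on the parameter sphere
# axes: +x right / -x left, +y posterior / -y anterior, +z superior
_PV_DIRS = {
    7: np.array([-0.62, 0.55, 0.56]),   # left upper (superior) PV
    8: np.array([-0.62, 0.55, -0.56]),  # left lower (inferior) PV
    9: np.array([0.62, 0.55, 0.56]),    # right upper PV
    10: np.array([0.62, 0.55, -0.56]),  # right lower PV
}
_MITRAL_DIR = np.array([0.0, -0.55, -0.84])
_APPENDAGE_DIR = np.array([-0.65, -0.55, 0.52])
_LANDMARK_DIRS = {
    1: np.array([1.0, -0.15, 0.0]),     # septum
    2: np.array([0.0, -1.0, 0.15]),     # anterior wall
    5: np.array([0.0, 0.75, -0.66]),    # posterior inferior wall
    6: np.array([0.0, 0.95, 0.32]),     # posterior wall
}


@dataclass(frozen=True)
class SyntheticLAParams:
    """Generator parameters for the synthetic left atrium.

    Defaults give an anteroposterior extent of ~48 mm (matching the clinical
    LA dimension the study population reports), four 5.5-mm PV ostia with
    10-mm tubes, a 12-mm open mitral annulus and an appendage bump.  ``seed``
    fixes the vertex jitter; with ``jitter_mm = 0`` the mesh is seed-free.
    """

    semi_axes: tuple = (32.0, 24.0, 27.0)   # mm; y-axis = anteroposterior
    pv_radius_mm: float = 5.5
    pv_tube_length_mm: float = 10.0
    mitral_radius_mm: float = 12.0
    appendage_neck_mm: float = 7.0
    appendage_tip_mm: float = 4.5
    appendage_depth_mm: float = 26.0
    target_edge_length_mm: float = 2.0
    jitter_mm: float = 0.25
    roughness_mm: float = 2.5
    roughness_waves: int = 12
    roughness_freq: float = 6.0
    seed: int = 0
    smoothing_iters: int = 6

    def __post_init__(self):
        for name in ("pv_radius_mm", "pv_tube_length_mm", "mitral_radius_mm",
                     "target_edge_length_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be > 0")


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _sphere_triangulation(n: int, iters: int) -> tuple[np.ndarray, np.ndarray]:
    """Near-uniform triangulated unit sphere with ``n`` vertices."""
    pts = _fibonacci_sphere(n)
    for _ in range(iters):
        hull = ConvexHull(pts)
        tris = hull.simplices
        acc = np.zeros_like(pts)
        cnt = np.zeros(n)
        for k in range(3):
            a = tris[:, k]
            for kk in (1, 2):
                b = tris[:, (k + kk) % 3]
                np.add.at(acc, a, pts[b])
                np.add.at(cnt, a, 1.0)
        pts = acc / cnt[:, None]
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    hull = ConvexHull(pts)
    tris = hull.simplices.astype(np.int64)
    # orient all faces outward
    cents = pts[tris].mean(axis=1)
    norms = np.cross(pts[tris[:, 1]] - pts[tris[:, 0]],
                     pts[tris[:, 2]] - pts[tris[:, 0]])
    flip = np.einsum("ij,ij->i", cents, norms) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return pts, tris


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    p = 1.6075
    return 4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)


def make_synthetic_la(params: SyntheticLAParams = SyntheticLAParams()) -> SurfaceMesh:
    """Closed-but-for-five-orifices LA-like surface, labeled R1-R10.

    The result has exactly 5 boundary loops (4 PV ostia, mitral annulus),
    hence Euler characteristic V - E + F = 2 - 5 = -3, and is bit-for-bit
    deterministic for a given parameter set.
    """
    a, b, c = params.semi_axes
    h = params.target_edge_length_mm
    n_target = int(2.0 * _ellipsoid_area(a, b, c) / (np.sqrt(3.0) * h * h))
    u, tris = _sphere_triangulation(max(200, n_target), params.smoothing_iters)

    pts = u * np.array([a, b, c])
    radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)

    rng = np.random.default_rng(params.seed)
    # anatomical surface irregularity: seeded smooth low-wavenumber radial
    # field (patient CT atria are far from smooth ellipsoids); kept away from
    # the orifice rims so tubes attach cleanly
    if params.roughness_mm > 0 and params.roughness_waves > 0:
        f = np.zeros(len(u))
        for _ in range(params.roughness_waves):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            om = params.roughness_freq * rng.uniform(0.5, 1.5)
            ph = rng.uniform(0, 2 * np.pi)
            f += np.cos(om * (u @ d) + ph)
        f = (f - f.mean()) / max(f.std(), 1e-12)
        damp = np.ones(len(u))
        for dirs in list(_PV_DIRS.values()) + [_MITRAL_DIR, _APPENDAGE_DIR]:
            dn = dirs / np.linalg.norm(dirs)
            th = np.arccos(np.clip(u @ dn, -1, 1))
            damp = np.minimum(damp, np.clip(th / 0.5, 0.0, 1.0))
        pts = pts + radial * (params.roughness_mm * f * damp)[:, None]

    # seeded jitter on interior vertices (before holes, so rims stay clean)
    if params.jitter_mm > 0:
        pts = pts + rng.uniform(-params.jitter_mm, params.jitter_mm, pts.shape)

    # cut orifices: 4 PV ostia, the open mitral annulus, and the appendage
    # ostium (which receives a closed, narrow-necked pouch)
    scale = np.array([a, b, c])
    orifices = []
    for rid, d in _PV_DIRS.items():
        dn = d / np.linalg.norm(d)
        orifices.append((rid, dn, params.pv_radius_mm / np.linalg.norm(dn * scale),
                         "pv"))
    dm = _MITRAL_DIR / np.linalg.norm(_MITRAL_DIR)
    orifices.append((0, dm, params.mitral_radius_mm / np.linalg.norm(dm * scale),
                     "mitral"))
    da = _APPENDAGE_DIR / np.linalg.norm(_APPENDAGE_DIR)
    orifices.append((3, da, params.appendage_neck_mm / np.linalg.norm(da * scale),
                     "appendage"))

    remove = np.zeros(len(pts), dtype=bool)
    for _, d, th, _kind in orifices:
        remove |= np.arccos(np.clip(u @ d, -1, 1)) < th
    keep = ~remove
    new_id = -np.ones(len(pts), dtype=np.int64)
    new_id[keep] = np.arange(keep.sum())
    tri_keep = keep[tris].all(axis=1)
    tris2 = new_id[tris[tri_keep]]
    pts2 = pts[keep]
    region = np.zeros(len(pts2), dtype=np.int16)

    mesh = SurfaceMesh(pts2, tris2, region)
    loops = mesh.boundary_loops()
    if len(loops) != 6:
        raise MeshError(f"generation failure: {len(loops)} boundary loops "
                        "(expected 6 before tube attachment); reduce jitter "
                        "or refine the mesh")

    # attach tubes: open PV sleeves, and the capped appendage pouch whose
    # narrow neck acts as the anatomical conduction bottleneck
    all_pts = [pts2]
    all_tris = [tris2]
    all_region = [region]
    next_id = len(pts2)
    loop_centroids = np.array([pts2[lp].mean(axis=0) for lp in loops])
    for rid, d, _th, kind in orifices:
        if kind == "mitral":
            continue
        scaled = d * scale
        which = int(np.argmin(np.linalg.norm(loop_centroids - scaled, axis=1)))
        loop = loops[which]
        ring_prev = loop.copy()
        cen = pts2[loop].mean(axis=0)
        axis = d / np.linalg.norm(d)
        e1 = np.cross(axis, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(axis, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        rel = pts2[loop] - cen
        phi = np.arctan2(rel @ e2, rel @ e1)
        # morph toward evenly spaced angles (rank order) so the jagged rim's
        # uneven spacing does not propagate skinny triangles up the tube
        rank = np.empty(len(phi), dtype=float)
        rank[np.argsort(phi)] = np.arange(len(phi))
        phi_even = phi[np.argsort(phi)[0]] + 2 * np.pi * rank / len(phi)
        if kind == "pv":
            length = params.pv_tube_length_mm
            r_of_t = lambda t: params.pv_radius_mm  # noqa: E731
        else:
            length = params.appendage_depth_mm
            r_of_t = lambda t: ((1 - t) * params.appendage_neck_mm  # noqa: E731
                                + t * params.appendage_tip_mm)
        n_rings = max(2, int(round(length / h)))
        m = len(loop)
        base = pts2[loop]
        for s in range(1, n_rings + 1):
            t = s / n_rings
            ang = (1 - t) * phi + t * phi_even
            circ = (cen + r_of_t(t)
                    * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2))
            ring_pts = (1 - t) * base + t * circ + axis * (length * t)
            ids = np.arange(next_id, next_id + m)
            next_id += m
            all_pts.append(ring_pts)
            all_region.append(np.full(m, rid, dtype=np.int16))
            tri = []
            for k in range(m):
                k2 = (k + 1) % m
                tri.append((ring_prev[k], ring_prev[k2], ids[k2]))
                tri.append((ring_prev[k], ids[k2], ids[k]))
            all_tris.append(np.array(tri))
            ring_prev = ids
        if kind == "appendage":
            # cap the pouch with an apex fan (apex one ring-spacing above)
            apex = cen + axis * (length + length / n_rings)
            all_pts.append(apex[None, :])
            all_region.append(np.full(1, rid, dtype=np.int16))
            tri = [(ring_prev[k], ring_prev[(k + 1) % m], next_id)
                   for k in range(m)]
            all_tris.append(np.array(tri))
            next_id += 1

    mesh = SurfaceMesh(np.vstack(all_pts),
                       np.vstack(all_tris),
                       np.concatenate(all_region))
    loops = mesh.boundary_loops()
    if len(loops) != 5:
        raise MeshError("generation failure after tube attachment")
    if mesh.euler_characteristic() != -3:
        raise MeshError("generation failure: unexpected topology")

    gcomp = connected_components(mesh.adjacency(), directed=False)[0]
    if gcomp != 1:
        raise MeshError("generation failure: disconnected surface")

    landmarks = default_landmarks(mesh, params)
    return partition_regions(mesh, landmarks)


def default_landmarks(mesh: SurfaceMesh,
                      params: SyntheticLAParams = SyntheticLAParams(),
                      ) -> dict[int, np.ndarray]:
    """Seed nodes for the wall sections labeled by geodesic proximity.

    R4 (peri-mitral) is seeded by the whole mitral rim so the section forms
    an annular band; R1/R2/R5/R6 by the surface node nearest each canonical
    landmark direction.  PV (R7-R10) and appendage (R3) nodes are pre-tagged
    by the generator.
    """
    a, b, c = params.semi_axes
    body = ~np.isin(mesh.region, (3,) + PV_REGIONS)  # atrial wall only
    lm: dict[int, np.ndarray] = {}
    for rid, d in _LANDMARK_DIRS.items():
        dn = d / np.linalg.norm(d)
        target = dn * np.array([a, b, c])
        dist = np.linalg.norm(mesh.points - target, axis=1)
        dist[~body] = np.inf
        lm[rid] = np.array([int(np.argmin(dist))])
    # mitral rim = boundary loop nearest the mitral direction
    loops = mesh.boundary_loops()
    dm = _MITRAL_DIR / np.linalg.norm(_MITRAL_DIR)
    cents = np.array([mesh.points[lp].mean(axis=0) for lp in loops])
    which = int(np.argmin(np.linalg.norm(cents - dm * np.array([a, b, c]), axis=1)))
    lm[4] = loops[which]
    return lm


def partition_regions(mesh: SurfaceMesh,
                      landmarks: dict[int, np.ndarray]) -> SurfaceMesh:
    """Label every node with a section R1-R10.

    Pre-tagged PV-tube nodes keep their label; remaining nodes take the label
    of the geodesically nearest landmark seed set (graph geodesics on mesh
    edges), which yields contiguous sections.
    """
    mesh = mesh.copy()
    graph = mesh.adjacency()
    free = mesh.region == UNLABELED
    rids = sorted(landmarks)
    dists = np.full((len(rids), mesh.n_nodes), np.inf)
    for k, rid in enumerate(rids):
        seeds = np.atleast_1d(np.asarray(landmarks[rid], dtype=int))
        d = dijkstra(graph, directed=False, indices=seeds, min_only=True)
        dists[k] = d
    assign = np.argmin(dists, axis=0)
    mesh.region[free] = np.array([rids[k] for k in assign[free]], dtype=np.int16)
    for r in range(1, N_REGIONS + 1):
        if not np.any(mesh.region == r):
            raise MeshError(f"partition failure: empty region {REGION_NAMES[r]}")
    return mesh


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_mesh(mesh: SurfaceMesh, path) -> None:
    """Write PLY/OFF (geometry) or legacy VTK / VTU (geometry + node fields).

    The region labels and any ``point_data`` scalars are stored as per-node
    fields in the VTK formats; PLY and OFF carry geometry only.
    """
    path = str(path)
    ext = path.rsplit(".", 1)[-1].lower()
    if ext in ("ply", "off"):
        import trimesh
        tm = trimesh.Trimesh(vertices=mesh.points, faces=mesh.triangles,
                             process=False)
        tm.export(path)
    elif ext == "vtk":
        _write_vtk(mesh, path)
    elif ext == "vtu":
        _write_vtu(mesh, path)
    else:
        raise MeshError(f"unknown mesh extension .{ext}")


def read_mesh(path) -> SurfaceMesh:
    path = str(path)
    ext = path.rsplit(".", 1)[-1].lower()
    if ext in ("ply", "off"):
        import trimesh
        tm = trimesh.load(path, process=False, force="mesh")
        faces = np.asarray(tm.faces)
        if faces.shape[1] != 3:
            raise MeshError(f"{path}: non-triangle face encountered")
        return SurfaceMesh(np.asarray(tm.vertices, dtype=float), faces)
    if ext == "vtk":
        return _read_vtk(path)
    raise MeshError(f"unknown or unsupported mesh extension .{ext}")


def _write_vtk(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nlafib surface mesh\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.points:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        m = mesh.n_triangles
        f.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"POINT_DATA {mesh.n_nodes}\n")
        f.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(r)) for r in mesh.region) + "\n")
        for name, arr in mesh.point_data.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(f"{v:.9g}" for v in arr) + "\n")


def _read_vtk(path: str) -> SurfaceMesh:
    with open(path) as f:
        lines = f.read().splitlines()
    idx = 0

    def fail(msg):
        raise MeshError(f"{path}:{idx + 1}: {msg}")

    toks_all = []
    line_of_tok = []
    for ln, line in enumerate(lines):
        for tk in line.split():
            toks_all.append(tk)
            line_of_tok.append(ln)
    pos = 0

    def next_tok():
        nonlocal pos, idx
        if pos >= len(toks_all):
            idx = len(lines) - 1
            fail("unexpected end of file")
        tk = toks_all[pos]
        idx = line_of_tok[pos]
        pos += 1
        return tk

    # header: skip until DATASET
    while True:
        tk = next_tok()
        if tk.upper() == "DATASET":
            kind = next_tok().upper()
            if kind != "POLYDATA":
                fail(f"unsupported dataset {kind}")
            break
    points = None
    tris = None
    region = None
    fields = {}
    n_pts = 0
    while pos < len(toks_all):
        tk = next_tok().upper()
        if tk == "POINTS":
            n_pts = int(next_tok())
            next_tok()  # dtype
            vals = [float(next_tok()) for _ in range(3 * n_pts)]
            points = np.array(vals).reshape(n_pts, 3)
        elif tk == "POLYGONS":
            m = int(next_tok())
            next_tok()  # total size
            rows = []
            for _ in range(m):
                k = int(next_tok())
                if k != 3:
                    fail(f"non-triangle face with {k} vertices")
                rows.append([int(next_tok()) for _ in range(3)])
            tris = np.array(rows)
        elif tk == "POINT_DATA":
            n = int(next_tok())
            if n != n_pts:
                fail("POINT_DATA size mismatch")
        elif tk == "SCALARS":
            name = next_tok()
            next_tok()  # dtype
            ncomp = next_tok()
            if ncomp.upper() == "LOOKUP_TABLE":
                next_tok()
            else:
                lt = next_tok()
                if lt.upper() == "LOOKUP_TABLE":
                    next_tok()
            vals = np.array([float(next_tok()) for _ in range(n_pts)])
            if name == "region":
                region = vals.astype(np.int16)
            else:
                fields[name] = vals
        else:
            fail(f"unexpected token {tk}")
    if points is None or tris is None:
        fail("missing POINTS or POLYGONS block")
    return SurfaceMesh(points, tris, region, point_data=fields)


def _write_vtu(mesh: SurfaceMesh, path: str) -> None:
    n, m = mesh.n_nodes, mesh.n_triangles
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" '
                'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        f.write(f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n')
        f.write('<Points><DataArray type="Float64" NumberOfComponents="3" '
                'format="ascii">\n')
        for p in mesh.points:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write("</DataArray></Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for t in mesh.triangles:
            f.write(f"{t[0]} {t[1]} {t[2]}\n")
        f.write('</DataArray>\n<DataArray type="Int64" Name="offsets" '
                'format="ascii">\n')
        f.write(" ".join(str(3 * (k + 1)) for k in range(m)) + "\n")
        f.write('</DataArray>\n<DataArray type="UInt8" Name="types" '
                'format="ascii">\n')
        f.write(" ".join("5" for _ in range(m)) + "\n")
        f.write("</DataArray>\n</Cells>\n<PointData>\n")
        f.write('<DataArray type="Int32" Name="region" format="ascii">\n')
        f.write(" ".join(str(int(r)) for r in mesh.region) + "\n")
        f.write("</DataArray>\n")
        for name, arr in mesh.point_data.items():
            f.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
            f.write(" ".join(f"{v:.9g}" for v in arr) + "\n")
            f.write("</DataArray>\n")
        f.write("</PointData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
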