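"""Triangulated interfaces, nested head models, sources and sensors.

All geometric quantities are in SI units (meters).  Interfaces are closed,
consistently oriented triangle meshes with outward normals; a head model is
an ordered list of strictly nested interfaces, innermost first, with one
conductivity per enclosed domain and zero conductivity outside.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TriangleMesh",
    "HeadModel",
    "DipoleSet",
    "SurfaceSource",
    "EITInjection",
    "SensorSet",
    "ValidationReport",
    "make_icosphere",
    "make_random_sphere_mesh",
    "validate_mesh",
    "check_nesting",
    "project_electrodes",
    "nearest_triangle",
    "locate_domain",
    "winding_number",
    "OUTSIDE",
]

#: Sentinel returned by :func:`locate_domain` for points outside the head.
OUTSIDE = 0

#: Default minimum admissible distance from a point source to any interface.
DEFAULT_EPS = 1e-6


@dataclass(frozen=True)
class TriangleMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (nv, 3) float array, meters.
    triangles : (nt, 3) int array of 0-based vertex indices.  For closed
        surfaces the triangles must be consistently oriented so that normals
        point outward.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        t = np.ascontiguousarray(np.asarray(self.triangles, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (nv, 3) array")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be an (nt, 3) array")
        if not np.isfinite(v).all():
            raise ValueError("non-finite vertex coordinates")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle index out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The three (nt, 3) corner arrays of every triangle."""
        v, t = self.vertices, self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    @property
    def face_normals(self) -> np.ndarray:
        """(nt, 3) unit normals, right-hand rule on the vertex order."""
        p0, p1, p2 = self.corners
        n = np.cross(p1 - p0, p2 - p0)
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @property
    def areas(self) -> np.ndarray:
        p0, p1, p2 = self.corners
        return 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)

    @property
    def centroids(self) -> np.ndarray:
        p0, p1, p2 = self.corners
        return (p0 + p1 + p2) / 3.0

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def signed_volume(self) -> float:
        """Volume enclosed by the surface; positive for outward orientation."""
        p0, p1, p2 = self.corners
        return float(np.einsum("ij,ij->i", p0, np.cross(p1, p2)).sum() / 6.0)

    def edge_set(self) -> np.ndarray:
        """All directed edges, one row (a, b) per triangle edge."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def vertex_areas(self) -> np.ndarray:
        """Mass-lumped vertex areas (one third of the adjacent triangle area)."""
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.triangles.ravel(),
                  np.repeat(self.areas / 3.0, 3))
        return out

    def bounding_radius(self) -> float:
        return float(np.linalg.norm(self.vertices, axis=1).max())


# ---------------------------------------------------------------------------
# mesh generators
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts[0])
    tris = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return verts, tris


MAX_ICOSPHERE_LEVEL = 7


def make_icosphere(radius: float, level: int) -> TriangleMesh:
    """Regular sphere mesh by recursive icosahedron subdivision.

    The result has ``10 * 4**level + 2`` vertices and ``20 * 4**level``
    triangles, all vertices at distance ``radius`` from the origin, outward
    orientation.  Deterministic.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    level = int(level)
    if level < 0:
        raise ValueError("level must be non-negative")
    if level > MAX_ICOSPHERE_LEVEL:
        raise ValueError(f"level capped at {MAX_ICOSPHERE_LEVEL}")
    verts, tris = _icosahedron()
    for _ in range(level):
        verts, tris = _subdivide(verts, tris)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return TriangleMesh(verts, tris)


def _subdivide(verts: np.ndarray, tris: np.ndarray):
    """One 1:4 subdivision step; midpoints re-projected onto the unit sphere."""
    cache: dict[tuple[int, int], int] = {}
    verts = [v for v in verts]

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        idx = cache.get(key)
        if idx is None:
            m = verts[a] + verts[b]
            m = m / np.linalg.norm(m)
            idx = len(verts)
            verts.append(m)
            cache[key] = idx
        return idx

    new_tris = []
    for a, b, c in tris:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_tris.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.asarray(verts), np.asarray(new_tris, dtype=np.int64)


def make_random_sphere_mesh(radius: float, n_vertices: int,
                            seed: int) -> TriangleMesh:
    """Convex-hull triangulation of ``n_vertices`` uniform points on a sphere.

    Uniform directions are drawn as normalized 3-D Gaussian samples; the same
    ``(n_vertices, seed)`` pair always returns a bitwise-identical mesh.
    """
    from scipy.spatial import ConvexHull

    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        pts = rng.standard_normal((n_vertices, 3))
        norms = np.linalg.norm(pts, axis=1)
        if (norms < 1e-12).any():
            continue
        pts = pts / norms[:, None] * radius
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        if len(hull.vertices) != n_vertices:
            continue  # degenerate sample (coplanar points merged)
        tris = hull.simplices.astype(np.int64)
        # orient all facets outward (centroid of sphere is the origin)
        p0, p1, p2 = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
        n = np.cross(p1 - p0, p2 - p0)
        flip = np.einsum("ij,ij->i", n, (p0 + p1 + p2) / 3.0) < 0
        tris[flip] = tris[flip][:, [0, 2, 1]]
        return TriangleMesh(pts, tris)
    raise RuntimeError("could not build a non-degenerate sphere mesh")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    closed: bool
    oriented: bool
    min_angle: float          # radians
    min_area: float
    euler_characteristic: int
    boundary_edges: list[tuple[int, int]] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (self.closed and self.oriented and self.min_area > 0.0
                and self.euler_characteristic == 2)


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Check closedness, orientation consistency and triangle quality.

    A closed oriented mesh has every undirected edge shared by exactly two
    triangles, traversed in opposite directions.
    """
    edges = mesh.edge_set()
    und = np.sort(edges, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary = [tuple(e) for e in uniq[counts == 1]]
    closed = bool((counts == 2).all())

    # orientation: each directed edge must appear exactly once
    d_uniq, d_counts = np.unique(edges, axis=0, return_counts=True)
    oriented = bool((d_counts == 1).all()) and closed

    p0, p1, p2 = mesh.corners
    areas = mesh.areas
    # minimum interior angle over all triangles
    def angles(a, b, c):
        u, w = b - a, c - a
        cosv = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1))
        return np.arccos(np.clip(cosv, -1.0, 1.0))

    all_angles = np.stack([angles(p0, p1, p2), angles(p1, p2, p0),
                           angles(p2, p0, p1)])
    v_used = np.unique(mesh.triangles)
    euler = len(v_used) - len(uniq) + mesh.n_triangles

    messages = []
    if not closed:
        messages.append(f"{len(boundary)} boundary edge(s): {boundary[:10]}")
    if not oriented:
        messages.append("inconsistent triangle orientation")
    if areas.size and areas.min() <= 0:
        messages.append("degenerate (zero-area) triangle")
    if euler != 2:
        messages.append(f"Euler characteristic {euler} != 2")
    return ValidationReport(
        closed=closed,
        oriented=oriented,
        min_angle=float(all_angles.min()) if areas.size else 0.0,
        min_area=float(areas.min()) if areas.size else 0.0,
        euler_characteristic=int(euler),
        boundary_edges=boundary,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# point-in-mesh tests (winding numbers)
# ---------------------------------------------------------------------------

def winding_number(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Integer winding number of each point with respect to a closed mesh.

    Computed as the summed signed solid angle divided by 4*pi, rounded; 1 for
    points inside, 0 outside.  Robust for non-convex closed meshes.
    """
    from ._kernels import solid_angles_sum

    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    p0, p1, p2 = mesh.corners
    omega = solid_angles_sum(np.ascontiguousarray(points),
                             np.ascontiguousarray(p0),
                             np.ascontiguousarray(p1),
                             np.ascontiguousarray(p2))
    return np.rint(omega / (4.0 * np.pi)).astype(int)


@dataclass(frozen=True)
class HeadModel:
    """Nested interfaces S_1 (innermost) .. S_N (scalp) with conductivities.

    ``conductivities[i]`` is the conductivity (S/m) of the domain bounded
    outside by ``interfaces[i]``; the exterior conductivity is fixed at 0.
    """

    interfaces: tuple[TriangleMesh, ...]
    conductivities: tuple[float, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self):
        interfaces = tuple(self.interfaces)
        sig = tuple(float(s) for s in self.conductivities)
        if len(interfaces) < 1:
            raise ValueError("need at least one interface")
        if len(sig) != len(interfaces):
            raise ValueError("one conductivity per interface is required")
        if any(s <= 0 for s in sig):
            raise ValueError("conductivities must be positive")
        names = tuple(self.names) or tuple(
            f"domain{i + 1}" for i in range(len(interfaces)))
        object.__setattr__(self, "interfaces", interfaces)
        object.__setattr__(self, "conductivities", sig)
        object.__setattr__(self, "names", names)

    @property
    def n_interfaces(self) -> int:
        return len(self.interfaces)

    @property
    def scalp(self) -> TriangleMesh:
        return self.interfaces[-1]

    def sigma(self, domain: int) -> float:
        """Conductivity of domain ``1..N``; 0 for the exterior ``N+1``."""
        if domain == self.n_interfaces + 1:
            return 0.0
        return self.conductivities[domain - 1]

    def with_conductivities(self, sigmas: Sequence[float]) -> "HeadModel":
        return dataclasses.replace(self, conductivities=tuple(sigmas))


def check_nesting(model: HeadModel, verbose: bool = False):
    """True iff the interfaces are strictly nested, innermost first.

    Every vertex of ``S_i`` must have winding number 1 with respect to
    ``S_{i+1}`` and no vertex of ``S_{i+1}`` may lie inside ``S_i``.
    Returns ``(ok, report)`` where the report lists per-pair diagnostics.
    """
    report = []
    ok = True
    for i in range(model.n_interfaces - 1):
        inner, outer = model.interfaces[i], model.interfaces[i + 1]
        w_in = winding_number(inner.vertices, outer)
        w_out = winding_number(outer.vertices, inner)
        pair_ok = bool((w_in == 1).all() and (w_out == 0).all())
        ok &= pair_ok
        report.append({
            "pair": (i + 1, i + 2),
            "inner_inside_outer": int((w_in == 1).sum()),
            "inner_total": inner.n_vertices,
            "outer_inside_inner": int((w_out != 0).sum()),
            "ok": pair_ok,
        })
    if verbose:
        for row in report:
            print(row)
    return ok, report


def locate_domain(point, model: HeadModel, eps: float = DEFAULT_EPS) -> int:
    """Index (1..N) of the innermost domain containing ``point``.

    Returns :data:`OUTSIDE` (0) for points outside the scalp.  Points within
    ``eps`` of any interface raise ``ValueError``; callers must not silently
    perturb such degenerate placements.
    """
    point = np.asarray(point, dtype=float)
    for i, surf in enumerate(model.interfaces):
        d = _distance_to_mesh(point, surf)
        if d < eps:
            raise ValueError(
                f"point {point.tolist()} is within {eps} of interface "
                f"{i + 1} (distance {d:.3e})")
    for i, surf in enumerate(model.interfaces):
        if winding_number(point[None, :], surf)[0] == 1:
            return i + 1
    return OUTSIDE


# ---------------------------------------------------------------------------
# point/triangle projection
# ---------------------------------------------------------------------------

def closest_point_on_triangle(p, a, b, c):
    """Closest point of triangle (a, b, c) to p, with barycentric coords."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a, np.array([1.0, 0.0, 0.0])
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b, np.array([0.0, 1.0, 0.0])
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return a + v * ab, np.array([1 - v, v, 0.0])
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c, np.array([0.0, 0.0, 1.0])
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return a + w * ac, np.array([1 - w, 0.0, w])
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b), np.array([0.0, 1 - w, w])
    denom = va + vb + vc
    v, w = vb / denom, vc / denom
    return a + v * ab + w * ac, np.array([1 - v - w, v, w])


def _closest_points_all(p, a, b, c):
    """Closest point of every triangle (rows of a, b, c) to p, vectorized;
    returns ((nt, 3) points, (nt, 3) barycentric coordinates)."""
    ab, ac = b - a, c - a
    ap = p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    nt = len(a)
    bary = np.empty((nt, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        # interior case
        denom = va + vb + vc
        v_in = vb / denom
        w_in = vc / denom
        bary[:, 1] = v_in
        bary[:, 2] = w_in
        bary[:, 0] = 1.0 - v_in - w_in
        # edge AB region
        v_ab = d1 / (d1 - d3)
        m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
        bary[m] = np.stack([1 - v_ab[m], v_ab[m],
                            np.zeros(m.sum())], axis=1)
        # edge AC region
        w_ac = d2 / (d2 - d6)
        m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
        bary[m] = np.stack([1 - w_ac[m], np.zeros(m.sum()),
                            w_ac[m]], axis=1)
        # edge BC region
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        m = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
        bary[m] = np.stack([np.zeros(m.sum()), 1 - w_bc[m],
                            w_bc[m]], axis=1)
    # vertex regions (checked last: they win over edge formulas)
    m = (d1 <= 0) & (d2 <= 0)
    bary[m] = [1.0, 0.0, 0.0]
    m = (d3 >= 0) & (d4 <= d3)
    bary[m] = [0.0, 1.0, 0.0]
    m = (d6 >= 0) & (d5 <= d6)
    bary[m] = [0.0, 0.0, 1.0]
    pts = bary[:, 0, None] * a + bary[:, 1, None] * b + bary[:, 2, None] * c
    return pts, bary


def _project_point(point, mesh: TriangleMesh):
    """(closest point, triangle index, barycentric coords) on a mesh."""
    p0, p1, p2 = mesh.corners
    pts, bary = _closest_points_all(np.asarray(point, float), p0, p1, p2)
    d = np.linalg.norm(pts - np.asarray(point, float)[None, :], axis=1)
    k = int(np.argmin(d))
    return pts[k], k, bary[k]


def _distance_to_mesh(point, mesh: TriangleMesh) -> float:
    q, _, _ = _project_point(np.asarray(point, float), mesh)
    return float(np.linalg.norm(np.asarray(point, float) - q))


def nearest_triangle(point, mesh: TriangleMesh) -> int:
    """Triangle whose centroid is nearest to ``point`` (lowest index wins)."""
    d = np.linalg.norm(mesh.centroids - np.asarray(point, float), axis=1)
    return int(np.argmin(d))  # argmin takes the first (lowest) index on ties


# ---------------------------------------------------------------------------
# sources and sensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DipoleSet:
    """Pointwise dipoles: positions (m), moments (A*m), resolved domains."""

    positions: np.ndarray
    moments: np.ndarray
    domains: np.ndarray | None = None  # filled by resolve()

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        mom = np.atleast_2d(np.asarray(self.moments, dtype=np.float64))
        if pos.shape != mom.shape or pos.shape[1] != 3:
            raise ValueError("positions and moments must both be (n, 3)")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "moments", mom)

    def __len__(self) -> int:
        return len(self.positions)

    def resolve(self, model: HeadModel, eps: float = DEFAULT_EPS) -> "DipoleSet":
        """Assign a domain index to every dipole; error if outside or on an
        interface."""
        domains = np.array([locate_domain(p, model, eps=eps)
                            for p in self.positions])
        if (domains == OUTSIDE).any():
            bad = np.where(domains == OUTSIDE)[0]
            raise ValueError(f"dipole(s) {bad.tolist()} outside the head")
        return dataclasses.replace(self, domains=domains)


@dataclass(frozen=True)
class SurfaceSource:
    """Surfacic source: P1 intensities on a (possibly open) support mesh."""

    mesh: TriangleMesh
    intensities: np.ndarray

    def __post_init__(self):
        j = np.asarray(self.intensities, dtype=np.float64)
        if j.shape != (self.mesh.n_vertices,):
            raise ValueError("one intensity per support-mesh vertex required")
        object.__setattr__(self, "intensities", j)


@dataclass(frozen=True)
class EITInjection:
    """Current injection electrodes resolved to scalp triangles.

    ``currents`` is (n_electrodes, n_patterns); every pattern (column) must
    sum to zero for the Neumann problem to be solvable.
    """

    positions: np.ndarray
    currents: np.ndarray
    triangles: np.ndarray  # one scalp triangle index per electrode

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        cur = np.asarray(self.currents, dtype=np.float64)
        if cur.ndim == 1:
            cur = cur[:, None]
        tri = np.asarray(self.triangles, dtype=np.int64)
        if len(pos) != len(cur) or len(pos) != len(tri):
            raise ValueError("positions/currents/triangles length mismatch")
        net = np.abs(cur.sum(axis=0))
        if (net > 1e-12 * max(1.0, np.abs(cur).max())).any():
            raise ValueError(
                f"injected currents must sum to zero per pattern (net={net})")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "currents", cur)
        object.__setattr__(self, "triangles", tri)

    @classmethod
    def from_points(cls, points, currents, scalp: TriangleMesh):
        points = np.atleast_2d(np.asarray(points, float))
        tri = np.array([nearest_triangle(p, scalp) for p in points])
        return cls(points, currents, tri)

    @property
    def n_patterns(self) -> int:
        return self.currents.shape[1]


@dataclass(frozen=True)
class SensorSet:
    """EEG electrodes, MEG channels or internal points.

    kind == "EEG": projected scalp positions with owning triangle and
        barycentric coordinates.
    kind == "MEG": flat arrays of integration points / weighted directions,
        plus a channel id per integration point; a channel reading is the
        weighted sum of directional field samples over its points.
    kind == "IP":  internal points with resolved domain indices.
    """

    kind: str
    positions: np.ndarray
    names: tuple[str, ...] = ()
    # EEG
    triangles: np.ndarray | None = None
    barycentric: np.ndarray | None = None
    # MEG
    directions: np.ndarray | None = None
    weights: np.ndarray | None = None
    channels: np.ndarray | None = None
    # IP
    domains: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("EEG", "MEG", "IP"):
            raise ValueError("kind must be EEG, MEG or IP")
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        object.__setattr__(self, "positions", pos)

    @property
    def n_sensors(self) -> int:
        if self.kind == "MEG":
            return len(np.unique(self.channels))
        return len(self.positions)


def project_electrodes(points, scalp: TriangleMesh,
                       names: Sequence[str] = ()) -> SensorSet:
    """Project electrode positions orthogonally onto the scalp triangulation.

    Each point is replaced by its nearest point on the surface; the owning
    triangle and barycentric coordinates (in [0, 1], summing to 1) are kept
    for potential interpolation.  Idempotent.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(points) == 0:
        raise ValueError("empty electrode list")
    proj = np.empty_like(points)
    tris = np.empty(len(points), dtype=np.int64)
    bary = np.empty((len(points), 3))
    for i, p in enumerate(points):
        q, k, b = _project_point(p, scalp)
        proj[i], tris[i], bary[i] = q, k, b
    return SensorSet(kind="EEG", positions=proj, names=tuple(names),
                     triangles=tris, barycentric=bary)


def meg_sensors(points, directions, weights=None, channels=None,
                names: Sequence[str] = ()) -> SensorSet:
    """Build an MEG sensor set from integration points and directions."""
    points = np.atleast_2d(np.asarray(points, float))
    directions = np.atleast_2d(np.asarray(directions, float))
    n = len(points)
    if weights is None:
        weights = np.ones(n)
    if channels is None:
        channels = np.arange(n)
    weights = np.asarray(weights, float)
    channels = np.asarray(channels)
    if not (len(directions) == len(weights) == len(channels) == n):
        raise ValueError("points/directions/weights/channels length mismatch")
    if n == 0:
        raise ValueError("MEG channels need at least one integration point")
    return SensorSet(kind="MEG", positions=points, names=tuple(names),
                     directions=directions, weights=weights,
                     channels=channels)


def internal_points(points, model: HeadModel,
                    eps: float = DEFAULT_EPS) -> SensorSet:
    """Internal-potential points with their resolved domain index."""
    points = np.atleast_2d(np.asarray(points, float))
    domains = np.array([locate_domain(p, model, eps=eps) for p in points])
    if (domains == OUTSIDE).any():
        bad = np.where(domains == OUTSIDE)[0]
        raise ValueError(f"internal point(s) {bad.tolist()} outside the head")
    return SensorSet(kind="IP", positions=points, domains=domains)
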