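"""Closed genus-0 triangulated vesicle meshes and their geometry.

Lengths are measured in units of the minimum bond length ``l_min``; a valid
vesicle keeps every bonded pair strictly inside (l_min, 1.7 l_min) and every
non-bonded pair at least l_min apart (hard-core self-avoidance).

Vesicle meshes are built from a Fibonacci point set of exactly ``n``
vertices on the sphere, triangulated by their convex hull (genus 0 by
convexity, so F = 2V − 4 and E = 3V − 6 automatically), then relaxed by
tangential Lloyd-style smoothing with periodic re-hulling until the edge
lengths fit the bond window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "TriMesh",
    "make_vesicle_mesh",
    "asphericity",
    "mean_curvature",
    "vertex_normals",
    "vertex_areas",
    "mixed_vertex_areas",
]


@dataclass
class TriMesh:
    """Triangulated surface with consistently outward-wound faces."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int, outward winding

    _edges: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int32)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) sorted unique vertex pairs."""
        if self._edges is None:
            e = np.vstack(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            )
            self._edges = np.unique(np.sort(e, axis=1), axis=0)
        return self._edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def is_closed_genus0(self) -> bool:
        v, e, f = self.n_vertices, self.n_edges, self.n_faces
        return f == 2 * v - 4 and e == 3 * v - 6

    def face_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def total_area(self) -> float:
        return float(self.face_areas().sum())

    def min_nonbonded_distance(self) -> float:
        """Smallest distance between any two vertices that do not share a bond."""
        tree = cKDTree(self.vertices)
        bonded = {tuple(e) for e in self.edges.tolist()}
        # query enough neighbors to get past the bonded ring
        k = min(self.n_vertices, 20)
        dist, idx = tree.query(self.vertices, k=k)
        best = np.inf
        for i in range(self.n_vertices):
            for j, d in zip(idx[i, 1:], dist[i, 1:]):
                if tuple(sorted((i, int(j)))) not in bonded:
                    best = min(best, float(d))
                    break
        return best


def _fix_outward_winding(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Flip faces whose normal points toward the centroid."""
    center = vertices.mean(axis=0)
    p = vertices[faces]
    normals = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    toward = np.einsum("ij,ij->i", normals, p.mean(axis=1) - center)
    faces = faces.copy()
    faces[toward < 0] = faces[toward < 0][:, [0, 2, 1]]
    return faces


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    # random rotation so different seeds give independent meshes
    q = rng.normal(size=(3, 3))
    qr, _ = np.linalg.qr(q)
    if np.linalg.det(qr) < 0:
        qr[:, 0] = -qr[:, 0]
    return pts @ qr.T


def _adjacency_lists(n: int, faces: np.ndarray) -> list[set[int]]:
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for a, b, c in faces:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return nbrs


def make_vesicle_mesh(
    n_vertices: int,
    radius: float | None = None,
    seed: int | None = 0,
    l_min: float = 1.0,
    l_ratio: float = 1.7,
    relax_iters: int = 400,
    rehull_every: int = 10,
    target_ratio: float = 1.55,
) -> TriMesh:
    """Build a closed, relaxed vesicle mesh with exactly ``n_vertices``.

    The mesh is scaled so its edge lengths sit centered (geometrically)
    inside the bond window (l_min, l_ratio·l_min); pass ``radius`` (in l_min
    units) to fix the sphere radius instead. Raises ``ValueError`` with a
    diagnostic if the edge window or self-avoidance cannot be satisfied.
    """
    if n_vertices < 12:
        raise ValueError("need at least 12 vertices for a closed triangulation")
    rng = np.random.default_rng(seed)
    pts = _fibonacci_sphere(n_vertices, rng)
    hull = ConvexHull(pts)
    faces = hull.simplices
    edges = TriMesh(pts, faces).edges
    for it in range(relax_iters):
        # springs with a common rest length pull the edge spectrum together
        vec = pts[edges[:, 1]] - pts[edges[:, 0]]
        lens = np.linalg.norm(vec, axis=1)
        rest = lens.mean()
        force = (1.0 - rest / lens)[:, None] * vec
        disp = np.zeros_like(pts)
        np.add.at(disp, edges[:, 0], force)
        np.add.at(disp, edges[:, 1], -force)
        pts = pts + 0.25 * disp
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        if (it + 1) % rehull_every == 0 or it == relax_iters - 1:
            faces = ConvexHull(pts).simplices
            edges = TriMesh(pts, faces).edges
            lens = np.linalg.norm(pts[edges[:, 1]] - pts[edges[:, 0]], axis=1)
            if lens.max() / lens.min() < target_ratio:
                break
    faces = _fix_outward_winding(pts, ConvexHull(pts).simplices)
    mesh = TriMesh(pts, faces)
    lens = mesh.edge_lengths()
    ratio = lens.max() / lens.min()
    if ratio >= l_ratio:
        raise ValueError(
            f"edge-length ratio {ratio:.3f} exceeds the bond window {l_ratio} "
            f"after {relax_iters} relaxation iterations (n={n_vertices})"
        )
    if radius is None:
        # geometric centering inside the window maximizes both margins
        scale = np.sqrt(l_min * l_ratio * l_min / (lens.min() * lens.max()))
    else:
        scale = radius  # unit sphere -> requested radius
    mesh = TriMesh(pts * scale, faces)
    lens = mesh.edge_lengths()
    if lens.min() <= l_min or lens.max() >= l_ratio * l_min:
        raise ValueError(
            f"edges [{lens.min():.3f}, {lens.max():.3f}] violate the bond window "
            f"({l_min}, {l_ratio * l_min}) at radius {scale:.2f}; "
            "choose a radius consistent with the vertex count"
        )
    if mesh.min_nonbonded_distance() < l_min:
        raise ValueError("self-avoidance violated: non-bonded vertices closer than l_min")
    return mesh


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Barycentric dual area per vertex (one third of incident face areas)."""
    p = vertices[faces]
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    out = np.zeros(len(vertices))
    for k in range(3):
        np.add.at(out, faces[:, k], areas / 3.0)
    return out


def mixed_vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Meyer mixed (Voronoi-with-obtuse-fallback) dual area per vertex.

    For acute triangles the true Voronoi portion is used; obtuse triangles
    contribute half their area to the obtuse corner and a quarter to each
    of the others. Mixed areas tile the surface, so they sum to the total
    area, and make the cotangent mean curvature exact on a sphere.
    """
    p = vertices[faces]
    e = [p[:, (k + 2) % 3] - p[:, (k + 1) % 3] for k in range(3)]  # edge opposite corner k
    sq = [np.sum(v * v, axis=1) for v in e]
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    cot = []
    for k in range(3):
        u = p[:, (k + 1) % 3] - p[:, k]
        v = p[:, (k + 2) % 3] - p[:, k]
        cr = np.linalg.norm(np.cross(u, v), axis=1)
        cot.append(np.einsum("ij,ij->i", u, v) / np.where(cr > 0, cr, np.inf))
    cot = np.stack(cot, axis=1)
    obtuse_any = (cot < 0).any(axis=1)
    out = np.zeros(len(vertices))
    for k in range(3):
        voronoi = (sq[(k + 1) % 3] * cot[:, (k + 1) % 3] + sq[(k + 2) % 3] * cot[:, (k + 2) % 3]) / 8.0
        fallback = np.where(cot[:, k] < 0, area / 2.0, area / 4.0)
        np.add.at(out, faces[:, k], np.where(obtuse_any, fallback, voronoi))
    return out


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted outward unit normals (faces must be wound outward)."""
    p = vertices[faces]
    fn = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    out = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(out, faces[:, k], fn)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("degenerate vertex star: zero normal")
    return out / norms


def mean_curvature(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Discrete mean curvature H per vertex (1/l_min units).

    Cotangent Laplace–Beltrami with Meyer mixed dual areas; the sign is
    fixed by the outward normal, so a sphere gives H = +1/R (exactly, for
    vertices on a sphere). For open test patches only interior vertices are
    meaningful.
    """
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces)
    lap = np.zeros_like(vertices)
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # angle at vertex `c` of each face opposes edge (a, b)
        pa, pb, pc = (vertices[faces[:, k]] for k in (a, b, c))
        u, v = pa - pc, pb - pc
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.where(cross > 0, cross, np.inf)
        np.add.at(lap, faces[:, a], cot[:, None] * (pb - pa))
        np.add.at(lap, faces[:, b], cot[:, None] * (pa - pb))
    areas = mixed_vertex_areas(vertices, faces)
    normals = vertex_normals(vertices, faces)
    k_vec = lap / (2.0 * areas[:, None])
    return -0.5 * np.einsum("ij,ij->i", k_vec, normals)


def asphericity(points: np.ndarray) -> tuple[float, float, float, float]:
    """Gyration-tensor eigenvalues λ1 ≥ λ2 ≥ λ3 and the asphericity.

    A = [(λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²] / [2 (λ1+λ2+λ3)²] lies in [0, 1]:
    0 for a sphere, 1/4 for a flat axisymmetric disk, 1 for a line.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    centered = pts - pts.mean(axis=0)
    gyr = centered.T @ centered / len(pts)
    lam = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    total = lam.sum()
    if total <= 0:
        raise ValueError("all points coincide")
    a = ((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2) / (
        2.0 * total**2
    )
    return float(lam[0]), float(lam[1]), float(lam[2]), float(a)
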