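"""Metropolis Monte-Carlo of a dynamically triangulated active vesicle.

The microstate is a closed genus-0 triangulation whose vertices are either
bare membrane or protein (actin-nucleator) nodes. Its energy is

    W = W_A + W_b + W_d + W_F

with W_A the triangle stretching energy (k_A/2)Σ(a_i/a0 − 1)², W_b the
Helfrich bending energy (κ/2)Σ_i A_i(2H_i − C0,i)² discretized with the
cotangent Laplacian on Meyer mixed dual areas, W_d = −w Σ Heaviside(r0−r_ij)
the protein contact attraction, and W_F = −F Σ n̂_i·x_i the active outward
force on protein nodes, treated as a state function.

Three move types sample the ensemble: vertex displacements (uniform in a
cube of half-width δ), bond flips within the fixed spherical topology, and
protein hops to a random 1-ring neighbor (label diffusion). Every move is
first checked against the hard constraints — bond window (l_min, l_max),
hard-core self-avoidance of non-bonded vertices, optional parallel plates
at z = ±d/2 — and then accepted with probability min[1, exp(−βΔW)].

The hot loop is compiled with numba; connectivity is kept in flat arrays
(neighbor lists, edge records with their two incident faces, vertex→face
incidence) that bond flips update in place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .mesh import (
    TriMesh,
    asphericity,
    make_vesicle_mesh,
    mean_curvature,
    mixed_vertex_areas,
    vertex_normals,
)
from .params import ModelParams

__all__ = [
    "SimState",
    "EnergyBreakdown",
    "Observables",
    "make_state",
    "energy_total",
    "metropolis_accept",
    "run_sweeps",
    "thermalize",
    "sample_ensemble",
    "tension",
]

DMAX = 20  # max vertex degree / incident faces tracked per vertex


# ---------------------------------------------------------------------------
# dataclasses


@dataclass
class EnergyBreakdown:
    """Energy terms in kT0; W is their sum."""

    W_A: float
    W_b: float
    W_d: float
    W_F: float

    @property
    def W(self) -> float:
        return self.W_A + self.W_b + self.W_d + self.W_F


@dataclass
class Observables:
    """Per-microstate observables."""

    sigma: float  # stretching energy per area, kT0/l_min^2
    area: float
    lam1: float
    lam2: float
    lam3: float
    asphericity: float
    energy: EnergyBreakdown


@dataclass
class SimState:
    """Mutable simulation state: geometry, connectivity, occupancy, energy."""

    pos: np.ndarray  # (V, 3)
    occ: np.ndarray  # (V,) uint8
    prot: np.ndarray  # (n_prot,) int32 indices of protein vertices
    nbr: np.ndarray  # (V, DMAX) int32
    ndeg: np.ndarray  # (V,) int32
    eidx: np.ndarray  # (V, DMAX) int32, edge index parallel to nbr
    edges: np.ndarray  # (E, 2) int32
    edge_face: np.ndarray  # (E, 2) int32
    faces: np.ndarray  # (F, 3) int32, outward winding
    vface: np.ndarray  # (V, DMAX) int32
    nvf: np.ndarray  # (V,) int32
    energy4: np.ndarray  # running [W_A, W_b, W_d, W_F]
    energy_drift: float = 0.0
    z_wall: float = field(default=np.inf)  # current half-gap (d/2)

    @property
    def n_vertices(self) -> int:
        return len(self.pos)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_proteins(self) -> int:
        return len(self.prot)

    @property
    def mesh(self) -> TriMesh:
        return TriMesh(self.pos.copy(), self.faces.copy())

    def check_invariants(self, params: ModelParams) -> None:
        """Abort with a diagnostic if any hard invariant is violated."""
        v, e, f = self.n_vertices, self.n_edges, self.n_faces
        if f != 2 * v - 4 or e != 3 * v - 6:
            raise AssertionError(f"topology broken: V={v} E={e} F={f}")
        mesh = self.mesh
        me = mesh.edges
        if len(me) != e:
            raise AssertionError("face-derived edges disagree with edge table")
        lens = mesh.edge_lengths()
        if lens.min() <= params.l_min or lens.max() >= params.l_max:
            raise AssertionError(
                f"bond window violated: [{lens.min():.4f}, {lens.max():.4f}]"
            )
        if mesh.min_nonbonded_distance() < params.l_min:
            raise AssertionError("self-avoidance violated")
        if int(self.occ.sum()) != self.n_proteins:
            raise AssertionError("protein count not conserved")
        if np.isfinite(self.z_wall) and np.abs(self.pos[:, 2]).max() > self.z_wall:
            raise AssertionError("vertex outside confinement walls")


# ---------------------------------------------------------------------------
# state construction


def make_state(
    mesh: TriMesh,
    params: ModelParams,
    seed: int | None = 0,
) -> SimState:
    """Build a simulation state from a valid vesicle mesh.

    ``round(rho * V)`` protein labels are placed on uniformly random
    vertices; the running energy is initialized from scratch.
    """
    v = mesh.n_vertices
    faces = np.ascontiguousarray(mesh.faces, dtype=np.int32)
    edges = np.ascontiguousarray(mesh.edges, dtype=np.int32)
    e = len(edges)
    nbr = np.full((v, DMAX), -1, dtype=np.int32)
    ndeg = np.zeros(v, dtype=np.int32)
    eidx = np.full((v, DMAX), -1, dtype=np.int32)
    lookup: dict[tuple[int, int], int] = {}
    for k, (a, b) in enumerate(edges):
        a, b = int(a), int(b)
        lookup[(a, b)] = k
        lookup[(b, a)] = k
        for x, y in ((a, b), (b, a)):
            if ndeg[x] >= DMAX:
                raise ValueError(f"vertex degree exceeds DMAX={DMAX}")
            nbr[x, ndeg[x]] = y
            eidx[x, ndeg[x]] = k
            ndeg[x] += 1
    edge_face = np.full((e, 2), -1, dtype=np.int32)
    vface = np.full((v, DMAX), -1, dtype=np.int32)
    nvf = np.zeros(v, dtype=np.int32)
    for f, (a, b, c) in enumerate(faces):
        for x, y in ((int(a), int(b)), (int(b), int(c)), (int(c), int(a))):
            k = lookup[(x, y)]
            slot = 0 if edge_face[k, 0] < 0 else 1
            edge_face[k, slot] = f
        for x in (int(a), int(b), int(c)):
            vface[x, nvf[x]] = f
            nvf[x] += 1
    if (edge_face < 0).any():
        raise ValueError("mesh is not closed: some edge borders fewer than 2 faces")
    rng = np.random.default_rng(seed)
    n_prot = int(round(params.rho * v))
    prot = rng.choice(v, size=n_prot, replace=False).astype(np.int32)
    occ = np.zeros(v, dtype=np.uint8)
    occ[prot] = 1
    state = SimState(
        pos=np.ascontiguousarray(mesh.vertices, dtype=np.float64),
        occ=occ,
        prot=prot,
        nbr=nbr,
        ndeg=ndeg,
        eidx=eidx,
        edges=edges.copy(),
        edge_face=edge_face,
        faces=faces.copy(),
        vface=vface,
        nvf=nvf,
        energy4=np.zeros(4),
        z_wall=np.inf if params.d is None else params.d / 2.0,
    )
    eb = energy_total(state, params)
    state.energy4[:] = (eb.W_A, eb.W_b, eb.W_d, eb.W_F)
    return state


# ---------------------------------------------------------------------------
# from-scratch energies (vectorized; independent of the incremental kernel)


def energy_total(state: SimState, params: ModelParams) -> EnergyBreakdown:
    """Recompute the full energy breakdown from the current configuration."""
    mesh = TriMesh(state.pos, state.faces)
    areas = mesh.face_areas()
    if areas.min() <= 1e-12:
        raise ValueError("degenerate (zero-area) triangle")
    W_A = 0.5 * params.k_A * float(np.sum((areas / params.a0 - 1.0) ** 2))
    H = mean_curvature(state.pos, state.faces)
    A_mix = mixed_vertex_areas(state.pos, state.faces)
    c0_i = np.where(state.occ > 0, params.c0, 0.0)
    W_b = 0.5 * params.kappa * float(np.sum(A_mix * (2.0 * H - c0_i) ** 2))
    W_d = 0.0
    if state.n_proteins >= 2 and params.w != 0.0:
        ppos = state.pos[state.prot]
        tree = cKDTree(ppos)
        pairs = tree.query_pairs(r=params.r0, output_type="ndarray")
        if len(pairs):
            d = np.linalg.norm(ppos[pairs[:, 0]] - ppos[pairs[:, 1]], axis=1)
            W_d = -params.w * float(np.sum(d < params.r0))
    W_F = 0.0
    if state.n_proteins and params.F != 0.0:
        normals = vertex_normals(state.pos, state.faces)
        W_F = -params.F * float(
            np.einsum("ij,ij->i", normals[state.prot], state.pos[state.prot]).sum()
        )
    return EnergyBreakdown(W_A=W_A, W_b=W_b, W_d=W_d, W_F=W_F)


def metropolis_accept(
    delta_e: float, beta: float, rng: np.random.Generator
) -> bool:
    """min[1, exp(−β ΔE)] acceptance rule."""
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-beta * delta_e)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True, fastmath=False)
def _face_term_and_area(pos, faces, f, kA, a0):
    a, b, c = faces[f, 0], faces[f, 1], faces[f, 2]
    ux, uy, uz = pos[b, 0] - pos[a, 0], pos[b, 1] - pos[a, 1], pos[b, 2] - pos[a, 2]
    vx, vy, vz = pos[c, 0] - pos[a, 0], pos[c, 1] - pos[a, 1], pos[c, 2] - pos[a, 2]
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    area = 0.5 * math.sqrt(nx * nx + ny * ny + nz * nz)
    r = area / a0 - 1.0
    return 0.5 * kA * r * r, area


@njit(cache=True, fastmath=False)
def _vertex_term(pos, faces, vface, nvf, occ, i, kappa, c0, Factive):
    """Bending + active-force energy attributed to vertex i.

    Uses the cotangent Laplacian with Meyer mixed dual area and the
    area-weighted outward normal of the vertex star. Returns (e_bend, e_F);
    a degenerate star returns a huge energy so the move is rejected.
    """
    area_i = 0.0
    nrm0 = 0.0
    nrm1 = 0.0
    nrm2 = 0.0
    lap0 = 0.0
    lap1 = 0.0
    lap2 = 0.0
    xi0, xi1, xi2 = pos[i, 0], pos[i, 1], pos[i, 2]
    for s in range(nvf[i]):
        f = vface[i, s]
        v0, v1, v2 = faces[f, 0], faces[f, 1], faces[f, 2]
        if v0 == i:
            a, b = v1, v2
        elif v1 == i:
            a, b = v2, v0
        else:
            a, b = v0, v1
        ax, ay, az = pos[a, 0] - xi0, pos[a, 1] - xi1, pos[a, 2] - xi2
        bx, by, bz = pos[b, 0] - xi0, pos[b, 1] - xi1, pos[b, 2] - xi2
        # face normal (outward, winding i -> a -> b)
        fnx = 0.5 * (ay * bz - az * by)
        fny = 0.5 * (az * bx - ax * bz)
        fnz = 0.5 * (ax * by - ay * bx)
        area_f = math.sqrt(fnx * fnx + fny * fny + fnz * fnz)
        if area_f <= 1e-12:
            return 1e30, 0.0
        nrm0 += fnx
        nrm1 += fny
        nrm2 += fnz
        # cotangents of the three corners; every corner's |cross| is 2*area_f
        la2 = ax * ax + ay * ay + az * az  # |edge i-a|^2
        lb2 = bx * bx + by * by + bz * bz  # |edge i-b|^2
        dot_i = ax * bx + ay * by + az * bz
        cot_i = dot_i / (2.0 * area_f)
        cot_a = (la2 - dot_i) / (2.0 * area_f)  # corner a: (i-a)·(b-a)
        cot_b = (lb2 - dot_i) / (2.0 * area_f)  # corner b: (i-b)·(a-b)
        # Meyer mixed area contribution of this face to vertex i
        if cot_i < 0.0 or cot_a < 0.0 or cot_b < 0.0:
            if cot_i < 0.0:
                area_i += 0.5 * area_f
            else:
                area_i += 0.25 * area_f
        else:
            area_i += (lb2 * cot_a + la2 * cot_b) * 0.125
        # cotangent Laplacian: cot at a opposes edge (i,b); cot at b opposes (i,a)
        lap0 += cot_a * bx + cot_b * ax
        lap1 += cot_a * by + cot_b * ay
        lap2 += cot_a * bz + cot_b * az
    nlen = math.sqrt(nrm0 * nrm0 + nrm1 * nrm1 + nrm2 * nrm2)
    if nlen <= 1e-12 or area_i <= 1e-12:
        return 1e30, 0.0
    nrm0 /= nlen
    nrm1 /= nlen
    nrm2 /= nlen
    k0 = lap0 / (2.0 * area_i)
    k1 = lap1 / (2.0 * area_i)
    k2 = lap2 / (2.0 * area_i)
    h = -0.5 * (k0 * nrm0 + k1 * nrm1 + k2 * nrm2)
    c0i = c0 if occ[i] == 1 else 0.0
    dev = 2.0 * h - c0i
    e_bend = 0.5 * kappa * area_i * dev * dev
    e_f = 0.0
    if occ[i] == 1:
        e_f = -Factive * (nrm0 * xi0 + nrm1 * xi1 + nrm2 * xi2)
    return e_bend, e_f


@njit(cache=True, fastmath=False)
def _protein_contacts(pos, prot, i, r0sq):
    """Number of protein vertices (other than i) within binding range of i."""
    cnt = 0
    xi0, xi1, xi2 = pos[i, 0], pos[i, 1], pos[i, 2]
    for k in range(prot.shape[0]):
        j = prot[k]
        if j == i:
            continue
        d0 = pos[j, 0] - xi0
        d1 = pos[j, 1] - xi1
        d2 = pos[j, 2] - xi2
        if d0 * d0 + d1 * d1 + d2 * d2 < r0sq:
            cnt += 1
    return cnt


@njit(cache=True, fastmath=False)
def _local_energy_around_vertex(pos, faces, vface, nvf, occ, nbr, ndeg, v, kappa, c0, Factive, kA, a0):
    """(e_area, e_bend, e_F) of everything a move of vertex v can change."""
    e_area = 0.0
    for s in range(nvf[v]):
        ft, _ = _face_term_and_area(pos, faces, vface[v, s], kA, a0)
        e_area += ft
    eb, ef = _vertex_term(pos, faces, vface, nvf, occ, v, kappa, c0, Factive)
    e_bend = eb
    e_f = ef
    for s in range(ndeg[v]):
        u = nbr[v, s]
        eb, ef = _vertex_term(pos, faces, vface, nvf, occ, u, kappa, c0, Factive)
        e_bend += eb
        e_f += ef
    return e_area, e_bend, e_f


@njit(cache=True, fastmath=False)
def _try_vertex_move(
    pos, occ, prot, nbr, ndeg, faces, vface, nvf,
    v, delta, kappa, c0, Factive, kA, a0, w,
    beta, lmin2, lmax2, r0sq, zhalf, energy4,
):
    nx = pos[v, 0] + delta * (2.0 * np.random.random() - 1.0)
    ny = pos[v, 1] + delta * (2.0 * np.random.random() - 1.0)
    nz = pos[v, 2] + delta * (2.0 * np.random.random() - 1.0)
    if abs(nz) > zhalf:
        return 0
    # bond window for every neighbor
    for s in range(ndeg[v]):
        u = nbr[v, s]
        d0 = nx - pos[u, 0]
        d1 = ny - pos[u, 1]
        d2 = nz - pos[u, 2]
        d2sum = d0 * d0 + d1 * d1 + d2 * d2
        if d2sum <= lmin2 or d2sum >= lmax2:
            return 0
    # hard-core self-avoidance against all non-bonded vertices
    for u in range(pos.shape[0]):
        if u == v:
            continue
        bonded = False
        for s in range(ndeg[v]):
            if nbr[v, s] == u:
                bonded = True
                break
        if bonded:
            continue
        d0 = nx - pos[u, 0]
        d1 = ny - pos[u, 1]
        d2 = nz - pos[u, 2]
        if d0 * d0 + d1 * d1 + d2 * d2 < lmin2:
            return 0
    eA0, eB0, eF0 = _local_energy_around_vertex(
        pos, faces, vface, nvf, occ, nbr, ndeg, v, kappa, c0, Factive, kA, a0
    )
    eD0 = 0.0
    if occ[v] == 1 and w != 0.0:
        eD0 = -w * _protein_contacts(pos, prot, v, r0sq)
    ox, oy, oz = pos[v, 0], pos[v, 1], pos[v, 2]
    pos[v, 0], pos[v, 1], pos[v, 2] = nx, ny, nz
    eA1, eB1, eF1 = _local_energy_around_vertex(
        pos, faces, vface, nvf, occ, nbr, ndeg, v, kappa, c0, Factive, kA, a0
    )
    eD1 = 0.0
    if occ[v] == 1 and w != 0.0:
        eD1 = -w * _protein_contacts(pos, prot, v, r0sq)
    dE = (eA1 - eA0) + (eB1 - eB0) + (eF1 - eF0) + (eD1 - eD0)
    if dE <= 0.0 or np.random.random() < math.exp(-beta * dE):
        energy4[0] += eA1 - eA0
        energy4[1] += eB1 - eB0
        energy4[2] += eD1 - eD0
        energy4[3] += eF1 - eF0
        return 1
    pos[v, 0], pos[v, 1], pos[v, 2] = ox, oy, oz
    return 0


@njit(cache=True, fastmath=False)
def _force_vertex_z(
    pos, occ, prot, nbr, ndeg, faces, vface, nvf,
    v, new_z, kappa, c0, Factive, kA, a0, w, lmin2, lmax2, r0sq, energy4,
):
    """Push vertex v to z = new_z if the hard constraints allow it.

    Used only by the confinement initialization protocol (wall descent);
    not a Metropolis move — the energy change is booked unconditionally.
    """
    nx, ny, nz = pos[v, 0], pos[v, 1], new_z
    for s in range(ndeg[v]):
        u = nbr[v, s]
        d0 = nx - pos[u, 0]
        d1 = ny - pos[u, 1]
        d2 = nz - pos[u, 2]
        d2sum = d0 * d0 + d1 * d1 + d2 * d2
        if d2sum <= lmin2 or d2sum >= lmax2:
            return 0
    for u in range(pos.shape[0]):
        if u == v:
            continue
        bonded = False
        for s in range(ndeg[v]):
            if nbr[v, s] == u:
                bonded = True
                break
        if bonded:
            continue
        d0 = nx - pos[u, 0]
        d1 = ny - pos[u, 1]
        d2 = nz - pos[u, 2]
        if d0 * d0 + d1 * d1 + d2 * d2 < lmin2:
            return 0
    eA0, eB0, eF0 = _local_energy_around_vertex(
        pos, faces, vface, nvf, occ, nbr, ndeg, v, kappa, c0, Factive, kA, a0
    )
    eD0 = 0.0
    if occ[v] == 1 and w != 0.0:
        eD0 = -w * _protein_contacts(pos, prot, v, r0sq)
    pos[v, 2] = nz
    eA1, eB1, eF1 = _local_energy_around_vertex(
        pos, faces, vface, nvf, occ, nbr, ndeg, v, kappa, c0, Factive, kA, a0
    )
    eD1 = 0.0
    if occ[v] == 1 and w != 0.0:
        eD1 = -w * _protein_contacts(pos, prot, v, r0sq)
    energy4[0] += eA1 - eA0
    energy4[1] += eB1 - eB0
    energy4[2] += eD1 - eD0
    energy4[3] += eF1 - eF0
    return 1


@njit(cache=True, fastmath=False)
def _find_slot(arr, n, val):
    for s in range(n):
        if arr[s] == val:
            return s
    return -1


@njit(cache=True, fastmath=False)
def _remove_entry(arr, n, val):
    s = _find_slot(arr, n, val)
    arr[s] = arr[n - 1]
    arr[n - 1] = -1
    return s


@njit(cache=True, fastmath=False)
def _apply_flip(e, edges, edge_face, faces, nbr, eidx, ndeg, vface, nvf):
    """Flip edge e in place; calling it again on e undoes the flip."""
    a, b = edges[e, 0], edges[e, 1]
    f1, f2 = edge_face[e, 0], edge_face[e, 1]
    # orient so that f1 traverses a -> b
    sa = _find_slot(faces[f1], 3, a)
    if faces[f1, (sa + 1) % 3] != b:
        f1, f2 = f2, f1
        sa = _find_slot(faces[f1], 3, a)
    c = faces[f1, (sa + 2) % 3]
    sb = _find_slot(faces[f2], 3, b)
    d = faces[f2, (sb + 2) % 3]  # f2 traverses b -> a -> d
    # rewrite faces, keeping outward winding
    faces[f1, 0], faces[f1, 1], faces[f1, 2] = c, a, d
    faces[f2, 0], faces[f2, 1], faces[f2, 2] = d, b, c
    # edge record: (a,b) becomes (c,d)
    edges[e, 0], edges[e, 1] = c, d
    edge_face[e, 0], edge_face[e, 1] = f1, f2
    # adjacency: drop a-b, add c-d
    s = _remove_entry(nbr[a], ndeg[a], b)
    eidx[a, s] = eidx[a, ndeg[a] - 1]
    eidx[a, ndeg[a] - 1] = -1
    s = _remove_entry(nbr[b], ndeg[b], a)
    eidx[b, s] = eidx[b, ndeg[b] - 1]
    eidx[b, ndeg[b] - 1] = -1
    ndeg[a] -= 1
    ndeg[b] -= 1
    nbr[c, ndeg[c]] = d
    eidx[c, ndeg[c]] = e
    ndeg[c] += 1
    nbr[d, ndeg[d]] = c
    eidx[d, ndeg[d]] = e
    ndeg[d] += 1
    # quad edges that change their incident face: (b,c): f1 -> f2, (a,d): f2 -> f1
    s = _find_slot(nbr[b], ndeg[b], c)
    ebc = eidx[b, s]
    edge_face[ebc, _find_slot(edge_face[ebc], 2, f1)] = f2
    s = _find_slot(nbr[a], ndeg[a], d)
    ead = eidx[a, s]
    edge_face[ead, _find_slot(edge_face[ead], 2, f2)] = f1
    # vertex-face incidence: b loses f1, d gains it; a loses f2, c gains it
    _remove_entry(vface[b], nvf[b], f1)
    nvf[b] -= 1
    vface[d, nvf[d]] = f1
    nvf[d] += 1
    _remove_entry(vface[a], nvf[a], f2)
    nvf[a] -= 1
    vface[c, nvf[c]] = f2
    nvf[c] += 1
    return a, b, c, d


@njit(cache=True, fastmath=False)
def _flip_local_energy(pos, occ, faces, vface, nvf, f1, f2, a, b, c, d, kappa, c0, Factive, kA, a0):
    t1, _ = _face_term_and_area(pos, faces, f1, kA, a0)
    t2, _ = _face_term_and_area(pos, faces, f2, kA, a0)
    eA = t1 + t2
    eB = 0.0
    eF = 0.0
    eb, ef = _vertex_term(pos, faces, vface, nvf, occ, a, kappa, c0, Factive)
    eB += eb
    eF += ef
    eb, ef = _vertex_term(pos, faces, vface, nvf, occ, b, kappa, c0, Factive)
    eB += eb
    eF += ef
    eb, ef = _vertex_term(pos, faces, vface, nvf, occ, c, kappa, c0, Factive)
    eB += eb
    eF += ef
    eb, ef = _vertex_term(pos, faces, vface, nvf, occ, d, kappa, c0, Factive)
    eB += eb
    eF += ef
    return eA, eB, eF


@njit(cache=True, fastmath=False)
def _try_bond_flip(
    pos, occ, nbr, ndeg, eidx, edges, edge_face, faces, vface, nvf,
    e, kappa, c0, Factive, kA, a0, beta, lmin2, lmax2, energy4,
):
    a, b = edges[e, 0], edges[e, 1]
    f1, f2 = edge_face[e, 0], edge_face[e, 1]
    # third vertices of the two incident faces
    c = -1
    d = -1
    for s in range(3):
        if faces[f1, s] != a and faces[f1, s] != b:
            c = faces[f1, s]
        if faces[f2, s] != a and faces[f2, s] != b:
            d = faces[f2, s]
    if c == d or c < 0 or d < 0:
        return 0
    if ndeg[a] <= 3 or ndeg[b] <= 3 or ndeg[c] >= DMAX or ndeg[d] >= DMAX:
        return 0
    if _find_slot(nbr[c], ndeg[c], d) >= 0:  # duplicate edge
        return 0
    d0 = pos[c, 0] - pos[d, 0]
    d1 = pos[c, 1] - pos[d, 1]
    d2 = pos[c, 2] - pos[d, 2]
    dcd = d0 * d0 + d1 * d1 + d2 * d2
    if dcd <= lmin2 or dcd >= lmax2:
        return 0
    eA0, eB0, eF0 = _flip_local_energy(
        pos, occ, faces, vface, nvf, f1, f2, a, b, c, d, kappa, c0, Factive, kA, a0
    )
    _apply_flip(e, edges, edge_face, faces, nbr, eidx, ndeg, vface, nvf)
    eA1, eB1, eF1 = _flip_local_energy(
        pos, occ, faces, vface, nvf, f1, f2, a, b, c, d, kappa, c0, Factive, kA, a0
    )
    dE = (eA1 - eA0) + (eB1 - eB0) + (eF1 - eF0)
    if dE <= 0.0 or np.random.random() < math.exp(-beta * dE):
        energy4[0] += eA1 - eA0
        energy4[1] += eB1 - eB0
        energy4[3] += eF1 - eF0
        return 1
    _apply_flip(e, edges, edge_face, faces, nbr, eidx, ndeg, vface, nvf)
    return 0


@njit(cache=True, fastmath=False)
def _try_protein_hop(
    pos, occ, prot, nbr, ndeg, faces, vface, nvf, edges,
    e, kappa, c0, Factive, kA, a0, w, beta, r0sq, energy4,
):
    # a uniformly random edge keeps the proposal symmetric (detailed balance
    # would break if we picked a random neighbor of a random protein, since
    # vertex degrees differ)
    a, b = edges[e, 0], edges[e, 1]
    if occ[a] + occ[b] != 1:
        return 0
    v = a if occ[a] == 1 else b
    u = b if occ[a] == 1 else a
    pi = -1
    for k in range(prot.shape[0]):
        if prot[k] == v:
            pi = k
            break
    eb_v, ef_v = _vertex_term(pos, faces, vface, nvf, occ, v, kappa, c0, Factive)
    eb_u, ef_u = _vertex_term(pos, faces, vface, nvf, occ, u, kappa, c0, Factive)
    eB0 = eb_v + eb_u
    eF0 = ef_v + ef_u
    eD0 = -w * _protein_contacts(pos, prot, v, r0sq) if w != 0.0 else 0.0
    occ[v] = 0
    occ[u] = 1
    prot[pi] = u
    eb_v, ef_v = _vertex_term(pos, faces, vface, nvf, occ, v, kappa, c0, Factive)
    eb_u, ef_u = _vertex_term(pos, faces, vface, nvf, occ, u, kappa, c0, Factive)
    eB1 = eb_v + eb_u
    eF1 = ef_v + ef_u
    eD1 = -w * _protein_contacts(pos, prot, u, r0sq) if w != 0.0 else 0.0
    dE = (eB1 - eB0) + (eF1 - eF0) + (eD1 - eD0)
    if dE <= 0.0 or np.random.random() < math.exp(-beta * dE):
        energy4[1] += eB1 - eB0
        energy4[2] += eD1 - eD0
        energy4[3] += eF1 - eF0
        return 1
    occ[v] = 1
    occ[u] = 0
    prot[pi] = v
    return 0


@njit(cache=True, fastmath=False)
def _run_sweeps_kernel(
    pos, occ, prot, nbr, ndeg, eidx, edges, edge_face, faces, vface, nvf,
    energy4, n_sweeps, zhalf_sched,
    kappa, c0, Factive, kA, a0, w, beta, lmin2, lmax2, r0sq, delta, seed, counters,
):
    np.random.seed(seed)
    V = pos.shape[0]
    E = edges.shape[0]
    n_prot = prot.shape[0]
    for s in range(n_sweeps):
        zhalf = zhalf_sched[s]
        if zhalf != np.inf:
            # wall-descent protocol: vertices left outside the scheduled wall
            # are pushed onto it whenever the hard constraints permit;
            # stragglers keep the effective wall at their own |z| until they
            # can follow, so the wall never cuts through the membrane
            for i in range(V):
                if abs(pos[i, 2]) > zhalf:
                    tz = zhalf - 1e-9 if pos[i, 2] > 0 else -(zhalf - 1e-9)
                    _force_vertex_z(
                        pos, occ, prot, nbr, ndeg, faces, vface, nvf,
                        i, tz, kappa, c0, Factive, kA, a0, w, lmin2, lmax2, r0sq,
                        energy4,
                    )
            for i in range(V):
                az = abs(pos[i, 2])
                if az >= zhalf:
                    zhalf = az + 1e-9
        total = V + E + n_prot
        for _ in range(total):
            r = np.random.randint(0, total)
            if r < V:
                counters[0, 0] += 1
                counters[0, 1] += _try_vertex_move(
                    pos, occ, prot, nbr, ndeg, faces, vface, nvf,
                    np.random.randint(0, V), delta, kappa, c0, Factive, kA, a0, w,
                    beta, lmin2, lmax2, r0sq, zhalf, energy4,
                )
            elif r < V + E:
                counters[1, 0] += 1
                counters[1, 1] += _try_bond_flip(
                    pos, occ, nbr, ndeg, eidx, edges, edge_face, faces, vface, nvf,
                    np.random.randint(0, E), kappa, c0, Factive, kA, a0,
                    beta, lmin2, lmax2, energy4,
                )
            elif n_prot > 0:
                counters[2, 0] += 1
                counters[2, 1] += _try_protein_hop(
                    pos, occ, prot, nbr, ndeg, faces, vface, nvf, edges,
                    np.random.randint(0, E), kappa, c0, Factive, kA, a0, w,
                    beta, r0sq, energy4,
                )


# ---------------------------------------------------------------------------
# python drivers


def run_sweeps(
    state: SimState,
    params: ModelParams,
    n_sweeps: int,
    seed: int = 0,
    z_wall_schedule: np.ndarray | None = None,
    debug: bool = False,
    drift_tol: float = 1e-6,
) -> SimState:
    """Advance the state by ``n_sweeps`` Monte-Carlo sweeps in place.

    One sweep makes V vertex-move, E bond-flip and n_protein hop attempts
    in random order. The running energy breakdown is maintained
    incrementally and compared against a from-scratch recomputation at the
    end; the relative drift is recorded (and the running value resynced).
    With ``debug=True`` all hard invariants are re-checked afterwards.
    """
    if n_sweeps <= 0:
        return state
    if z_wall_schedule is None:
        z_wall_schedule = np.full(n_sweeps, state.z_wall)
    z_wall_schedule = np.asarray(z_wall_schedule, dtype=float)
    if len(z_wall_schedule) != n_sweeps:
        raise ValueError("z_wall_schedule length must equal n_sweeps")
    counters = np.zeros((3, 2), dtype=np.int64)
    _run_sweeps_kernel(
        state.pos, state.occ, state.prot, state.nbr, state.ndeg, state.eidx,
        state.edges, state.edge_face, state.faces, state.vface, state.nvf,
        state.energy4, n_sweeps, z_wall_schedule,
        params.kappa, params.c0, params.F, params.k_A, params.a0, params.w,
        params.beta, params.l_min**2, params.l_max**2, params.r0**2,
        params.delta, seed % (2**31), counters,
    )
    # the piston never cuts through the membrane, so the effective wall may
    # still sit above the scheduled target; record what actually holds
    state.z_wall = max(float(z_wall_schedule[-1]), float(np.abs(state.pos[:, 2]).max()))
    fresh = energy_total(state, params)
    fresh4 = np.array([fresh.W_A, fresh.W_b, fresh.W_d, fresh.W_F])
    scale = max(1.0, float(np.abs(fresh4).sum()))
    state.energy_drift = float(np.abs(state.energy4 - fresh4).max() / scale)
    state.energy4[:] = fresh4
    state.acceptance = counters
    if debug:
        state.check_invariants(params)
        if state.energy_drift > drift_tol:
            raise AssertionError(f"incremental energy drift {state.energy_drift:.2e}")
    return state


def thermalize(
    state: SimState,
    params: ModelParams,
    n_sweeps: int = 2000,
    seed: int = 0,
    ramp_fraction: float = 0.8,
) -> SimState:
    """Thermalize, gradually lowering confinement walls when d is set.

    With plates requested, the half-gap ramps linearly from just above the
    current vesicle extent down to d/2 over the first ``ramp_fraction`` of
    the sweeps and is held at d/2 for the remainder; vertices the wall
    overtakes are pushed onto it as soon as the hard constraints allow.
    """
    if params.d is None:
        return run_sweeps(state, params, n_sweeps, seed=seed)
    z_target = params.d / 2.0
    z_start = max(z_target, float(np.abs(state.pos[:, 2]).max()) + 1.0)
    ramp = int(ramp_fraction * n_sweeps)
    sched = np.concatenate(
        [
            np.linspace(z_start, z_target, max(ramp, 1)),
            np.full(n_sweeps - max(ramp, 1), z_target),
        ]
    )
    run_sweeps(state, params, n_sweeps, seed=seed, z_wall_schedule=sched)
    reached = float(np.abs(state.pos[:, 2]).max())
    if reached > z_target:
        raise ValueError(
            f"confinement to d={params.d} not reached (thickness {2 * reached:.2f}); "
            "the gap is infeasible or thermalization was too short"
        )
    state.z_wall = z_target
    return state


def observables(state: SimState, params: ModelParams) -> Observables:
    """Measure tension proxy, area, gyration eigenvalues and asphericity."""
    eb = energy_total(state, params)
    area = TriMesh(state.pos, state.faces).total_area()
    lam1, lam2, lam3, asph = asphericity(state.pos)
    return Observables(
        sigma=eb.W_A / area,
        area=area,
        lam1=lam1,
        lam2=lam2,
        lam3=lam3,
        asphericity=asph,
        energy=eb,
    )


def tension(obs_or_states: list) -> float:
    """Ensemble tension σ = ⟨W_A / A⟩ over sampled microstates."""
    if not obs_or_states:
        raise ValueError("need at least one sampled state")
    vals = []
    for item in obs_or_states:
        if isinstance(item, Observables):
            vals.append(item.sigma)
        else:
            raise TypeError("tension expects Observables")
    return float(np.mean(vals))


def sample_ensemble(
    params: ModelParams,
    n_vertices: int = 600,
    n_states: int = 200,
    therm_sweeps: int = 2000,
    seed: int = 0,
    debug: bool = False,
) -> tuple[list[Observables], dict]:
    """Ensemble of independently seeded, thermalized microstates.

    Each replicate builds its own relaxed mesh and protein placement from
    ``seed + replicate index``, thermalizes, and is measured once. Returns
    the per-state observables and a mean ± SD summary; replicates that
    abort are reported in the summary and skipped.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    obs: list[Observables] = []
    failures: list[str] = []
    for k in range(n_states):
        s = seed + k
        try:
            mesh = make_vesicle_mesh(n_vertices, seed=s, l_min=params.l_min, l_ratio=params.l_ratio)
            state = make_state(mesh, params, seed=s)
            thermalize(state, params, n_sweeps=therm_sweeps, seed=s)
            if debug:
                state.check_invariants(params)
            obs.append(observables(state, params))
        except (ValueError, AssertionError) as err:  # pragma: no cover - defensive
            failures.append(f"replicate {k}: {err}")
    summary = {
        "n_ok": len(obs),
        "failures": failures,
        "sigma_mean": float(np.mean([o.sigma for o in obs])) if obs else np.nan,
        "sigma_sd": float(np.std([o.sigma for o in obs], ddof=1)) if len(obs) > 1 else np.nan,
        "asphericity_mean": float(np.mean([o.asphericity for o in obs])) if obs else np.nan,
        "asphericity_sd": (
            float(np.std([o.asphericity for o in obs], ddof=1)) if len(obs) > 1 else np.nan
        ),
    }
    return obs, summary
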