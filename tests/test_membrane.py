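"""Membrane MC: geometry, energies, Metropolis sampling, observables."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from blebkit.membrane import (
    ModelParams,
    TriMesh,
    asphericity,
    energy_total,
    make_state,
    make_vesicle_mesh,
    mean_curvature,
    metropolis_accept,
    observables,
    run_sweeps,
    thermalize,
)
from blebkit.membrane.mesh import _fix_outward_winding


def tetrahedron(side):
    """Regular tetrahedron with the given edge length (closed, V=4, F=4)."""
    verts = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    ) * (side / (2.0 * math.sqrt(2.0)))
    faces = _fix_outward_winding(verts, np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]))
    return TriMesh(verts, faces)


def bipyramid(re=0.95, h=0.85):
    """Triangular bipyramid whose topology is frozen under bond flips."""
    verts = np.array(
        [[re * np.cos(2 * np.pi * k / 3), re * np.sin(2 * np.pi * k / 3), 0.0] for k in range(3)]
        + [[0.0, 0.0, h], [0.0, 0.0, -h]]
    )
    faces = _fix_outward_winding(
        verts, np.array([[3, 0, 1], [3, 1, 2], [3, 2, 0], [4, 1, 0], [4, 2, 1], [4, 0, 2]])
    )
    return TriMesh(verts, faces)


class TestCurvature:
    def test_sphere_curvature_is_one_over_radius_everywhere(self, sphere_mesh_600):
        mesh = sphere_mesh_600
        R = np.linalg.norm(mesh.vertices - mesh.vertices.mean(axis=0), axis=1).mean()
        H = mean_curvature(mesh.vertices, mesh.faces)
        assert np.all(np.abs(H * R - 1.0) < 0.05)

    def test_flat_patch_interior_curvature_is_zero(self):
        n = 9
        rows, cols = np.mgrid[0:n, 0:n]
        verts = np.stack([rows.ravel() * 1.0, cols.ravel() * 1.0, np.zeros(n * n)], axis=1)
        faces = []
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces += [[a, a + 1, a + n + 1], [a, a + n + 1, a + n]]
        H = mean_curvature(verts, np.array(faces))
        interior = [i * n + j for i in range(2, n - 2) for j in range(2, n - 2)]
        assert np.abs(H[interior]).max() < 1e-12

    def test_cylinder_patch_curvature_is_half_inverse_radius(self):
        r, m, levels = 3.0, 60, 11
        theta = 2 * np.pi * np.arange(m) / m
        verts = np.array(
            [[r * np.cos(t), r * np.sin(t), k * 0.5] for k in range(levels) for t in theta]
        )
        faces = []
        for k in range(levels - 1):
            for j in range(m):
                a = k * m + j
                b = k * m + (j + 1) % m
                faces += [[a, b, b + m], [a, b + m, a + m]]
        H = mean_curvature(verts, np.array(faces))
        interior = [k * m + j for k in range(3, levels - 3) for j in range(m)]
        assert np.all(np.abs(H[interior] * 2 * r - 1.0) < 0.05)


class TestEnergy:
    def test_equilateral_l0_triangles_have_zero_stretching(self):
        params = ModelParams(rho=0.0)
        mesh = tetrahedron(params.l0)
        state = make_state(mesh, params, seed=0)
        assert energy_total(state, params).W_A == pytest.approx(0.0, abs=1e-12)

    def test_two_bonded_proteins_contribute_minus_w(self):
        params = ModelParams(w=1.0, rho=0.5, F=0.0, c0=0.0)
        state = make_state(tetrahedron(params.l0), params, seed=0)
        state.occ[:] = 0
        state.occ[:2] = 1
        state.prot = np.array([0, 1], dtype=np.int32)
        assert energy_total(state, params).W_d == pytest.approx(-1.0)

    def test_closed_sphere_bending_energy_is_8_pi_kappa(self, sphere_mesh_600):
        """Continuum Helfrich limit for a protein-free sphere."""
        params = ModelParams(kappa=20.0, rho=0.0, c0=0.0, F=0.0, w=0.0)
        state = make_state(sphere_mesh_600, params, seed=0)
        wb = energy_total(state, params).W_b
        assert wb == pytest.approx(8 * math.pi * params.kappa, rel=0.05)

    def test_breakdown_sums_to_total(self, small_mesh):
        params = ModelParams()
        state = make_state(small_mesh, params, seed=1)
        eb = energy_total(state, params)
        assert eb.W == pytest.approx(eb.W_A + eb.W_b + eb.W_d + eb.W_F)

    def test_contact_and_force_terms_scale_linearly(self, small_mesh):
        base = ModelParams(w=1.0, F=1.0)
        state = make_state(small_mesh, base, seed=2)
        e1 = energy_total(state, base)
        e2 = energy_total(state, ModelParams(w=2.0, F=3.0))
        assert e2.W_d == pytest.approx(2.0 * e1.W_d)
        assert e2.W_F == pytest.approx(3.0 * e1.W_F)

    def test_degenerate_triangle_raises(self):
        params = ModelParams(rho=0.0)
        mesh = tetrahedron(params.l0)
        state = make_state(mesh, params, seed=0)
        state.pos[3] = state.pos[2]  # collapse one face
        with pytest.raises(ValueError):
            energy_total(state, params)


class TestMetropolis:
    def test_downhill_moves_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-1.0, 1.0, rng) for _ in range(100))
        assert all(metropolis_accept(0.0, 1.0, rng) for _ in range(100))

    def test_acceptance_rate_follows_the_boltzmann_factor(self):
        rng = np.random.default_rng(1)
        n = 20000
        acc = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n)) / n
        se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / n)
        assert abs(acc - math.exp(-1)) < 3 * se


class TestMoves:
    def test_invariants_survive_aggressive_sweeps(self, default_params):
        """Topology, bond window, self-avoidance and protein count all hold."""
        params = ModelParams(kappa=10.0, k_A=1.0, w=1.0, F=3.0, c0=1.5, rho=0.2)
        state = make_state(make_vesicle_mesh(162, seed=4), params, seed=4)
        v, e, f = state.n_vertices, state.n_edges, state.n_faces
        run_sweeps(state, params, 200, seed=5, debug=True)
        assert (state.n_vertices, state.n_edges, state.n_faces) == (v, e, f)
        assert int(state.occ.sum()) == state.n_proteins

    def test_incremental_energy_matches_from_scratch(self, default_params):
        state = make_state(make_vesicle_mesh(162, seed=6), default_params, seed=6)
        run_sweeps(state, default_params, 300, seed=7)
        assert state.energy_drift < 1e-6

    def test_runs_are_reproducible_for_equal_seeds(self, default_params):
        out = []
        for _ in range(2):
            state = make_state(make_vesicle_mesh(122, seed=8), default_params, seed=8)
            run_sweeps(state, default_params, 50, seed=9)
            out.append(state.pos.copy())
        assert np.array_equal(out[0], out[1])

    def test_detailed_balance_on_a_two_level_protein_system(self):
        """Frozen bipyramid, one protein: apex/equator occupancy is Boltzmann.

        All bond flips are invalid on this mesh and the vertex-move
        amplitude is zero, so only protein hops act; the long-run apex
        occupancy must match 2 exp(−βW_a) / (2 exp(−βW_a) + 3 exp(−βW_e)).
        """
        params = ModelParams(kappa=5.0, c0=2.0, F=0.5, w=0.0, rho=0.2, delta=0.0)
        state = make_state(bipyramid(), params, seed=0)

        def site_energy(site):
            state.occ[:] = 0
            state.occ[site] = 1
            state.prot[0] = site
            return energy_total(state, params).W

        w_apex, w_eq = site_energy(3), site_energy(0)
        z_apex = 2 * math.exp(-params.beta * w_apex)
        z_eq = 3 * math.exp(-params.beta * w_eq)
        expected = z_apex / (z_apex + z_eq)
        state.occ[:] = 0
        state.occ[0] = 1
        state.prot[0] = 0
        n = 2500
        hits = np.empty(n)
        for k in range(n):
            run_sweeps(state, params, 1, seed=50_000 + k)
            hits[k] = state.occ[3] + state.occ[4]
        blocks = hits.reshape(25, 100).mean(axis=1)
        se = blocks.std(ddof=1) / math.sqrt(len(blocks))
        assert abs(hits.mean() - expected) < 3 * se + 0.01


class TestEquilibrium:
    def test_protein_free_vesicle_relaxes_from_a_squashed_start(self):
        """A force-free vesicle released from plates returns to quasi-spherical."""
        conf = ModelParams(kappa=20.0, w=0.0, F=0.0, c0=0.0, rho=0.0, d=6.0)
        state = make_state(make_vesicle_mesh(302, seed=7), conf, seed=7)
        thermalize(state, conf, n_sweeps=1500, seed=8)
        squashed = observables(state, conf).asphericity
        free = ModelParams(kappa=20.0, w=0.0, F=0.0, c0=0.0, rho=0.0)
        state.z_wall = np.inf
        run_sweeps(state, free, 2500, seed=9)
        relaxed = observables(state, free).asphericity
        assert squashed > 0.05
        assert relaxed < 0.05

    def test_protein_attraction_increases_contact_count(self):
        """At w = 1 kT0 proteins aggregate: more contacts than at w = 0."""
        for seed in (0, 1, 2):
            counts = {}
            for w in (0.0, 1.0):
                params = ModelParams(w=w)
                state = make_state(make_vesicle_mesh(242, seed=seed), params, seed=seed)
                run_sweeps(state, params, 400, seed=100 + seed)
                pp = state.pos[state.prot]
                counts[w] = len(cKDTree(pp).query_pairs(r=params.r0 * (1 - 1e-9)))
            assert counts[1.0] > counts[0.0]


class TestObservables:
    def test_tension_is_zero_for_unstrained_triangles(self):
        params = ModelParams(rho=0.0)
        state = make_state(tetrahedron(params.l0), params, seed=0)
        assert observables(state, params).sigma == pytest.approx(0.0, abs=1e-12)

    def test_tension_scales_with_stretch_modulus_on_fixed_configuration(self, small_mesh):
        p1 = ModelParams(k_A=1.0, rho=0.0)
        p2 = ModelParams(k_A=2.0, rho=0.0)
        s1 = make_state(small_mesh, p1, seed=0)
        s2 = make_state(small_mesh, p2, seed=0)
        assert observables(s2, p2).sigma == pytest.approx(2.0 * observables(s1, p1).sigma)

    def test_equilibrium_tension_increases_with_stretch_modulus(self):
        """Stiffer membranes carry more stretching energy per area in the
        bond-window-limited fluctuation regime."""
        sigmas = {}
        for k_a in (1.0, 10.0):
            vals = []
            for seed in (0, 1, 2):
                params = ModelParams(k_A=k_a, w=0.0, F=0.0, c0=0.0, rho=0.0)
                state = make_state(make_vesicle_mesh(242, seed=seed), params, seed=seed)
                run_sweeps(state, params, 400, seed=200 + seed)
                vals.append(observables(state, params).sigma)
            sigmas[k_a] = np.mean(vals)
        assert sigmas[10.0] > sigmas[1.0]

    def test_asphericity_bounded_in_unit_interval_for_sampled_meshes(self, default_params):
        state = make_state(make_vesicle_mesh(162, seed=11), default_params, seed=11)
        for k in range(5):
            run_sweeps(state, default_params, 50, seed=300 + k)
            a = observables(state, default_params).asphericity
            assert 0.0 <= a <= 1.0

    def test_asphericity_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            asphericity(np.zeros((5, 3)))


class TestConfinement:
    def test_walls_bound_all_vertices(self):
        params = ModelParams(w=0.0, F=0.0, c0=0.0, rho=0.0, d=6.0)
        state = make_state(make_vesicle_mesh(242, seed=3), params, seed=3)
        thermalize(state, params, n_sweeps=1500, seed=4)
        assert np.abs(state.pos[:, 2]).max() <= params.d / 2

    def test_infeasible_gap_aborts_with_diagnostic(self):
        params = ModelParams(w=0.0, F=0.0, c0=0.0, rho=0.0, d=0.8)
        state = make_state(make_vesicle_mesh(162, seed=5), params, seed=5)
        with pytest.raises(ValueError, match="confinement"):
            thermalize(state, params, n_sweeps=200, seed=6)
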