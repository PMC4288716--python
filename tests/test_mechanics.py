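"""Constitutive model and force computation oracles.

The master checks are finite-difference consistency (forces equal minus
the gradient of the energy) and rigid-motion invariance.
"""

import numpy as np
import pytest

from morphomech import mechanics as mech
from morphomech.mechanics import (MembraneSet, OrthotropicMaterial,
                                  PressureSet, SpringElement, SpringSet,
                                  TriangleElement, effective_pressures,
                                  elastic_deformation_gradient,
                                  energy_density, green_lagrange,
                                  pressure_nodal_forces, spring_force,
                                  stress, triangle_nodal_forces)
from morphomech.template_gen import build_icosphere
from morphomech.tissue_mesh import triangulate

MAT = OrthotropicMaterial(Ex=7.0, Ey=3.0, G=2.0)


def _rand_element(rng, material=MAT):
    pts = rng.standard_normal((3, 3))
    while np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) < 0.3:
        pts = rng.standard_normal((3, 3))
    return TriangleElement.from_positions((0, 1, 2), pts, material), pts


class TestDeformationGradient:
    def test_rigid_placement_gives_identity_metric(self, rng):
        el, pts = _rand_element(rng)
        # rotate + translate the rest shape
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        q *= np.sign(np.linalg.det(q))
        moved = pts @ q.T + rng.standard_normal(3)
        F = elastic_deformation_gradient(el, moved)
        assert np.allclose(F.T @ F, np.eye(2), atol=1e-10)

    def test_uniaxial_stretch_along_material_x(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        el = TriangleElement.from_positions((0, 1, 2), pts, MAT,
                                            stiff_dir=[1, 0, 0])
        lam = 1.3
        stretched = pts * np.array([lam, 1.0, 1.0])
        F = elastic_deformation_gradient(el, stretched)
        assert np.allclose(F.T @ F, np.diag([lam ** 2, 1.0]), atol=1e-12)

    def test_metric_matches_gram_matrix_oracle(self, rng):
        el, pts = _rand_element(rng)
        cur = pts + 0.2 * rng.standard_normal((3, 3))
        F = elastic_deformation_gradient(el, cur)
        # independent: FtF = R^-T Gram(current edges) R^-1
        D = np.stack([cur[1] - cur[0], cur[2] - cur[0]], axis=1)
        gram = D.T @ D
        Rinv = np.linalg.inv(el.R)
        assert np.allclose(F.T @ F, Rinv.T @ gram @ Rinv, atol=1e-12)

    def test_degenerate_rest_shape_rejected(self):
        with pytest.raises(mech.ElementError):
            TriangleElement((0, 1, 2), [[1.0, 2.0], [0.5, 1.0]], MAT)


class TestGreenLagrange:
    def test_rigid_is_zero(self):
        assert np.allclose(green_lagrange(np.eye(3, 2)), 0.0)

    def test_uniaxial(self):
        lam = 1.4
        F = np.diag([lam, 1.0])[..., :2]
        E = green_lagrange(np.vstack([F, np.zeros(2)]))
        assert E[0, 0] == pytest.approx((lam ** 2 - 1) / 2)
        assert E[1, 1] == 0 and E[0, 1] == 0

    def test_simple_shear_expansion(self):
        # x' = x + gamma*y: E_xy = gamma/2, E_yy = gamma^2/2 (symbolic)
        gamma = 0.37
        F = np.array([[1.0, gamma], [0.0, 1.0], [0.0, 0.0]])
        E = green_lagrange(F)
        assert E[0, 1] == pytest.approx(gamma / 2)
        assert E[1, 1] == pytest.approx(gamma ** 2 / 2)
        assert E[0, 0] == pytest.approx(0.0)


class TestStressAndEnergy:
    def test_zero_strain_zero_stress_zero_energy(self):
        E = np.zeros((2, 2))
        assert np.allclose(stress(E, MAT), 0.0)
        assert energy_density(E, MAT) == 0.0

    def test_null_poisson_decoupling(self):
        E = np.array([[0.05, 0.0], [0.0, 0.0]])
        S = stress(E, MAT)
        assert S[0, 0] == pytest.approx(MAT.Ex * 0.05)
        assert S[1, 1] == 0.0 and S[0, 1] == 0.0

    def test_energy_analytic_cases(self):
        e = 0.04
        E = np.diag([e, 0.0])
        assert energy_density(E, MAT) == pytest.approx(0.5 * MAT.Ex * e ** 2)
        iso = OrthotropicMaterial(5.0, 5.0, 2.5)
        Eb = np.diag([e, e])
        assert energy_density(Eb, iso) == pytest.approx(iso.Ex * e ** 2)

    def test_stress_is_energy_gradient(self, rng):
        # dW = S : dE with symmetric perturbations
        for _ in range(20):
            A = rng.standard_normal((2, 2))
            E = 0.1 * (A + A.T) / 2
            S = stress(E, MAT)
            h = 1e-7
            for (i, j) in ((0, 0), (1, 1), (0, 1)):
                dE = np.zeros((2, 2))
                dE[i, j] = dE[j, i] = h
                fd = (energy_density(E + dE, MAT)
                      - energy_density(E - dE, MAT)) / (2 * h)
                # dW = S:dE -> h*S_ii for a diagonal bump, 2h*S_xy for the
                # symmetric shear pair
                expected = S[i, j] * (1 if i == j else 2)
                assert fd == pytest.approx(expected, rel=1e-6, abs=1e-8)


class TestTriangleForces:
    def test_zero_at_rest(self, rng):
        el, pts = _rand_element(rng)
        assert np.allclose(triangle_nodal_forces(el, pts), 0.0, atol=1e-12)

    def test_forces_sum_and_torque_vanish(self, rng):
        for _ in range(10):
            el, pts = _rand_element(rng)
            cur = pts + 0.3 * rng.standard_normal((3, 3))
            f = triangle_nodal_forces(el, cur)
            scale = np.abs(f).max() + 1e-30
            assert np.linalg.norm(f.sum(axis=0)) < 1e-10 * scale
            cen = cur.mean(axis=0)
            torque = sum(np.cross(cur[i] - cen, f[i]) for i in range(3))
            assert np.linalg.norm(torque) < 1e-9 * scale

    def test_matches_finite_difference_of_energy(self, rng):
        el, pts = _rand_element(rng)
        cur = pts + 0.25 * rng.standard_normal((3, 3))
        f = triangle_nodal_forces(el, cur)
        h = 1e-6

        def total(p):
            F = elastic_deformation_gradient(el, p)
            return el.rest_area * energy_density(green_lagrange(F),
                                                 el.material)

        for i in range(3):
            for c in range(3):
                plus, minus = cur.copy(), cur.copy()
                plus[i, c] += h
                minus[i, c] -= h
                fd = -(total(plus) - total(minus)) / (2 * h)
                assert f[i, c] == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestSpringForce:
    def test_zero_at_rest_length(self):
        s = SpringElement((0, 1), k=3.0, l0=2.0)
        pts = np.array([[0, 0, 0], [2, 0, 0]], float)
        assert np.allclose(spring_force(s, pts), 0.0)

    def test_magnitude_k_at_double_length(self):
        s = SpringElement((0, 1), k=3.0, l0=1.0)
        pts = np.array([[0, 0, 0], [2, 0, 0]], float)
        f = spring_force(s, pts)
        assert np.allclose(f[0], [3.0, 0, 0])    # node 0 pulled toward node 1
        assert np.allclose(f[1], [-3.0, 0, 0])

    def test_matches_finite_difference_of_energy(self, rng):
        s = SpringElement((0, 1), k=2.5, l0=0.8)
        pts = rng.standard_normal((2, 3))
        f = spring_force(s, pts)
        h = 1e-7

        def U(p):
            l = np.linalg.norm(p[1] - p[0])
            return 0.5 * s.k * s.l0 * ((l - s.l0) / s.l0) ** 2

        for i in range(2):
            for c in range(3):
                plus, minus = pts.copy(), pts.copy()
                plus[i, c] += h
                minus[i, c] -= h
                fd = -(U(plus) - U(minus)) / (2 * h)
                assert f[i, c] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_coincident_nodes_rejected(self):
        s = SpringElement((0, 1), k=1.0, l0=1.0)
        with pytest.raises(mech.ElementError):
            spring_force(s, np.zeros((2, 3)))


class TestPressureForces:
    def test_single_triangle_gets_third_of_load(self):
        pts = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]], float)
        out = pressure_nodal_forces([[0, 1, 2]], [5.0], pts)
        expected = 5.0 * 2.0 / 3.0 * np.array([0, 0, 1.0])  # P*A*n/3, A=2
        for i in range(3):
            assert np.allclose(out[i], expected)

    def test_closed_cube_net_force_and_torque_vanish(self, cube_mesh):
        tri = triangulate(cube_mesh)
        x = cube_mesh.vertices
        out = pressure_nodal_forces(tri.triangles, 2.0, x)
        scale = np.abs(out).sum()
        assert np.linalg.norm(out.sum(axis=0)) < 1e-10 * scale
        torque = np.cross(x - x.mean(axis=0), out).sum(axis=0)
        assert np.linalg.norm(torque) < 1e-10 * scale

    def test_icosphere_total_outward_load_approaches_pressure(self):
        # mean(force)/area -> P as the sphere is refined
        for sub, tol in ((2, 0.02), (3, 0.005)):
            mesh = build_icosphere(1.0, sub)
            tri = triangulate(mesh)
            x = mesh.vertices
            out = pressure_nodal_forces(tri.triangles, 1.0, x)
            radial = np.einsum("ij,ij->i", out,
                               x / np.linalg.norm(x, axis=1, keepdims=True))
            area = sum(0.5 * np.linalg.norm(np.cross(
                x[b] - x[a], x[c] - x[a])) for a, b, c in tri.triangles)
            assert radial.sum() / area == pytest.approx(1.0, rel=tol)


class TestEffectivePressure:
    def test_uniform_pressure_cancels_on_inner_walls(self, small_dome):
        p = effective_pressures(small_dome, np.ones(len(small_dome.cells)))
        for wi, adj in enumerate(small_dome.wall_cells):
            assert p[wi] == (1.0 if len(adj) == 1 else 0.0)

    def test_triple_pressure_cell_loads_walls_with_difference(self, small_dome):
        cp = np.ones(len(small_dome.cells))
        inner_cells = [ci for ci in range(len(small_dome.cells))
                       if small_dome.region_labels[ci] == "inner"]
        target = inner_cells[0]
        cp[target] = 3.0
        p = effective_pressures(small_dome, cp)
        for wi, adj in enumerate(small_dome.wall_cells):
            if len(adj) == 2 and target in adj:
                other = adj[0] if adj[1] == target else adj[1]
                if cp[other] == 1.0:
                    assert abs(p[wi]) == pytest.approx(2.0)

    def test_swapping_pressures_flips_wall_sign(self, small_dome):
        cp = np.ones(len(small_dome.cells))
        wi, adj = next((w, a) for w, a in enumerate(small_dome.wall_cells)
                       if len(a) == 2)
        cp[adj[0]], cp[adj[1]] = 2.0, 5.0
        p1 = effective_pressures(small_dome, cp)[wi]
        cp[adj[0]], cp[adj[1]] = 5.0, 2.0
        p2 = effective_pressures(small_dome, cp)[wi]
        assert p1 == -p2 != 0


class TestBatchSets:
    def test_membrane_set_matches_scalar_elements(self, rng):
        pts = rng.standard_normal((6, 3)) * 2
        tris = np.array([[0, 1, 2], [3, 4, 5]])
        mset = MembraneSet.from_triangles(pts, tris, None,
                                          [7.0, 4.0], [3.0, 2.0], [2.0, 1.0])
        cur = pts + 0.2 * rng.standard_normal((6, 3))
        out = np.zeros_like(cur)
        mset.add_forces(cur, out)
        total = 0.0
        expected = np.zeros_like(cur)
        for t, (Ex, Ey, G) in enumerate([(7, 3, 2), (4, 2, 1)]):
            el = TriangleElement(tuple(tris[t]), mset.R[t],
                                 OrthotropicMaterial(Ex, Ey, G))
            f = triangle_nodal_forces(el, cur)
            for i, n in enumerate(tris[t]):
                expected[n] += f[i]
            F = elastic_deformation_gradient(el, cur)
            total += el.rest_area * energy_density(green_lagrange(F),
                                                   el.material)
        assert np.allclose(out, expected, atol=1e-12)
        assert mset.energy(cur) == pytest.approx(total)

    def test_spring_set_matches_scalar_elements(self, rng):
        pts = rng.standard_normal((4, 3))
        sset = SpringSet([[0, 1], [2, 3]], [2.0, 3.0], [1.0, 0.5])
        out = np.zeros_like(pts)
        sset.add_forces(pts, out)
        expected = np.zeros_like(pts)
        for nodes, k, l0 in (((0, 1), 2.0, 1.0), ((2, 3), 3.0, 0.5)):
            f = spring_force(SpringElement(nodes, k, l0), pts)
            expected[nodes[0]] += f[0]
            expected[nodes[1]] += f[1]
        assert np.allclose(out, expected, atol=1e-12)

    def test_pressure_potential_gradient_is_force(self, cube_mesh, rng):
        tri = triangulate(cube_mesh)
        pset = PressureSet(tri.triangles, 1.5)
        x = cube_mesh.vertices + 0.05 * rng.standard_normal(
            cube_mesh.vertices.shape)
        f = np.zeros_like(x)
        pset.add_forces(x, f)
        h = 1e-6
        for i in (0, 5):
            for c in range(3):
                plus, minus = x.copy(), x.copy()
                plus[i, c] += h
                minus[i, c] -= h
                fd = -(pset.potential(plus) - pset.potential(minus)) / (2 * h)
                assert f[i, c] == pytest.approx(fd, rel=1e-6, abs=1e-9)


class TestRigidMotionInvariance:
    def test_energy_invariant_forces_covariant(self, rng, small_dome):
        from morphomech.scenarios import scenario_suite
        from morphomech.simulator import SimulationSystem

        sc = scenario_suite()["uniform-dome"]
        system = SimulationSystem(small_dome, sc)
        x = small_dome.vertices * 1.03  # stressed state
        e0 = system.state.elastic_energy(x)
        f0 = system.state.raw_forces(x)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            q *= np.sign(np.linalg.det(q))
            t = rng.standard_normal(3)
            xr = x @ q.T + t
            e1 = system.state.elastic_energy(xr)
            assert abs(e1 - e0) < 1e-9 * abs(e0)
            f1 = system.state.raw_forces(xr)
            # pressure is a follower load; restrict to elastic+spring parts
            fe0 = np.zeros_like(x)
            system.state.membranes.add_forces(x, fe0)
            system.state.springs.add_forces(x, fe0)
            fe1 = np.zeros_like(x)
            system.state.membranes.add_forces(xr, fe1)
            system.state.springs.add_forces(xr, fe1)
            assert np.allclose(fe1, fe0 @ q.T,
                               atol=1e-9 * np.abs(fe0).max())

    def test_global_internal_force_balance(self, small_dome):
        from morphomech.scenarios import scenario_suite
        from morphomech.simulator import SimulationSystem

        system = SimulationSystem(small_dome, scenario_suite()["uniform-dome"])
        x = small_dome.vertices * 1.05
        f = np.zeros_like(x)
        system.state.membranes.add_forces(x, f)
        system.state.springs.add_forces(x, f)
        scale = np.abs(f).sum() + 1e-30
        assert np.linalg.norm(f.sum(axis=0)) < 1e-10 * scale
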