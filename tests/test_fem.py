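"""Macroscale FE solver: elements, boundary conditions, Newton iteration."""

import numpy as np
import pytest

import pcmech as pm
from pcmech import fem
from pcmech.mesh import HexMesh
from pcmech.network import RveLibrary


def unit_block_mesh(n=1, size=1.0):
    """n×n×n block of hexes on [0, size]^3 with surface/base/sides sets."""
    g = np.linspace(0, size, n + 1)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    coords = np.column_stack([X.ravel(order="F"), Y.ravel(order="F"),
                              Z.ravel(order="F")])
    nid = lambda i, j, k: i + (n + 1) * (j + (n + 1) * k)
    elems = []
    for k in range(n):
        for j in range(n):
            for i in range(n):
                elems.append([nid(i, j, k), nid(i + 1, j, k),
                              nid(i + 1, j + 1, k), nid(i, j + 1, k),
                              nid(i, j, k + 1), nid(i + 1, j, k + 1),
                              nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    c = coords
    sets = {
        "surface": np.flatnonzero(c[:, 2] > size - 1e-12),
        "base": np.flatnonzero(c[:, 2] < 1e-12),
        "sides": np.flatnonzero((np.abs(c[:, 0] - size / 2) > size / 2 - 1e-12)
                                | (np.abs(c[:, 1] - size / 2) > size / 2 - 1e-12)),
        "boundary": np.flatnonzero(
            np.any((c < 1e-12) | (c > size - 1e-12), axis=1)),
    }
    return HexMesh(coords, np.asarray(elems, dtype=np.int64),
                   np.zeros(n ** 3, dtype=np.int64), node_sets=sets)


def uniform_library(mesh, net):
    """Every Gauss point shares the same network realization (patch tests)."""
    return RveLibrary([net] * (8 * mesh.n_elements), mesh.n_elements, net.seed)


class TestShapeGradients:
    def test_unit_cube_jacobian(self):
        m = unit_block_mesh(1)
        for g in range(8):
            _, detJ = pm.shape_gradients(m, 0, g)
            assert detJ == pytest.approx(1 / 8)  # volume 1 over 8 Gauss points

    def test_translation_invariance(self):
        m1 = unit_block_mesh(1)
        m2 = unit_block_mesh(1)
        m2.node_coords = m2.node_coords + np.array([5.0, -3.0, 2.0])
        for g in range(8):
            d1, _ = pm.shape_gradients(m1, 0, g)
            d2, _ = pm.shape_gradients(m2, 0, g)
            assert np.allclose(d1, d2)

    def test_affine_displacement_reproduced_exactly(self, params):
        # trilinear elements are exact for affine fields
        m = unit_block_mesh(1)
        A = np.array([[0.02, 0.01, 0], [0, -0.01, 0.005], [0.003, 0, 0.015]])
        u = m.node_coords @ A.T
        dN, _ = pm.shape_gradients(m, 0, 3)
        F = np.eye(3) + u[m.elements[0]].T @ dN
        assert np.allclose(F, np.eye(3) + A, atol=1e-12)

    def test_bad_gauss_index(self):
        with pytest.raises(ValueError):
            pm.shape_gradients(unit_block_mesh(1), 0, 8)


class TestIndenter:
    def test_inclusive_footprint_radius(self):
        m = unit_block_mesh(2, size=250.0)  # surface nodes at x,y ∈ {0,125,250}
        prot = fem.IndentationProtocol(kind="cylinder", diameter=250.0,
                                       center=(0.0, 0.0), increments=(5.0,))
        foot = fem.footprint_nodes(m, prot)
        r = np.linalg.norm(m.node_coords[foot, :2], axis=1)
        assert np.isclose(r.max(), 125.0)  # node at exactly the radius: included
        # node at (125, 125): r ≈ 177 > 125 -> free
        assert not any(np.allclose(m.node_coords[f, :2], [125, 125])
                       for f in foot)

    def test_empty_footprint_raises(self):
        m = unit_block_mesh(1, size=1000.0)
        prot = fem.IndentationProtocol(kind="cylinder", diameter=100.0,
                                       center=(500.0, 500.0))
        with pytest.raises(ValueError, match="refine"):
            fem.footprint_nodes(m, prot)

    def test_single_node_kind(self):
        m = unit_block_mesh(2, size=100.0)
        prot = fem.IndentationProtocol(kind="node", center=(50.0, 50.0))
        assert len(fem.footprint_nodes(m, prot)) == 1

    def test_prescribed_values_downward(self):
        m = unit_block_mesh(2, size=250.0)
        prot = fem.IndentationProtocol(kind="cylinder", diameter=250.0,
                                       center=(0, 0), increments=(4.0,),
                                       fixed={"base": "clamp"})
        mask, vals = fem.apply_indenter(m, prot, 4.0)
        foot = fem.footprint_nodes(m, prot)
        assert np.all(vals[foot, 2] == -4.0)
        assert mask[m.node_sets["base"]].all()

    def test_negative_increment_rejected(self):
        with pytest.raises(ValueError):
            fem.IndentationProtocol(increments=(1.0, -1.0))


class TestPatchAndBalance:
    def test_patch_test_matches_single_rve(self, params, small_rve):
        # homogeneous 2x2x2 block under affine Dirichlet BCs: every interior
        # Gauss point must carry the single-RVE stress (same network shared)
        m = unit_block_mesh(2, size=100.0)
        lib = uniform_library(m, small_rve)
        grad = np.array([[0.01, 0.004, 0], [0, -0.008, 0.002], [0, 0, 0.012]])
        bnd = m.node_sets["boundary"]
        mask = np.zeros((m.n_nodes, 3), dtype=bool)
        mask[bnd] = True
        vals = np.zeros((m.n_nodes, 3))
        vals[bnd] = m.node_coords[bnd] @ grad.T
        state = pm.solve_dirichlet(m, mask, vals, lib, params)
        F = np.eye(3) + grad
        S_oracle, _ = pm.rve_total_stress(small_rve, F, params, tangent=False)
        S = state.S_gp.reshape(-1, 3, 3)
        scale = max(np.abs(S_oracle).max(), 1e-12)
        for s in S:
            assert np.abs(s - S_oracle).max() < 1e-6 * scale
        assert np.allclose(state.F_gp, F, atol=1e-10)

    def test_global_force_balance(self, params, small_rve):
        m = unit_block_mesh(2, size=100.0)
        lib = uniform_library(m, small_rve)
        prot = fem.IndentationProtocol(kind="node", center=(50.0, 50.0),
                                       increments=(2.0,),
                                       fixed={"base": "clamp"})
        s = pm.newton_solve(m, prot, lib, params)[-1]
        # reactions on prescribed dofs balance: total force sums to ~0
        total = s.reactions.sum(axis=0)
        assert np.abs(total).max() < 50 * max(np.abs(s.reactions).max(), 1e-12) * 1e-3

    def test_zero_depth_protocol_gives_zero_solution(self, params, small_rve):
        m = unit_block_mesh(2, size=100.0)
        lib = uniform_library(m, small_rve)
        prot = fem.IndentationProtocol(kind="node", center=(50.0, 50.0),
                                       increments=(0.0,),
                                       fixed={"base": "clamp"})
        s = pm.newton_solve(m, prot, lib, params)[-1]
        assert np.abs(s.u).max() == 0.0

    def test_zero_displacement_zero_residual(self, params, small_rve):
        m = unit_block_mesh(2, size=100.0)
        packed = fem.pack_library(uniform_library(m, small_rve))
        r = pm.assemble_residual(m, np.zeros((m.n_nodes, 3)), packed, params)
        assert np.abs(r).max() < 1e-9 * params.A

    def test_single_element_uniform_stress_nodal_forces(self, params, small_rve):
        # one element under affine displacement: nodal forces equal the
        # closed-form equivalent of a uniform-stress element, f = B^T P V
        m = unit_block_mesh(1, size=50.0)
        packed = fem.pack_library(uniform_library(m, small_rve))
        grad = np.diag([0.02, -0.01, 0.015])
        u = m.node_coords @ grad.T
        r = pm.assemble_residual(m, u, packed, params)
        F = np.eye(3) + grad
        S, _ = pm.rve_total_stress(small_rve, F, params, tangent=False)
        P = np.linalg.det(F) * S @ np.linalg.inv(F).T
        expected = np.zeros_like(r)
        for g in range(8):
            dN, detJ = pm.shape_gradients(m, 0, g)
            expected[m.elements[0]] += detJ * dN @ P.T
        assert np.allclose(r, expected, atol=1e-8 * max(np.abs(expected).max(), 1))


class TestNewtonSolve:
    def test_mirror_symmetric_displacements_matrix_only(self, params):
        # symmetric mesh + symmetric (matrix-only) constitutive response:
        # a centered indentation gives mirror-symmetric displacement fields
        m = pm.mesh_half_ellipsoid(pm.CorpuscleGeometry(), resolution=2)
        lib = pm.matrix_only_library(m)
        prot = fem.isolated_protocol(m, increments=(5.0,))
        s = pm.newton_solve(m, prot, lib, params)[-1]
        c = m.node_coords
        key = np.round(c / 1e-3).astype(np.int64)
        lookup = {tuple(k): i for i, k in enumerate(key)}
        for i, k in enumerate(key):
            j = lookup[(-k[0], k[1], k[2])]
            assert s.u[i, 2] == pytest.approx(s.u[j, 2], abs=1e-5)
            assert s.u[i, 0] == pytest.approx(-s.u[j, 0], abs=1e-5)

    def test_halving_increments_path_independence(self, params, small_rve):
        m = unit_block_mesh(2, size=100.0)
        lib = uniform_library(m, small_rve)
        tol = 1e-8
        mk = lambda inc: pm.newton_solve(
            m, fem.IndentationProtocol(kind="node", center=(50.0, 50.0),
                                       increments=inc, fixed={"base": "clamp"}),
            fem.pack_library(lib), params, tol_rel=1e-7, tol_abs=1e-8)[-1]
        a = mk((4.0,))
        b = mk((2.0, 2.0))
        assert np.abs(a.u - b.u).max() < 1e-3 * np.abs(a.u).max()

    def test_nonconvergence_reports_history(self, params, small_rve):
        m = unit_block_mesh(2, size=100.0)
        lib = uniform_library(m, small_rve)
        prot = fem.IndentationProtocol(kind="node", center=(50.0, 50.0),
                                       increments=(5.0,),
                                       fixed={"base": "clamp"})
        with pytest.raises(fem.MacroNonConvergence, match="smaller"):
            pm.newton_solve(m, prot, lib, params, max_iter=1)

    def test_determinism_bitwise(self, params, tiny_isolated_mesh):
        m = tiny_isolated_mesh
        mk = lambda: pm.newton_solve(
            m, fem.isolated_protocol(m, increments=(3.0,)),
            pm.assign_networks(m, {"corpuscle": pm.AlignmentPolicy("isotropic")},
                               seed=4, fiber_count_range=(30, 70)),
            params)[-1]
        a, b = mk(), mk()
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.S_gp, b.S_gp)

    def test_eq4_flag_runs_and_logs(self, params, small_rve, caplog):
        import logging
        m = unit_block_mesh(1, size=100.0)
        lib = uniform_library(m, small_rve)
        prot = fem.IndentationProtocol(kind="node", center=(50.0, 50.0),
                                       increments=(1.0,),
                                       fixed={"base": "clamp"})
        with caplog.at_level(logging.INFO, logger="pcmech.fem"):
            pm.newton_solve(m, prot, lib, params, eq4_correction=True)
        assert any("surface-term" in r.message for r in caplog.records)
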