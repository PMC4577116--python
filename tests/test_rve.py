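"""RVE micromechanics: fiber law, equilibrium, homogenized stress."""

import numpy as np
import pytest

import pcmech as pm
from pcmech.materials import MaterialParams
from pcmech.rve import RveDivergenceError

from conftest import two_node_network


def brute_force_boundary_stress(net, x, params, volume):
    """Independent Eq-style oracle: loop fibers, accumulate nodal forces,
    sum x ⊗ reaction over boundary nodes."""
    fnode = np.zeros((net.n_nodes, 3))
    for (p, q), L0 in zip(net.fibers, net.rest_lengths):
        v = x[q] - x[p]
        l = np.linalg.norm(v)
        lam = l / L0
        E = 0.5 * (lam ** 2 - 1)
        f = (params.A / params.B) * (np.exp(params.B * E) - 1.0)
        fnode[p] += f * v / l
        fnode[q] -= f * v / l
    S = np.zeros((3, 3))
    for i in np.flatnonzero(net.boundary_mask):
        S += np.outer(x[i], -fnode[i])
    return S / volume


def interior_residual(net, x, params):
    """Independent equilibrium certificate: max interior nodal force."""
    fnode = np.zeros((net.n_nodes, 3))
    for (p, q), L0 in zip(net.fibers, net.rest_lengths):
        v = x[q] - x[p]
        lam = np.linalg.norm(v) / L0
        f = (params.A / params.B) * (np.exp(params.B * 0.5 * (lam ** 2 - 1)) - 1)
        fnode[p] += f * v / np.linalg.norm(v)
        fnode[q] -= f * v / np.linalg.norm(v)
    interior = ~net.boundary_mask
    return np.abs(fnode[interior]).max() if interior.any() else 0.0


class TestFiberLaw:
    @pytest.mark.parametrize("lam, expected", [
        (1.0, 0.0), (1.1, 0.105), (0.9, -0.095)])
    def test_green_strain_values(self, lam, expected):
        assert pm.fiber_green_strain(lam) == pytest.approx(expected)

    def test_green_strain_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pm.fiber_green_strain(0.0)

    def test_force_zero_at_zero_strain(self, params):
        assert pm.fiber_force(0.0, params) == 0.0

    def test_small_strain_slope_equals_A(self, params):
        h = 1e-8
        slope = (pm.fiber_force(h, params) - pm.fiber_force(-h, params)) / (2 * h)
        assert slope == pytest.approx(params.A, rel=1e-6)

    def test_reference_value(self, params):
        # (114/10)(e^{1.05} − 1) evaluated independently
        assert pm.fiber_force(0.105, params) == pytest.approx(
            11.4 * (np.exp(1.05) - 1.0))
        assert pm.fiber_force(0.105, params) == pytest.approx(21.177, abs=5e-3)

    def test_strictly_increasing(self, params):
        E = np.linspace(-0.5, 0.5, 101)
        assert np.all(np.diff(pm.fiber_force(E, params)) > 0)

    def test_overflow_guard(self, params):
        with pytest.raises(RveDivergenceError):
            pm.fiber_force(100.0, params)


class TestAffineBoundary:
    def test_identity_gives_zero(self, small_rve):
        disp = pm.apply_affine_boundary(small_rve, np.eye(3))
        assert np.allclose(disp[small_rve.boundary_mask], 0.0)

    def test_uniaxial_scales_x(self, small_rve):
        F = np.diag([1.1, 1.0, 1.0])
        disp = pm.apply_affine_boundary(small_rve, F)
        b = small_rve.boundary_mask
        assert np.allclose(disp[b, 0], 0.1 * small_rve.node_coords[b, 0])
        assert np.allclose(disp[b, 1:], 0.0)

    def test_noninvertible_rejected(self, small_rve):
        with pytest.raises(ValueError):
            pm.apply_affine_boundary(small_rve, np.zeros((3, 3)))


class TestEquilibrium:
    def test_all_boundary_network_follows_affine(self, params):
        net = two_node_network([0, .5, .5], [1, .5, .5], 1.0)
        F = np.diag([1.2, 1.0, 1.0])
        st = pm.solve_rve_equilibrium(net, None, params, macro_F=F)
        assert st.fiber_stretches[0] == pytest.approx(1.2)

    def test_symmetric_interior_node_stays_at_midpoint(self, params):
        net = pm.FiberNetwork(
            node_coords=np.array([[0, .5, .5], [.5, .5, .5], [1, .5, .5]]),
            fibers=np.array([[0, 1], [1, 2]], dtype=np.int32),
            rest_lengths=np.array([0.5, 0.5]),
            boundary_mask=np.array([True, False, True]),
        )
        F = np.diag([1.3, 1.0, 1.0])
        st = pm.solve_rve_equilibrium(net, None, params, macro_F=F)
        assert st.network.node_coords[1] == pytest.approx([0.65, 0.5, 0.5])

    def test_residual_certificate_random_net(self, params, small_rve):
        F = np.eye(3) + np.array([[0.02, 0.01, 0], [0, -0.015, 0.005],
                                  [0, 0, 0.01]])
        st = pm.solve_rve_equilibrium(small_rve, None, params, macro_F=F)
        tol = 1e-8 * params.A
        assert interior_residual(small_rve, st.network.node_coords,
                                 params) < tol

    def test_rigid_rotation_leaves_stretches_at_one(self, params, small_rve):
        # objectivity: a rotation is stress- and stretch-free
        from scipy.spatial.transform import Rotation
        Q = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        st = pm.solve_rve_equilibrium(small_rve, None, params, macro_F=Q)
        assert np.allclose(st.fiber_stretches, 1.0, atol=1e-9)
        assert np.abs(st.avg_stress).max() < 1e-8 * params.A

    def test_explicit_boundary_displacements(self, params, small_rve):
        F = np.diag([1.05, 1.0, 1.0])
        disp = pm.apply_affine_boundary(small_rve, F)
        disp[~small_rve.boundary_mask] = 0.0
        a = pm.solve_rve_equilibrium(small_rve, disp, params)
        b = pm.solve_rve_equilibrium(small_rve, None, params, macro_F=F)
        assert np.allclose(a.network.node_coords, b.network.node_coords,
                           atol=1e-6)


class TestVolumeAvgStress:
    def test_single_fiber_closed_form(self, params):
        # fiber spanning x=0..1, rest length 0.8: S_xx = f / V, rest zero
        net = two_node_network([0, .5, .5], [1, .5, .5], 0.8)
        st = pm.solve_rve_equilibrium(net, None, params, macro_F=np.eye(3))
        f = pm.fiber_force(pm.fiber_green_strain(1 / 0.8), params)
        S = pm.volume_avg_stress(st, params)
        assert S[0, 0] == pytest.approx(f)
        S_off = S.copy(); S_off[0, 0] = 0.0
        assert np.abs(S_off).max() < 1e-12 * abs(f)

    def test_zero_forces_zero_stress(self, params):
        net = two_node_network([0, .5, .5], [1, .5, .5], 1.0)
        st = pm.solve_rve_equilibrium(net, None, params, macro_F=np.eye(3))
        assert np.allclose(pm.volume_avg_stress(st, params), 0.0)

    def test_brute_force_oracle_small_networks(self, params):
        # Eq-style boundary sum recomputed by an independent loop, <= 5 fibers
        rng = np.random.default_rng(0)
        for trial in range(4):
            pts = np.array([[0, .3, .4], [1, .6, .5], [.5, .5, .5],
                            [.4, 0, .6], [.6, 1, .4]])
            fibers = np.array([[0, 2], [1, 2], [2, 3], [2, 4]], dtype=np.int32)
            L0 = np.linalg.norm(pts[fibers[:, 1]] - pts[fibers[:, 0]],
                                axis=1) * rng.uniform(0.85, 1.0, 4)
            net = pm.FiberNetwork(pts, fibers, L0,
                                  np.array([1, 1, 0, 1, 1], dtype=bool))
            F = np.eye(3) + rng.normal(0, 0.03, (3, 3))
            if np.linalg.det(F) <= 0:
                continue
            st = pm.solve_rve_equilibrium(net, None, params, macro_F=F)
            oracle = brute_force_boundary_stress(
                net, st.network.node_coords, params, st.rve_volume)
            assert np.allclose(st.avg_stress, oracle, atol=1e-10)

    def test_isotropic_expansion_near_hydrostatic(self, params):
        # ensemble-mean stress under isotropic expansion is near hydrostatic
        S = np.zeros((3, 3))
        n = 6
        for seed in range(n):
            net = pm.generate_rve_network((80, 140), np.eye(3), seed=seed)
            st = pm.solve_rve_equilibrium(net, None, params,
                                          macro_F=1.03 * np.eye(3))
            S += st.avg_stress / n
        off = np.abs(S - np.diag(np.diag(S))).max()
        assert off < 0.2 * np.abs(np.diag(S)).mean()


class TestMatrixStress:
    def test_identity_zero(self, params):
        assert np.allclose(pm.matrix_stress(np.eye(3), params), 0.0)

    def test_small_simple_shear(self, params):
        g = 1e-6
        F = np.eye(3); F[0, 1] = g
        S = pm.matrix_stress(F, params)
        assert S[0, 1] == pytest.approx(params.G * g, rel=1e-4)

    def test_closed_form_oracle_from_strain_energy(self, params):
        # independent oracle: σ = (1/J) (dW/dF) Fᵀ with dW/dF by central FD
        F = np.diag([1.05, 0.99, 1.01]); F[0, 2] = 0.02
        G, K = params.G, params.bulk_modulus

        def W(Fm):
            J = np.linalg.det(Fm)
            I1 = np.trace(Fm.T @ Fm)
            return 0.5 * G * (I1 - 3 - 2 * np.log(J)) + 0.5 * K * np.log(J) ** 2

        h = 1e-7
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp = F.copy(); Fp[i, j] += h
                Fm_ = F.copy(); Fm_[i, j] -= h
                P[i, j] = (W(Fp) - W(Fm_)) / (2 * h)
        sigma_oracle = P @ F.T / np.linalg.det(F)
        assert np.allclose(pm.matrix_stress(F, params), sigma_oracle,
                           rtol=1e-6, atol=1e-8)

    def test_nonpositive_det_rejected(self, params):
        with pytest.raises(ValueError):
            pm.matrix_stress(-np.eye(3), params)


class TestTotalStress:
    def test_empty_network_reduces_to_matrix(self, params):
        empty = pm.FiberNetwork(np.zeros((0, 3)), np.zeros((0, 2), np.int32),
                                np.zeros(0), np.zeros(0, bool))
        F = np.diag([1.07, 0.98, 1.0])
        S, _ = pm.rve_total_stress(empty, F, params, tangent=False)
        Sm = pm.matrix_stress(F, params)
        assert np.abs(S - Sm).max() <= 1e-8 * max(np.abs(Sm).max(), 1.0)

    def test_identity_zero_total(self, params, small_rve):
        S, _ = pm.rve_total_stress(small_rve, np.eye(3), params, tangent=False)
        assert np.abs(S).max() < 1e-8 * params.A

    def test_tangent_richardson(self, params, small_rve):
        # tangent column vs directional difference at half the step
        F = np.diag([1.02, 1.0, 0.99])
        S0, C = pm.rve_total_stress(small_rve, F, params, fd_step=2e-5)
        h = 1e-5
        D = np.zeros((3, 3)); D[0, 0] = 1.0
        Sp, _ = pm.rve_total_stress(small_rve, (np.eye(3) + h * D) @ F,
                                    params, tangent=False)
        Sm, _ = pm.rve_total_stress(small_rve, (np.eye(3) - h * D) @ F,
                                    params, tangent=False)
        col = (Sp - Sm) / (2 * h)
        assert C[0, 0] == pytest.approx(col[0, 0], rel=5e-3)
        assert C[1, 0] == pytest.approx(col[1, 1], rel=5e-3, abs=1e-3 * abs(C[0, 0]))

    def test_objectivity_under_rotation(self, params, small_rve):
        from scipy.spatial.transform import Rotation
        F = np.diag([1.04, 1.0, 0.98]); F[0, 1] = 0.02
        Q = Rotation.from_rotvec([0.4, 0.1, -0.3]).as_matrix()
        S, _ = pm.rve_total_stress(small_rve, F, params, tangent=False)
        SQ, _ = pm.rve_total_stress(small_rve, Q @ F, params, tangent=False)
        assert np.allclose(SQ, Q @ S @ Q.T,
                           atol=1e-6 * max(np.abs(S).max(), 1.0))

    def test_stress_symmetry(self, params):
        for seed in (1, 2, 3):
            net = pm.generate_rve_network((80, 140), np.eye(3), seed=seed)
            F = np.diag([1.03, 0.99, 1.01])
            S, _ = pm.rve_total_stress(net, F, params, tangent=False)
            assert np.linalg.norm(S - S.T) < 1e-6 * np.linalg.norm(S)

    def test_aligned_stiffer_along_alignment_axis(self, params):
        # ensemble ordering: x-aligned networks carry more stress under
        # x-stretch than isotropic ones at the same macroscopic F
        M = np.diag([3.0, 1.0, 1.0])
        F = np.diag([1.05, 1.0, 1.0])
        sal = siso = 0.0
        for seed in range(4):
            al = pm.generate_rve_network((80, 140), M, seed=seed)
            iso = pm.generate_rve_network((80, 140), np.eye(3), seed=seed)
            sal += pm.rve_total_stress(al, F, params, tangent=False)[0][0, 0]
            siso += pm.rve_total_stress(iso, F, params, tangent=False)[0][0, 0]
        assert sal > siso


def test_material_params_validation():
    with pytest.raises(ValueError):
        MaterialParams(A=-1)
    with pytest.raises(ValueError):
        MaterialParams(nu=0.5)
    K = MaterialParams().bulk_modulus
    assert K == pytest.approx(2 * 4.2 * 1.47 / (3 * 0.06))
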