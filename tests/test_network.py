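"""Fiber-network generation, alignment and characterization."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pcmech as pm
from pcmech import network


class TestDelaunayGeneration:
    def test_four_points_give_one_tetrahedron(self):
        # a single Delaunay tetrahedron has 6 edges
        net = pm.generate_delaunay_network(4, seed=1)
        assert net.n_fibers == 6
        assert np.all(net.rest_lengths > 0)

    def test_same_seed_is_byte_identical(self):
        a = pm.generate_delaunay_network(50, seed=7)
        b = pm.generate_delaunay_network(50, seed=7)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())

    def test_different_seeds_differ(self):
        a = pm.generate_delaunay_network(50, seed=7)
        b = pm.generate_delaunay_network(50, seed=8)
        assert not np.array_equal(a.node_coords, b.node_coords)

    def test_coordinates_in_unit_cube_and_valid(self):
        net = pm.generate_delaunay_network(200, seed=3)
        net.validate()
        assert net.node_coords.min() >= 0 and net.node_coords.max() <= 1

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            pm.generate_delaunay_network(3, seed=0)


class TestOrientationTensor:
    def test_single_fiber_along_x(self):
        from conftest import two_node_network
        net = two_node_network([0, 0.5, 0.5], [1, 0.5, 0.5], 1.0)
        assert np.allclose(pm.orientation_tensor(net), np.diag([1, 0, 0]))

    def test_two_equal_fibers_x_and_y(self):
        net = pm.FiberNetwork(
            node_coords=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
            fibers=np.array([[0, 1], [0, 2]], dtype=np.int32),
            rest_lengths=np.array([1.0, 1.0]),
            boundary_mask=np.ones(3, dtype=bool),
        )
        assert np.allclose(pm.orientation_tensor(net), np.diag([0.5, 0.5, 0]))

    @given(st.integers(0, 2 ** 30))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_trace_one_symmetric_eigs_in_unit_interval(self, seed):
        net = pm.generate_delaunay_network(30, seed=seed)
        O = pm.orientation_tensor(net)
        assert np.isclose(np.trace(O), 1.0)
        assert np.allclose(O, O.T)
        w = np.linalg.eigvalsh(O)
        assert np.all(w > -1e-12) and np.all(w < 1 + 1e-12)

    def test_empty_network_rejected(self):
        net = pm.FiberNetwork(np.zeros((0, 3)), np.zeros((0, 2), np.int32),
                              np.zeros(0), np.zeros(0, bool))
        with pytest.raises(ValueError):
            pm.orientation_tensor(net)


class TestAlignment:
    def test_identity_stretch_preserves_network(self, small_rve):
        out = pm.align_network(small_rve, (1, 1, 1))
        assert np.allclose(pm.orientation_tensor(out),
                           pm.orientation_tensor(small_rve), atol=1e-12)

    def test_stretch_x_raises_omega_xx(self, small_rve):
        # direct recomputation of Ω after a 2:1:1 stretch-and-clip
        O0 = pm.orientation_tensor(small_rve)
        O2 = pm.orientation_tensor(pm.align_network(small_rve, (2, 1, 1)))
        assert O2[0, 0] > O0[0, 0]
        assert O2[0, 0] > 1 / 3

    def test_large_stretch_saturates_omega(self):
        net = pm.generate_rve_network((150, 250), np.eye(3), seed=5)
        O = pm.orientation_tensor(pm.align_network(net, (25, 1, 1)))
        assert O[0, 0] > 0.85

    def test_monotone_in_stretch_over_seed_ensemble(self):
        # Ω_xx nondecreasing in the stretch ratio, averaged over seeds
        ratios = [1.0, 1.5, 2.5, 4.0]
        means = []
        for s in ratios:
            vals = []
            for seed in range(5):
                net = pm.generate_rve_network((80, 140), np.eye(3), seed=seed)
                vals.append(pm.orientation_tensor(
                    pm.align_network(net, (s, 1, 1)))[0, 0])
            means.append(np.mean(vals))
        assert all(b >= a - 0.01 for a, b in zip(means, means[1:]))

    def test_invalid_stretch_rejected(self, small_rve):
        with pytest.raises(ValueError):
            pm.align_network(small_rve, (0, 1, 1))


class TestRveGeneration:
    def test_fiber_count_in_range_and_boundary_on_faces(self):
        net = pm.generate_rve_network((120, 180), np.eye(3), seed=9)
        net.validate((120, 180))
        b = net.node_coords[net.boundary_mask]
        on_face = np.any((b < 1e-9) | (b > 1 - 1e-9), axis=1)
        assert on_face.all()
        assert net.boundary_mask.sum() > 0

    def test_isotropy_control_over_ensemble(self):
        # ensemble-mean Ω over >= 50 isotropic networks near identity/3
        O = np.zeros((3, 3))
        n = 50
        for seed in range(n):
            O += pm.orientation_tensor(
                pm.generate_rve_network((80, 140), np.eye(3), seed=seed))
        O /= n
        assert np.abs(O - np.eye(3) / 3).max() < 0.02

    def test_interior_connected_to_boundary(self):
        net = pm.generate_rve_network((200, 300), np.eye(3), seed=11)
        net.validate()  # raises on free-floating interior components

    def test_no_degenerate_short_fibers(self):
        net = pm.generate_rve_network((200, 300), np.eye(3), seed=12)
        assert net.rest_lengths.min() > network.MIN_FIBER_LENGTH


class TestLocalFrame:
    GEO = {"center": np.zeros(3), "semi_axes": np.array([250.0, 500.0, 250.0])}

    def test_skin_frame_is_identity(self):
        assert np.allclose(pm.local_frame([10, 20, 30], "skin", self.GEO),
                           np.eye(3))

    def test_pole_normal_is_z(self):
        R = pm.local_frame([0, 0, 200.0], "corpuscle", self.GEO)
        assert np.allclose(np.abs(R[2]), [0, 0, 1], atol=1e-9)

    def test_equator_normal_is_x(self):
        # gradient of the ellipsoid level function at a +x equator point
        R = pm.local_frame([200.0, 0, 0], "corpuscle", self.GEO)
        assert np.allclose(np.abs(R[2]), [1, 0, 0], atol=1e-9)

    def test_center_falls_back_to_identity(self):
        assert np.allclose(
            pm.local_frame([0, 0, 0], "corpuscle", self.GEO), np.eye(3))

    def test_frames_orthonormal_det_plus_one_everywhere(self, tiny_isolated_mesh):
        m = tiny_isolated_mesh
        for e in range(m.n_elements):
            R = pm.local_frame(m.element_centroid(e), "corpuscle",
                               m.geometry_params)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(R), 1.0)


class TestAssignNetworks:
    def test_eight_distinct_networks_per_element(self, tiny_isolated_mesh):
        lib = pm.assign_networks(tiny_isolated_mesh,
                                 {"corpuscle": pm.AlignmentPolicy("isotropic")},
                                 seed=5, fiber_count_range=(30, 70))
        seeds = {lib.network(0, g).seed for g in range(8)}
        assert len(seeds) == 8
        assert len(lib) == 8 * tiny_isolated_mesh.n_elements

    def test_same_seed_bit_identical(self, tiny_isolated_mesh):
        mk = lambda: pm.assign_networks(
            tiny_isolated_mesh, {"corpuscle": pm.AlignmentPolicy("isotropic")},
            seed=5, fiber_count_range=(30, 70))
        a, b = mk(), mk()
        for na, nb in zip(a.networks, b.networks):
            assert json.dumps(na.to_dict()) == json.dumps(nb.to_dict())

    def test_isotropic_policy_near_isotropic_omega(self, tiny_isolated_mesh):
        lib = pm.assign_networks(tiny_isolated_mesh,
                                 {"corpuscle": pm.AlignmentPolicy("isotropic")},
                                 seed=5, fiber_count_range=(30, 70))
        O = np.mean([pm.orientation_tensor(n) for n in lib.networks[:64]],
                    axis=0)
        assert np.abs(O - np.eye(3) / 3).max() < 0.05

    def test_missing_policy_raises(self, tiny_isolated_mesh):
        with pytest.raises(ValueError, match="policy"):
            pm.assign_networks(tiny_isolated_mesh, {}, seed=1)

    def test_aligned_policy_follows_surface_normal(self, tiny_isolated_mesh):
        m = tiny_isolated_mesh
        lib = pm.assign_networks(
            m, {"corpuscle": pm.AlignmentPolicy("surface_aligned_corpuscle")},
            seed=5, fiber_count_range=(60, 120))
        cents = m.element_centroids()
        etop = int(np.argmin(np.linalg.norm(cents - [0, 0, 230], axis=1)))
        O = pm.orientation_tensor(lib.network(etop, 0))
        # fibers concentrate in the tangent plane: small normal (z) eigenvalue
        assert O[2, 2] < 0.2


def test_alignment_policy_invariants():
    assert pm.AlignmentPolicy("isotropic", 5.0).stretch_ratio == 1.0
    with pytest.raises(ValueError):
        pm.AlignmentPolicy("isotropic", 0.5)
    with pytest.raises(ValueError):
        pm.AlignmentPolicy("bogus")
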