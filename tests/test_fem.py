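"""Finite-element oracles: constitutive limits, patch and bar tests,
equilibrium, limit-stress force, densified insert, convergence."""

import numpy as np
import pytest

from osteofem.fem import (ElasticConstants, ScaffoldMaterial, _HEX_SIGNS,
                          add_densified_insert, assemble_system,
                          build_box_mesh, build_mesh, embedding_force,
                          hex8_stiffness, hmh_stress, mesh_convergence,
                          periapical_limit_stress, solve_embedding)
from osteofem.geometry import ScaffoldParams, build_spike_layout


def solve_bar(lengths, h, u_top, bone=None):
    """Uniaxial-stress bar: base and top planes constrained axially only,
    lateral faces free (rigid-body modes pinned)."""
    mesh = build_box_mesh(lengths, h)
    system = assemble_system(mesh, bone or ElasticConstants())
    bcs = {}
    for nid in mesh.node_sets["fixed_base"]:
        bcs[3 * nid + 2] = 0.0
    for nid in mesh.node_sets["top"]:
        bcs[3 * nid + 2] = u_top
    base = mesh.node_sets["fixed_base"]
    origin = base[np.argmin(np.linalg.norm(mesh.nodes[base, :2], axis=1))]
    bcs[3 * origin] = bcs[3 * origin + 1] = 0.0
    on_y = base[(np.abs(mesh.nodes[base, 0]) < 1e-9)
                & (mesh.nodes[base, 1] > 1e-9)]
    bcs[3 * on_y[0]] = 0.0  # block rotation about z
    return mesh, system, solve_embedding(system, u_top, dirichlet=bcs)


class TestHMH:
    def test_uniaxial_stress_maps_to_itself(self):
        assert hmh_stress(np.array([5.0, 0, 0, 0, 0, 0])) == pytest.approx(5.0)

    def test_hydrostatic_state_is_stress_free(self):
        assert hmh_stress(np.array([3.0, 3.0, 3.0, 0, 0, 0])) == pytest.approx(0.0)

    def test_pure_shear_closed_form(self):
        tau = 2.0
        for idx in (3, 4, 5):
            s = np.zeros(6)
            s[idx] = tau
            assert hmh_stress(s) == pytest.approx(np.sqrt(3.0) * tau)

    def test_invariant_under_pressure_shift(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((20, 6))
        shifted = s.copy()
        shifted[:, :3] += 7.3
        np.testing.assert_allclose(hmh_stress(shifted), hmh_stress(s), atol=1e-9)


class TestConstitutive:
    def test_isotropic_limit_matches_closed_form(self):
        E, nu = 500.0, 0.3
        G = E / (2 * (1 + nu))
        C = ElasticConstants(E1=E, E2=E, G1=G, G2=G, nu1=nu, nu2=nu).stiffness()
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        Ciso = np.zeros((6, 6))
        Ciso[:3, :3] = lam
        Ciso[np.arange(3), np.arange(3)] += 2 * G
        Ciso[3, 3] = Ciso[4, 4] = Ciso[5, 5] = G
        assert np.abs(C - Ciso).max() < 1e-9

    def test_stiffness_symmetric_positive_definite(self):
        C = ElasticConstants().stiffness()
        np.testing.assert_allclose(C, C.T, atol=1e-9)
        assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            ElasticConstants(E2=-10.0)
        with pytest.raises(ValueError):
            ElasticConstants(nu1=0.6)
        with pytest.raises(ValueError):           # thermodynamically invalid
            ElasticConstants(E1=700.0, E2=10.0, nu2=0.4)
        with pytest.raises(ValueError):
            ScaffoldMaterial(nu=0.6)

    def test_insert_scaling_preserves_ratios(self):
        bone = ElasticConstants()
        ins = bone.scaled_to_modulus(1144.0)
        r = 1144.0 / bone.E2
        assert ins.E1 == pytest.approx(bone.E1 * r)
        assert ins.G2 == pytest.approx(bone.G2 * r)
        assert ins.nu1 == bone.nu1


class TestElementStiffness:
    def test_matches_independent_quadrature_on_random_parallelepipeds(self):
        """Element stiffness equals an independently coded 3x3x3
        Gauss-Legendre integration of B'CB (exact for affine elements)."""
        C = ElasticConstants().stiffness()
        pts, wts = np.polynomial.legendre.leggauss(3)
        rng = np.random.default_rng(12)
        for _ in range(10):
            A = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            if np.linalg.det(A) < 0.2:
                continue
            coords = _HEX_SIGNS @ A.T + rng.standard_normal(3)
            Ke = hex8_stiffness(coords, C)
            Ko = np.zeros((24, 24))
            for i3, wx in zip(pts, wts):
                for j3, wy in zip(pts, wts):
                    for k3, wz in zip(pts, wts):
                        dN_nat = np.array([
                            [0.125 * s[0] * (1 + s[1] * j3) * (1 + s[2] * k3)
                             for s in _HEX_SIGNS],
                            [0.125 * s[1] * (1 + s[0] * i3) * (1 + s[2] * k3)
                             for s in _HEX_SIGNS],
                            [0.125 * s[2] * (1 + s[0] * i3) * (1 + s[1] * j3)
                             for s in _HEX_SIGNS]])
                        J = dN_nat @ coords
                        dN = np.linalg.solve(J, dN_nat).T   # (8, 3) cartesian
                        B = np.zeros((6, 24))
                        for n in range(8):
                            bx, by, bz = dN[n]
                            B[:, 3 * n:3 * n + 3] = [
                                [bx, 0, 0], [0, by, 0], [0, 0, bz],
                                [0, bz, by], [bz, 0, bx], [by, bx, 0]]
                        Ko += wx * wy * wz * np.linalg.det(J) * (B.T @ C @ B)
            assert np.abs(Ke - Ko).max() < 1e-9 * np.abs(Ko).max()

    def test_inverted_element_rejected(self):
        coords = _HEX_SIGNS.copy()
        coords[:, 2] *= -1.0
        with pytest.raises(ValueError):
            hex8_stiffness(coords, ElasticConstants().stiffness())


class TestStructuredMesh:
    def test_unit_cube_counts(self):
        mesh = build_box_mesh((1.0, 1.0, 1.0), 0.5)
        assert len(mesh.elements) == 8
        assert mesh.n_nodes == 27

    def test_refinement_scales_element_count_by_eight(self):
        coarse = build_box_mesh((1.0, 1.0, 1.0), 0.5)
        fine = build_box_mesh((1.0, 1.0, 1.0), 0.25)
        assert len(fine.elements) == 8 * len(coarse.elements)

    def test_default_layout_footprints_resolved(self, default_layout):
        mesh = build_mesh(2.2, 4.0, default_layout, 2.5, 0.1)
        names = mesh.footprint_sets()
        assert names
        for name in names:
            i = int(name.rsplit("_", 1)[1])
            s = default_layout.spikes[i]
            pts = mesh.nodes[mesh.node_sets[name]]
            assert len(pts) > 0
            r = np.hypot(pts[:, 0] - s.center_x, pts[:, 1] - s.center_y)
            assert r.max() <= 0.25 + 1e-6

    def test_unresolved_footprint_rejected(self, single_spike_layout):
        with pytest.raises(ValueError):
            build_mesh(1.0, 3.0, single_spike_layout, 0.5, 0.2)


class TestSolves:
    def test_uniaxial_bar_reaction_closed_form(self):
        """Bar 1x1x10 mm under 0.01 mm axial displacement: uniaxial stress
        gives R = E2*A*u/L = 771*1*0.001 = 0.771 N, exactly representable."""
        for h in (0.5, 0.25):
            mesh, system, res = solve_bar((1.0, 1.0, 10.0), h, 0.01)
            assert res.reactions["top"][2] == pytest.approx(0.771, rel=1e-6)
            szz = res.element_stress[:, 2]
            np.testing.assert_allclose(szz, 0.771, rtol=1e-6)

    def test_single_element_patch_uniform_strain(self):
        mesh = build_box_mesh((1.0, 1.0, 1.0), 1.0)
        bone = ElasticConstants()
        system = assemble_system(mesh, bone)
        eps = 1e-3
        bcs = {}
        for nid in range(mesh.n_nodes):
            z = mesh.nodes[nid, 2]
            bcs[3 * nid] = 0.0
            bcs[3 * nid + 1] = 0.0
            bcs[3 * nid + 2] = eps * z
        res = solve_embedding(system, eps, dirichlet=bcs)
        expected = bone.stiffness()[:, 2] * eps
        np.testing.assert_allclose(res.element_stress[0], expected, atol=1e-12)

    @pytest.fixture(scope="class")
    def spike_model(self, single_spike_layout):
        mesh = build_mesh(0.8, 3.0, single_spike_layout, 1.8, 0.08)
        system = assemble_system(mesh, ElasticConstants())
        return mesh, system

    def test_zero_displacement_gives_zero_fields(self, spike_model):
        mesh, system = spike_model
        res = solve_embedding(system, 0.0)
        assert np.abs(res.displacement).max() == 0.0
        assert res.reaction_footprint == 0.0

    def test_linearity_in_prescribed_displacement(self, spike_model):
        mesh, system = spike_model
        r1 = solve_embedding(system, 0.01)
        r2 = solve_embedding(system, 0.02)
        np.testing.assert_allclose(r2.displacement, 2 * r1.displacement,
                                   rtol=1e-6, atol=1e-12)
        assert r2.reaction_footprint == pytest.approx(2 * r1.reaction_footprint,
                                                      rel=1e-6)

    def test_global_equilibrium_and_energy_positivity(self, spike_model):
        mesh, system = spike_model
        res = solve_embedding(system, 0.05)
        u = res.displacement.ravel()
        f = system.K @ u
        for d in range(3):
            total = f[d::3].sum()
            assert abs(total) <= 1e-6 * max(res.reaction_footprint, 1e-12)
        assert u @ system.K @ u > 0.0

    def test_embedding_force_scales_with_limit_stress(self, spike_model):
        mesh, system = spike_model
        res = solve_embedding(system, 0.05)
        bone = ElasticConstants()
        f1 = embedding_force(res, mesh, bone)
        f2 = embedding_force(res, mesh,
                             ElasticConstants(sigma_c=2 * bone.sigma_c))
        assert f2 == pytest.approx(2 * f1, rel=1e-12)
        peri = periapical_limit_stress(res, mesh)
        assert f1 == pytest.approx(bone.sigma_c / peri
                                   * res.reaction_footprint * 4.0, rel=1e-12)

    def test_embedding_force_monotone_in_depth(self):
        # a wide spike so the footprint holds 13-30 nodes at this element
        # size; deeper embedding must cost more force
        layout = build_spike_layout(ScaffoldParams(
            n_rings=0, base_diameter=1.0, apex_diameter=0.3,
            spike_height=3.0, embed_depth_max=2.8))
        forces = []
        bone = ElasticConstants()
        for depth in (1.0, 1.8, 2.6):
            mesh = build_mesh(1.0, 3.0, layout, depth, 0.08)
            system = assemble_system(mesh, bone)
            res = solve_embedding(system, 0.05)
            forces.append(embedding_force(res, mesh, bone))
        assert forces[0] < forces[1] < forces[2]


class TestDensifiedInsert:
    @pytest.fixture(scope="class")
    def meshes(self, single_spike_layout):
        mesh = build_mesh(0.8, 3.0, single_spike_layout, 1.8, 0.08)
        modified = add_densified_insert(mesh, single_spike_layout, 1.8, 0.3,
                                        domain_height=3.0)
        return mesh, modified

    def test_bulk_modulus_insert_changes_nothing(self, meshes):
        mesh, modified = meshes
        bone = ElasticConstants()
        r0 = solve_embedding(assemble_system(mesh, bone), 0.05)
        r1 = solve_embedding(assemble_system(modified, bone, insert=bone), 0.05)
        np.testing.assert_allclose(r1.displacement, r0.displacement, atol=1e-14)

    def test_stiffer_insert_raises_reaction_at_fixed_displacement(self, meshes):
        mesh, modified = meshes
        bone = ElasticConstants()
        insert = bone.scaled_to_modulus(1144.0)
        r0 = solve_embedding(assemble_system(mesh, bone), 0.05)
        r1 = solve_embedding(assemble_system(modified, bone, insert=insert), 0.05)
        assert r1.reaction_footprint > r0.reaction_footprint

    def test_zero_thickness_insert_rejected(self, meshes, single_spike_layout):
        mesh, _ = meshes
        with pytest.raises(ValueError):
            add_densified_insert(mesh, single_spike_layout, 1.8, 0.0,
                                 domain_height=3.0)


class TestMeshConvergence:
    def test_refinement_sweep_reports_decreasing_changes(self, single_spike_layout):
        df = mesh_convergence(1.0, 3.0, single_spike_layout, 1.8,
                              ElasticConstants(), 0.05, [0.12, 0.1, 0.08])
        assert len(df) == 3
        changes = df["rel_change"].to_numpy()
        assert np.isnan(changes[0])
        assert changes[2] < changes[1]

    def test_requires_three_decreasing_sizes(self, single_spike_layout):
        with pytest.raises(ValueError):
            mesh_convergence(1.0, 3.0, single_spike_layout, 1.8,
                             ElasticConstants(), 0.05, [0.12, 0.1])
        with pytest.raises(ValueError):
            mesh_convergence(1.0, 3.0, single_spike_layout, 1.8,
                             ElasticConstants(), 0.05, [0.1, 0.12, 0.08])
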