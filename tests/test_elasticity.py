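"""Plane-stress solver: patch tests, energy bookkeeping, crack opening."""

import numpy as np
import pytest

import ocufrac as oc
from ocufrac.elasticity import ElasticityError

A = 1.1e-3
E = 9.82e6
NU = 0.49


class TestMaterial:
    def test_isotropic_stiffness_inverts_to_compliance(self):
        D = oc.Material.isotropic(E=E, nu=0.3).stiffness()
        S = np.linalg.inv(D)
        assert S[0, 0] == pytest.approx(1 / E, rel=1e-12)
        assert S[0, 1] == pytest.approx(-0.3 / E, rel=1e-12)

    def test_orthotropic_reciprocity(self):
        m = oc.Material.orthotropic(E_x=19.64e6, E_y=9.82e6)
        D = m.stiffness()
        # symmetric stiffness encodes nu_xy E_y = nu_yx E_x
        assert D[0, 1] == pytest.approx(D[1, 0], rel=1e-14)
        assert m.eta == pytest.approx(2.0)

    def test_orthotropic_stability_enforced(self):
        with pytest.raises(ElasticityError, match="stability"):
            oc.Material.orthotropic(E_x=9.82e6, E_y=19.64e6, nu_xy=0.9)

    def test_invalid_materials_rejected(self):
        with pytest.raises(ElasticityError):
            oc.Material.isotropic(E=-1.0)
        with pytest.raises(ElasticityError):
            oc.Material.isotropic(nu=0.5)
        with pytest.raises(ElasticityError):
            oc.Material.isotropic(G_c=0.0)


class TestPatchAndLinearity:
    @pytest.mark.parametrize("mat", [
        oc.Material.isotropic(E=E, nu=NU),
        oc.Material.orthotropic(E_x=19.64e6, E_y=9.82e6),
    ], ids=["isotropic", "orthotropic"])
    def test_uncracked_plate_reproduces_homogeneous_state(self, straight_mesh, mat):
        """Equibiaxial traction on the uncracked plate gives sigma = sigma0*I
        exactly, element by element, on the irregular mesh (patch test)."""
        flat = oc.merge_seam(straight_mesh)
        sol = oc.assemble_and_solve(flat, mat, oc.LoadCase(1e6))
        np.testing.assert_allclose(sol.stress[:, 0], 1e6, rtol=1e-9)
        np.testing.assert_allclose(sol.stress[:, 1], 1e6, rtol=1e-9)
        np.testing.assert_allclose(sol.stress[:, 2], 0.0, atol=1e-9 * 1e6)

    def test_uncracked_displacements_match_linear_field(self, straight_mesh):
        flat = oc.merge_seam(straight_mesh)
        mat = oc.Material.isotropic(E=E, nu=NU)
        sol = oc.assemble_and_solve(flat, mat, oc.LoadCase(1e6))
        fac = 1e6 * (1 - NU) / E
        uex = fac * flat.nodes
        # remove the gauge difference (a rigid translation)
        used = np.zeros(flat.n_nodes, bool)
        for _, conn in flat.iter_elements():
            used[conn] = True
        shift = (sol.u[used] - uex[used]).mean(axis=0)
        err = np.abs(sol.u[used] - uex[used] - shift).max()
        assert err < 1e-10 * np.abs(uex).max()

    def test_doubling_load_doubles_displacements(self, straight_mesh, material):
        s1 = oc.assemble_and_solve(straight_mesh, material, oc.LoadCase(1e6))
        s2 = oc.assemble_and_solve(straight_mesh, material, oc.LoadCase(2e6))
        np.testing.assert_allclose(s2.u, 2 * s1.u, rtol=1e-9, atol=1e-18)

    def test_work_energy_balance(self, straight_solution):
        U, W = straight_solution.strain_energy, straight_solution.external_work
        assert abs(U - W) < 1e-6 * U
        assert straight_solution.residual_rel < 1e-9

    def test_mirror_symmetric_displacements(self, straight_solution, straight_mesh):
        from scipy.spatial import cKDTree

        nodes = straight_mesh.nodes
        u = straight_solution.u
        # coincident seam pairs confuse a nearest-node mirror map: skip them
        seam = set(straight_mesh.seam_pairs.ravel().tolist())
        keep = np.array([i not in seam for i in range(len(nodes))])
        tree = cKDTree(nodes[keep])
        kept_ids = np.where(keep)[0]
        d, j = tree.query(nodes[keep] * [-1.0, 1.0])
        assert (d < 1e-9).all()  # the mirror map exists off the seam
        u_k, u_m = u[kept_ids], u[kept_ids[j]]
        np.testing.assert_allclose(u_k[:, 0], -u_m[:, 0], atol=1e-9 * np.abs(u).max())
        np.testing.assert_allclose(u_k[:, 1], u_m[:, 1], atol=1e-9 * np.abs(u).max())

    def test_under_constrained_system_raises(self, straight_mesh, material):
        with pytest.raises(ElasticityError):
            oc.assemble_and_solve(straight_mesh, material, oc.LoadCase(1e6),
                                  constraints=[(0, 0), (0, 1)])

    def test_strain_energy_increases_under_crack_refinement(self, material):
        """Displacement FE underestimates compliance: the cracked-plate energy
        grows monotonically toward the true value as the mesh is refined."""
        path = oc.make_crack_path(oc.IncisionShape.straight(A))
        energies = []
        for mp in (
            oc.MeshParams(n_spokes=16, crack_spacing_cap_frac=1 / 8,
                          far_field_size=6e-3, outer_growth=1.7, n_blend=5),
            oc.MeshParams(n_spokes=16, crack_spacing_cap_frac=1 / 12,
                          far_field_size=4e-3, outer_growth=1.4, n_blend=8),
            oc.MeshParams(),
        ):
            mesh = oc.build_mesh(oc.PlateSpec(), path, mp)
            sol = oc.assemble_and_solve(mesh, material, oc.LoadCase(1e6))
            energies.append(sol.strain_energy)
        assert energies[0] < energies[1] < energies[2]


class TestCrackOpening:
    def test_straight_opening_matches_griffith_form(self, straight_solution_fine):
        an = oc.analytic_center_crack(1e6, A, E)
        op = oc.crack_opening(straight_solution_fine)
        assert op.midpoint == pytest.approx(an.max_opening, rel=0.02)
        assert op.maximum == pytest.approx(op.midpoint, rel=1e-9)
        assert not op.interpenetration

    def test_opening_profile_is_elliptical(self, straight_solution_fine,
                                           straight_mesh_fine):
        an = oc.analytic_center_crack(1e6, A, E)
        op = oc.crack_opening(straight_solution_fine)
        x = op.arclengths - A  # distance from crack center
        for frac in (0.0, 0.3, 0.5, 0.7, 0.85):
            i = np.argmin(np.abs(x - frac * A))
            assert op.separation[i] == pytest.approx(an.opening(x[i]), rel=0.03)

    def test_chevron_opening_profile_asymmetric_along_arm(self, chevron150_solution):
        """The chevron opens more toward the tips than an elliptical profile
        centered on each arm would: the profile is skewed along the arm."""
        op = oc.crack_opening(chevron150_solution)
        s = op.arclengths
        # compare the two halves of one arm (between apex and tip)
        arm = (s > 0.0) & (s < A)
        sep = op.separation[arm]
        mid = len(sep) // 2
        assert not np.allclose(sep[:mid], sep[-mid:][::-1], rtol=0.05)

    def test_merged_mesh_has_no_opening(self, straight_mesh, material):
        flat = oc.merge_seam(straight_mesh)
        sol = oc.assemble_and_solve(flat, material, oc.LoadCase(1e6))
        with pytest.raises(ElasticityError, match="no seam"):
            oc.crack_opening(sol)

    def test_interpenetration_flagged(self, straight_solution, straight_mesh):
        sol = oc.PlaneStressSolution(u=-straight_solution.u.copy(),
                                     mesh=straight_mesh,
                                     material=straight_solution.material,
                                     load=straight_solution.load)
        with pytest.warns(UserWarning, match="interpenetrate"):
            op = oc.crack_opening(sol)
        assert op.interpenetration
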