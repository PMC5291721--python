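"""Hypoelastic cell mechanics: kinematics, stress update, equilibrium."""

import numpy as np
import pytest

from fasim import (
    ActiveDeformation,
    CellState,
    ElasticMaterial,
    SpringSet,
    build_disc_mesh,
    cell_area,
    hypoelastic_stress_update,
    solve_cell_equilibrium,
    total_rate_of_deformation,
)
from fasim.materials import plane_stress_stiffness


class TestRateOfDeformation:
    def test_radial_field_is_isotropic(self, coarse_disc):
        alpha = 0.01
        v = alpha * coarse_disc.nodes
        D = total_rate_of_deformation(coarse_disc, v)
        np.testing.assert_allclose(
            D, np.broadcast_to(alpha * np.eye(2), D.shape), atol=1e-12
        )

    def test_rigid_rotation_gives_zero(self, coarse_disc):
        omega = 0.3
        v = omega * np.column_stack([-coarse_disc.nodes[:, 1], coarse_disc.nodes[:, 0]])
        D = total_rate_of_deformation(coarse_disc, v)
        np.testing.assert_allclose(D, 0.0, atol=1e-10)

    def test_simple_shear(self, coarse_disc):
        gamma = 0.2
        v = np.column_stack([gamma * coarse_disc.nodes[:, 1], np.zeros(coarse_disc.n_nodes)])
        D = total_rate_of_deformation(coarse_disc, v)
        want = np.array([[0.0, gamma / 2], [gamma / 2, 0.0]])
        np.testing.assert_allclose(D, np.broadcast_to(want, D.shape), atol=1e-12)


class TestHypoelasticUpdate:
    def setup_method(self):
        self.C = plane_stress_stiffness(2.0, 0.3)

    def test_fully_active_deformation_is_stress_free(self):
        alpha = 0.00725
        D = np.array([[alpha, alpha, 0.0]])
        L = np.array([[[alpha, 0.0], [0.0, alpha]]])
        s = hypoelastic_stress_update(
            np.zeros((1, 3)), L, D, np.array([alpha, alpha, 0.0]), self.C, dt=0.5
        )
        np.testing.assert_allclose(s, 0.0, atol=1e-15)

    def test_isotropic_passive_strain_rate(self):
        # σ_new = dt ε E/(1-ν) I for D - D^A = ε I at zero stress and spin
        eps, dt, E, nu = 0.01, 0.25, 2.0, 0.3
        s = hypoelastic_stress_update(
            np.zeros((1, 3)),
            np.zeros((1, 2, 2)),
            np.array([[eps, eps, 0.0]]),
            np.zeros(3),
            plane_stress_stiffness(E, nu),
            dt,
        )
        want = dt * eps * E / (1 - nu)
        np.testing.assert_allclose(s[0], [want, want, 0.0], rtol=1e-12)

    def test_pure_spin_rotates_stress(self):
        """Under rigid spin with zero passive rate the stress co-rotates and
        its Frobenius norm is conserved up to O(dt) over the history."""
        omega, dt, T = 0.5, 1e-3, 1.0
        W = np.array([[[0.0, -omega], [omega, 0.0]]])
        sigma = np.array([[1.0, -0.4, 0.3]])
        zero_rate = np.zeros((1, 3))
        for _ in range(int(T / dt)):
            sigma = hypoelastic_stress_update(
                sigma, W, zero_rate, np.zeros(3), 0.0 * self.C, dt
            )
        th = omega * T
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        S0 = np.array([[1.0, 0.3], [0.3, -0.4]])
        want = R @ S0 @ R.T
        got = np.array([[sigma[0, 0], sigma[0, 2]], [sigma[0, 2], sigma[0, 1]]])
        np.testing.assert_allclose(got, want, atol=5e-3)
        assert np.linalg.norm(got) == pytest.approx(np.linalg.norm(S0), rel=5e-3)

    def test_objectivity_of_invariants_under_superposed_spin(self):
        """Adding a rigid spin changes the one-step stress invariants only
        at O(dt)."""
        dt, omega = 1e-3, 2.0
        L = np.array([[[0.01, 0.002], [-0.003, -0.004]]])
        W = np.array([[[0.0, -omega], [omega, 0.0]]])
        sigma = np.array([[0.8, -0.2, 0.1]])
        D = _rate_of_deformation_voigt_from_L(L)
        s_plain = hypoelastic_stress_update(sigma, L, D, np.zeros(3), self.C, dt)
        s_spun = hypoelastic_stress_update(sigma, L + W, D, np.zeros(3), self.C, dt)
        tr = lambda s: s[0, 0] + s[0, 1]
        assert abs(tr(s_spun) - tr(s_plain)) < 5 * omega * dt * np.abs(sigma).max()


def _rate_of_deformation_voigt_from_L(L):
    return np.stack([L[:, 0, 0], L[:, 1, 1], L[:, 0, 1] + L[:, 1, 0]], axis=1)


class TestCellEquilibrium:
    def test_free_spreading_matches_exponential(self):
        """With no adhesions the cell grows self-similarly: boundary radius
        multiplies by e^{αt} and the stress stays identically zero."""
        alpha, dt, T = 0.00725, 1.0, 120.0
        mesh = build_disc_mesh(10.0, 2.5)
        st = CellState.initial(mesh)
        C = ElasticMaterial(0.5, 0.3).stiffness
        for _ in range(int(T / dt)):
            st = solve_cell_equilibrium(st, None, ActiveDeformation(alpha), dt, C)
        r = np.linalg.norm(st.mesh.nodes[st.mesh.boundary], axis=1)
        assert r.mean() / 10.0 == pytest.approx(np.exp(alpha * T), rel=0.01)
        np.testing.assert_allclose(st.sigma, 0.0, atol=1e-10)

    def test_zero_activity_invariance(self, coarse_disc):
        st = CellState.initial(coarse_disc)
        C = ElasticMaterial(0.5, 0.3).stiffness
        for _ in range(10):
            st = solve_cell_equilibrium(st, None, ActiveDeformation(0.0), 0.5, C)
        np.testing.assert_allclose(st.u, 0.0, atol=1e-12)
        np.testing.assert_allclose(st.sigma, 0.0, atol=1e-12)

    def test_zero_stiffness_springs_match_spring_free(self, coarse_disc):
        C = ElasticMaterial(0.5, 0.3).stiffness
        act = ActiveDeformation(0.005)
        free = solve_cell_equilibrium(CellState.initial(coarse_disc), None, act, 0.5, C)
        springs = SpringSet()
        tri, bary = coarse_disc.locate(np.array([[0.0, 0.0], [3.0, 2.0]]))
        springs.add(tri, bary, np.zeros((2, 2)), np.zeros(2, int),
                    np.full((2, 3), 1 / 3), np.zeros((2, 2)), np.zeros(2), 0.0)
        pinned = solve_cell_equilibrium(
            CellState.initial(coarse_disc), springs, act, 0.5, C,
            u_s_at_anchors=np.zeros((2, 2)),
        )
        np.testing.assert_allclose(pinned.u, free.u, atol=1e-10)

    def test_single_spring_leaves_spreading_stress_free(self, coarse_disc):
        """A single spring cannot frustrate isotropic spreading: the cell
        simply spreads about the anchor, the anchor never moves, the spring
        carries no force and the stress stays zero."""
        C = ElasticMaterial(0.5, 0.3).stiffness
        act = ActiveDeformation(0.00725)
        springs = SpringSet()
        tri, bary = coarse_disc.locate(np.array([[5.0, 0.0]]))
        springs.add(tri, bary, np.array([[5.0, 0.0]]), np.zeros(1, int),
                    np.full((1, 3), 1 / 3), np.zeros((1, 2)), np.array([50.0]), 0.0)
        st = CellState.initial(coarse_disc)
        for _ in range(40):
            st = solve_cell_equilibrium(
                st, springs, act, 0.5, C, u_s_at_anchors=np.zeros((1, 2))
            )
        assert np.linalg.norm(springs.u_c_at_anchors(st)[0]) < 1e-8
        assert np.abs(st.sigma).max() < 1e-10

    def test_two_springs_frustrate_spreading(self, coarse_disc):
        """Two stiff anchors hold their material points apart/together
        against active spreading, so stress develops and anchor motion is a
        fraction of the free-spreading displacement."""
        C = ElasticMaterial(0.5, 0.3).stiffness
        alpha = 0.00725
        act = ActiveDeformation(alpha)
        springs = SpringSet()
        pts = np.array([[5.0, 0.0], [-5.0, 0.0]])
        tri, bary = coarse_disc.locate(pts)
        springs.add(tri, bary, pts, np.zeros(2, int),
                    np.full((2, 3), 1 / 3), np.zeros((2, 2)), np.full(2, 50.0), 0.0)
        st = CellState.initial(coarse_disc)
        T = 20.0
        for _ in range(40):
            st = solve_cell_equilibrium(
                st, springs, act, 0.5, C, u_s_at_anchors=np.zeros((2, 2))
            )
        anchor_u = np.linalg.norm(springs.u_c_at_anchors(st), axis=1).max()
        free_u = 5.0 * (np.exp(alpha * T) - 1.0)
        assert anchor_u < 0.5 * free_u
        assert np.abs(st.sigma).max() > 1e-4


class TestCellArea:
    def test_initial_disc(self, disc_mesh):
        st = CellState.initial(disc_mesh)
        assert cell_area(st) == pytest.approx(np.pi * 100, rel=0.02)

    def test_scaling_and_translation(self, coarse_disc):
        st = CellState.initial(coarse_disc)
        a0 = cell_area(st)
        grown = st.mesh.with_nodes(1.5 * coarse_disc.nodes)
        assert grown.total_area == pytest.approx(1.5**2 * a0, rel=1e-12)
        moved = st.mesh.with_nodes(coarse_disc.nodes + [11.0, -4.0])
        assert moved.total_area == pytest.approx(a0, rel=1e-12)
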