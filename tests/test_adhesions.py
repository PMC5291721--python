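"""Focal-adhesion dynamics: φ evolution, spring population, rupture, pruning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fasim import (
    AdhesionParams,
    CellState,
    ElasticMaterial,
    SpringSet,
    SubstrateState,
    advance_phi,
    average_bulk_stress,
    build_disc_mesh,
    build_square_mesh,
    initialize_fa_layout,
    microtubule_prune,
    phi_rate,
    rupture_springs,
    total_fa_area,
    update_spring_population,
)


@pytest.fixture
def params():
    return AdhesionParams()


@pytest.fixture
def cell_and_substrate(coarse_disc):
    cell = CellState.initial(coarse_disc)
    sub = SubstrateState(build_square_mesh(60.0, 4.0), ElasticMaterial(1.0, 0.3))
    return cell, sub


class TestBulkStress:
    @pytest.mark.parametrize(
        "sigma,want",
        [
            ([-2.0, -4.0, 0.0], -3.0),
            ([0.0, 0.0, 5.0], 0.0),   # pure shear has no hydrostatic part
            ([1.0, -1.0, 0.0], 0.0),
        ],
    )
    def test_values(self, sigma, want):
        assert average_bulk_stress(np.array([sigma]))[0] == pytest.approx(want)


class TestPhiRate:
    def test_gate_and_magnitude(self, params):
        assert phi_rate(0.0, params) == 0.0
        assert phi_rate(5.0, params) == 0.0  # tension has no effect
        assert phi_rate(-1.0, params) == pytest.approx(360.0 * math.tanh(1.0))
        assert phi_rate(-1.0, params) == pytest.approx(274.13, rel=1e-3)

    @settings(deadline=None, max_examples=60)
    @given(sb=st.floats(-50, 50, allow_nan=False))
    def test_never_negative_and_zero_under_tension(self, sb):
        r = phi_rate(sb, AdhesionParams())
        assert r >= 0.0
        if sb >= 0:
            assert r == 0.0


class TestAdvancePhi:
    def test_unchanged_under_tension(self, coarse_disc, params):
        phi = np.random.default_rng(0).random(coarse_disc.n_nodes)
        sb = np.full(coarse_disc.n_triangles, 0.7)
        np.testing.assert_array_equal(
            advance_phi(phi, coarse_disc, sb, 0.25, params), phi
        )

    def test_clamped_at_one(self, coarse_disc, params):
        phi = np.full(coarse_disc.n_nodes, 0.95)
        sb = np.full(coarse_disc.n_triangles, -5.0)
        out = advance_phi(phi, coarse_disc, sb, 1.0, params)
        np.testing.assert_allclose(out, 1.0)

    def test_forward_euler_value(self, coarse_disc, params):
        phi = np.full(coarse_disc.n_nodes, 0.2)
        sb = np.full(coarse_disc.n_triangles, -1.0)
        out = advance_phi(phi, coarse_disc, sb, 0.001, params)
        np.testing.assert_allclose(out, 0.2 + 0.001 * 360 * math.tanh(1.0), rtol=1e-9)
        # φ never decreases under Eq-free growth (no decay term)
        assert np.all(out >= phi)


class TestTotalFaArea:
    def test_saturated_field_covers_cell(self, coarse_disc):
        assert total_fa_area(np.ones(coarse_disc.n_nodes), coarse_disc) == (
            pytest.approx(coarse_disc.total_area)
        )

    def test_below_threshold_counts_nothing(self, coarse_disc):
        assert total_fa_area(np.full(coarse_disc.n_nodes, 0.49), coarse_disc) == 0.0

    def test_unit_disc_patch(self):
        mesh = build_disc_mesh(5.0, 0.3)
        phi = np.where(np.linalg.norm(mesh.nodes, axis=1) <= 1.0, 1.0, 0.0)
        got = total_fa_area(phi, mesh)
        assert got == pytest.approx(np.pi, abs=1.0)  # one-edge mesh tolerance
        fine = build_disc_mesh(5.0, 0.15)
        phi_f = np.where(np.linalg.norm(fine.nodes, axis=1) <= 1.0, 1.0, 0.0)
        assert abs(total_fa_area(phi_f, fine) - np.pi) < abs(got - np.pi) + 0.2


class TestLayout:
    def test_peripheral_layout_area(self, disc_mesh):
        # quantitative check on a mesh fine enough to resolve 1-μm patches
        fine = build_disc_mesh(10.0, 0.4)
        phi = initialize_fa_layout(fine, R=7.0, n_patches=8, patch_area=3.14)
        assert total_fa_area(phi, fine) == pytest.approx(8 * 3.14, rel=0.4)
        assert phi.max() == pytest.approx(0.6)
        # at working resolution every patch still seeds at least one node
        coarse = initialize_fa_layout(disc_mesh, 7.0, 8, 3.14)
        assert (coarse > 0).sum() >= 8

    def test_central_layout_same_total(self, disc_mesh):
        per = initialize_fa_layout(disc_mesh, 7.0, 8, 3.14)
        cen = initialize_fa_layout(disc_mesh, 4.0, 8, 3.14)
        assert total_fa_area(cen, disc_mesh) == pytest.approx(
            total_fa_area(per, disc_mesh), rel=0.5
        )
        # central patches sit closer to the center
        r_per = np.linalg.norm(disc_mesh.nodes[per > 0], axis=1).mean()
        r_cen = np.linalg.norm(disc_mesh.nodes[cen > 0], axis=1).mean()
        assert r_cen < r_per

    def test_no_patches_no_phi(self, disc_mesh):
        phi = initialize_fa_layout(disc_mesh, 7.0, 0, 3.14)
        np.testing.assert_array_equal(phi, 0.0)


class TestSpringPopulation:
    def test_no_phi_no_springs(self, cell_and_substrate, params):
        cell, sub = cell_and_substrate
        springs = SpringSet()
        update_spring_population(cell, sub, springs, params, 1.1)
        assert springs.n_active == 0

    def test_springs_born_with_zero_stretch(self, cell_and_substrate, params):
        cell, sub = cell_and_substrate
        cell.phi[:] = 0.0
        cell.phi[np.linalg.norm(cell.mesh.nodes, axis=1) < 4.0] = 0.8
        springs = SpringSet()
        created, _ = update_spring_population(cell, sub, springs, params, 1.1)
        assert created == springs.n_active > 0
        np.testing.assert_allclose(springs.stretches(cell, sub), 0.0, atol=1e-14)

    def test_one_spring_per_candidate_node(self, cell_and_substrate, params):
        cell, sub = cell_and_substrate
        nodes = np.flatnonzero(np.linalg.norm(cell.mesh.nodes, axis=1) < 4.0)
        cell.phi[:] = 0.0
        cell.phi[nodes] = 0.7
        springs = SpringSet()
        created, _ = update_spring_population(cell, sub, springs, params, 0.1)
        assert created == len(nodes)

    def test_springs_removed_when_phi_drops(self, cell_and_substrate, params):
        cell, sub = cell_and_substrate
        cell.phi[:] = 0.8
        springs = SpringSet()
        update_spring_population(cell, sub, springs, params, 1.1)
        n = springs.n_active
        cell.phi[:] = 0.1
        _, removed = update_spring_population(cell, sub, springs, params, 1.1)
        assert removed == n and springs.n_active == 0


class TestRupture:
    def _one_spring(self, cell, sub, stretch):
        springs = SpringSet()
        tri, bary = cell.mesh.locate(np.array([[2.0, 0.0]]))
        stri, sbary = sub.mesh.locate(np.array([[2.0, 0.0]]))
        springs.add(tri, bary, np.array([[2.0, 0.0]]), stri, sbary,
                    np.array([[-stretch, 0.0]]), np.array([1.0]), 0.0)
        return springs

    def test_rupture_threshold(self, cell_and_substrate):
        cell, sub = cell_and_substrate
        weak = AdhesionParams(rupture_stretch=0.4)
        over = self._one_spring(cell, sub, 0.41)
        assert rupture_springs(over, cell, sub, weak) == 1
        assert over.n_active == 0
        under = self._one_spring(cell, sub, 0.39)
        assert rupture_springs(under, cell, sub, weak) == 0
        assert under.n_active == 1

    def test_strong_mode_never_ruptures(self, cell_and_substrate, params):
        cell, sub = cell_and_substrate
        s = self._one_spring(cell, sub, 100.0)
        assert rupture_springs(s, cell, sub, params) == 0
        assert s.n_active == 1


class TestMicrotubulePrune:
    def test_below_cap_untouched(self, cell_and_substrate, params):
        cell, sub = cell_and_substrate
        cell.phi[:] = 0.0
        cell.phi[np.linalg.norm(cell.mesh.nodes, axis=1) < 3.0] = 0.9
        springs = SpringSet()
        update_spring_population(cell, sub, springs, params, 1.1)
        n = springs.n_active
        assert microtubule_prune(cell, springs, params, 1.1) == 0
        assert springs.n_active == n

    def test_cap_enforced_and_phi_reset(self, cell_and_substrate):
        cell, sub = cell_and_substrate
        p = AdhesionParams(critical_area_ratio=0.2)
        cell.phi[:] = 0.9  # FA area = full cell, far above the 20 % cap
        springs = SpringSet()
        update_spring_population(cell, sub, springs, p, 1.1)
        removed = microtubule_prune(cell, springs, p, 1.1)
        assert removed > 0
        ratio = total_fa_area(cell.phi, cell.mesh) / cell.mesh.total_area
        assert ratio <= 0.2 + 0.02  # one-triangle tolerance
        # every reset node carries φ = 0.2
        reset = cell.phi < 0.5
        np.testing.assert_allclose(cell.phi[reset], 0.2, atol=1e-12)
        # pruning works outward from the center: survivors are peripheral
        idx = springs.active_indices()
        r_active = np.linalg.norm(springs.anchor_positions(cell.mesh, idx), axis=1)
        assert r_active.min() > 4.0

    def test_equidistant_tie_breaks_by_lowest_id(self, cell_and_substrate):
        cell, sub = cell_and_substrate
        p = AdhesionParams(critical_area_ratio=1e-9)
        springs = SpringSet()
        for _ in range(2):  # two springs at the same anchor: exact tie
            tri, bary = cell.mesh.locate(np.array([[3.0, 0.0]]))
            stri, sbary = sub.mesh.locate(np.array([[3.0, 0.0]]))
            springs.add(tri, bary, np.array([[3.0, 0.0]]), stri, sbary,
                        np.zeros((1, 2)), np.array([1.0]), 0.0)
        cell.phi[:] = 0.0
        cell.phi[np.argmin(np.linalg.norm(cell.mesh.nodes - [3.0, 0.0], axis=1))] = 0.6
        microtubule_prune(cell, springs, p, site_radius=2.5)
        # one removal empties the φ ≥ 0.5 patch; the lowest id went first
        assert not springs.active[0]
        assert springs.active[1]
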