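"""Focal-adhesion dynamics: the φ field, spring registry, and FA rules.

The FA complex is a nodal volume-fraction field φ on the cell mesh that
grows where the average bulk (hydrostatic) stress σ̄ = (σ_xx + σ_yy)/2 is
compressive,

    ∂φ/∂t = k_σ tanh(-k₂ σ̄) H(-σ̄),

and is clamped to [0, 1]. Wherever φ ≥ 0.5 the cell is attached to the
substrate by linear springs; springs are born stretch-free (u_a snapshots
the cell displacement at binding), rupture at a critical stretch in the
weak-FA mode, and are pruned from the cell center outward when the FA area
exceeds a critical fraction of the cell area (a microtubule-mediated
disassembly proxy), resetting the local φ to 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cell import CellState
from .mesh import TriMesh
from .substrate import SubstrateState


@dataclass
class AdhesionParams:
    """FA evolution and spring parameters (μm / kPa / min / nN units)."""

    k_sigma: float = 360.0          # min⁻¹, φ growth rate scale
    k_2: float = 1.0                # kPa⁻¹, stress feedback inside tanh
    phi_threshold: float = 0.5      # φ level at/above which springs exist
    rupture_stretch: float = math.inf  # μm; ∞ = strong (non-rupturing) FAs
    critical_area_ratio: float = 0.3   # FA area / cell area cap
    phi_reset: float = 0.2          # φ after microtubule-mediated removal
    k_a: float = 0.5                # nN/μm per spring (5e-5 dyn/μm)
    rho_ref: float = 1.0            # reference spring density, μm⁻²
    #: If True, u_a at binding absorbs the current substrate displacement so
    #: the spring is born with exactly zero extension — the behavior of
    #: ruptured weak FAs, which "immediately reattach (with zero stretch)".
    #: If None (default), this is resolved per scenario: True in weak
    #: (rupturing) mode, False in strong mode, where binding snapshots only
    #: the cell displacement and the substrate displacement at attachment is
    #: neglected as small.
    bind_absorbs_substrate_displacement: bool | None = None

    def resolve_bind_convention(self) -> bool:
        if self.bind_absorbs_substrate_displacement is None:
            return self.weak
        return self.bind_absorbs_substrate_displacement

    def __post_init__(self):
        if self.k_sigma <= 0 or self.k_2 <= 0 or self.k_a <= 0 or self.rho_ref <= 0:
            raise ValueError("adhesion rate/stiffness parameters must be positive")
        if not (0.0 < self.phi_threshold < 1.0):
            raise ValueError("phi_threshold must lie in (0, 1)")
        if not self.rupture_stretch > 0:
            raise ValueError("rupture_stretch must be positive (inf for strong FAs)")
        if not (0.0 < self.critical_area_ratio <= 1.0):
            raise ValueError("critical_area_ratio must lie in (0, 1]")

    @property
    def weak(self) -> bool:
        return math.isfinite(self.rupture_stretch)


def average_bulk_stress(sigma: np.ndarray) -> np.ndarray:
    """σ̄ = (σ_xx + σ_yy)/2 per element (the hydrostatic stress), kPa."""
    sigma = np.atleast_2d(sigma)
    return 0.5 * (sigma[:, 0] + sigma[:, 1])


def phi_rate(sigma_bar, params: AdhesionParams):
    """dφ/dt = k_σ tanh(-k₂ σ̄) H(-σ̄); zero under tension, never negative."""
    sigma_bar = np.asarray(sigma_bar, dtype=float)
    rate = np.where(
        sigma_bar < 0.0, params.k_sigma * np.tanh(-params.k_2 * sigma_bar), 0.0
    )
    return rate if rate.ndim else float(rate)


def nodal_bulk_stress(mesh: TriMesh, sigma_bar_elem: np.ndarray) -> np.ndarray:
    """Area-weighted average of adjacent element σ̄ values at each node."""
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    w = np.repeat(mesh.areas, 3)
    np.add.at(num, mesh.triangles.ravel(), np.repeat(sigma_bar_elem * mesh.areas, 3))
    np.add.at(den, mesh.triangles.ravel(), w)
    return num / den


def advance_phi(phi: np.ndarray, mesh: TriMesh, sigma_bar_elem: np.ndarray,
                dt: float, params: AdhesionParams) -> np.ndarray:
    """Forward-Euler update of φ, clamped to [0, 1]."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    sb = nodal_bulk_stress(mesh, sigma_bar_elem)
    return np.clip(phi + dt * phi_rate(sb, params), 0.0, 1.0)


def total_fa_area(phi: np.ndarray, mesh: TriMesh) -> float:
    """Area where φ ≥ 0.5: Σ triangle area × (fraction of nodes above)."""
    above = (np.asarray(phi)[mesh.triangles] >= 0.5).sum(axis=1)
    return float((mesh.areas * above / 3.0).sum())


def initialize_fa_layout(mesh: TriMesh, R: float, n_patches: int,
                         patch_area: float, phi_seed: float = 0.6,
                         phase: float = 0.0) -> np.ndarray:
    """Seed φ in circular patches equispaced on a ring of radius R (μm).

    φ = phi_seed inside the patches (above the 0.5 spring threshold, below
    saturation) and 0 elsewhere.
    """
    phi = np.zeros(mesh.n_nodes)
    if n_patches == 0:
        return phi
    r_patch = math.sqrt(patch_area / math.pi)
    angles = phase + 2 * np.pi * np.arange(n_patches) / n_patches
    centers = np.column_stack([R * np.cos(angles), R * np.sin(angles)])
    d = np.linalg.norm(mesh.nodes[:, None, :] - centers[None, :, :], axis=2)
    phi[(d <= r_patch).any(axis=1)] = phi_seed
    return phi


class SpringSet:
    """Registry of FA springs (struct-of-arrays, append-only with an
    active mask).

    Cell anchors are material points (triangle id + barycentric weights on
    the current cell mesh); substrate anchors are fixed physical points x_s
    cached with their containing substrate triangle. u_a is the cell
    displacement at binding time, so the spring extension is
    u_c(anchor) - u_a - u_s(x_s) and every spring is born with zero stretch.
    """

    def __init__(self):
        self.cell_tri = np.zeros(0, dtype=np.int64)
        self.cell_bary = np.zeros((0, 3))
        self.x_s = np.zeros((0, 2))
        self.sub_tri = np.zeros(0, dtype=np.int64)
        self.sub_bary = np.zeros((0, 3))
        self.u_a = np.zeros((0, 2))
        self.k_eff = np.zeros(0)
        self.birth = np.zeros(0)
        self.active = np.zeros(0, dtype=bool)

    def __len__(self) -> int:
        return len(self.cell_tri)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_indices(self) -> np.ndarray:
        """Indices of active springs in id (creation) order."""
        return np.flatnonzero(self.active)

    def add(self, cell_tri, cell_bary, x_s, sub_tri, sub_bary, u_a, k_eff, birth):
        m = len(np.atleast_1d(cell_tri))
        self.cell_tri = np.concatenate([self.cell_tri, np.atleast_1d(cell_tri)])
        self.cell_bary = np.vstack([self.cell_bary, np.atleast_2d(cell_bary)])
        self.x_s = np.vstack([self.x_s, np.atleast_2d(x_s)])
        self.sub_tri = np.concatenate([self.sub_tri, np.atleast_1d(sub_tri)])
        self.sub_bary = np.vstack([self.sub_bary, np.atleast_2d(sub_bary)])
        self.u_a = np.vstack([self.u_a, np.atleast_2d(u_a)])
        self.k_eff = np.concatenate([self.k_eff, np.atleast_1d(k_eff)])
        self.birth = np.concatenate([self.birth, np.full(m, birth, dtype=float)])
        self.active = np.concatenate([self.active, np.ones(m, dtype=bool)])

    def deactivate(self, indices) -> None:
        self.active[np.asarray(indices, dtype=np.int64)] = False

    # -- geometry and forces -------------------------------------------------

    def anchor_positions(self, cell_mesh: TriMesh, idx=None) -> np.ndarray:
        idx = self.active_indices() if idx is None else np.asarray(idx)
        nodes = cell_mesh.triangles[self.cell_tri[idx]]
        return np.einsum("sk,sk...->s...", self.cell_bary[idx], cell_mesh.nodes[nodes])

    def u_c_at_anchors(self, cell: CellState, idx=None) -> np.ndarray:
        idx = self.active_indices() if idx is None else np.asarray(idx)
        nodes = cell.mesh.triangles[self.cell_tri[idx]]
        return np.einsum("sk,sk...->s...", self.cell_bary[idx], cell.u[nodes])

    def u_s_at_anchors(self, substrate: SubstrateState, idx=None) -> np.ndarray:
        idx = self.active_indices() if idx is None else np.asarray(idx)
        nodes = substrate.mesh.triangles[self.sub_tri[idx]]
        return np.einsum("sk,sk...->s...", self.sub_bary[idx], substrate.u[nodes])

    def extensions(self, cell: CellState, substrate: SubstrateState,
                   idx=None) -> np.ndarray:
        """Per-spring extension vectors u_c - u_a - u_s (μm)."""
        idx = self.active_indices() if idx is None else np.asarray(idx)
        return (
            self.u_c_at_anchors(cell, idx)
            - self.u_a[idx]
            - self.u_s_at_anchors(substrate, idx)
        )

    def stretches(self, cell: CellState, substrate: SubstrateState,
                  idx=None) -> np.ndarray:
        return np.linalg.norm(self.extensions(cell, substrate, idx), axis=1)

    def forces_on_substrate(self, cell: CellState, substrate: SubstrateState,
                            idx=None) -> np.ndarray:
        """k(u_c - u_a - u_s) per spring, nN. Forces on the cell are the
        exact negatives (shared spring objects: Newton's third law)."""
        idx = self.active_indices() if idx is None else np.asarray(idx)
        return self.k_eff[idx, None] * self.extensions(cell, substrate, idx)

    def relocalize(self, anchor_positions: np.ndarray, new_mesh: TriMesh) -> int:
        """Rebind all cell anchors to a new mesh at unchanged physical points.

        ``anchor_positions`` must be the anchors' physical positions on the
        old mesh for *all* springs (active and not). Anchors falling outside
        the new mesh are snapped to the nearest point on it; the number of
        snapped anchors is returned.
        """
        if len(self) == 0:
            return 0
        tri, bary = new_mesh.locate(anchor_positions, strict=False)
        outside = new_mesh.find_triangles(anchor_positions) < 0
        self.cell_tri = tri
        self.cell_bary = bary
        return int(outside.sum())


def rupture_springs(springs: SpringSet, cell: CellState,
                    substrate: SubstrateState, params: AdhesionParams) -> int:
    """Deactivate springs stretched beyond the rupture threshold.

    No-op for strong FAs (infinite threshold). A ruptured site whose φ is
    still ≥ 0.5 re-binds at the next population update with fresh u_a and
    x_s, i.e. it reattaches with zero stretch.
    """
    if not params.weak or springs.n_active == 0:
        return 0
    idx = springs.active_indices()
    s = springs.stretches(cell, substrate, idx)
    broken = idx[s > params.rupture_stretch]
    springs.deactivate(broken)
    return len(broken)


def update_spring_population(
    cell: CellState,
    substrate: SubstrateState,
    springs: SpringSet,
    params: AdhesionParams,
    site_radius: float,
) -> tuple[int, int]:
    """Create/remove springs according to the φ ≥ 0.5 rule.

    Candidate sites are cell-mesh nodes. A node with φ ≥ 0.5 spawns a new
    spring unless an active anchor already lies within ``site_radius`` (the
    anchors of surviving springs keep representing that patch of membrane
    after remeshing). Springs whose local φ has fallen below 0.5 are
    removed. New springs bind the substrate at the node's current physical
    position with u_a equal to the current cell displacement there — zero
    stretch at birth. Effective stiffness k_a × tributary area × ρ_ref.

    Returns (n_created, n_removed).
    """
    thr = params.phi_threshold
    # (b) removal where φ dropped below threshold
    removed = 0
    idx = springs.active_indices()
    if len(idx):
        pos = springs.anchor_positions(cell.mesh, idx)
        phi_at = cell.mesh.interpolate(cell.phi, pos)
        drop = idx[phi_at < thr]
        springs.deactivate(drop)
        removed = len(drop)

    # (a) creation at unoccupied sites
    candidates = np.flatnonzero(cell.phi >= thr)
    if len(candidates) == 0:
        return 0, removed
    idx = springs.active_indices()
    cand_pos = cell.mesh.nodes[candidates]
    if len(idx):
        occ = springs.anchor_positions(cell.mesh, idx)
        tree = cKDTree(occ)
        d, _ = tree.query(cand_pos)
        candidates = candidates[d > site_radius]
        cand_pos = cell.mesh.nodes[candidates]
    if len(candidates) == 0:
        return 0, removed

    # a node's containing triangle: first incident triangle, vertex weights
    node_tri = np.full(cell.mesh.n_nodes, -1, dtype=np.int64)
    node_slot = np.zeros(cell.mesh.n_nodes, dtype=np.int64)
    for k in range(3):
        node_tri[cell.mesh.triangles[:, k]] = np.arange(cell.mesh.n_triangles)
        node_slot[cell.mesh.triangles[:, k]] = k

    inside = substrate.mesh.find_triangles(cand_pos) >= 0
    candidates, cand_pos = candidates[inside], cand_pos[inside]
    if len(candidates) == 0:
        return 0, removed
    sub_tri, sub_bary = substrate.mesh.locate(cand_pos, strict=True)

    bary = np.zeros((len(candidates), 3))
    bary[np.arange(len(candidates)), node_slot[candidates]] = 1.0
    k_eff = params.k_a * cell.mesh.tributary_areas[candidates] * params.rho_ref
    u_a = cell.u[candidates]
    if params.resolve_bind_convention():
        u_s_at = np.einsum(
            "sk,sk...->s...", sub_bary, substrate.u[substrate.mesh.triangles[sub_tri]]
        )
        u_a = u_a - u_s_at
    springs.add(
        cell_tri=node_tri[candidates],
        cell_bary=bary,
        x_s=cand_pos,
        sub_tri=sub_tri,
        sub_bary=sub_bary,
        u_a=u_a,
        k_eff=k_eff,
        birth=cell.time,
    )
    return len(candidates), removed


def microtubule_prune(cell: CellState, springs: SpringSet,
                      params: AdhesionParams, site_radius: float) -> int:
    """Enforce the critical FA-cell area ratio by center-out spring removal.

    While the φ ≥ 0.5 area exceeds the cap, the active spring nearest the
    cell centroid is removed (ties broken by lowest spring id) and φ is
    lowered to 0.2 over the patch of nodes that spring represented (within
    ``site_radius`` of its anchor), modeling disassembly of the whole local
    FA complex. Returns the number of springs removed.
    """
    mesh = cell.mesh
    area_cell = mesh.total_area
    centroid = (mesh.tributary_areas @ mesh.nodes) / area_cell
    removed = 0
    while True:
        fa = total_fa_area(cell.phi, mesh)
        if fa / area_cell <= params.critical_area_ratio:
            break
        idx = springs.active_indices()
        if len(idx) == 0:
            break
        pos = springs.anchor_positions(mesh, idx)
        d = np.linalg.norm(pos - centroid, axis=1)
        k = int(np.argmin(d))  # first minimum → lowest id on ties
        springs.deactivate(idx[k])
        near = np.linalg.norm(mesh.nodes - pos[k], axis=1) <= site_radius
        cell.phi[near] = np.minimum(cell.phi[near], params.phi_reset)
        removed += 1
    return removed
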