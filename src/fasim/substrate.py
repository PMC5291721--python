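"""Quasi-static linear-elastic substrate loaded by FA spring forces.

The substrate mesh is a fixed reference configuration with zero
displacement clamped on its outer boundary; deformations stay small, so it
is never remeshed. Because each spring force k(u_c - u_a - u_s) depends on
the substrate displacement at the anchor, the spring stiffness is folded
into the system matrix and the solve is exact (no inner iteration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .materials import ElasticMaterial
from .mesh import TriMesh


@dataclass
class SubstrateState:
    mesh: TriMesh
    material: ElasticMaterial
    u: np.ndarray = None  # (N, 2) μm

    def __post_init__(self):
        if self.u is None:
            self.u = np.zeros((self.mesh.n_nodes, 2))
        self._free = np.ones(2 * self.mesh.n_nodes, dtype=bool)
        fixed = self.mesh.boundary
        self._free[2 * fixed] = False
        self._free[2 * fixed + 1] = False
        K = fem.assemble_stiffness(self.mesh, self.material.stiffness)
        D = sp.diags(self._free.astype(float))
        self._K_bc = (D @ K @ D + sp.diags((~self._free).astype(float))).tocsr()

    @property
    def free_dof_mask(self) -> np.ndarray:
        return self._free


def solve_substrate(state: SubstrateState, springs, u_c_at_anchors: np.ndarray,
                    in_place: bool = False) -> np.ndarray:
    """Solve the clamped substrate under the current spring loads.

    ``u_c_at_anchors`` is the cell displacement at each active spring's
    anchor (in the same order as ``springs.active_indices()``). Returns the
    nodal displacement field (N, 2); with ``in_place`` it is also stored on
    the state.
    """
    n = 2 * state.mesh.n_nodes
    idx = springs.active_indices() if springs is not None else np.array([], int)
    if len(idx) == 0:
        u = np.zeros((state.mesh.n_nodes, 2))
        if in_place:
            state.u = u
        return u
    tri = springs.sub_tri[idx]
    bary = springs.sub_bary[idx]
    k_eff = springs.k_eff[idx]
    u_a = springs.u_a[idx]
    nodes = state.mesh.triangles[tri]                     # (S, 3)
    free = state._free

    rows, cols, vals = [], [], []
    f = np.zeros(n)
    pull = k_eff[:, None] * (u_c_at_anchors - u_a)        # (S, 2)
    for comp in (0, 1):
        dof = 2 * nodes + comp
        w = bary * free[dof]                              # zero weight on clamped dofs
        rows.append(np.repeat(dof, 3, axis=1).ravel())
        cols.append(np.tile(dof, (1, 3)).ravel())
        vals.append((k_eff[:, None, None] * w[:, :, None] * w[:, None, :]).ravel())
        np.add.at(f, dof.ravel(), (w * pull[:, [comp]]).ravel())
    Ks = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    K = (state._K_bc + Ks).tocsc()
    f[~free] = 0.0
    u = spla.spsolve(K, f).reshape(-1, 2)
    if in_place:
        state.u = u
    return u


def max_substrate_displacement(state: SubstrateState) -> float:
    """Max over nodes of |u_s|, μm."""
    return float(np.linalg.norm(state.u, axis=1).max(initial=0.0))


def traction_field(mesh: TriMesh, anchor_tri: np.ndarray, anchor_bary: np.ndarray,
                   forces: np.ndarray):
    """Nodal traction from spring forces on the substrate.

    Forces (nN) are lumped to the anchor triangles' nodes by barycentric
    weights and divided by nodal tributary areas (μm²), giving kPa.

    Returns (vectors (N, 2), magnitudes (N,)). The identity
    Σ_nodes traction × tributary_area = Σ forces holds exactly.
    """
    f = np.zeros((mesh.n_nodes, 2))
    if len(anchor_tri):
        nodes = mesh.triangles[anchor_tri]
        for comp in (0, 1):
            np.add.at(
                f[:, comp], nodes.ravel(), (anchor_bary * forces[:, [comp]]).ravel()
            )
    t = f / mesh.tributary_areas[:, None]
    return t, np.linalg.norm(t, axis=1)
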