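"""Constant-strain-triangle plane-stress machinery.

Displacement DOFs are ordered (u0x, u0y, u1x, u1y, ...). Strains use the
Voigt convention (ε_xx, ε_yy, γ_xy) with engineering shear, matching
:func:`fasim.materials.plane_stress_stiffness`.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import ElasticMaterial
from .mesh import TriMesh


class SingularSystemError(RuntimeError):
    """The assembled system is rank deficient (unconstrained rigid modes)."""


def element_b_matrices(mesh: TriMesh):
    """Per-element strain-displacement matrices.

    Returns
    -------
    B : (M, 3, 6) array with ε = B @ u_e for element DOFs
        (u1x, u1y, u2x, u2y, u3x, u3y)
    areas : (M,) element areas
    """
    p = mesh.nodes[mesh.triangles]
    x, y = p[..., 0], p[..., 1]
    areas = mesh.areas
    # b_i = y_j - y_k ; c_i = x_k - x_j  (cyclic)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    B = np.zeros((mesh.n_triangles, 3, 6))
    B[:, 0, 0::2] = b
    B[:, 1, 1::2] = c
    B[:, 2, 0::2] = c
    B[:, 2, 1::2] = b
    B /= (2.0 * areas)[:, None, None]
    return B, areas


def velocity_gradients(mesh: TriMesh, v: np.ndarray) -> np.ndarray:
    """Per-element velocity gradient L_ij = ∂v_i/∂x_j, shape (M, 2, 2)."""
    B, _ = element_b_matrices(mesh)
    # B rows give shape-function gradients: dN_k/dx = B[0, 2k], dN_k/dy = B[2, 2k]
    dndx = B[:, 0, 0::2]
    dndy = B[:, 1, 1::2]
    ve = v[mesh.triangles]  # (M, 3, 2)
    L = np.empty((mesh.n_triangles, 2, 2))
    L[:, 0, 0] = np.einsum("mk,mk->m", dndx, ve[..., 0])
    L[:, 0, 1] = np.einsum("mk,mk->m", dndy, ve[..., 0])
    L[:, 1, 0] = np.einsum("mk,mk->m", dndx, ve[..., 1])
    L[:, 1, 1] = np.einsum("mk,mk->m", dndy, ve[..., 1])
    return L


def _gradient_operator(mesh: TriMesh) -> np.ndarray:
    """Per-element operator G with (H_xx, H_xy, H_yx, H_yy) = G @ u_e,
    H = ∇du. Shape (M, 4, 6)."""
    B, _ = element_b_matrices(mesh)
    dndx = B[:, 0, 0::2]
    dndy = B[:, 1, 1::2]
    G = np.zeros((mesh.n_triangles, 4, 6))
    G[:, 0, 0::2] = dndx
    G[:, 1, 0::2] = dndy
    G[:, 2, 1::2] = dndx
    G[:, 3, 1::2] = dndy
    return G


def convective_voigt_map(sigma: np.ndarray) -> np.ndarray:
    """Per-element M(σ) with (Hσ + σHᵀ) in Voigt order = M @ vec(H).

    vec(H) = (H_xx, H_xy, H_yx, H_yy). Shape (M, 3, 4).
    """
    sigma = np.atleast_2d(sigma)
    M = np.zeros((len(sigma), 3, 4))
    sxx, syy, sxy = sigma[:, 0], sigma[:, 1], sigma[:, 2]
    M[:, 0, 0] = 2 * sxx
    M[:, 0, 1] = 2 * sxy
    M[:, 1, 2] = 2 * sxy
    M[:, 1, 3] = 2 * syy
    M[:, 2, 0] = sxy
    M[:, 2, 1] = syy
    M[:, 2, 2] = sxx
    M[:, 2, 3] = sxy
    return M


def assemble_stiffness(mesh: TriMesh, C: np.ndarray,
                       sigma_conv: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble Σ_e A_e B_eᵀ C B_e as a sparse (2N, 2N) operator.

    With ``sigma_conv`` an additional (nonsymmetric) block
    A_e B_eᵀ M(σ_e) G_e is added per element: the contribution of the
    Oldroyd convective terms ∇du σ + σ ∇ᵀdu, linear in the increment.
    """
    B, areas = element_b_matrices(mesh)
    Ke = areas[:, None, None] * np.einsum("eji,jk,ekl->eil", B, C, B)
    if sigma_conv is not None:
        G = _gradient_operator(mesh)
        M = convective_voigt_map(sigma_conv)
        Ke = Ke + areas[:, None, None] * np.einsum("eji,ejk,ekl->eil", B, M, G)
    dof = np.empty((mesh.n_triangles, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes)
    )
    return K.tocsr()


def internal_forces(mesh: TriMesh, sigma: np.ndarray) -> np.ndarray:
    """Nodal internal force vector Σ_e A_e B_eᵀ σ_e, shape (2N,)."""
    B, areas = element_b_matrices(mesh)
    fe = areas[:, None] * np.einsum("eji,ej->ei", B, sigma)
    f = np.zeros(2 * mesh.n_nodes)
    dof = np.empty((mesh.n_triangles, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.triangles
    dof[:, 1::2] = 2 * mesh.triangles + 1
    np.add.at(f, dof.ravel(), fe.ravel())
    return f


def lump_point_loads(mesh: TriMesh, loads) -> np.ndarray:
    """Distribute point loads to nodes by barycentric weights.

    ``loads`` is an iterable of (location (2,), force (2,) nN) pairs.
    Raises :class:`OutOfDomainError` for a load outside the mesh.
    """
    f = np.zeros(2 * mesh.n_nodes)
    loads = list(loads)
    if not loads:
        return f
    pts = np.array([p for p, _ in loads], float)
    forces = np.array([q for _, q in loads], float)
    tri_idx, bary = mesh.locate(pts, strict=True)
    for t, w, force in zip(tri_idx, bary, forces):
        for node, wk in zip(mesh.triangles[t], w):
            f[2 * node] += wk * force[0]
            f[2 * node + 1] += wk * force[1]
    return f


def apply_dirichlet(K: sp.csr_matrix, f: np.ndarray, fixed_nodes) -> tuple:
    """Zero-displacement constraints: eliminate rows/cols, unit diagonal."""
    fixed_nodes = np.asarray(list(fixed_nodes), dtype=np.int64)
    fixed_dof = np.concatenate([2 * fixed_nodes, 2 * fixed_nodes + 1])
    mask = np.ones(K.shape[0], dtype=bool)
    mask[fixed_dof] = False
    D = sp.diags(mask.astype(float))
    Kbc = D @ K @ D + sp.diags((~mask).astype(float))
    fbc = np.where(mask, f, 0.0)
    return Kbc.tocsr(), fbc


def assemble_linear_elastic_system(
    mesh: TriMesh,
    material: ElasticMaterial,
    point_loads=(),
    fixed_nodes=(),
    allow_singular: bool = False,
):
    """Stiffness operator and load vector for a clamped plane-stress body.

    Point loads (nN) are lumped onto the containing triangle's nodes by
    barycentric weights; Dirichlet rows are eliminated.
    """
    fixed_nodes = list(fixed_nodes)
    if not fixed_nodes and not allow_singular:
        raise SingularSystemError(
            "no fixed nodes: rigid-body modes make the system singular"
        )
    K = assemble_stiffness(mesh, material.stiffness)
    f = lump_point_loads(mesh, point_loads)
    if fixed_nodes:
        K, f = apply_dirichlet(K, f, fixed_nodes)
    return K, f


def solve(K: sp.csr_matrix, f: np.ndarray) -> np.ndarray:
    """Direct sparse solve; returns nodal displacements shaped (N, 2)."""
    u = spla.spsolve(K.tocsc(), f)
    if not np.all(np.isfinite(u)):
        raise SingularSystemError("linear solve produced non-finite values")
    return u.reshape(-1, 2)


def solve_with_rigid_constraints(
    K: sp.csr_matrix, f: np.ndarray, mesh: TriMesh, modes: str = "all"
) -> np.ndarray:
    """Solve a floating (traction-free) system with rigid modes projected out.

    Lagrange constraints force zero mean translation and/or zero mean
    rotation about the area centroid. ``modes`` is "all" (tx, ty, rot) or
    "rotation" (rotation only, e.g. when one spring already pins
    translations).
    """
    n = K.shape[0]
    cx = (mesh.tributary_areas @ mesh.nodes) / mesh.total_area
    rows = []
    if modes == "all":
        tx = np.zeros(n)
        tx[0::2] = 1.0
        ty = np.zeros(n)
        ty[1::2] = 1.0
        rows += [tx, ty]
    rot = np.zeros(n)
    rot[0::2] = -(mesh.nodes[:, 1] - cx[1])
    rot[1::2] = mesh.nodes[:, 0] - cx[0]
    rows.append(rot)
    Cmat = sp.csr_matrix(np.array(rows))
    m = Cmat.shape[0]
    A = sp.bmat([[K, Cmat.T], [Cmat, None]], format="csc")
    rhs = np.concatenate([f, np.zeros(m)])
    sol = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(sol)):
        raise SingularSystemError("constrained solve produced non-finite values")
    return sol[:n].reshape(-1, 2)
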