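"""Hypoelastic cell mechanics.

The cell is a 2D plane-stress hypoelastic body on a moving Lagrangian mesh.
Its rate constitutive law relates the Oldroyd (upper-convected) stress rate
to the passive part of the rate of deformation,

    dσ/dt - ∇v σ - σ ∇ᵀv = C_c : (D - D^A),

where D = sym ∇v and D^A = α I is the prescribed isotropic active rate
(α > 0 spreading, α < 0 contraction). Focal-adhesion springs enter the
quasi-static equilibrium as point forces -k(u_c - u_a - u_s) at their cell
anchors. The cell boundary is traction free; rigid-body modes are projected
out via Lagrange constraints when the springs do not pin them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import fem
from .mesh import TriMesh


class StepFailureError(RuntimeError):
    """The per-step fixed-point iteration failed to converge."""


#: Cap (min⁻¹) on the per-element lagged velocity-gradient norm entering the
#: convective stress terms; an order of magnitude above the active rates
#: |α| ≤ 0.00725 min⁻¹, so it never binds in smooth operation.
CONVECTIVE_RATE_CAP = 0.05


@dataclass(frozen=True)
class ActiveDeformation:
    """Spatially uniform isotropic active rate of deformation, D^A = α I."""

    alpha: float  # min⁻¹; > 0 spreading, < 0 contraction

    @property
    def voigt(self) -> np.ndarray:
        return np.array([self.alpha, self.alpha, 0.0])


@dataclass
class CellState:
    """Cell on its current-configuration mesh.

    u is total displacement accumulated from the t = 0 configuration (the
    same quantity snapshotted as u_a when a spring binds), v the velocity of
    the last step, sigma the per-element Cauchy stress in Voigt order
    (σ_xx, σ_yy, σ_xy), phi the nodal FA volume fraction.
    """

    mesh: TriMesh
    u: np.ndarray          # (N, 2) μm
    v: np.ndarray          # (N, 2) μm/min
    sigma: np.ndarray      # (M, 3) kPa
    phi: np.ndarray        # (N,)
    time: float = 0.0      # min

    @classmethod
    def initial(cls, mesh: TriMesh, phi: np.ndarray | None = None) -> "CellState":
        return cls(
            mesh=mesh,
            u=np.zeros((mesh.n_nodes, 2)),
            v=np.zeros((mesh.n_nodes, 2)),
            sigma=np.zeros((mesh.n_triangles, 3)),
            phi=np.zeros(mesh.n_nodes) if phi is None else np.asarray(phi, float),
            time=0.0,
        )


def cell_area(state: CellState) -> float:
    """Current (deformed) cell spread area, μm²."""
    return state.mesh.total_area


def total_rate_of_deformation(mesh: TriMesh, v: np.ndarray) -> np.ndarray:
    """Per-element D = sym ∇v as 2×2 tensors, shape (M, 2, 2)."""
    L = fem.velocity_gradients(mesh, v)
    return 0.5 * (L + np.transpose(L, (0, 2, 1)))


def _convective(sigma_voigt: np.ndarray, L: np.ndarray) -> np.ndarray:
    """∇v σ + σ ∇ᵀv in Voigt order for per-element stresses."""
    s = np.empty((len(sigma_voigt), 2, 2))
    s[:, 0, 0] = sigma_voigt[:, 0]
    s[:, 1, 1] = sigma_voigt[:, 1]
    s[:, 0, 1] = s[:, 1, 0] = sigma_voigt[:, 2]
    c = L @ s + s @ np.transpose(L, (0, 2, 1))
    return np.stack([c[:, 0, 0], c[:, 1, 1], c[:, 0, 1]], axis=1)


def hypoelastic_stress_update(
    sigma_old: np.ndarray,
    grad_v: np.ndarray,
    D_voigt: np.ndarray,
    D_A_voigt: np.ndarray,
    C: np.ndarray,
    dt: float,
) -> np.ndarray:
    """One-step stress update of the rate law.

    The elastic term uses the strain increment dt·D of the current iterate
    (implicit within the step's fixed point); the convective terms use the
    lagged velocity gradient and the old stress (explicit).

    Parameters are per-element arrays: sigma_old (M, 3) Voigt, grad_v
    (M, 2, 2), D_voigt (M, 3) with engineering shear rate, D_A_voigt (3,).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    conv = _convective(sigma_old, grad_v)
    dstrain = dt * (D_voigt - D_A_voigt[None, :])
    return sigma_old + dt * conv + dstrain @ C.T


def _rate_of_deformation_voigt(mesh: TriMesh, v: np.ndarray) -> np.ndarray:
    """(D_xx, D_yy, 2 D_xy) per element — Voigt with engineering shear."""
    L = fem.velocity_gradients(mesh, v)
    return np.stack(
        [L[:, 0, 0], L[:, 1, 1], L[:, 0, 1] + L[:, 1, 0]], axis=1
    )


class CellStepSolver:
    """Per-step linear solver for the cell equilibrium.

    Geometry, stiffness, spring topology and rigid-mode constraints are
    frozen at the start of the step; each sweep only changes the right-hand
    side (lagged convective stress and the current substrate displacement).
    """

    def __init__(self, state: CellState, springs, active: ActiveDeformation,
                 dt: float, C: np.ndarray):
        self.state = state
        self.active = active
        self.dt = dt
        self.C = C
        mesh = state.mesh
        self.K = fem.assemble_stiffness(mesh, C)
        # Convective (Oldroyd) terms lagged one step: evaluated with the
        # previous step's converged velocity. Their per-step magnitude is
        # O(dt |∇v| |σ|), far below the elastic increment at the slow active
        # rates modeled here, and the lag keeps the tangent SPD even when
        # compressive stresses are comparable to the cell modulus. The
        # lagged gradient is capped at a physical rate scale so that a
        # transient local rearrangement (e.g. the rebound after a spring
        # removal) cannot feed a spurious convective stress increment.
        self.L_lag = fem.velocity_gradients(mesh, state.v)
        cap = CONVECTIVE_RATE_CAP
        norms = np.linalg.norm(self.L_lag.reshape(len(self.L_lag), 4), axis=1)
        factor = np.minimum(1.0, cap / np.maximum(norms, 1e-30))
        self.L_lag = self.L_lag * factor[:, None, None]
        self.conv_lag = _convective(state.sigma, self.L_lag)
        n = 2 * mesh.n_nodes

        idx = springs.active_indices() if springs is not None else np.array([], int)
        self.spring_idx = idx
        if len(idx):
            tri = springs.cell_tri[idx]
            bary = springs.cell_bary[idx]
            self.anchor_nodes = mesh.triangles[tri]           # (S, 3)
            self.anchor_bary = bary                           # (S, 3)
            self.k_eff = springs.k_eff[idx]
            self.u_a = springs.u_a[idx]
            self.u_c_old = np.einsum(
                "sk,sk...->s...", bary, state.u[self.anchor_nodes]
            )
            self.anchor_pos = np.einsum(
                "sk,sk...->s...", bary, mesh.nodes[self.anchor_nodes]
            )
            rows, cols, vals = [], [], []
            for comp in (0, 1):
                dof = 2 * self.anchor_nodes + comp            # (S, 3)
                rows.append(np.repeat(dof, 3, axis=1).ravel())
                cols.append(np.tile(dof, (1, 3)).ravel())
                vals.append(
                    (
                        self.k_eff[:, None, None]
                        * bary[:, :, None]
                        * bary[:, None, :]
                    ).ravel()
                )
            Ks = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(n, n),
            )
            self.K = (self.K + Ks).tocsr()
        else:
            self.anchor_pos = np.zeros((0, 2))
            self.u_c_old = np.zeros((0, 2))

        # rigid-mode constraints depending on how many distinct anchors carry
        # actual stiffness
        live = self.anchor_pos[self.k_eff > 0] if len(idx) else np.zeros((0, 2))
        distinct = 0
        if len(live):
            span = np.ptp(live, axis=0).max() if len(live) > 1 else 0.0
            distinct = len(live) if (len(live) > 1 and span > 1e-9) else 1
        if distinct >= 2:
            self._constraints = None
        else:
            mode = "rotation" if distinct == 1 else "all"
            self._constraints = self._constraint_matrix(mesh, mode)
        self._factor = None

    @staticmethod
    def _constraint_matrix(mesh: TriMesh, mode: str) -> sp.csr_matrix:
        n = 2 * mesh.n_nodes
        cx = (mesh.tributary_areas @ mesh.nodes) / mesh.total_area
        rows = []
        if mode == "all":
            tx = np.zeros(n)
            tx[0::2] = 1.0
            ty = np.zeros(n)
            ty[1::2] = 1.0
            rows += [tx, ty]
        rot = np.zeros(n)
        rot[0::2] = -(mesh.nodes[:, 1] - cx[1])
        rot[1::2] = mesh.nodes[:, 0] - cx[0]
        rows.append(rot)
        return sp.csr_matrix(np.array(rows))

    def _factorize(self):
        if self._factor is None:
            if self._constraints is not None:
                Cm = self._constraints
                A = sp.bmat([[self.K, Cm.T], [Cm, None]], format="csc")
                self._nlag = Cm.shape[0]
            else:
                A = self.K.tocsc()
                self._nlag = 0
            self._factor = spla.splu(A)
        return self._factor

    def fixed_rhs(self) -> np.ndarray:
        """RHS terms independent of the substrate displacement: the old
        stress plus its lagged convective increment, the active-deformation
        stress increment, and the spring pre-load -k(u_c_old - u_a)."""
        state, dt, mesh = self.state, self.dt, self.state.mesh
        sigma_fixed = (
            state.sigma
            + dt * self.conv_lag
            - dt * (self.active.voigt @ self.C.T)[None, :]
        )
        f = -fem.internal_forces(mesh, sigma_fixed)
        if len(self.spring_idx):
            fs = -(self.k_eff[:, None] * (self.u_c_old - self.u_a))
            for comp in (0, 1):
                dof = 2 * self.anchor_nodes + comp
                np.add.at(f, dof.ravel(), (self.anchor_bary * fs[:, [comp]]).ravel())
        return f

    def updated_stress(self, du: np.ndarray) -> np.ndarray:
        """Hypoelastic stress consistent with the solved increment du (same
        lagged convective increment the equilibrium solve saw)."""
        state, dt, mesh = self.state, self.dt, self.state.mesh
        D_voigt = _rate_of_deformation_voigt(mesh, du / dt)
        return hypoelastic_stress_update(
            state.sigma, self.L_lag, D_voigt, self.active.voigt, self.C, dt
        )

    def sweep(self, u_s_at_anchors: np.ndarray):
        """Solve the cell step with a frozen substrate displacement.

        Returns (du, sigma_new): the incremental displacement over the step
        and the hypoelastically updated stress consistent with it. Exact in
        one solve — the convective terms sit in the tangent.
        """
        mesh = self.state.mesh
        f = self.fixed_rhs()
        if len(self.spring_idx):
            fs = self.k_eff[:, None] * u_s_at_anchors
            for comp in (0, 1):
                dof = 2 * self.anchor_nodes + comp
                np.add.at(f, dof.ravel(), (self.anchor_bary * fs[:, [comp]]).ravel())
        self._factorize()
        sol = self._factor.solve(
            np.concatenate([f, np.zeros(self._nlag)]) if self._nlag else f
        )
        du = sol[: 2 * mesh.n_nodes].reshape(-1, 2)
        return du, self.updated_stress(du)

    def du_at_anchors(self, du: np.ndarray) -> np.ndarray:
        if not len(self.spring_idx):
            return np.zeros((0, 2))
        return np.einsum("sk,sk...->s...", self.anchor_bary, du[self.anchor_nodes])


def apply_increment(state: CellState, du: np.ndarray, sigma_new: np.ndarray,
                    dt: float) -> CellState:
    """Advect the mesh by du and install the updated fields."""
    from .mesh import _signed_areas

    if np.any(_signed_areas(state.mesh.nodes + du, state.mesh.triangles) <= 0):
        raise StepFailureError("displacement increment inverted a mesh element")
    return CellState(
        mesh=state.mesh.with_nodes(state.mesh.nodes + du),
        u=state.u + du,
        v=du / dt,
        sigma=sigma_new,
        phi=state.phi,
        time=state.time + dt,
    )


def solve_cell_equilibrium(
    state: CellState,
    springs,
    active: ActiveDeformation,
    dt: float,
    C: np.ndarray,
    u_s_at_anchors: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> CellState:
    """Advance the cell one step against a frozen substrate displacement.

    The elastic term, the spring stiffness, and the convective (Oldroyd)
    terms — all linear in the increment — are solved implicitly in a single
    linear system. Used standalone in tests and single-body scenarios; the
    coupled driver solves the cell and substrate monolithically instead.
    """
    solver = CellStepSolver(state, springs, active, dt, C)
    if u_s_at_anchors is None:
        u_s_at_anchors = np.zeros_like(solver.u_c_old)
    du, sigma_new = solver.sweep(u_s_at_anchors)
    return apply_increment(state, du, sigma_new, dt)
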