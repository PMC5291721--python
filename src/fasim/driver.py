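"""Scenario configuration, staggered time integration, and sweeps.

Each time step solves the coupled quasi-static cell/substrate system by
Gauss–Seidel alternation (cell solve with the current substrate
displacement, substrate solve with the current cell displacement) until the
inter-sweep change in both displacement fields falls below the coupling
tolerance, then applies the FA sub-steps in fixed order: φ advance
(forward difference) → stretch rupture → spring population update →
microtubule pruning. The cell mesh is rebuilt at a fixed step cadence so
that runs being compared are remeshed the same number of times.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import adhesions, metrics as metricsmod, remesh
from .adhesions import AdhesionParams, SpringSet
from .cell import ActiveDeformation, CellState, CellStepSolver, StepFailureError, apply_increment
from .materials import ElasticMaterial
from .mesh import (
    build_disc_mesh,
    build_square_mesh,
    build_triangle_mesh,
    mesh_quality,
    shape_quality,
)
from .substrate import SubstrateState


@dataclass
class ScenarioConfig:
    """Complete description of one simulation run (μm / kPa / min / nN)."""

    # geometry
    cell_shape: str = "disc"            # "disc" | "triangle"
    cell_radius: float = 10.0           # μm (disc)
    cell_edge: float = 30.0             # μm (equilateral triangle edge)
    cell_mesh_edge: float = 1.0         # μm target element edge
    substrate_shape: str = "square"     # "square" | "disc"
    substrate_size: float = 120.0       # μm: side (square) or diameter (disc)
    substrate_mesh_edge: float = 3.0    # μm

    # materials
    E_c: float = 0.5                    # kPa
    E_s: float = 1.0                    # kPa
    nu: float = 0.3

    # active deformation
    alpha: float = 0.00725              # min⁻¹

    # adhesion parameters
    k_a: float = 0.5                    # nN/μm  (5e-5 dyn/μm)
    rho_ref: float = 1.0                # μm⁻² reference spring density
    k_sigma: float = 360.0              # min⁻¹
    k_2: float = 1.0                    # kPa⁻¹
    rupture_stretch: float | None = None  # μm; None = strong FAs
    critical_area_ratio: float = 0.3
    phi_reset: float = 0.2

    # initial FA layout
    fa_radius: float = 7.0              # μm ring radius R
    n_patches: int = 8
    patch_area: float = 3.14            # μm² per patch
    phi_seed: float = 0.6
    layout_phase: float = 0.0           # rad, rotates the patch ring

    # numerics
    dt: float = 0.25                    # min
    duration: float = 90.0              # min
    remesh_every: int = 20              # steps
    coupling_tol: float = 1e-4          # μm
    max_sweeps: int = 50
    output_every: int = 4               # steps between metric samples
    plateau_stop: bool = False          # stop early when max|u_s| plateaus
    plateau_window: float = 10.0        # min
    plateau_rtol: float = 0.01
    seed: int = 0                       # reserved for mesher jitter
    vtk_dir: str | None = None

    def __post_init__(self):
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("need dt > 0 and duration >= 0")
        if self.coupling_tol <= 0:
            raise ValueError("coupling tolerance must be positive")

    # -- convenience ---------------------------------------------------------

    def adhesion_params(self) -> AdhesionParams:
        return AdhesionParams(
            k_sigma=self.k_sigma,
            k_2=self.k_2,
            rupture_stretch=(
                math.inf if self.rupture_stretch is None else self.rupture_stretch
            ),
            critical_area_ratio=self.critical_area_ratio,
            phi_reset=self.phi_reset,
            k_a=self.k_a,
            rho_ref=self.rho_ref,
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# -- presets -----------------------------------------------------------------


def smc_island_preset(**overrides) -> ScenarioConfig:
    """Spreading smooth-muscle cell on a clamped 50-μm circular island.

    Soft cell (0.5 kPa) on a soft gel (1 kPa), strong (non-rupturing) FAs,
    120 min of spreading at α = 0.00725 min⁻¹.
    """
    cfg = ScenarioConfig(
        cell_shape="disc",
        cell_radius=10.0,
        cell_mesh_edge=1.0,
        substrate_shape="disc",
        substrate_size=50.0,
        substrate_mesh_edge=1.6,
        E_c=0.5,
        E_s=1.0,
        alpha=0.00725,
        rupture_stretch=None,
        critical_area_ratio=0.3,
        fa_radius=7.0,
        n_patches=8,
        patch_area=3.14,
        duration=120.0,
    )
    return replace(cfg, **overrides)


def cardiomyocyte_preset(**overrides) -> ScenarioConfig:
    """Contracting cardiomyocyte: stiff triangular cell on a 15 kPa substrate.

    α = -0.001 min⁻¹, weak FAs rupturing at 0.4 μm stretch, run until the
    maximum substrate displacement plateaus. Initial FA patches sit near the
    three cell corners (0.7 × circumradius).
    """
    edge = 30.0
    cfg = ScenarioConfig(
        cell_shape="triangle",
        cell_edge=edge,
        cell_mesh_edge=1.5,
        substrate_shape="square",
        substrate_size=90.0,
        substrate_mesh_edge=1.5,
        E_c=20.0,
        E_s=15.0,
        alpha=-0.001,
        rupture_stretch=0.4,
        critical_area_ratio=0.3,
        fa_radius=0.7 * edge / math.sqrt(3.0),
        n_patches=3,
        patch_area=3.14,
        layout_phase=math.pi / 2.0,  # patches toward the triangle corners
        duration=300.0,
        plateau_stop=True,
        plateau_window=20.0,
    )
    return replace(cfg, **overrides)


def spreading_sweep_preset(**overrides) -> ScenarioConfig:
    """Base config for the central/peripheral FA sweeps (90 min spreading).

    The cell modulus is 1 kPa: with a fully adhered cell the mean
    compressive stress after time t is bounded by |α| t E_c/(1-ν), and the
    reported sweep stress levels sit just inside that bound for E_c = 1 kPa
    (the stated E_c range is 0.5-20 kPa without a sweep-specific value).
    """
    cfg = ScenarioConfig(
        cell_shape="disc",
        cell_radius=10.0,
        cell_mesh_edge=1.0,
        substrate_shape="square",
        substrate_size=120.0,
        substrate_mesh_edge=3.0,
        E_c=1.0,
        E_s=2.5,
        alpha=0.00725,
        rupture_stretch=None,
        critical_area_ratio=0.3,
        fa_radius=7.0,
        n_patches=8,
        patch_area=3.14,
        duration=90.0,
    )
    return replace(cfg, **overrides)


# -- state construction ------------------------------------------------------


def build_states(cfg: ScenarioConfig):
    """Meshes, initial cell/substrate states and the (empty) spring set."""
    if cfg.cell_shape == "disc":
        cmesh = build_disc_mesh(cfg.cell_radius, cfg.cell_mesh_edge)
    elif cfg.cell_shape == "triangle":
        cmesh = build_triangle_mesh(cfg.cell_edge, cfg.cell_mesh_edge)
    else:
        raise ValueError(f"unknown cell shape {cfg.cell_shape!r}")
    if cfg.substrate_shape == "square":
        smesh = build_square_mesh(cfg.substrate_size, cfg.substrate_mesh_edge)
    elif cfg.substrate_shape == "disc":
        smesh = build_disc_mesh(cfg.substrate_size / 2.0, cfg.substrate_mesh_edge)
    else:
        raise ValueError(f"unknown substrate shape {cfg.substrate_shape!r}")

    phi0 = adhesions.initialize_fa_layout(
        cmesh, cfg.fa_radius, cfg.n_patches, cfg.patch_area,
        phi_seed=cfg.phi_seed, phase=cfg.layout_phase,
    )
    cell = CellState.initial(cmesh, phi=phi0)
    sub = SubstrateState(smesh, ElasticMaterial(cfg.E_s, cfg.nu))
    springs = SpringSet()
    return cell, sub, springs


@dataclass
class RunResult:
    """Time series of metrics plus the final coupled state."""

    metrics: pd.DataFrame
    cell: CellState
    substrate: SubstrateState
    springs: SpringSet
    config: ScenarioConfig
    log: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)


# -- time stepping -----------------------------------------------------------


def _coupled_operator(solver: CellStepSolver, sub: SubstrateState,
                      springs: SpringSet):
    """Monolithic operator for (du_cell, u_s [, Lagrange multipliers]).

    The cell and substrate blocks each carry the spring stiffness at their
    own anchors; the off-diagonal blocks -k N_c N_sᵀ couple the two bodies.
    Assembled once per step and factorized; only the lagged convective load
    changes between iterations.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    idx = solver.spring_idx
    nc = solver.K.shape[0]
    ns = 2 * sub.mesh.n_nodes
    free = sub.free_dof_mask

    if len(idx):
        sub_nodes = sub.mesh.triangles[springs.sub_tri[idx]]
        sub_bary = springs.sub_bary[idx]
        k_eff = springs.k_eff[idx]
        rows_ss, cols_ss, vals_ss = [], [], []
        rows_cs, cols_cs, vals_cs = [], [], []
        for comp in (0, 1):
            sdof = 2 * sub_nodes + comp
            ws = sub_bary * free[sdof]          # clamped substrate dofs drop out
            cdof = 2 * solver.anchor_nodes + comp
            wc = solver.anchor_bary
            rows_ss.append(np.repeat(sdof, 3, axis=1).ravel())
            cols_ss.append(np.tile(sdof, (1, 3)).ravel())
            vals_ss.append(
                (k_eff[:, None, None] * ws[:, :, None] * ws[:, None, :]).ravel()
            )
            rows_cs.append(np.repeat(cdof, 3, axis=1).ravel())
            cols_cs.append(np.tile(sdof, (1, 3)).ravel())
            vals_cs.append(
                (-k_eff[:, None, None] * wc[:, :, None] * ws[:, None, :]).ravel()
            )
        Kss = sp.coo_matrix(
            (np.concatenate(vals_ss), (np.concatenate(rows_ss), np.concatenate(cols_ss))),
            shape=(ns, ns),
        )
        Kcs = sp.coo_matrix(
            (np.concatenate(vals_cs), (np.concatenate(rows_cs), np.concatenate(cols_cs))),
            shape=(nc, ns),
        )
        K_sub = (sub._K_bc + Kss).tocsr()
    else:
        Kcs = sp.coo_matrix((nc, ns))
        K_sub = sub._K_bc
    blocks = [[solver.K, Kcs], [Kcs.T, K_sub]]
    if solver._constraints is not None:
        Cm = solver._constraints
        blocks[0].append(Cm.T)
        blocks[1].append(None)
        blocks.append([Cm, None, None])
    A = sp.bmat(blocks, format="csc")
    return spla.splu(A), nc, ns


def _substrate_rhs(solver: CellStepSolver, sub: SubstrateState,
                   springs: SpringSet) -> np.ndarray:
    ns = 2 * sub.mesh.n_nodes
    f = np.zeros(ns)
    idx = solver.spring_idx
    if len(idx):
        sub_nodes = sub.mesh.triangles[springs.sub_tri[idx]]
        pull = springs.k_eff[idx, None] * (solver.u_c_old - springs.u_a[idx])
        free = sub.free_dof_mask
        for comp in (0, 1):
            sdof = 2 * sub_nodes + comp
            ws = springs.sub_bary[idx] * free[sdof]
            np.add.at(f, sdof.ravel(), (ws * pull[:, [comp]]).ravel())
    return f


def coupled_step(cell: CellState, sub: SubstrateState, springs: SpringSet,
                 cfg: ScenarioConfig, C_c: np.ndarray, dt: float):
    """One step of the coupled system.

    The cell/substrate/spring equilibrium is solved monolithically (exact
    two-field coupling); the fixed point iterates only over the lagged
    convective stress term. Returns (new_cell, sweep_count); the substrate
    state and spring set are updated in place.
    """
    active = ActiveDeformation(cfg.alpha)
    params = cfg.adhesion_params()
    solver = CellStepSolver(cell, springs, active, dt, C_c)
    lu, nc, ns = _coupled_operator(solver, sub, springs)
    f_sub = _substrate_rhs(solver, sub, springs)
    nlag = lu.shape[0] - nc - ns

    f_cell = solver.fixed_rhs()
    rhs = np.concatenate([f_cell, f_sub, np.zeros(nlag)])
    sol = lu.solve(rhs)
    if not np.all(np.isfinite(sol)):
        raise StepFailureError("coupled solve produced non-finite displacements")
    du = sol[:nc].reshape(-1, 2)
    u_s_new = sol[nc:nc + ns].reshape(-1, 2)

    # Incremental application: a sudden spring removal releases stored
    # elastic energy, and the quasi-static rebound can exceed the element
    # size. Scale the increment back so no element inverts or loses more
    # than 80 % of its area; the remaining imbalance is carried as stress
    # state and recovered by the next step's equilibrium solve.
    from .mesh import _signed_areas

    a0 = cell.mesh.areas
    s = 1.0
    for _ in range(24):
        a1 = _signed_areas(cell.mesh.nodes + s * du, cell.mesh.triangles)
        if np.all(a1 > 0.2 * a0):
            break
        s *= 0.7
    else:
        raise StepFailureError("could not find a non-inverting increment")
    du = s * du
    u_s_new = s * u_s_new + (1.0 - s) * sub.u
    sigma_new = solver.updated_stress(du)
    sweeps = 1

    new_cell = apply_increment(cell, du, sigma_new, dt)
    sub.u = u_s_new

    # FA sub-steps: φ advance → rupture → populate → prune
    sigma_bar = adhesions.average_bulk_stress(new_cell.sigma)
    new_cell.phi = adhesions.advance_phi(
        new_cell.phi, new_cell.mesh, sigma_bar, dt, params
    )
    site_radius = 0.55 * cfg.cell_mesh_edge
    adhesions.rupture_springs(springs, new_cell, sub, params)
    adhesions.update_spring_population(new_cell, sub, springs, params, site_radius)
    adhesions.microtubule_prune(new_cell, springs, params, site_radius)
    return new_cell, sweeps


def _remesh_cell(cell: CellState, springs: SpringSet, cfg: ScenarioConfig):
    """Rebuild the cell mesh over its deformed boundary, transfer fields,
    and re-localize spring anchors at unchanged physical points."""
    anchor_pos = (
        springs.anchor_positions(cell.mesh, np.arange(len(springs)))
        if len(springs)
        else np.zeros((0, 2))
    )
    new_mesh, nodal, elem = remesh.remesh_and_transfer(
        cell.mesh,
        {"u": cell.u, "v": cell.v, "phi": cell.phi},
        {"sigma": cell.sigma},
        cfg.cell_mesh_edge,
    )
    snapped = springs.relocalize(anchor_pos, new_mesh) if len(springs) else 0
    new_cell = CellState(
        mesh=new_mesh,
        u=nodal["u"],
        v=nodal["v"],
        sigma=elem["sigma"],
        phi=np.clip(nodal["phi"], 0.0, 1.0),
        time=cell.time,
    )
    return new_cell, snapped


def run_scenario(cfg: ScenarioConfig, progress: bool = False) -> RunResult:
    """Run one scenario to its duration (or displacement plateau)."""
    cell, sub, springs = build_states(cfg)
    C_c = ElasticMaterial(cfg.E_c, cfg.nu).stiffness
    params = cfg.adhesion_params()
    site_radius = 0.55 * cfg.cell_mesh_edge
    log: list[str] = []
    snapshots: list[str] = []

    # initial spring population from the seeded φ layout
    adhesions.update_spring_population(cell, sub, springs, params, site_radius)
    rows = [metricsmod.collect_metrics(cell, sub, springs, params)]

    vtk_dir = Path(cfg.vtk_dir) if cfg.vtk_dir else None
    if vtk_dir:
        vtk_dir.mkdir(parents=True, exist_ok=True)
        snapshots += metricsmod.write_snapshot(vtk_dir, 0, cell, sub, springs)

    n_steps = int(round(cfg.duration / cfg.dt))
    us_history = [(0.0, rows[0]["max_substrate_displacement"])]
    for step in range(1, n_steps + 1):
        if cfg.remesh_every > 0 and step % cfg.remesh_every == 0:
            cell, snapped = _remesh_cell(cell, springs, cfg)
            if snapped:
                log.append(f"step {step}: {snapped} anchors snapped to boundary")
        # attempt the step, halving dt on nonconvergence (up to 3 times)
        for halving in range(4):
            n_sub = 2**halving
            dt_sub = cfg.dt / n_sub
            try:
                trial = cell
                for _ in range(n_sub):
                    trial, sweeps = coupled_step(trial, sub, springs, cfg, C_c, dt_sub)
                cell = trial
                if halving:
                    log.append(f"step {step}: converged with dt/{n_sub}")
                break
            except StepFailureError:
                if halving == 3:
                    log.append(f"step {step}: aborted (nonconvergence)")
                    df = pd.DataFrame(rows)
                    return RunResult(df, cell, sub, springs, cfg, log, snapshots)
        # quality-triggered remeshing fallback between the fixed-cadence ones
        critical = 0.25 * (2.0 / cfg.cell_mesh_edge)
        q = mesh_quality(cell.mesh, critical)
        shape_q = shape_quality(cell.mesh)
        if q.remesh_needed or shape_q < 0.15:
            cell, snapped = _remesh_cell(cell, springs, cfg)
            log.append(f"step {step}: quality-triggered remesh "
                       f"(altitude ratio {q.min_ratio:.3f}, shape {shape_q:.3f})")
        log.append(
            f"step {step} t={cell.time:.2f} sweeps={sweeps} "
            f"springs={springs.n_active} min_quality={q.min_ratio:.3f}"
        )
        if step % cfg.output_every == 0 or step == n_steps:
            row = metricsmod.collect_metrics(cell, sub, springs, params)
            rows.append(row)
            us_history.append((cell.time, row["max_substrate_displacement"]))
            if vtk_dir:
                snapshots += metricsmod.write_snapshot(vtk_dir, step, cell, sub, springs)
            if progress:
                print(
                    f"  t={cell.time:6.1f} min  max|u_s|="
                    f"{row['max_substrate_displacement']:.4f} μm  "
                    f"springs={springs.n_active}"
                )
            if cfg.plateau_stop and _plateaued(us_history, cfg):
                log.append(f"step {step}: plateau reached, stopping early")
                break
    return RunResult(pd.DataFrame(rows), cell, sub, springs, cfg, log, snapshots)


def _plateaued(history, cfg: ScenarioConfig) -> bool:
    """True when the running peak of max|u_s| has stopped growing.

    Spring ruptures make the raw signal saw-toothed, so the plateau is
    declared on the cumulative maximum: no more than plateau_rtol relative
    growth over the trailing plateau_window minutes.
    """
    t_now, u_now = history[-1]
    if t_now < 2 * cfg.plateau_window:
        return False
    peak_now = max(u for _, u in history)
    past = [u for t, u in history if t <= t_now - cfg.plateau_window]
    if not past or peak_now <= 0:
        return False
    peak_past = max(past)
    return peak_now <= peak_past * (1.0 + cfg.plateau_rtol)


# -- sweeps ------------------------------------------------------------------

_AXIS_FIELDS = {
    "E_s", "critical_area_ratio", "fa_radius", "rupture_stretch", "E_c", "alpha",
}


def run_sweep(base: ScenarioConfig, axes: dict, progress: bool = False
              ) -> pd.DataFrame:
    """Cross-product of runs over the given config axes.

    ``axes`` maps ScenarioConfig field names (e.g. ``E_s``,
    ``critical_area_ratio``) to value lists. Each run goes to the base
    config's duration; one row of end-state metrics per run. Failed runs are
    recorded with ``error`` set and the sweep continues.
    """
    if not axes:
        raise ValueError("axes must be nonempty")
    bad = set(axes) - _AXIS_FIELDS
    if bad:
        raise ValueError(f"unsupported sweep axes: {sorted(bad)}")
    names = list(axes)
    rows = []
    for values in itertools.product(*(axes[n] for n in names)):
        cfg = replace(base, **dict(zip(names, values)))
        row = {n: v for n, v in zip(names, values)}
        try:
            res = run_scenario(cfg, progress=progress)
            end = res.metrics.iloc[-1].to_dict()
            end.pop("time", None)
            row.update(end)
            row["time"] = res.metrics.iloc[-1]["time"]
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - record and continue
            row["error"] = str(exc)
        rows.append(row)
        if progress:
            print(dict(row))
    return pd.DataFrame(rows)
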