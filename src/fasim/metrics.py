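"""Derived quantities and tabular/VTK export.

Metrics follow the global read-outs of the model: maximum substrate
displacement, area-weighted mean bulk stress over the cell (negative =
compression), cell spread area, total FA area and its ratio to cell area,
total spring force, and the maximum FA traction magnitude. Radial profiles
average φ and σ̄ in annular rings about the cell centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import vtkio
from .adhesions import AdhesionParams, SpringSet, average_bulk_stress, total_fa_area
from .cell import CellState
from .substrate import SubstrateState, max_substrate_displacement, traction_field


def mean_bulk_stress(cell: CellState) -> float:
    """Area-weighted mean of element σ̄ over the cell (kPa)."""
    sb = average_bulk_stress(cell.sigma)
    return float((cell.mesh.areas * sb).sum() / cell.mesh.total_area)


def substrate_tractions(cell: CellState, sub: SubstrateState, springs: SpringSet):
    """Nodal traction vectors and magnitudes on the substrate (kPa)."""
    idx = springs.active_indices()
    forces = springs.forces_on_substrate(cell, sub, idx)
    return traction_field(sub.mesh, springs.sub_tri[idx], springs.sub_bary[idx], forces)


def collect_metrics(cell: CellState, sub: SubstrateState, springs: SpringSet,
                    params: AdhesionParams) -> dict:
    """One metrics row for the current coupled state."""
    fa = total_fa_area(cell.phi, cell.mesh)
    area = cell.mesh.total_area
    idx = springs.active_indices()
    forces = springs.forces_on_substrate(cell, sub, idx)
    total_f = forces.sum(axis=0) if len(forces) else np.zeros(2)
    _, tmag = substrate_tractions(cell, sub, springs)
    return {
        "time": cell.time,
        "max_substrate_displacement": max_substrate_displacement(sub),
        "mean_bulk_stress": mean_bulk_stress(cell),
        "cell_area": area,
        "total_fa_area": fa,
        "fa_cell_ratio": fa / area,
        "n_springs": springs.n_active,
        "spring_force_x": float(total_f[0]),
        "spring_force_y": float(total_f[1]),
        "spring_force_mag": float(np.linalg.norm(total_f)),
        # unsigned total: Σ|f_i| does not cancel for symmetric layouts
        "spring_force_abs_sum": float(
            np.linalg.norm(forces, axis=1).sum() if len(forces) else 0.0
        ),
        "max_traction": float(tmag.max(initial=0.0)),
    }


@dataclass
class RadialProfile:
    """Ring-averaged φ and σ̄ about the cell centroid."""

    r_centers: np.ndarray   # μm
    delta_r: float          # μm
    mean_phi: np.ndarray
    mean_sigma_bar: np.ndarray  # kPa
    ring_areas: np.ndarray  # μm² of cell material per ring


def radial_profile(cell: CellState, delta_r: float = 0.5) -> RadialProfile:
    """Area-weighted ring averages of φ and σ̄, rings of width Δr.

    Element samples (centroid radius, area weight) are binned over
    [0, R_max]; element φ is the mean of its nodal values.
    """
    if delta_r <= 0:
        raise ValueError("delta_r must be positive")
    mesh = cell.mesh
    centroid = (mesh.tributary_areas @ mesh.nodes) / mesh.total_area
    r = np.linalg.norm(mesh.centroids - centroid, axis=1)
    r_max = r.max() + 1e-12
    n_rings = max(1, int(np.ceil(r_max / delta_r)))
    bins = np.minimum((r / delta_r).astype(int), n_rings - 1)
    areas = mesh.areas
    phi_e = cell.phi[mesh.triangles].mean(axis=1)
    sb = average_bulk_stress(cell.sigma)
    ring_area = np.bincount(bins, weights=areas, minlength=n_rings)
    with np.errstate(invalid="ignore"):
        mean_phi = np.bincount(bins, weights=areas * phi_e, minlength=n_rings) / ring_area
        mean_sb = np.bincount(bins, weights=areas * sb, minlength=n_rings) / ring_area
    centers = (np.arange(n_rings) + 0.5) * delta_r
    return RadialProfile(centers, delta_r, mean_phi, mean_sb, ring_area)


def radial_compressive_force(profile: RadialProfile) -> pd.DataFrame:
    """Compressive force carried per ring, inward-to-outward cumulative.

    Per ring: |min(σ̄, 0)| averaged over the ring × ring area / 2π (the
    area integral of the compressive bulk stress averaged over the angle);
    compression is reported positive. The unnormalized area integral is
    also returned.
    """
    comp = np.abs(np.minimum(np.nan_to_num(profile.mean_sigma_bar), 0.0))
    integral = comp * profile.ring_areas          # nN (kPa·μm²)
    per_ring = integral / (2.0 * np.pi)
    return pd.DataFrame(
        {
            "r": profile.r_centers,
            "compressive_force": per_ring,
            "cumulative_force": np.cumsum(per_ring),
            "area_integral": integral,
        }
    )


def export_tables(result_or_df, out_dir, prefix: str = "run") -> list:
    """Write tidy CSVs: a sweep table or a per-run time series."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = result_or_df if isinstance(result_or_df, pd.DataFrame) else result_or_df.metrics
    path = out / f"{prefix}.csv"
    df.to_csv(path, index=False)
    return [str(path)]


def write_snapshot(out_dir, step: int, cell: CellState, sub: SubstrateState,
                   springs: SpringSet) -> list:
    """VTK snapshots of the cell and substrate states."""
    out = Path(out_dir)
    tvec, tmag = substrate_tractions(cell, sub, springs)
    sb = average_bulk_stress(cell.sigma)
    cpath = out / f"cell_{step:05d}.vtk"
    spath = out / f"substrate_{step:05d}.vtk"
    vtkio.write_vtk(
        cpath,
        cell.mesh,
        point_data={"u_c": cell.u, "v_c": cell.v, "phi": cell.phi},
        cell_data={
            "sigma_xx": cell.sigma[:, 0],
            "sigma_yy": cell.sigma[:, 1],
            "sigma_xy": cell.sigma[:, 2],
            "sigma_bar": sb,
        },
    )
    vtkio.write_vtk(
        spath,
        sub.mesh,
        point_data={"u_s": sub.u, "traction": tvec, "traction_mag": tmag},
    )
    return [str(cpath), str(spath)]
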